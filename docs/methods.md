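# Methods

## The measurement model

Bistranded phosphorothioate (PT) modification at a GAAC/GTTC duplex site is
converted by iodine into a double-strand break with strand-specific 5′
ends. With the motif window at 0-based positions `[s, s+4)` on the forward
strand, the cleavage geometry is fixed by the chemistry: the forward strand
is cut after the modified G, so the downstream fragment's forward 5′ end
sits at `s+1` (its read begins `AAC` or `TTC`); the complementary-strand
cut leaves the upstream fragment's reverse 5′ end at forward coordinate
`s+2`. End repair fills the two-nucleotide 5′ overhang, so both fragments
retain the overhang bases and the 5′ ends are preserved exactly — ended-read
matching is therefore exact-coordinate by default (a configurable slack
exists for noisy aligners but is 0 everywhere in this package).

Per site, aligned reads are classified as:

* **ended (forward)** — `+`-strand reads starting exactly at `s+1`;
* **ended (reverse)** — `−`-strand reads whose 5′-terminal base is exactly
  `s+2`;
* **spanning** — reads whose alignment covers the whole window `[s, s+4)`.

Reads covering only part of the window carry no information about the cut
and count as neither. The two ended classes are geometrically disjoint from
the spanning class (a forward ended read starts one base inside the window;
a reverse ended read stops one base short of its end), so
`depth = ended + spanning` without double counting. Strands are pooled for
the ratio; per-strand counts are kept for diagnostics.

The per-site frequency proxy is `ratio = ended / (ended + spanning)`,
undefined (status `no_coverage`, never 0) at depth 0: an unobserved site is
not an unmodified site.

### Detection

Random shearing creates false ends. The detection threshold is the
arithmetic mean of the pseudo-ratios of `n_controls = 10` uniformly sampled
non-GAAC/GTTC 4-bp windows scored with the identical geometry
(rejection-sampled against motif membership and N-containing windows,
seeded, persisted to JSON for reproducibility). A site passes with
`ratio > threshold`, strictly. Under the default simulated conditions the
threshold lands near 0.5–0.8% — below 1%, the false-detection magnitude
reported for real libraries.

Threshold-count (ICDS-style) detection calls a site modified when
`ended >= min_ended` (default 50; "reached" is the operational reading of
the rule, so the comparison is `>=`). Depth saturation uses nested
subsampling: for target depth D, `N = round(D·L/read_length)` reads are
drawn without replacement, with deeper samples supersets of shallower ones,
so detected-site curves are monotone by construction and any non-monotonic
step would indicate a counting bug, not sampling noise.

## The simulator

`ptmap.simulate` emulates exactly the generative process the estimator
assumes:

1. `n_molecules` full-length linear copies of the genome (default: 50-kb
   random genome at GC 0.5, 500 molecules ≈ 600× read coverage — mid-range
   of the 200–1000× depths the saturation analysis operates over).
2. Independent per-molecule, per-site cleavage with probability `f_i`.
   True frequencies come either from an explicit list or from a two-band
   mixture (60% of sites Beta-distributed in [0, 0.05), the rest in
   [0.05, 0.40)), reflecting the observed predominance of low-frequency
   sites and the absence of sites above ~40% in sequenced genomes.
3. Sonication: recursive uniform breakpoints until every fragment is
   ≤ 350 bp, then size selection discards fragments < 150 bp. The real
   protocol states only the 150–350 bp window; recursive uniform breakage
   is this package's model of it.
4. Error-free reads from both fragment ends (paired mode), truncated to
   150 bp, with true alignment coordinates emitted as a TSV so
   quantification runs aligner-free; FASTQ is also written for optional
   real-aligner integration. A per-end capture probability (default 1.0)
   allows exploring unequal recovery of the two fragments flanking a cut.

Fragment ends carry provenance (`terminus`/`iodine`/`shear`); iodine ends
occur only at cleavage coordinates, and with shearing disabled and `f = 0`
no read 5′ end can fall on any cleavage coordinate at all (cleavage
coordinates are strictly interior to the molecule), which is why the
frequency extremes are exact: `f = 0` gives ratio exactly 0 at every
covered site and `f = 1` exactly 1.

### The estimator is biased, and the oracle knows by how much

A double-strand cut contributes up to **two** ended reads (one from each
flanking fragment), while an uncut molecule contributes spanning reads in
proportion to read-coverage geometry; the raw ratio therefore overestimates
small `f` (roughly `2f / (2f + c(1−f))` with `c` ≈ spanning reads per
molecule, before size-selection effects). Rather than silently correcting
this, the estimator is implemented exactly as the assay defines it, and
`expected_ratio(f, config)` provides a Monte-Carlo calibration oracle: the
expected ratio under identical library geometry at a single planted site,
with a batch-means standard error. Recovery tests compare estimates with
this oracle (within 3 combined standard errors, where the per-site estimate
standard error is a binomial term inflated by √2 for the within-molecule
correlation of the two reads per fragment) and require Spearman rank
correlation > 0.95 between truth and estimate at ~600× depth. What passing
shows: the counting, geometry and threshold logic are exact, and the
estimator is monotone and calibrated under its own generative assumptions.
What it does not show: robustness to alignment artifacts, PCR/GC bias,
incomplete iodine conversion, or single-stranded PT (the assay chemistry
only cleaves bistranded sites) — none of which the simulator models.

## ddPCR quantification

Droplet occupancy is Poisson: `λ = −ln(1 − k/n)` copies per droplet,
`conc = λ / v` copies/µl with droplet volume `v = 0.85 nl` (QX200 nominal;
it cancels in the paired-arm frequency but not in copies/µl, so it is a
visible parameter), `copies_total = conc × 20 µl`. Wells with fewer than
10,000 accepted droplets are excluded; no-template-control wells never
enter the arms (positives there are logged as contamination). Saturated
wells (`k = n`) raise rather than returning an infinite estimate.

The paired assay aggregates per-well concentrations over QC-passing
replicates (mean by default, median optionally) into X (iodine arm,
unmodified survivors) and Y (mock arm, total), with
`frequency = (Y − X)/Y`, clamped to [0, 1] with a flag when sampling noise
near `f ≈ 0` drives the raw value negative.

Standard-curve diagnostics regress measured on expected concentration on
`log10(c + 1)` axes (the +1 offset retained exactly as the assay defines
it) and report per-level RSD% on raw concentrations with a 25% pass limit.
Numerical choices for the simulated diagnostics: the round-trip check uses
the mean of nine replicate wells per level (triplicate wells repeated on
three days, as the assay is actually run), because at 10⁶ droplets the
single-well binomial error at the lowest of four decades (~1.1%) exceeds
the 1% recovery target by itself; the dilution series uses six 5-fold
levels (3 → 9,375 copies/µl), since 20,000 droplets quantify roughly 3.5
decades between Poisson saturation (λ ≳ 8) and counting noise (λ ≲ 0.003).

## Reports

* Frequency histograms use left-closed, right-open 5%-wide bins up to 40%.
* Region summaries classify each site by its window-start base with
  precedence ORF > ncRNA > noncoding (exclusive assignment, so category
  denominators partition the site total); the promoter subset is the
  user-supplied promoter BED or, by default, the 250 bp upstream of each
  ORF start (strand-aware) intersected with noncoding — promoter
  annotations are never inferable from sequence alone, so this default is
  explicit in every output. "Modified" means ratio strictly > 5%.
* Every percentage names its denominator (`detected_sites` vs
  `all_motif_sites`): the fraction of low-frequency sites, in particular,
  differs sharply between the two conventions.
* `pt_per_million` is the frequency-weighted site density
  `Σ f_i / L × 10⁶` per strand — directly comparable to LC-MS/MS
  d(G_ps_A)/d(G_ps_T) per-nucleotide densities, because a site modified in
  a fraction f of molecules contributes f PT linkages per genome copy on
  each strand.
* The flanking-consensus search orients all sites as GAAC-centred
  (reverse-complementing GTTC windows), builds a position frequency matrix
  over ±5 bp, and calls consensus at ≥ 90% base frequency; with hundreds
  of sites and random flanks the chance of a spurious call is ≪ 10⁻⁶.

## Coordinates, rounding, degenerate inputs

Internally everything is 0-based half-open; report TSVs print 1-based loci;
BED output is 0-based per the standard. Report percentages round to one
decimal (two for overlap percentages) while machine-readable outputs retain
full precision. Circular replicons are scanned linearly by default; a flag
enables junction-spanning windows (output headers record which was used).
Empty categories report "not applicable" rather than 0%. Ratios at depth 0
are undefined, excluded from histograms, and counted separately.

## Problem sizes

Simulation-backed checks run on 17–50 kb genomes at ~600× equivalent
coverage (≈ 10⁵–2×10⁵ reads) — sizes at which the exact brute-force
oracles remain feasible while every statistical assertion has comfortable
power. All randomness flows from explicit seeds; identical configuration
and seed give byte-identical outputs.
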