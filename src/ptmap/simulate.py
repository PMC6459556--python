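"""Synthetic-data generator for iodine-cleavage sequencing.

The generative model mirrors what the quantification method assumes about a
real library:

1. A population of full-length genomic molecules.
2. Each bistranded GAAC/GTTC site is iodine-cleaved independently on each
   molecule with that site's true modification frequency ``f``.  A cut is a
   double-strand break whose ends, after repair, place the downstream
   fragment's forward 5' end at ``start0 + 1`` and the upstream fragment's
   reverse 5' end at ``start0 + 2`` (the two fragments share the repaired
   2-nt overhang).
3. Random sonication: fragments are recursively broken at uniform positions
   until no fragment exceeds ``max_frag``; fragments shorter than
   ``min_frag`` are then discarded (size selection).  Defaults 150-350 bp.
4. Read emission: one read from each fragment end (paired mode), truncated
   to ``read_length``, error-free, with the true alignment recorded so the
   quantification can run aligner-free.

Note the raw PT ratio is *not* an unbiased estimator of ``f``: one cut
yields up to two ended reads (one per flanking fragment) while an uncut
molecule yields spanning reads according to coverage geometry.  The
:func:`expected_ratio` Monte-Carlo oracle characterises the mapping
``f -> E[ratio]`` under identical conditions so estimates can be compared
with truth on the estimator's own scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .quantify import AlignedRead, count_sites, pt_ratio
from .reference import MOTIF_LEN, PT_MOTIFS, Genome, MotifSite, revcomp, scan_motifs

#: Fragment-end provenance labels.
TERMINUS, IODINE, SHEAR = "terminus", "iodine", "shear"


@dataclass
class SimConfig:
    """Study conditions for a simulated PT-IC-seq experiment.

    Frequencies above 0.40 are not generated by the default mixture: in
    sequenced genomes every detected site was partially modified below that
    level.  ``p_low`` controls the fraction of sites in the low band
    [0, 0.05); the rest fall in [0.05, 0.40).
    """

    genome_length: int = 50_000
    gc: float = 0.5
    n_molecules: int = 500
    read_length: int = 150
    paired: bool = True
    min_frag: int = 150
    max_frag: int = 350
    shear_enabled: bool = True
    capture_prob: float = 1.0
    seed: int = 0
    # mixture frequency model
    p_low: float = 0.6
    beta_low: tuple[float, float] = (1.5, 3.0)
    beta_high: tuple[float, float] = (1.5, 3.0)
    low_band: tuple[float, float] = (0.0, 0.05)
    high_band: tuple[float, float] = (0.05, 0.40)

    def __post_init__(self):
        if self.min_frag > self.max_frag:
            raise ValueError("min_frag must not exceed max_frag")
        if not (0 <= self.capture_prob <= 1):
            raise ValueError("capture_prob must be in [0,1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Fragment:
    """One double-stranded fragment with per-end provenance."""

    replicon: str
    start0: int
    end0: int
    start_prov: str = TERMINUS
    end_prov: str = TERMINUS

    def __len__(self) -> int:
        return self.end0 - self.start0


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    genome: Genome
    sites: list[MotifSite]
    frequencies: np.ndarray
    fragments: list[Fragment]
    reads: list[AlignedRead]
    config: SimConfig

    def truth_table(self) -> list[tuple[str, int, str, float]]:
        """(replicon, locus1, motif, f_true) rows."""
        return [
            (s.replicon, s.locus1, s.motif, float(f))
            for s, f in zip(self.sites, self.frequencies)
        ]


def sim_genome(length: int, gc: float = 0.5, seed: int = 0) -> Genome:
    """Random genome with i.i.d. bases, P(G)=P(C)=gc/2."""
    if length < 100:
        raise ValueError("length must be >= 100")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return Genome({"sim": seq})


def planted_genome(
    n_sites: int,
    spacing: int = 800,
    gc: float = 0.5,
    seed: int = 0,
    replicon: str = "sim",
) -> tuple[Genome, list[MotifSite]]:
    """Random genome with exactly ``n_sites`` motif occurrences at known,
    regularly spaced positions (alternating GAAC/GTTC), and no others.

    Useful for controlled recovery experiments where each site must sit far
    from its neighbours and from the molecule termini.
    """
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    length = spacing * (n_sites + 1)
    bases = np.array(list("ACGT"))
    seq = list("".join(bases[rng.choice(4, size=length, p=p)]))
    planted: list[int] = []
    for i in range(n_sites):
        pos = spacing * (i + 1)
        motif = PT_MOTIFS[i % 2]
        seq[pos : pos + MOTIF_LEN] = list(motif)
        planted.append(pos)
    # knock out any accidental motif occurrence outside the planted windows
    text = "".join(seq)
    planted_set = set(planted)
    changed = True
    while changed:
        changed = False
        genome = Genome({replicon: text})
        for site in scan_motifs(genome):
            if site.start0 in planted_set:
                continue
            # mutate a base of the stray window that lies outside every
            # planted window (windows are >= spacing apart, so one exists)
            for off in range(MOTIF_LEN):
                pos = site.start0 + off
                if all(abs(pos - q) >= MOTIF_LEN for q in planted):
                    cur = text[pos]
                    text = text[:pos] + ("A" if cur != "A" else "C") + text[pos + 1:]
                    changed = True
                    break
        if changed:
            continue
    genome = Genome({replicon: text})
    sites = scan_motifs(genome)
    assert [s.start0 for s in sites] == planted
    return genome, sites


def assign_frequencies(
    sites: Sequence[MotifSite], config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-site true frequencies from the two-band mixture model."""
    n = len(sites)
    low = rng.random(n) < config.p_low
    a1, b1 = config.beta_low
    a2, b2 = config.beta_high
    lo0, lo1 = config.low_band
    hi0, hi1 = config.high_band
    f = np.where(
        low,
        lo0 + rng.beta(a1, b1, size=n) * (lo1 - lo0),
        hi0 + rng.beta(a2, b2, size=n) * (hi1 - hi0),
    )
    return f


def sim_cleave_and_shear(
    genome: Genome,
    sites: Sequence[MotifSite],
    f: Sequence[float],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Cleave and shear ``n_molecules`` copies of each replicon.

    Each site is cut independently with its frequency on every molecule;
    cut fragments carry iodine provenance at the break (upstream fragment
    ends at ``start0 + 3``, downstream starts at ``start0 + 1``, modelling
    the filled-in 2-nt overhang).  With shearing enabled, fragments are
    then broken uniformly at random until all are <= ``max_frag`` and
    fragments < ``min_frag`` are discarded.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = np.asarray(f, dtype=float)
    if len(f) != len(sites):
        raise ValueError("one frequency per site required")
    by_rep: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_rep.setdefault(s.replicon, []).append(i)

    fragments: list[Fragment] = []
    for rid, seq in genome.replicons.items():
        L = len(seq)
        idx = by_rep.get(rid, [])
        starts_sorted = sorted(idx, key=lambda i: sites[i].start0)
        site_starts = np.array([sites[i].start0 for i in starts_sorted], dtype=int)
        site_f = f[starts_sorted] if starts_sorted else np.empty(0)
        for _ in range(config.n_molecules):
            if len(site_starts):
                cut = rng.random(len(site_starts)) < site_f
                cuts = site_starts[cut]
            else:
                cuts = np.empty(0, dtype=int)
            mol_frags: list[Fragment] = []
            prev_start, prev_prov = 0, TERMINUS
            for c in cuts:
                mol_frags.append(Fragment(rid, prev_start, c + 3, prev_prov, IODINE))
                prev_start, prev_prov = c + 1, IODINE
            mol_frags.append(Fragment(rid, prev_start, L, prev_prov, TERMINUS))
            if config.shear_enabled:
                stack = mol_frags
                done: list[Fragment] = []
                while stack:
                    fr = stack.pop()
                    if len(fr) <= config.max_frag:
                        done.append(fr)
                        continue
                    bp = int(rng.integers(fr.start0 + 1, fr.end0))
                    stack.append(Fragment(fr.replicon, fr.start0, bp, fr.start_prov, SHEAR))
                    stack.append(Fragment(fr.replicon, bp, fr.end0, SHEAR, fr.end_prov))
                mol_frags = [fr for fr in done if len(fr) >= config.min_frag]
            fragments.extend(mol_frags)
    return fragments


def sim_reads(
    fragments: Sequence[Fragment],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[AlignedRead]:
    """Emit error-free reads from fragment ends with true coordinates.

    Paired mode sequences both fragment ends (a forward read from the
    fragment start and a reverse read from the fragment end); single mode
    sequences the forward end only.  ``capture_prob`` drops each end's read
    independently, emulating unequal recovery of the two fragments flanking
    a cut.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    reads: list[AlignedRead] = []
    rl = config.read_length
    for i, fr in enumerate(fragments):
        if config.capture_prob >= 1.0 or rng.random() < config.capture_prob:
            reads.append(
                AlignedRead(fr.replicon, fr.start0, min(fr.start0 + rl, fr.end0), "+",
                            read_id=f"frag{i}/1")
            )
        if config.paired and (config.capture_prob >= 1.0 or rng.random() < config.capture_prob):
            reads.append(
                AlignedRead(fr.replicon, max(fr.end0 - rl, fr.start0), fr.end0, "-",
                            read_id=f"frag{i}/2")
            )
    return reads


def run_simulation(
    config: SimConfig,
    genome: Genome | None = None,
    sites: Sequence[MotifSite] | None = None,
    frequencies: Sequence[float] | None = None,
) -> SimTruth:
    """Full generative run: genome -> sites -> frequencies -> fragments -> reads.

    Deterministic for a fixed config (and fixed supplied genome/sites);
    all randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = sim_genome(config.genome_length, config.gc, config.seed)
    if sites is None:
        sites = scan_motifs(genome)
    if frequencies is None:
        frequencies = assign_frequencies(sites, config, rng)
    frequencies = np.asarray(frequencies, dtype=float)
    fragments = sim_cleave_and_shear(genome, sites, frequencies, config, rng)
    reads = sim_reads(fragments, config, rng)
    return SimTruth(genome, list(sites), frequencies, fragments, reads, config)


def expected_ratio(
    f: float,
    config: SimConfig,
    n_molecules: int = 2000,
    n_batches: int = 10,
    seed: int = 12345,
) -> tuple[float, float]:
    """Monte-Carlo expectation of the PT ratio at a single site of
    frequency ``f`` under the configured library geometry.

    Returns ``(ratio, se)`` where the standard error comes from batch means
    over independent molecule batches.  This is the calibration oracle: the
    raw ratio reflects read-end geometry, not ``f`` itself, so estimator
    checks compare against this mapping rather than against ``f``.
    """
    genome, sites = planted_genome(1, spacing=1500, seed=seed)
    batch_cfg = dataclasses.replace(
        config, n_molecules=max(n_molecules // n_batches, 1), seed=seed
    )
    ratios = []
    ended_tot = span_tot = 0
    for b in range(n_batches):
        cfg = dataclasses.replace(batch_cfg, seed=seed + 1000 * (b + 1))
        truth = run_simulation(cfg, genome=genome, sites=sites, frequencies=[f])
        counts = count_sites(truth.reads, sites, genome.lengths)[0]
        ended_tot += counts.ended
        span_tot += counts.spanning
        if counts.depth > 0:
            ratios.append(counts.ended / counts.depth)
    overall = ended_tot / (ended_tot + span_tot) if (ended_tot + span_tot) else 0.0
    se = float(np.std(ratios, ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
    return overall, se


def write_truth_tsv(truth: SimTruth, path) -> None:
    """Truth table TSV: per-site true modification frequency."""
    with open(path, "w") as fh:
        fh.write("replicon\tlocus1\tmotif\tf_true\n")
        for rid, locus1, motif, f in truth.truth_table():
            fh.write(f"{rid}\t{locus1}\t{motif}\t{f:.6g}\n")


def write_fastq(truth: SimTruth, r1_path, r2_path=None) -> None:
    """Emit reads as FASTQ (revcomp for reverse-strand reads, Q40 bases)."""
    r1 = open(r1_path, "w")
    r2 = open(r2_path, "w") if r2_path else None
    try:
        for r in truth.reads:
            seq = truth.genome[r.replicon][r.start0 : r.end0]
            if r.strand == "-":
                seq = revcomp(seq)
            rec = f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n"
            if r2 is not None and r.read_id.endswith("/2"):
                r2.write(rec)
            else:
                r1.write(rec)
    finally:
        r1.close()
        if r2:
            r2.close()
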