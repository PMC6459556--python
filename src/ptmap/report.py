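"""Genome-wide heterogeneity summaries.

Frequency histograms, region-category percentages, overlap between site
sets called by different methods, the frequency-weighted PT density per
10^6 nt (comparable to LC-MS/MS dinucleotide measurements), and the
flanking-consensus search around high-frequency sites.

Every percentage output names its denominator: bacterial PT maps are
routinely summarised either over all motif sites in the genome or over the
detected subset, and the two conventions give very different numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .quantify import SiteRatio
from .reference import MOTIF_LEN, Genome, MotifSite, RegionAnnotation, revcomp

logger = logging.getLogger(__name__)

#: Default histogram bin edges: 5%-wide bands up to the 40% ceiling.
DEFAULT_EDGES = tuple(np.round(np.arange(0, 0.45, 0.05), 10))

#: "Modified with PT" means ratio strictly above this frequency.
DEFAULT_CUTOFF = 0.05


@dataclass
class FrequencyHistogram:
    edges: tuple[float, ...]
    counts: list[int]
    n_excluded: int  # sites with undefined ratio
    denominator_mode: str  # detected_sites | all_motif_sites

    @property
    def fractions(self) -> list[float]:
        total = sum(self.counts)
        return [c / total if total else float("nan") for c in self.counts]


def histogram(
    ratios: Sequence[SiteRatio],
    edges: Sequence[float] = DEFAULT_EDGES,
    denominator_mode: str = "detected_sites",
) -> FrequencyHistogram:
    """Left-closed right-open frequency histogram of per-site PT ratios.

    ``detected_sites`` restricts to sites passing the control threshold;
    ``all_motif_sites`` bins every site with a defined ratio.  Sites with no
    coverage are excluded and counted separately.
    """
    edges = tuple(edges)
    if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly ascending")
    if denominator_mode not in ("detected_sites", "all_motif_sites"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    vals = []
    n_excluded = 0
    for r in ratios:
        if r.ratio is None:
            n_excluded += 1
            continue
        if denominator_mode == "detected_sites" and not r.passes_threshold:
            continue
        vals.append(r.ratio)
    # np.histogram closes the last bin on the right; emulate fully
    # half-open bins by counting values == last edge into an overflow
    counts, _ = np.histogram(vals, bins=list(edges))
    if len(vals):
        last = np.sum(np.asarray(vals) == edges[-1])
        counts[-1] -= last
        if last:
            logger.warning("%d ratio(s) at or above the last edge excluded", int(last))
    return FrequencyHistogram(edges, [int(c) for c in counts], n_excluded, denominator_mode)


@dataclass
class CategorySummary:
    category: str
    denominator: int
    numerator: int

    @property
    def percentage(self) -> float | None:
        """Percent modified, one decimal; None when the category is empty."""
        if self.denominator == 0:
            return None
        return round(100.0 * self.numerator / self.denominator, 1)


@dataclass
class RegionSummary:
    categories: dict[str, CategorySummary]
    cutoff: float

    def __getitem__(self, cat: str) -> CategorySummary:
        return self.categories[cat]


def summarize_counts(pairs: dict[str, tuple[int, int]], cutoff: float = DEFAULT_CUTOFF) -> RegionSummary:
    """Build a RegionSummary directly from (numerator, denominator) pairs."""
    return RegionSummary(
        {cat: CategorySummary(cat, den, num) for cat, (num, den) in pairs.items()},
        cutoff,
    )


def region_summary(
    ratios: Sequence[SiteRatio],
    annotation: RegionAnnotation,
    cutoff: float = DEFAULT_CUTOFF,
) -> RegionSummary:
    """Fraction of motif sites modified above ``cutoff`` per genomic region.

    Each site is classified by its start base with precedence
    ORF > ncRNA > noncoding; the promoter subset is reported alongside
    (promoter bases are a subset of noncoding).  "Modified" means
    ratio strictly > cutoff.
    """
    cats = {c: CategorySummary(c, 0, 0) for c in ("ORF", "ncRNA", "noncoding", "promoter")}
    for r in ratios:
        site = r.site
        if site.replicon not in annotation.lengths:
            raise ValueError(f"annotation missing replicon {site.replicon!r}")
        cat = annotation.classify(site.replicon, site.start0)
        modified = r.ratio is not None and r.ratio > cutoff
        cats[cat].denominator += 1
        cats[cat].numerator += int(modified)
        if cat == "noncoding" and annotation.is_promoter(site.replicon, site.start0):
            cats["promoter"].denominator += 1
            cats["promoter"].numerator += int(modified)
    return RegionSummary(cats, cutoff)


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_common: int

    @property
    def pct_a_in_b(self) -> float:
        """Percent of A found in B, two decimals."""
        return round(100.0 * self.n_common / self.n_a, 2) if self.n_a else float("nan")


def overlap(a: Iterable[tuple], b: Iterable[tuple]) -> OverlapResult:
    """Exact intersection of two site sets keyed by (replicon, locus1)."""
    sa, sb = set(a), set(b)
    return OverlapResult(len(sa), len(sb), len(sa & sb))


def pt_per_million(ratios: Sequence[SiteRatio], genome_length: int) -> float:
    """Frequency-weighted PT site density per 10^6 nt.

    Sums per-site modification frequencies and normalises by per-strand
    genome length; comparable to LC-MS/MS d(G_ps_A)/d(G_ps_T) densities,
    since a site modified in a fraction f of molecules contributes f PT
    dinucleotides per genome copy on each strand.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    total = sum(r.ratio for r in ratios if r.ratio is not None)
    return total / genome_length * 1e6


@dataclass
class FlankConsensus:
    """Position frequency matrix around oriented (GAAC-centred) sites."""

    halfwidth: int
    pfm: np.ndarray  # shape (2*halfwidth + 4, 4), columns A,C,G,T
    n_sites: int
    n_skipped: int
    consensus: list[str | None]  # base or None per position

    @property
    def positions(self) -> list[int]:
        """Offsets relative to the motif start (0..3 are the core)."""
        return list(range(-self.halfwidth, MOTIF_LEN + self.halfwidth))


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def flank_consensus(
    sites: Sequence[MotifSite],
    genome: Genome,
    halfwidth: int = 5,
    consensus_cutoff: float = 0.9,
) -> FlankConsensus:
    """Search for extra sequence preference flanking the 4-bp core.

    GTTC-labelled windows are reverse-complemented so all sites align as
    GAAC-centred; a position is called consensus when one base reaches the
    cutoff frequency.  Sites too close to a contig edge are skipped with a
    warning.
    """
    width = 2 * halfwidth + MOTIF_LEN
    pfm = np.zeros((width, 4), dtype=float)
    n_used = n_skipped = 0
    for s in sites:
        seq = genome[s.replicon]
        lo, hi = s.start0 - halfwidth, s.start0 + MOTIF_LEN + halfwidth
        if lo < 0 or hi > len(seq):
            n_skipped += 1
            continue
        window = seq[lo:hi]
        if s.motif == "GTTC":
            window = revcomp(window)
        if "N" in window:
            n_skipped += 1
            continue
        for i, b in enumerate(window):
            pfm[i, _BASE_IDX[b]] += 1
        n_used += 1
    if n_skipped:
        logger.warning("%d site(s) skipped near contig edges or containing N", n_skipped)
    consensus: list[str | None] = []
    for i in range(width):
        tot = pfm[i].sum()
        if tot and pfm[i].max() / tot >= consensus_cutoff:
            consensus.append("ACGT"[int(pfm[i].argmax())])
        else:
            consensus.append(None)
    return FlankConsensus(halfwidth, pfm, n_used, n_skipped, consensus)


def write_histogram_tsv(hist: FrequencyHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# denominator_mode={hist.denominator_mode}\tn_no_coverage={hist.n_excluded}\n")
        fh.write("bin_lo\tbin_hi\tcount\tfraction\n")
        for lo, hi, c, fr in zip(hist.edges[:-1], hist.edges[1:], hist.counts, hist.fractions):
            fh.write(f"{lo:g}\t{hi:g}\t{c}\t{fr:.6g}\n")


def write_pfm_tsv(fc: FlankConsensus, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_sites={fc.n_sites}\tn_skipped={fc.n_skipped}\n")
        fh.write("offset\tA\tC\tG\tT\tconsensus\n")
        for pos, row, cons in zip(fc.positions, fc.pfm, fc.consensus):
            cells = "\t".join(f"{v:g}" for v in row)
            fh.write(f"{pos}\t{cells}\t{cons or '.'}\n")


def write_bedgraph(ratios: Sequence[SiteRatio], path, header: str | None = None) -> None:
    """Per-site ratios as bedGraph over the 4-bp windows (browser track)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write('track type=bedGraph name="PT ratio"\n')
        for r in ratios:
            if r.ratio is None:
                continue
            s = r.site
            fh.write(f"{s.replicon}\t{s.start0}\t{s.end0}\t{r.ratio:.6g}\n")
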