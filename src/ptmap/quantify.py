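"""Core PT-IC-seq computation.

Iodine cleaves bistranded phosphorothioate (PT) sites into double-strand
breaks, so after shearing and sequencing a modified molecule leaves reads
whose 5' termini coincide exactly with the site's strand-specific cleavage
coordinates ("ended" reads), while unmodified molecules leave reads whose
alignments cover the whole 4-bp motif window ("spanning" reads).  The PT
ratio at a site,

    ratio = ended / (ended + spanning),

is the proxy for the fraction of molecules modified there.  Random shearing
also produces a low rate of false ends; a panel of randomly chosen
non-GAAC/GTTC control windows, scored with the same geometry, provides the
detection threshold (mean of the control pseudo-ratios).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .reference import MOTIF_LEN, PT_MOTIFS, Genome, MotifSite

logger = logging.getLogger(__name__)

#: Ended-read count at or above which a site is called modified (ICDS rule).
DEFAULT_MIN_ENDED = 50

#: Number of non-motif control windows for the false-end threshold.
DEFAULT_N_CONTROLS = 10


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read, reduced to the fields the counting needs."""

    replicon: str
    start0: int
    end0: int
    strand: str
    mapq: int = 60
    duplicate: bool = False
    read_id: str = ""

    def __post_init__(self):
        if self.start0 >= self.end0:
            raise ValueError(f"empty alignment span [{self.start0},{self.end0})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the 5'-terminal base."""
        return self.start0 if self.strand == "+" else self.end0 - 1


@dataclass
class SiteCounts:
    """Ended/spanning read tallies at one motif site."""

    site: MotifSite
    ended_fwd: int = 0
    ended_rev: int = 0
    spanning: int = 0

    @property
    def ended(self) -> int:
        return self.ended_fwd + self.ended_rev

    @property
    def depth(self) -> int:
        return self.ended + self.spanning


@dataclass
class SiteRatio:
    """Per-site PT frequency estimate with detection flags."""

    site: MotifSite
    counts: SiteCounts
    ratio: float | None
    status: str = "ok"
    passes_threshold: bool = False
    detected_icds: bool = False


@dataclass
class ControlPanel:
    """Random non-motif windows used to estimate the false-end rate."""

    windows: list[MotifSite]
    ratios: list[float]
    threshold: float
    seed: int
    n_controls: int = DEFAULT_N_CONTROLS

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "n_controls": self.n_controls,
            "threshold": self.threshold,
            "controls": [
                {"replicon": w.replicon, "locus1": w.locus1, "window": w.motif, "ratio": r}
                for w, r in zip(self.windows, self.ratios)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def load_alignments(
    path,
    min_mapq: int = 1,
    drop_duplicates: bool = True,
    genome: Genome | None = None,
) -> list[AlignedRead]:
    """Load reads from SAM/BAM (via pysam) or the simulator-native TSV.

    Secondary/supplementary and unmapped records are always excluded; reads
    below ``min_mapq`` and (optionally) duplicates are filtered.  If a
    genome is supplied, replicon ids are validated against it.
    """
    path = str(path)
    reads: list[AlignedRead] = []
    n_dropped = 0
    if path.endswith((".sam", ".bam", ".cram")):
        import pysam

        with pysam.AlignmentFile(path, require_index=False) as af:
            for rec in af:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    n_dropped += 1
                    continue
                if rec.mapping_quality < min_mapq or (drop_duplicates and rec.is_duplicate):
                    n_dropped += 1
                    continue
                reads.append(
                    AlignedRead(
                        replicon=rec.reference_name,
                        start0=rec.reference_start,
                        end0=rec.reference_end,
                        strand="-" if rec.is_reverse else "+",
                        mapq=rec.mapping_quality,
                        duplicate=rec.is_duplicate,
                        read_id=rec.query_name,
                    )
                )
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                mapq = int(f[idx["mapq"]]) if "mapq" in idx else 60
                dup = f[idx["duplicate"]] == "1" if "duplicate" in idx else False
                if mapq < min_mapq or (drop_duplicates and dup):
                    n_dropped += 1
                    continue
                reads.append(
                    AlignedRead(
                        replicon=f[idx["replicon"]],
                        start0=int(f[idx["start0"]]),
                        end0=int(f[idx["end0"]]),
                        strand=f[idx["strand"]],
                        mapq=mapq,
                        duplicate=dup,
                        read_id=f[idx["read_id"]] if "read_id" in idx else "",
                    )
                )
    if genome is not None:
        missing = {r.replicon for r in reads} - set(genome.replicons)
        if missing:
            raise ValueError(f"reads reference replicons absent from genome: {sorted(missing)}")
    logger.info("loaded %d reads (%d dropped by filters)", len(reads), n_dropped)
    return reads


def write_alignments_tsv(reads: Iterable[AlignedRead], path) -> None:
    """Write reads in the simulator-native TSV (round-trips with loader)."""
    with open(path, "w") as fh:
        fh.write("replicon\tstart0\tend0\tstrand\tmapq\tduplicate\tread_id\n")
        for r in reads:
            fh.write(
                f"{r.replicon}\t{r.start0}\t{r.end0}\t{r.strand}\t{r.mapq}\t"
                f"{int(r.duplicate)}\t{r.read_id}\n"
            )


def _read_arrays(reads: Sequence[AlignedRead]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group reads per replicon into (starts, ends, is_fwd) arrays."""
    by_rep: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_rep.setdefault(r.replicon, []).append(r)
    out = {}
    for rid, rs in by_rep.items():
        starts = np.fromiter((r.start0 for r in rs), dtype=np.int64, count=len(rs))
        ends = np.fromiter((r.end0 for r in rs), dtype=np.int64, count=len(rs))
        fwd = np.fromiter((r.strand == "+" for r in rs), dtype=bool, count=len(rs))
        out[rid] = (starts, ends, fwd)
    return out


def count_sites(
    reads: Sequence[AlignedRead],
    sites: Sequence[MotifSite],
    lengths: dict[str, int] | None = None,
) -> list[SiteCounts]:
    """Tally ended and spanning reads at every site in a single pass.

    * ended_fwd: +-strand reads whose ``start0`` equals the site's forward
      cleavage coordinate;
    * ended_rev: −-strand reads whose 5'-terminal base (``end0 - 1``) equals
      the reverse cleavage coordinate;
    * spanning: reads whose alignment covers the whole 4-bp window.

    Ended reads are geometrically incapable of spanning (a forward ended
    read starts one base into the window; a reverse ended read stops one
    base short of its end), so the classes are disjoint by construction.
    The result is independent of read order.
    """
    reads = list(reads)
    arrays = _read_arrays(reads)
    if lengths is None:
        lengths = {}
        for rid, (starts, ends, _) in arrays.items():
            lengths[rid] = int(ends.max())
        for s in sites:
            lengths[s.replicon] = max(lengths.get(s.replicon, 0), s.end0)

    results: list[SiteCounts] = []
    per_rep: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for rid, L in lengths.items():
        if rid not in arrays:
            per_rep[rid] = (
                np.zeros(L, dtype=np.int64),
                np.zeros(L, dtype=np.int64),
                np.zeros(L + 1, dtype=np.int64),
            )
            continue
        starts, ends, fwd = arrays[rid]
        ended_fwd = np.bincount(starts[fwd], minlength=L)[:L]
        rev5 = ends[~fwd] - 1
        ended_rev = np.bincount(rev5, minlength=L)[:L]
        # spanning count for the window starting at p, for every p, via a
        # difference array: read [a,b) spans windows with p in [a, b-4]
        diff = np.zeros(L + 1, dtype=np.int64)
        long_enough = (ends - starts) >= MOTIF_LEN
        a = starts[long_enough]
        b = ends[long_enough]
        np.add.at(diff, a, 1)
        np.add.at(diff, np.minimum(b - (MOTIF_LEN - 1), L), -1)
        spanning = np.cumsum(diff)
        per_rep[rid] = (ended_fwd, ended_rev, spanning)

    for site in sites:
        ended_fwd, ended_rev, spanning = per_rep[site.replicon]
        L = lengths[site.replicon]
        ef = int(ended_fwd[site.cleave_fwd]) if site.cleave_fwd < L else 0
        er = int(ended_rev[site.cleave_rev]) if site.cleave_rev < L else 0
        sp = int(spanning[site.start0]) if site.start0 < L else 0
        results.append(SiteCounts(site, ef, er, sp))
    return results


def pt_ratio(counts: SiteCounts) -> SiteRatio:
    """PT frequency estimate ended/(ended+spanning); undefined at depth 0."""
    if counts.depth == 0:
        return SiteRatio(counts.site, counts, ratio=None, status="no_coverage")
    return SiteRatio(counts.site, counts, ratio=counts.ended / counts.depth)


def pt_ratios(
    reads: Sequence[AlignedRead],
    sites: Sequence[MotifSite],
    lengths: dict[str, int] | None = None,
) -> list[SiteRatio]:
    """Count and convert to ratios for every site."""
    return [pt_ratio(c) for c in count_sites(reads, sites, lengths)]


def sample_control_windows(
    genome: Genome,
    n_controls: int = DEFAULT_N_CONTROLS,
    seed: int = 0,
    max_tries: int = 100_000,
) -> list[MotifSite]:
    """Uniformly sample non-motif 4-bp windows with the site geometry.

    Rejection-samples window starts against motif membership and
    N-containing windows.  Window positions are drawn across replicons in
    proportion to length.
    """
    rng = np.random.default_rng(seed)
    rids = list(genome.replicons)
    lens = np.array([len(genome[r]) for r in rids], dtype=float)
    if all(L < MOTIF_LEN for L in lens):
        raise ValueError("genome too small to place control windows")
    weights = np.maximum(lens - MOTIF_LEN + 1, 0)
    weights /= weights.sum()
    controls: list[MotifSite] = []
    seen: set[tuple[str, int]] = set()
    tries = 0
    while len(controls) < n_controls:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place the requested number of control windows")
        rid = rids[rng.choice(len(rids), p=weights)]
        seq = genome[rid]
        start0 = int(rng.integers(0, len(seq) - MOTIF_LEN + 1))
        window = seq[start0 : start0 + MOTIF_LEN]
        if window in PT_MOTIFS or "N" in window or (rid, start0) in seen:
            continue
        seen.add((rid, start0))
        controls.append(MotifSite(rid, start0, window))
    return controls


def control_threshold(
    reads: Sequence[AlignedRead],
    genome: Genome,
    n_controls: int = DEFAULT_N_CONTROLS,
    seed: int = 0,
) -> ControlPanel:
    """False-end detection threshold from random non-motif control windows.

    Each control window is scored with the full site geometry (forward and
    reverse pseudo-cleavage coordinates, spanning window) and the threshold
    is the arithmetic mean of the control pseudo-ratios.  Controls with no
    coverage contribute a pseudo-ratio of 0.
    """
    controls = sample_control_windows(genome, n_controls, seed)
    ratios = []
    for c in count_sites(reads, controls, genome.lengths):
        r = pt_ratio(c)
        ratios.append(r.ratio if r.ratio is not None else 0.0)
    threshold = float(np.mean(ratios)) if ratios else 0.0
    return ControlPanel(controls, ratios, threshold, seed, n_controls)


def apply_threshold(ratios: Iterable[SiteRatio], panel: ControlPanel) -> list[SiteRatio]:
    """Set passes_threshold on each ratio (strict: ratio > threshold)."""
    out = []
    for r in ratios:
        r.passes_threshold = r.ratio is not None and r.ratio > panel.threshold
        out.append(r)
    return out


def icds_detect(
    counts: Sequence[SiteCounts], min_ended: int = DEFAULT_MIN_ENDED
) -> list[bool]:
    """ICDS-style detection: a site is called modified when its ended-read
    count reaches ``min_ended`` (>=)."""
    return [c.ended >= min_ended for c in counts]


@dataclass
class SaturationPoint:
    """Detection result at one subsampled sequencing depth."""

    depth: float
    n_reads: int
    n_detected: int
    detected_keys: set = field(default_factory=set, repr=False)


def subsample_depths(
    reads: Sequence[AlignedRead],
    sites: Sequence[MotifSite],
    genome_length: int,
    read_length: int,
    depths: Sequence[float],
    seed: int = 0,
    min_ended: int = DEFAULT_MIN_ENDED,
    lengths: dict[str, int] | None = None,
) -> list[SaturationPoint]:
    """Depth-saturation analysis by nested read subsampling.

    For target depth D the number of reads is N = round(D * L / read_length),
    sampled without replacement; samples are nested (each deeper sample is a
    superset of the shallower ones) so detected-site curves are monotone.
    """
    depths = list(depths)
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    if sorted(depths) != depths:
        raise ValueError("depths must be ascending")
    reads = list(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    points: list[SaturationPoint] = []
    for d in depths:
        n = min(int(round(d * genome_length / read_length)), len(reads))
        sub = [reads[i] for i in order[:n]]
        counts = count_sites(sub, sites, lengths)
        detected = icds_detect(counts, min_ended)
        keys = {c.site.key for c, ok in zip(counts, detected) if ok}
        points.append(SaturationPoint(d, n, len(keys), keys))
    return points


def write_site_table(ratios: Sequence[SiteRatio], path, header: str | None = None) -> None:
    """Per-site TSV: counts, ratio, status and both detection flags."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(
            "replicon\tlocus1\tmotif\tended_fwd\tended_rev\tspanning\t"
            "ratio\tstatus\tpasses_threshold\tdetected_icds\n"
        )
        for r in ratios:
            ratio = f"{r.ratio:.6g}" if r.ratio is not None else "NA"
            fh.write(
                f"{r.site.replicon}\t{r.site.locus1}\t{r.site.motif}\t"
                f"{r.counts.ended_fwd}\t{r.counts.ended_rev}\t{r.counts.spanning}\t"
                f"{ratio}\t{r.status}\t{int(r.passes_threshold)}\t{int(r.detected_icds)}\n"
            )
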