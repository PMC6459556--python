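"""Genome I/O, bistranded GAAC/GTTC motif discovery, and genomic region model.

Phosphorothioate (PT) modification in bacteria occurs at bistranded
GAAC/GTTC duplex positions: one strand carries G_ps_AAC and the other
G_ps_TTC.  Scanning the forward strand for both 4-mers is therefore
equivalent to scanning GAAC on both strands, and each occurrence defines
two strand-specific iodine cleavage coordinates:

* forward-strand 5' end after cleavage: ``start0 + 1`` (reads begin AAC/TTC
  after a G_ps_A cut, with the leading G removed),
* reverse-strand 5' end (in forward coordinates): ``start0 + 2``.

All coordinates are 0-based half-open internally; report outputs are
1-based (``locus1 = start0 + 1``); BED outputs are 0-based per the standard.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Bistranded PT target motifs on the forward strand.
PT_MOTIFS = ("GAAC", "GTTC")

MOTIF_LEN = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Category precedence used when annotation features overlap.
CATEGORY_PRECEDENCE = ("ORF", "ncRNA", "noncoding")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaError(ValueError):
    """Raised for malformed or invalid FASTA input."""


@dataclass
class Genome:
    """An ordered collection of replicon sequences.

    Parameters
    ----------
    replicons
        Mapping of replicon id to uppercase DNA string over {A,C,G,T,N}.
    circular
        Per-replicon circularity flag; defaults to linear.
    """

    replicons: dict[str, str]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for rid, seq in self.replicons.items():
            seq = seq.upper()
            if not seq:
                raise FastaError(f"replicon {rid!r} has zero length")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FastaError(
                    f"replicon {rid!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            clean[rid] = seq
        self.replicons = clean
        for rid in self.replicons:
            self.circular.setdefault(rid, False)

    def __contains__(self, rid: str) -> bool:
        return rid in self.replicons

    def __getitem__(self, rid: str) -> str:
        return self.replicons[rid]

    @property
    def lengths(self) -> dict[str, int]:
        return {rid: len(seq) for rid, seq in self.replicons.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.replicons.values())


@dataclass(frozen=True, order=True)
class MotifSite:
    """One bistranded GAAC/GTTC occurrence with its cleavage geometry."""

    replicon: str
    start0: int
    motif: str

    @property
    def cleave_fwd(self) -> int:
        """0-based coordinate of the forward-strand 5' end after cleavage."""
        return self.start0 + 1

    @property
    def cleave_rev(self) -> int:
        """0-based forward coordinate of the reverse-strand 5' end."""
        return self.start0 + 2

    @property
    def locus1(self) -> int:
        """1-based position used in reports."""
        return self.start0 + 1

    @property
    def end0(self) -> int:
        return self.start0 + MOTIF_LEN

    @property
    def key(self) -> tuple[str, int]:
        """Identity key (replicon, locus1) used for overlap comparisons."""
        return (self.replicon, self.locus1)


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Lowercase input is accepted and folded to uppercase.  Duplicate record
    ids, empty files and empty records raise :class:`FastaError` naming the
    offending record.
    """
    replicons: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in replicons:
            raise FastaError(f"duplicate replicon id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"record {rec.id!r} has empty sequence")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FastaError(
                f"record {rec.id!r} contains invalid characters: {sorted(bad)}"
            )
        replicons[rec.id] = seq
    if not replicons:
        raise FastaError(f"no FASTA records found in {path}")
    return Genome(replicons)


def scan_motifs(
    genome: Genome,
    motifs: Sequence[str] = PT_MOTIFS,
    include_circular_junction: bool = False,
) -> list[MotifSite]:
    """Find every forward-strand occurrence of the PT target motifs.

    Because GAAC and GTTC are reverse complements of each other, this
    forward scan enumerates all bistranded sites.  Windows containing N are
    excluded.  Overlapping windows are all reported.  With
    ``include_circular_junction`` set, windows wrapping the origin of
    circular replicons are scanned too (their ``start0`` lies within 3 bp of
    the replicon end and coordinates wrap modulo the length).
    """
    motifs = tuple(m.upper() for m in motifs)
    sites: list[MotifSite] = []
    for rid, seq in genome.replicons.items():
        for motif in motifs:
            pos = seq.find(motif)
            while pos != -1:
                sites.append(MotifSite(rid, pos, motif))
                pos = seq.find(motif, pos + 1)
        if include_circular_junction and genome.circular.get(rid) and len(seq) >= MOTIF_LEN:
            junction = seq[-(MOTIF_LEN - 1):] + seq[: MOTIF_LEN - 1]
            for motif in motifs:
                pos = junction.find(motif)
                while pos != -1:
                    sites.append(MotifSite(rid, len(seq) - (MOTIF_LEN - 1) + pos, motif))
                    pos = junction.find(motif, pos + 1)
    order = {rid: i for i, rid in enumerate(genome.replicons)}
    sites.sort(key=lambda s: (order[s.replicon], s.start0))
    return sites


@dataclass
class RegionAnnotation:
    """Categorised genomic intervals for site classification.

    Each base resolves to exactly one of ORF, ncRNA or noncoding after
    precedence resolution (ORF > ncRNA > noncoding); noncoding bases may
    additionally carry a promoter flag.
    """

    trees: dict[str, dict[str, IntervalTree]]
    promoters: dict[str, IntervalTree]
    lengths: dict[str, int]

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[str, int, int, str]],
        lengths: dict[str, int],
        promoter_intervals: Iterable[tuple[str, int, int]] = (),
    ) -> "RegionAnnotation":
        trees: dict[str, dict[str, IntervalTree]] = {
            rid: {"ORF": IntervalTree(), "ncRNA": IntervalTree()} for rid in lengths
        }
        for rid, s, e, cat in intervals:
            if rid not in lengths:
                raise ValueError(f"interval on unknown replicon {rid!r}")
            if not (0 <= s < e <= lengths[rid]):
                raise ValueError(f"interval [{s},{e}) out of bounds on {rid!r}")
            if cat not in ("ORF", "ncRNA"):
                raise ValueError(f"unknown category {cat!r}")
            trees[rid][cat].addi(s, e)
        promoters = {rid: IntervalTree() for rid in lengths}
        for rid, s, e in promoter_intervals:
            if s < e:
                promoters[rid].addi(s, e)
        return cls(trees, promoters, dict(lengths))

    def classify(self, replicon: str, pos0: int) -> str:
        """Category of a single base, with ORF > ncRNA > noncoding precedence.

        Returns ``"promoter"`` only via :meth:`is_promoter`; the base
        category for promoter bases is ``"noncoding"``.
        """
        if replicon not in self.trees:
            raise KeyError(f"annotation missing replicon {replicon!r}")
        if self.trees[replicon]["ORF"].overlaps(pos0):
            return "ORF"
        if self.trees[replicon]["ncRNA"].overlaps(pos0):
            return "ncRNA"
        return "noncoding"

    def is_promoter(self, replicon: str, pos0: int) -> bool:
        """True if a noncoding base lies in an upstream promoter window."""
        return (
            self.classify(replicon, pos0) == "noncoding"
            and bool(self.promoters.get(replicon))
            and self.promoters[replicon].overlaps(pos0)
        )


_ORF_FEATURES = {"CDS", "gene"}
_NCRNA_FEATURES = {"rRNA", "tRNA", "ncRNA", "tmRNA", "rRNA_gene", "tRNA_gene"}


def read_annotation(
    path,
    lengths: dict[str, int],
    promoter_window_bp: int = 250,
    promoter_bed=None,
) -> RegionAnnotation:
    """Build a :class:`RegionAnnotation` from a GFF3 or BED file.

    ORF intervals come from CDS/gene features, ncRNA from rRNA/tRNA/ncRNA
    features; everything else is noncoding.  The promoter flag covers the
    ``promoter_window_bp`` bases immediately upstream of each ORF start
    (strand-aware), intersected with noncoding — unless an explicit
    ``promoter_bed`` is supplied, which takes precedence.  Unknown feature
    types are ignored with a warning.  A 3-column BED (no feature name)
    defaults every interval to ORF, with a warning.
    """
    path = str(path)
    intervals: list[tuple[str, int, int, str]] = []
    orf_spans: list[tuple[str, int, int, str]] = []  # (rid, start, end, strand)
    unknown: set[str] = set()

    is_gff = path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz"))
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_gff or len(fields) >= 8:
                rid, _, ftype, start1, end1, _, strand = fields[:7]
                s, e = int(start1) - 1, int(end1)
                if ftype in _ORF_FEATURES:
                    intervals.append((rid, s, e, "ORF"))
                    orf_spans.append((rid, s, e, strand))
                elif ftype in _NCRNA_FEATURES:
                    intervals.append((rid, s, e, "ncRNA"))
                else:
                    unknown.add(ftype)
            else:
                rid, s, e = fields[0], int(fields[1]), int(fields[2])
                if len(fields) >= 4 and fields[3] in ("ORF", "ncRNA"):
                    cat = fields[3]
                else:
                    cat = "ORF"
                    if len(fields) < 4:
                        logger.warning(
                            "BED line without category column; defaulting to ORF: %s", line
                        )
                strand = fields[5] if len(fields) >= 6 else "+"
                intervals.append((rid, s, e, cat))
                if cat == "ORF":
                    orf_spans.append((rid, s, e, strand))
    if unknown:
        logger.warning("ignored feature types: %s", sorted(unknown))

    if promoter_bed is not None:
        promoter_intervals = []
        with open(str(promoter_bed)) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                promoter_intervals.append((f[0], int(f[1]), int(f[2])))
    else:
        promoter_intervals = []
        for rid, s, e, strand in orf_spans:
            if strand == "-":
                ps, pe = e, min(e + promoter_window_bp, lengths.get(rid, e))
            else:
                ps, pe = max(0, s - promoter_window_bp), s
            if ps < pe:
                promoter_intervals.append((rid, ps, pe))

    return RegionAnnotation.from_intervals(intervals, lengths, promoter_intervals)


def write_sites_bed(sites: Iterable[MotifSite], path, header: str | None = None) -> None:
    """Write motif sites as BED6 (0-based; name=motif, score=0, strand='.')."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for s in sites:
            fh.write(f"{s.replicon}\t{s.start0}\t{s.end0}\t{s.motif}\t0\t.\n")


def write_sites_tsv(sites: Iterable[MotifSite], path=sys.stdout, header: str | None = None) -> None:
    """Write motif sites as a 1-based TSV with both cleavage coordinates."""
    own = isinstance(path, (str, bytes)) or hasattr(path, "__fspath__")
    fh = open(path, "w") if own else path
    try:
        if header:
            fh.write(f"# {header}\n")
        fh.write("replicon\tlocus1\tmotif\tcleave_fwd1\tcleave_rev1\n")
        for s in sites:
            fh.write(
                f"{s.replicon}\t{s.locus1}\t{s.motif}\t{s.cleave_fwd + 1}\t{s.cleave_rev + 1}\n"
            )
    finally:
        if own:
            fh.close()
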