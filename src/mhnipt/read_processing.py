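"""Turn aligned amplicon reads into per-locus haplotype observations.

The pipeline is deliberately conservative: a read contributes to a locus
profile only if it aligns uniquely, with mapping quality strictly above the
threshold, and with a cigar containing nothing but alignment matches —
indels or clips would shift the SNP coordinates. Bases below the quality
threshold (and SNPs the read does not cover) become the unknown symbol
``-``; a haplotype with unknowns is *partial* and is either rescued by
pairing it with a unique matching *total* haplotype from the same
sample-locus read list, or discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .panel import MicrohapDef

__all__ = [
    "AlignedReadView",
    "ReadHaplotype",
    "LocusReadProfile",
    "filter_read",
    "extract_read_haplotype",
    "resolve_partials",
    "build_locus_profile",
    "read_sam_views",
    "profile_alignment_file",
]

UNKNOWN = "-"
#: cigar operations that keep reference coordinates linear: M, = and X
MATCH_OPS = frozenset("M=X")
DEFAULT_MAPQ_MIN = 20
DEFAULT_BASEQ_MIN = 20
DEFAULT_MIN_KNOWN_FRACTION = 0.70


@dataclass
class AlignedReadView:
    """Aligner-independent view of one aligned read.

    ``bases``/``base_quals`` cover consecutive reference positions starting
    at ``ref_start`` (1-based). That linear layout is only meaningful for
    match-only cigars; reads with other operations are rejected before their
    bases are consulted, so views built from such reads may carry empty
    bases.
    """

    read_id: str
    mapq: int
    cigar_ops: tuple[tuple[str, int], ...]
    ref_start: int
    bases: str
    base_quals: Sequence[int]
    unique_flag: bool = True

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.base_quals):
            raise ValueError(f"{self.read_id}: bases and base_quals differ in length")

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost covered reference position."""
        return self.ref_start + len(self.bases) - 1

    def base_at(self, pos: int) -> tuple[str, int] | None:
        if self.ref_start <= pos <= self.ref_end:
            i = pos - self.ref_start
            return self.bases[i], int(self.base_quals[i])
        return None


@dataclass(frozen=True)
class ReadHaplotype:
    """One read's symbols at a locus's SNP positions, ``-`` marking
    unknown (low-quality or uncovered) bases."""

    symbols: str

    @property
    def n_known(self) -> int:
        return len(self.symbols) - self.symbols.count(UNKNOWN)

    @property
    def is_total(self) -> bool:
        return UNKNOWN not in self.symbols


@dataclass
class LocusReadProfile:
    """Accepted haplotype observations for one sample at one locus."""

    locus_id: str
    sample_id: str
    accepted: dict[str, int]
    rejected_counts: dict[str, int] = field(default_factory=dict)

    @property
    def coverage(self) -> int:
        return sum(self.accepted.values())

    @property
    def rel_freqs(self) -> dict[str, float]:
        cov = self.coverage
        if cov == 0:
            return {}
        return {h: c / cov for h, c in sorted(self.accepted.items(),
                                              key=lambda kv: (-kv[1], kv[0]))}


# ---------------------------------------------------------------------------

def filter_read(
    read: AlignedReadView,
    locus: MicrohapDef,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> str | None:
    """Accept or reject one read for a locus; returns ``None`` on accept,
    otherwise the rejection reason.

    Acceptance requires overlap with the locus interval, a unique alignment,
    mapping quality strictly greater than ``mapq_min``, and a cigar
    consisting only of alignment-match operations (M/=/X).
    """
    if read.ref_start > locus.end or read.ref_end < locus.start:
        return "off_target"
    if not read.unique_flag:
        return "not_unique"
    if read.mapq <= mapq_min:
        return "low_mapq"
    if any(op not in MATCH_OPS for op, _ in read.cigar_ops):
        return "cigar"
    return None


def extract_read_haplotype(
    read: AlignedReadView,
    locus: MicrohapDef,
    baseq_min: int = DEFAULT_BASEQ_MIN,
) -> ReadHaplotype:
    """Read the base at each SNP position, masking low-quality and
    uncovered positions with ``-``."""
    symbols = []
    for pos in locus.snp_positions:
        hit = read.base_at(pos)
        if hit is None:
            symbols.append(UNKNOWN)
        else:
            base, qual = hit
            symbols.append(base if qual >= baseq_min else UNKNOWN)
    return ReadHaplotype("".join(symbols))


def resolve_partials(
    observations: Iterable[ReadHaplotype | str],
    min_known_fraction: float = DEFAULT_MIN_KNOWN_FRACTION,
) -> tuple[Counter, Counter]:
    """Count total haplotypes and rescue resolvable partials.

    Totals (no unknown symbol) are counted directly. A partial with fewer
    than ``min_known_fraction`` of its bases known is discarded
    (``too_partial``); otherwise it is compared with the distinct totals of
    the same observation list — a match agrees at every known position — and
    counted as the total it matches if that match is unique, else discarded
    (``ambiguous_partial``). Order-independent by construction.
    """
    symbols = [o.symbols if isinstance(o, ReadHaplotype) else o for o in observations]
    accepted: Counter = Counter()
    rejected: Counter = Counter()
    totals = [s for s in symbols if UNKNOWN not in s]
    accepted.update(totals)
    distinct_totals = sorted(set(totals))
    for s in symbols:
        if UNKNOWN not in s:
            continue
        length = len(s)
        n_known = length - s.count(UNKNOWN)
        if n_known / length < min_known_fraction:
            rejected["too_partial"] += 1
            continue
        matches = [
            t for t in distinct_totals
            if all(c == UNKNOWN or c == tc for c, tc in zip(s, t))
        ]
        if len(matches) == 1:
            accepted[matches[0]] += 1
        else:
            rejected["ambiguous_partial"] += 1
    return accepted, rejected


def build_locus_profile(
    reads: Iterable[AlignedReadView],
    locus: MicrohapDef,
    sample_id: str,
    *,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    baseq_min: int = DEFAULT_BASEQ_MIN,
    min_known_fraction: float = DEFAULT_MIN_KNOWN_FRACTION,
) -> LocusReadProfile:
    """Filter reads, extract their haplotypes, resolve partials, and return
    the accepted counts with relative frequencies for one sample-locus.

    A profile with zero accepted reads (coverage 0) is a valid value;
    downstream callers treat it as uncallable.
    """
    rejected: Counter = Counter()
    observations: list[str] = []
    for read in reads:
        reason = filter_read(read, locus, mapq_min)
        if reason is not None:
            rejected[reason] += 1
            continue
        observations.append(extract_read_haplotype(read, locus, baseq_min).symbols)
    accepted, partial_rejects = resolve_partials(observations, min_known_fraction)
    rejected.update(partial_rejects)
    return LocusReadProfile(
        locus_id=locus.locus_id,
        sample_id=sample_id,
        accepted=dict(accepted),
        rejected_counts=dict(rejected),
    )


# ---------------------------------------------------------------------------
# pysam bridge

def _view_from_pysam(aln) -> AlignedReadView:
    unique = not (aln.is_secondary or aln.is_supplementary)
    nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
    if nh > 1:
        unique = False
    cigar = tuple((op, length) for op, length in
                  ((c[0], c[1]) for c in (aln.cigartuples or ())))
    # translate pysam's integer op codes into cigar characters
    opchar = "MIDNSHP=X"
    cigar_ops = tuple((opchar[op], length) for op, length in cigar)
    linear = all(op in MATCH_OPS for op, _ in cigar_ops)
    seq = aln.query_sequence or ""
    quals = aln.query_qualities if aln.query_qualities is not None else [0] * len(seq)
    if not linear:
        seq, quals = "", []
    return AlignedReadView(
        read_id=aln.query_name,
        mapq=aln.mapping_quality,
        cigar_ops=cigar_ops,
        ref_start=aln.reference_start + 1,
        bases=seq,
        base_quals=list(quals),
        unique_flag=unique,
    )


def read_sam_views(path, locus: MicrohapDef) -> list[AlignedReadView]:
    """Read SAM/BAM records overlapping a locus as ``AlignedReadView``s."""
    import pysam

    views = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.reference_name != locus.chrom:
                continue
            view = _view_from_pysam(aln)
            if view.ref_start <= locus.end and view.ref_end >= locus.start:
                views.append(view)
    return views


def profile_alignment_file(
    path,
    defs: list[MicrohapDef],
    sample_id: str,
    **thresholds,
) -> dict[str, LocusReadProfile]:
    """Build a per-locus profile map for one sample's SAM/BAM file."""
    return {
        d.locus_id: build_locus_profile(read_sam_views(path, d), d, sample_id, **thresholds)
        for d in defs
    }
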