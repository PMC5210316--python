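"""Per-site, per-replicate base-count stacks from alignments.

The central container is the :class:`BaseCountVector`: integer counts of the
four nucleotides observed at one genomic site in one replicate, together with
the per-call Phred qualities and, when the input is an alignment file, the
read-level context (distance of the call to read ends, INDELs, splice
junctions and reference homopolymer runs) that the artifact filters consume.

Counts are always ordered (A, C, G, T).  Coordinates are 0-based internally;
output intervals are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import inf
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: complement permutation of the (A,C,G,T) axis: A<->T, C<->G
COMPLEMENT_PERM = np.array([3, 2, 1, 0])

LIBRARY_TYPES = ("unstranded", "fr-firststrand", "fr-secondstrand")

#: minimum run length of identical reference bases that counts as a
#: homopolymer for the B filter (configurable in :func:`build_pileup`)
DEFAULT_HOMOPOLYMER_MIN_RUN = 7


@dataclass(frozen=True)
class SiteCoordinate:
    """One genomic position; ``strand`` is '.' for unstranded libraries."""

    contig: str
    position: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ReadContext:
    """Distances (nt) from one base call to artifact-prone read features.

    ``None`` means the feature does not occur in (or near) the read; the
    distance filters treat that as infinity.  Distances to deleted/intronic
    bases count the nearest removed reference base (an aligned base directly
    adjacent to a splice junction has distance 1); an insertion sits between
    two reference bases and both flanking aligned bases get distance 1.
    """

    dist_to_read_start: int = 0
    dist_to_read_end: int = 0
    dist_to_nearest_indel: int | None = None
    dist_to_nearest_splice_junction: int | None = None
    in_homopolymer_within: int | None = None
    is_duplicate_flagged: bool = False

    def distance(self, feature: str) -> float:
        """Distance of this call to ``feature`` (inf when absent)."""
        if feature == "read_edge":
            return min(self.dist_to_read_start, self.dist_to_read_end)
        if feature == "indel":
            d = self.dist_to_nearest_indel
        elif feature == "splice":
            d = self.dist_to_nearest_splice_junction
        elif feature == "homopolymer":
            d = self.in_homopolymer_within
        else:
            raise ValueError(f"unknown read feature {feature!r}")
        return inf if d is None else d


@dataclass(frozen=True)
class BaseCall:
    base: str
    quality: int
    read_context: ReadContext | None = None

    def __post_init__(self) -> None:
        if self.base not in BASE_INDEX:
            raise ValueError(f"invalid base {self.base!r}")
        if not 0 <= self.quality <= 93:
            raise ValueError(f"Phred quality out of range: {self.quality}")


class BaseCountVector:
    """Base calls at one site in one replicate.

    Stores the four counts plus parallel arrays of called-base indices and
    Phred qualities (`call_bases`, `call_quals`); `contexts` is a list of
    :class:`ReadContext` or ``None`` when the input format carries no
    read-level information (count tables).
    """

    __slots__ = ("counts", "call_bases", "call_quals", "contexts")

    def __init__(
        self,
        call_bases: Sequence[int] | np.ndarray,
        call_quals: Sequence[int] | np.ndarray,
        contexts: list[ReadContext] | None = None,
    ) -> None:
        self.call_bases = np.asarray(call_bases, dtype=np.int64)
        self.call_quals = np.asarray(call_quals, dtype=np.int64)
        if self.call_bases.shape != self.call_quals.shape:
            raise ValueError("call_bases and call_quals must align")
        if self.call_bases.size and not (
            (self.call_bases >= 0).all() and (self.call_bases <= 3).all()
        ):
            raise ValueError("base indices must be in 0..3")
        if contexts is not None and len(contexts) != self.call_bases.size:
            raise ValueError("one context per call required")
        self.contexts = contexts
        self.counts = np.bincount(self.call_bases, minlength=4).astype(np.int64)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_calls(cls, calls: Iterable[BaseCall]) -> "BaseCountVector":
        calls = list(calls)
        return cls(
            [BASE_INDEX[c.base] for c in calls],
            [c.quality for c in calls],
            [c.read_context or ReadContext() for c in calls],
        )

    @classmethod
    def from_counts(cls, counts: Sequence[int], quality: int = 30) -> "BaseCountVector":
        """Synthesize uniform-quality calls from a bare count quadruple."""
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (4,) or (counts < 0).any():
            raise ValueError("counts must be a non-negative 4-vector")
        bases = np.repeat(np.arange(4), counts)
        return cls(bases, np.full(bases.size, quality, dtype=np.int64))

    # -- views --------------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def calls(self) -> list[BaseCall]:
        ctx = self.contexts or [None] * self.call_bases.size
        return [
            BaseCall(BASES[b], int(q), c)
            for b, q, c in zip(self.call_bases, self.call_quals, ctx)
        ]

    def observed_bases(self) -> set[str]:
        return {BASES[i] for i in range(4) if self.counts[i] > 0}

    def complemented(self) -> "BaseCountVector":
        """Counts on the opposite strand (A<->T, C<->G); an involution."""
        return BaseCountVector(
            COMPLEMENT_PERM[self.call_bases], self.call_quals, self.contexts
        )

    def relabel_to(self, target_base: str, which: np.ndarray) -> "BaseCountVector":
        """Copy with calls selected by boolean mask ``which`` renamed to
        ``target_base`` (qualities and contexts retained)."""
        bases = self.call_bases.copy()
        bases[which] = BASE_INDEX[target_base]
        return BaseCountVector(bases, self.call_quals, self.contexts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BaseCountVector(counts={self.counts.tolist()})"


@dataclass
class ReplicateSample:
    """Ordered replicate stack for one sample (label 'I' or 'II')."""

    label: str
    replicates: list[BaseCountVector]

    def __post_init__(self) -> None:
        if self.label not in ("I", "II"):
            raise ValueError("sample label must be 'I' or 'II'")
        if not self.replicates:
            raise ValueError("a sample needs at least one replicate")

    @property
    def N(self) -> int:
        return len(self.replicates)

    def pooled_counts(self) -> np.ndarray:
        return np.sum([r.counts for r in self.replicates], axis=0)

    def total_coverage(self) -> int:
        return int(self.pooled_counts().sum())


# ---------------------------------------------------------------------------
# alignment-file pileup
# ---------------------------------------------------------------------------


def _homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of >= min_run identical bases in seq."""
    runs = []
    i, L = 0, len(seq)
    while i < L:
        j = i + 1
        while j < L and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run and seq[i] in BASE_INDEX:
            runs.append((i, j))
        i = j
    return runs


def _distance_to_gap(pos: int, start: int, end: int) -> int:
    """Distance from aligned ref position to a removed ref interval
    [start, end): 0 if inside (cannot happen for aligned calls), adjacent
    base = 1."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - end + 1
    return 0


def _walk_read(read) -> tuple[list[tuple[int, int]], list[tuple[int, int]], list[int]]:
    """Parse a pysam AlignedSegment CIGAR.

    Returns (aligned pairs (qpos, rpos) for M/=/X, removed-reference gaps
    [(start, end), ...] for D and N combined into (interval, kind) where kind
    'indel' or 'splice', insertion breakpoint ref positions).
    """
    pairs: list[tuple[int, int]] = []
    gaps: list[tuple[int, int, str]] = []
    ins: list[int] = []
    qpos, rpos = 0, read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            pairs.extend((qpos + k, rpos + k) for k in range(length))
            qpos += length
            rpos += length
        elif op == 1:  # I: between rpos-1 and rpos
            ins.append(rpos)
            qpos += length
        elif op == 2:  # D
            gaps.append((rpos, rpos + length, "indel"))
            rpos += length
        elif op == 3:  # N
            gaps.append((rpos, rpos + length, "splice"))
            rpos += length
        elif op in (4,):  # S
            qpos += length
        # H (5) and P (6) consume nothing relevant
    return pairs, gaps, ins  # type: ignore[return-value]


def _read_transcribed_strand(read, library_type: str) -> str:
    if library_type == "unstranded":
        return "."
    # for paired data the strand is defined by read1; read2 is its mate
    forward = not read.is_reverse
    if read.is_paired and read.is_read2:
        forward = not forward
    if library_type == "fr-secondstrand":
        return "+" if forward else "-"
    return "-" if forward else "+"  # fr-firststrand


def build_pileup(
    alignments: dict[str, list[str]],
    reference: str,
    region: tuple[str, int, int],
    min_mapq: int = 20,
    min_bq: int = 20,
    library_type: str = "unstranded",
    homopolymer_min_run: int = DEFAULT_HOMOPOLYMER_MIN_RUN,
    homopolymer_pad: int = 100,
) -> Iterator[tuple[SiteCoordinate, dict[str, ReplicateSample]]]:
    """Stream per-site replicate stacks for two samples from BAM files.

    ``alignments`` maps sample label ('I', 'II') to its list of replicate BAM
    paths.  Reads below ``min_mapq``, duplicate-flagged reads (SAM flag
    0x400), secondary/supplementary alignments and calls below ``min_bq`` or
    calling N are excluded.  Only sites covered by >= 1 retained call in
    *every* replicate of *both* samples are emitted, in coordinate order.
    For stranded library types counts are reported on the transcribed strand
    (base identities complemented for reverse-strand assignment) and sites on
    different strands are kept separate.
    """
    import pysam

    if library_type not in LIBRARY_TYPES:
        raise ValueError(f"library_type must be one of {LIBRARY_TYPES}")
    contig, start, end = region

    fasta = pysam.FastaFile(reference)
    if contig not in fasta.references:
        raise ValueError(f"contig {contig!r} absent from reference {reference}")
    pad = homopolymer_pad
    ref_window_start = max(0, start - pad)
    ref_seq = fasta.fetch(contig, ref_window_start, end + pad).upper()
    runs = [
        (ref_window_start + a, ref_window_start + b)
        for a, b in _homopolymer_runs(ref_seq, homopolymer_min_run)
    ]

    # site -> sample -> replicate index -> list of (base_idx, qual, ctx)
    stacks: dict[tuple[int, str], dict[str, dict[int, list]]] = {}

    for label, paths in alignments.items():
        for rep_idx, path in enumerate(paths):
            try:
                bam = pysam.AlignmentFile(path, "rb")
            except (ValueError, OSError) as exc:
                raise RuntimeError(f"cannot open alignment file {path}: {exc}")
            if not bam.has_index():
                raise RuntimeError(
                    f"{path} is not indexed; coordinate-sort and index it first"
                )
            for read in bam.fetch(contig, start, end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_qcfail
                    or read.is_duplicate
                    or read.mapping_quality < min_mapq
                ):
                    continue
                strand = _read_transcribed_strand(read, library_type)
                pairs, gaps, ins = _walk_read(read)
                quals = read.query_qualities
                seq = read.query_sequence
                qlen = len(seq)
                for qpos, rpos in pairs:
                    if not (start <= rpos < end):
                        continue
                    base = seq[qpos]
                    q = quals[qpos] if quals is not None else 0
                    if base not in BASE_INDEX or q < min_bq:
                        continue
                    d_ind = [
                        _distance_to_gap(rpos, a, b) for a, b, kind in gaps if kind == "indel"
                    ] + [(b - rpos if rpos < b else rpos - b + 1) for b in ins]
                    d_spl = [
                        _distance_to_gap(rpos, a, b) for a, b, kind in gaps if kind == "splice"
                    ]
                    hp = None
                    for a, b in runs:
                        d = 0 if a <= rpos < b else _distance_to_gap(rpos, a, b)
                        hp = d if hp is None else min(hp, d)
                    ctx = ReadContext(
                        dist_to_read_start=qpos,
                        dist_to_read_end=qlen - 1 - qpos,
                        dist_to_nearest_indel=min(d_ind) if d_ind else None,
                        dist_to_nearest_splice_junction=min(d_spl) if d_spl else None,
                        in_homopolymer_within=hp,
                        is_duplicate_flagged=False,
                    )
                    bidx = BASE_INDEX[base]
                    if strand == "-":
                        bidx = int(COMPLEMENT_PERM[bidx])
                    site = stacks.setdefault((rpos, strand), {})
                    site.setdefault(label, {}).setdefault(rep_idx, []).append(
                        (bidx, int(q), ctx)
                    )
            bam.close()

    n_reps = {label: len(paths) for label, paths in alignments.items()}
    for (rpos, strand) in sorted(stacks):
        per_sample = stacks[(rpos, strand)]
        complete = all(
            label in per_sample and len(per_sample[label]) == n_reps[label]
            for label in alignments
        )
        if not complete:
            continue
        out: dict[str, ReplicateSample] = {}
        for label in alignments:
            reps = []
            for rep_idx in range(n_reps[label]):
                calls = per_sample[label][rep_idx]
                reps.append(
                    BaseCountVector(
                        [c[0] for c in calls],
                        [c[1] for c in calls],
                        [c[2] for c in calls],
                    )
                )
            out[label] = ReplicateSample(label, reps)
        yield SiteCoordinate(contig, rpos, strand), out
    fasta.close()
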