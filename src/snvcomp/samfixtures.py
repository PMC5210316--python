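"""Synthetic SAM/BAM fixtures for exercising the pileup and filter code.

These writers generate small, fully synthetic read sets (fixed read length
100 by default) with configurable CIGAR events — insertions, deletions,
splice gaps — over a random reference, plus the metadata needed to compute
feature distances independently of the CIGAR-walking pileup code.  They are
test scaffolding, not a read simulator: base identities and qualities are
chosen directly, with no error or fragment model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .pileup import BASES

READ_LENGTH = 100


@dataclass
class SimRead:
    """One synthetic read plus the truth needed by oracle recounts."""

    name: str
    start: int  # 0-based reference start
    cigar: str
    seq: str
    quals: list[int]
    mapq: int = 60
    flag: int = 0
    # truth metadata (reference coordinates; insertions are (breakpoint, length))
    deletions: list[tuple[int, int]] = field(default_factory=list)
    splices: list[tuple[int, int]] = field(default_factory=list)
    insertions: list[tuple[int, int]] = field(default_factory=list)


def random_reference(length: int, rng, homopolymer_at: int | None = None, run: int = 8) -> str:
    """Random ACGT sequence, optionally with a homopolymer run implanted."""
    seq = list(rng.choice(list(BASES), size=length))
    if homopolymer_at is not None:
        base = seq[homopolymer_at]
        for k in range(run):
            seq[homopolymer_at + k] = base
    return "".join(seq)


def make_read(
    name: str,
    start: int,
    ref: str,
    rng,
    event: str = "match",
    event_offset: int = 40,
    event_len: int = 10,
    read_length: int = READ_LENGTH,
    mapq: int = 60,
    quality: int = 35,
    flag: int = 0,
    mismatches: dict[int, str] | None = None,
) -> SimRead:
    """Build one read copying the reference, with one optional CIGAR event.

    ``event`` is 'match', 'insertion', 'deletion' or 'splice'; the event sits
    ``event_offset`` query bases into the read.  ``mismatches`` maps
    reference positions to substituted bases.
    """
    mismatches = mismatches or {}
    segs: list[tuple[str, int]] = []
    if event == "match":
        segs = [("M", read_length)]
    elif event == "insertion":
        segs = [("M", event_offset), ("I", event_len), ("M", read_length - event_offset - event_len)]
    elif event == "deletion":
        segs = [("M", event_offset), ("D", event_len), ("M", read_length - event_offset)]
    elif event == "splice":
        segs = [("M", event_offset), ("N", event_len), ("M", read_length - event_offset)]
    else:
        raise ValueError(f"unknown event {event!r}")

    seq = []
    quals: list[int] = []
    deletions: list[tuple[int, int]] = []
    splices: list[tuple[int, int]] = []
    insertions: list[int] = []
    rpos = start
    for op, length in segs:
        if op == "M":
            for k in range(length):
                base = mismatches.get(rpos + k, ref[rpos + k])
                seq.append(base)
                quals.append(quality)
            rpos += length
        elif op == "I":
            insertions.append((rpos, length))
            seq.extend(rng.choice(list(BASES), size=length))
            quals.extend([quality] * length)
        elif op == "D":
            deletions.append((rpos, rpos + length))
            rpos += length
        elif op == "N":
            splices.append((rpos, rpos + length))
            rpos += length
    cigar = "".join(f"{length}{op}" for op, length in segs)
    return SimRead(
        name=name,
        start=start,
        cigar=cigar,
        seq="".join(seq),
        quals=quals,
        mapq=mapq,
        flag=flag,
        deletions=deletions,
        splices=splices,
        insertions=insertions,
    )


def write_fasta(ref: str, path, contig: str = "chrS") -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(ref), 60):
            fh.write(ref[i : i + 60] + "\n")


def write_sam(reads: list[SimRead], path, contig: str, ref_length: int) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{ref_length}\n")
        for r in sorted(reads, key=lambda r: r.start):
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(
                "\t".join(
                    [
                        r.name,
                        str(r.flag),
                        contig,
                        str(r.start + 1),  # SAM is 1-based
                        str(r.mapq),
                        r.cigar,
                        "*",
                        "0",
                        "0",
                        r.seq,
                        qual,
                    ]
                )
                + "\n"
            )


def sam_to_indexed_bam(sam_path, bam_path) -> str:
    """Convert a SAM fixture to a coordinate-sorted, indexed BAM."""
    import pysam

    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return str(bam_path)


def build_fixture(
    workdir,
    reads: list[SimRead],
    ref: str,
    contig: str = "chrS",
    name: str = "fixture",
) -> tuple[str, str]:
    """Write reference FASTA (+faidx) and indexed BAM; returns their paths."""
    import pysam

    os.makedirs(workdir, exist_ok=True)
    fasta = os.path.join(workdir, f"{name}.fa")
    write_fasta(ref, fasta, contig)
    pysam.faidx(fasta)
    sam = os.path.join(workdir, f"{name}.sam")
    write_sam(reads, sam, contig, len(ref))
    bam = sam_to_indexed_bam(sam, os.path.join(workdir, f"{name}.bam"))
    return fasta, bam
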