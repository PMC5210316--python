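"""Randomized SAM fixtures plus an independent brute-force filter oracle.

The generator builds read stacks over a reference engineered to contain no
accidental homopolymer runs (only implanted ones) and records the
ground-truth layout of every read.  The oracle recomputes retained calls,
feature distances and filter flags by direct arithmetic on that layout —
never touching the package's CIGAR walker — so agreement between the two is
a genuine dual-route check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import numpy as np

from snvcomp.samfixtures import SimRead, make_read

BASES = "ACGT"
READ_LEN = 100


def reference_without_runs(length: int, rng, max_run: int = 3) -> str:
    """Random sequence whose identical-base runs never exceed max_run."""
    seq: list[str] = []
    run, prev = 0, None
    for _ in range(length):
        choices = [b for b in BASES if not (run >= max_run and b == prev)]
        b = str(rng.choice(choices))
        run = run + 1 if b == prev else 1
        prev = b
        seq.append(b)
    return "".join(seq)


@dataclass
class SiteFixture:
    site_pos: int
    reads_I: list[SimRead]
    reads_II: list[SimRead]
    homopolymer_runs: list[tuple[int, int]] = field(default_factory=list)


def random_site_fixture(rng, site_pos: int, ref: str) -> SiteFixture:
    """Randomized two-sample read stacks around one candidate site."""
    var_base = str(rng.choice([b for b in BASES if b != ref[site_pos]]))

    def reads(n: int, sample: str) -> list[SimRead]:
        out = []
        for k in range(n):
            event = str(
                rng.choice(["match", "match", "match", "insertion", "deletion", "splice"])
            )
            event_len = int(rng.integers(1, 6)) if event in ("insertion", "deletion") else 50
            event_offset = int(rng.integers(10, 85))
            start = site_pos - int(rng.integers(5, 95))
            mism = {site_pos: var_base} if sample == "II" and rng.random() < 0.5 else None
            mapq = 60 if rng.random() < 0.9 else 10
            out.append(
                make_read(
                    f"{sample}{site_pos}_{k}", start, ref, rng,
                    event=event, event_offset=event_offset, event_len=event_len,
                    mapq=mapq, mismatches=mism,
                )
            )
        return out

    return SiteFixture(
        site_pos,
        reads(int(rng.integers(3, 7)), "I"),
        reads(int(rng.integers(4, 10)), "II"),
    )


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------


def _oracle_call(read: SimRead, pos: int):
    """Recount one read at one site from its truth layout.

    Returns (base, edge, indel_dist, splice_dist) or None when the read
    contributes no call (low mapq, gap, or outside the footprint).
    """
    if read.mapq < 20:
        return None
    if pos < read.start:
        return None
    removed = sorted(read.deletions + read.splices)
    for a, b in removed:
        if a <= pos < b:
            return None
    qpos = pos - read.start
    qpos -= sum(b - a for a, b in removed if pos >= b)
    qpos += sum(L for rp, L in read.insertions if pos >= rp)
    if not 0 <= qpos < len(read.seq):
        return None
    base = read.seq[qpos]
    edge = min(qpos, len(read.seq) - 1 - qpos)

    def gap_dist(a: int, b: int) -> int:
        return a - pos if pos < a else pos - b + 1

    indels = [gap_dist(a, b) for a, b in read.deletions] + [
        (rp - pos if pos < rp else pos - rp + 1) for rp, _L in read.insertions
    ]
    splices = [gap_dist(a, b) for a, b in read.splices]
    return (
        base,
        edge,
        min(indels) if indels else inf,
        min(splices) if splices else inf,
    )


def oracle_flags(
    fix: SiteFixture,
    d: int = 5,
    r: float = 0.5,
    h_min_cov: int = 10,
    h_max_minor: float = 0.05,
):
    """(site_emitted, counts_I, counts_II, flag_set) by brute-force recount."""
    pos = fix.site_pos

    def recount(reads):
        return [c for c in (_oracle_call(rd, pos) for rd in reads) if c is not None]

    calls_I, calls_II = recount(fix.reads_I), recount(fix.reads_II)
    if not calls_I or not calls_II:
        return False, None, None, set()

    def counts(calls):
        out = np.zeros(4, dtype=int)
        for base, *_ in calls:
            out[BASES.index(base)] += 1
        return out

    c1, c2 = counts(calls_I), counts(calls_II)
    flags = set()
    # distance filters act on the RNA (sample II) calls in RDD mode
    n = len(calls_II)

    def hp_dist(p):
        ds = [
            0 if a <= p < b else (a - p if p < a else p - b + 1)
            for a, b in fix.homopolymer_runs
        ]
        return min(ds) if ds else inf

    if sum(1 for _, e, _, _ in calls_II if e <= d) / n >= r:
        flags.add("D")
    if sum(1 for _, _, i, _ in calls_II if i <= d) / n >= r:
        flags.add("I")
    if sum(1 for _, _, _, s in calls_II if s <= d) / n >= r:
        flags.add("Y")
    # every call at the site shares one reference position, so the
    # homopolymer distance is common to all calls: the fraction is 0 or 1
    if hp_dist(pos) <= d:
        flags.add("B")
    total = c1.sum()
    if total < h_min_cov or (total - c1.max()) / total > h_max_minor:
        flags.add("H")
    if int((c2 > 0).sum()) >= 3:
        flags.add("M")
    return True, c1, c2, flags
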