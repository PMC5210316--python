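"""Text formats: the count-table input and the BED-like result table.

Count table (TSV, '#'-prefixed header)::

    #contig  position  strand  s1_r1 ... s1_rN  s2_r1 ... s2_rM
    chr1     100       +       10,0,0,0  12,0,0,0  8,2,0,0  9,3,0,0

Positions are 0-based; each replicate column is an "A,C,G,T" integer
quadruple.  Count tables carry no per-call qualities or read context, so the
reader synthesizes uniform-quality calls (default q=30) with empty context;
distance filters are disabled on such input.

Results are a BED-like TSV (0-based half-open), one row per tested site:
contig, start, end, ref, z (6 decimals, round-half-even), strand, one
quadruple per replicate of sample I then sample II, filter flags
(comma-joined or '.'), balanced (0/1), passed (0/1).
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .compare import ComparisonResult
from .pileup import BaseCountVector, ReplicateSample, SiteCoordinate

logger = logging.getLogger(__name__)

DEFAULT_TABLE_QUALITY = 30


def format_z(z: float) -> str:
    """Six decimal places with round-half-even on the printed decimal value."""
    return str(Decimal(repr(float(z))).quantize(Decimal("0.000001"), ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def _parse_header(line: str) -> tuple[int, int]:
    fields = line.lstrip("#").split()
    if fields[:3] != ["contig", "position", "strand"]:
        raise ValueError("count-table header must start with contig position strand")
    n1 = sum(1 for f in fields[3:] if f.startswith("s1_"))
    n2 = sum(1 for f in fields[3:] if f.startswith("s2_"))
    if n1 < 1 or n2 < 1 or 3 + n1 + n2 != len(fields):
        raise ValueError("count-table header must name s1_r* and s2_r* columns")
    return n1, n2


def read_count_table(
    path, default_quality: int = DEFAULT_TABLE_QUALITY
) -> Iterator[tuple[SiteCoordinate, str | None, dict[str, ReplicateSample]]]:
    """Stream (site, ref_base, samples) records from a count table.

    The table format has no reference-base column; ref_base is yielded as
    None and callers fall back to the majority base of sample I (see
    :func:`infer_ref_base`).  Read context is empty, hence distance filters
    are disabled downstream (a warning is logged once).
    """
    logger.warning(
        "count-table input carries no read context; distance filters disabled"
    )
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}:1: missing '#'-prefixed header")
        n1, n2 = _parse_header(header)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n1 + n2:
                raise ValueError(
                    f"{path}:{lineno}: expected {3 + n1 + n2} columns, got {len(fields)}"
                )
            contig, pos_s, strand = fields[:3]
            try:
                pos = int(pos_s)
                quads = [
                    [int(v) for v in f.split(",")] for f in fields[3:]
                ]
                if any(len(q) != 4 for q in quads):
                    raise ValueError("quadruple must have 4 comma-separated counts")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            reps = [
                BaseCountVector.from_counts(q, quality=default_quality) for q in quads
            ]
            samples = {
                "I": ReplicateSample("I", reps[:n1]),
                "II": ReplicateSample("II", reps[n1:]),
            }
            yield SiteCoordinate(contig, pos, strand), None, samples


def infer_ref_base(sample_one: ReplicateSample) -> str:
    """Majority base of sample I's pooled counts (the genomic sample in RDD
    mode); ties break toward A<C<G<T order."""
    from .pileup import BASES

    return BASES[int(np.argmax(sample_one.pooled_counts()))]


def write_count_table(records: Iterable, path) -> None:
    """Write (site, ref_base_or_None, samples) records as a count table."""
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty count table")
    _, _, first = records[0]
    n1, n2 = first["I"].N, first["II"].N
    header = (
        ["contig", "position", "strand"]
        + [f"s1_r{i+1}" for i in range(n1)]
        + [f"s2_r{i+1}" for i in range(n2)]
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for site, _ref, samples in records:
            quads = [
                ",".join(str(int(v)) for v in rep.counts)
                for label in ("I", "II")
                for rep in samples[label].replicates
            ]
            fh.write(
                "\t".join([site.contig, str(site.position), site.strand] + quads)
                + "\n"
            )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_results(
    results: Iterable[ComparisonResult],
    path,
    config: dict | None = None,
) -> None:
    """Write the result TSV (see module docstring); results must already be
    in coordinate order.  Config values are echoed in a '##config=' line."""
    results = list(results)
    n1 = results[0].counts_I.__len__() if results else 1
    n2 = results[0].counts_II.__len__() if results else 1
    header = (
        ["contig", "start", "end", "ref", "z", "strand"]
        + [f"s1_r{i+1}" for i in range(n1)]
        + [f"s2_r{i+1}" for i in range(n2)]
        + ["filter", "balanced", "passed"]
    )
    with open(path, "w") as fh:
        if config is not None:
            items = ";".join(f"{k}={config[k]}" for k in sorted(config))
            fh.write(f"##config={items}\n")
        fh.write("#" + "\t".join(header) + "\n")
        for r in results:
            quads = [",".join(str(int(v)) for v in c) for c in r.counts_I + r.counts_II]
            flags = ",".join(sorted(r.filter_flags)) if r.filter_flags else "."
            fh.write(
                "\t".join(
                    [
                        r.site.contig,
                        str(r.site.position),
                        str(r.site.position + 1),
                        r.ref_base,
                        format_z(r.z),
                        r.site.strand,
                    ]
                    + quads
                    + [flags, "1" if r.balanced else "0", "1" if r.passed else "0"]
                )
                + "\n"
            )


def read_results(path) -> pd.DataFrame:
    """Read a result TSV back into a DataFrame (one row per site)."""
    rows = []
    config = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##config="):
                config = line[len("##config=") :]
                continue
            if line.startswith("#"):
                columns = line.lstrip("#").split("\t")
                continue
            if line:
                rows.append(line.split("\t"))
    df = pd.DataFrame(rows, columns=columns)
    df = df.rename(columns={"start": "position", "ref": "ref_base"})
    df["position"] = df["position"].astype(int)
    df["end"] = df["end"].astype(int)
    df["z"] = df["z"].astype(float)
    df["balanced"] = df["balanced"].astype(int)
    df["passed"] = df["passed"].astype(int)
    df.attrs["config"] = config
    return df


def results_to_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    """In-memory results as a DataFrame keyed by (contig, position)."""
    return pd.DataFrame(
        {
            "contig": r.site.contig,
            "position": r.site.position,
            "strand": r.site.strand,
            "ref_base": r.ref_base,
            "z": r.z,
            "filter": ",".join(sorted(r.filter_flags)) if r.filter_flags else ".",
            "balanced": int(r.balanced),
            "passed": int(r.passed),
        }
        for r in results
    )
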