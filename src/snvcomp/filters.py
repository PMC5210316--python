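"""Artifact filter panel for candidate sites.

Positional distance filters flag a site when a proportion r of the retained
RNA calls lies within d nucleotides of an artifact-prone read feature:

    D - read start/end        B - homopolymer run
    I - INDEL position        Y - splice junction

Two compositional filters complete the panel: H rejects sites whose genomic
(gDNA) sample is not confidently homozygous, and M rejects sites whose
pooled RNA counts show three or more distinct bases.  Letters are aliases;
feature names are the primary configuration vocabulary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import inf
from typing import Iterable

import numpy as np

from .pileup import BASES, ReplicateSample

logger = logging.getLogger(__name__)

#: filter letter -> read feature monitored by the distance filters
LETTER_TO_FEATURE = {
    "D": "read_edge",
    "B": "homopolymer",
    "I": "indel",
    "Y": "splice",
}
FEATURE_TO_LETTER = {v: k for k, v in LETTER_TO_FEATURE.items()}
ALL_FILTERS = frozenset("DBIYHM")


@dataclass
class FilterPanel:
    """Configuration of the artifact filters.

    d and r are shared defaults for the distance filters (site flagged when
    the fraction of calls at distance <= d reaches r); ``distance_overrides``
    maps a feature name or letter to a feature-specific d.
    """

    enabled: frozenset = frozenset("DBIYHM")
    d: int = 5
    r: float = 0.5
    distance_overrides: dict = field(default_factory=dict)
    H_min_gdna_coverage: int = 10
    H_max_minor_fraction: float = 0.05

    def __post_init__(self) -> None:
        self.enabled = frozenset(self.enabled)
        unknown = self.enabled - ALL_FILTERS
        if unknown:
            raise ValueError(f"unknown filter identifiers: {sorted(unknown)}")
        if self.d < 0 or not 0 < self.r <= 1:
            raise ValueError("need d >= 0 and 0 < r <= 1")

    def d_for(self, feature: str) -> int:
        letter = FEATURE_TO_LETTER[feature]
        for key in (feature, letter):
            if key in self.distance_overrides:
                return self.distance_overrides[key]
        return self.d


def _iter_contexts(samples: Iterable[ReplicateSample]):
    for sample in samples:
        for rep in sample.replicates:
            if rep.contexts is None:
                return None  # count-table input: no read-level context
    return [
        ctx
        for sample in samples
        for rep in sample.replicates
        for ctx in (rep.contexts or [])
    ]


def distance_filter(contexts, feature: str, d: int, r: float) -> bool:
    """True (site flagged) iff the fraction of calls whose distance to
    ``feature`` is <= d reaches r.  Calls lacking the feature count as
    distance infinity."""
    contexts = list(contexts)
    if not contexts:
        return False
    near = sum(1 for c in contexts if c.distance(feature) <= d)
    return near / len(contexts) >= r


def homozygous_filter(
    gdna: ReplicateSample, min_cov: int = 10, max_minor_fraction: float = 0.05
) -> bool:
    """True (site rejected) iff the pooled gDNA evidence does not support a
    confident homozygote: coverage below ``min_cov`` or pooled minor-allele
    fraction above ``max_minor_fraction``."""
    pooled = gdna.pooled_counts()
    total = pooled.sum()
    if total < min_cov:
        return True
    minor = total - pooled.max()
    return minor / total > max_minor_fraction


def max_allele_filter(rna_samples: Iterable[ReplicateSample]) -> bool:
    """True iff the pooled RNA counts show >= 3 distinct observed bases."""
    pooled = np.zeros(4, dtype=np.int64)
    for s in rna_samples:
        pooled += s.pooled_counts()
    return int((pooled > 0).sum()) >= 3


def variant_fraction_screen(
    rna_pooled: np.ndarray, ref_base: str, min_cov: int = 10, min_freq: float = 0.1
) -> bool:
    """Optional raw-count pre-screen (off by default in the panel): keep a
    site only when pooled RNA coverage >= min_cov and the non-reference
    fraction >= min_freq.  Returns True when the site *fails* the screen."""
    total = int(np.sum(rna_pooled))
    if total < min_cov:
        return True
    ref_idx = BASES.index(ref_base)
    return (total - int(rna_pooled[ref_idx])) / total < min_freq


def apply_panel(
    samples: dict[str, ReplicateSample],
    panel: FilterPanel,
    mode: str = "RDD",
    gdna_label: str = "I",
) -> set[str]:
    """Evaluate every enabled filter on one site; returns the set of flags.

    In RDD mode the sample with ``gdna_label`` is the genomic one (H filter
    target) and the other sample supplies the RNA calls; in RRD mode both
    samples are RNA and H is unavailable.  Order of evaluation never affects
    the result (pure union).
    """
    if mode not in ("RDD", "RRD"):
        raise ValueError("mode must be 'RDD' or 'RRD'")
    rna_labels = (
        [l for l in samples if l != gdna_label] if mode == "RDD" else list(samples)
    )
    rna = [samples[l] for l in sorted(rna_labels)]
    flags: set[str] = set()

    dist_letters = [l for l in "DBIY" if l in panel.enabled]
    if dist_letters:
        contexts = _iter_contexts(rna)
        if contexts is None:
            logger.warning(
                "no read-level context available (count-table input); "
                "distance filters disabled for this site"
            )
        else:
            for letter in dist_letters:
                feature = LETTER_TO_FEATURE[letter]
                if distance_filter(contexts, feature, panel.d_for(feature), panel.r):
                    flags.add(letter)

    if "H" in panel.enabled and mode == "RDD":
        if homozygous_filter(
            samples[gdna_label], panel.H_min_gdna_coverage, panel.H_max_minor_fraction
        ):
            flags.add("H")
    if "M" in panel.enabled and max_allele_filter(rna):
        flags.add("M")
    return flags
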