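"""Two-sample likelihood-ratio score and site-level calling.

For samples I and II with pseudocount-adjusted replicate stacks D~^I, D~^II
the score is

    z = [ L(alpha^I; D~^I) + L(alpha^II; D~^II) ]
        - [ L(alpha^{I,II}; D~^I) + L(alpha^{I,II}; D~^II) ]

where each L is a sum of log Dirichlet-Multinomial densities and alpha^{I,II}
is fitted on the union of both stacks.  Under the null that both samples
share one underlying base-probability distribution the separate fits buy
nothing and z is ~0; genuinely different spectra drive z up.  z is thresholded
directly (defaults 1.15 for RNA-DNA, 1.56 for RNA-RNA comparisons); no
p-value is attached.

Coverage balancing guards against overconfidence when one side is
mono-allelic and much deeper than the other: the deep mono-allelic stack is
replaced by a copy of the other side's stack with all non-reference calls
renamed to the reference base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dirmult import ConcentrationVector, fit_alpha, log_likelihood
from .filters import FilterPanel, apply_panel
from .pileup import ReplicateSample, SiteCoordinate
from .quality import DEFAULT_EPSILON, adjust_matrix

#: recommended score thresholds per comparison mode
DEFAULT_THRESHOLDS = {"RDD": 1.15, "RRD": 1.56}
DEFAULT_TRIGGER_RATIO = 2.0


@dataclass
class ComparisonResult:
    site: SiteCoordinate
    ref_base: str
    z: float
    alpha_I: ConcentrationVector
    alpha_II: ConcentrationVector
    alpha_pooled: ConcentrationVector
    counts_I: list[np.ndarray]
    counts_II: list[np.ndarray]
    balanced: bool
    filter_flags: set[str] = field(default_factory=set)
    passed: bool = False


def z_score(
    d_one: ReplicateSample,
    d_two: ReplicateSample,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[float, tuple[ConcentrationVector, ConcentrationVector, ConcentrationVector]]:
    """Likelihood-ratio score for one site plus the three fitted alphas.

    Each per-sample likelihood is evaluated at the better of its own fit and
    the pooled fit; since the MLE dominates every other point this only
    corrects optimizer shortfall and makes z >= 0 hold exactly.
    """
    X1 = adjust_matrix(d_one.replicates, epsilon)
    X2 = adjust_matrix(d_two.replicates, epsilon)
    fit1 = fit_alpha(X1)
    fit2 = fit_alpha(X2)
    pooled = fit_alpha(np.vstack([X1, X2]))

    # the separate optima are candidate pooled optima as well; taking the
    # best keeps the pooled likelihood an honest maximum (exact z=0 when the
    # two samples are identical)
    best = max(
        (pooled.alpha, fit1.alpha, fit2.alpha),
        key=lambda a: log_likelihood(X1, a) + log_likelihood(X2, a),
    )
    if best is not pooled.alpha:
        pooled = ConcentrationVector(
            best.copy(),
            log_likelihood(X1, best) + log_likelihood(X2, best),
            pooled.converged,
            pooled.iterations,
        )

    ll1_pool = log_likelihood(X1, pooled.alpha)
    ll2_pool = log_likelihood(X2, pooled.alpha)
    if ll1_pool > fit1.log_likelihood_at_fit:
        fit1 = ConcentrationVector(pooled.alpha.copy(), ll1_pool, fit1.converged, fit1.iterations)
    if ll2_pool > fit2.log_likelihood_at_fit:
        fit2 = ConcentrationVector(pooled.alpha.copy(), ll2_pool, fit2.converged, fit2.iterations)
    z = (
        fit1.log_likelihood_at_fit
        + fit2.log_likelihood_at_fit
        - (ll1_pool + ll2_pool)
    )
    return float(z), (fit1, fit2, pooled)


def _mono_allelic(sample: ReplicateSample) -> bool:
    pooled = sample.pooled_counts()
    return pooled.sum() > 0 and int((pooled > 0).sum()) == 1


def balance_coverage(
    d_one: ReplicateSample,
    d_two: ReplicateSample,
    ref_base: str,
    trigger_ratio: float = DEFAULT_TRIGGER_RATIO,
) -> tuple[ReplicateSample, ReplicateSample, bool]:
    """Even out extreme coverage imbalance against a mono-allelic stack.

    When exactly one side carries a single observed base (raw counts) and its
    total coverage exceeds the other side's by more than ``trigger_ratio``,
    that side is replaced by a copy of the other side's replicate vectors in
    which every non-reference call is renamed to the reference base
    (qualities and contexts retained).  Otherwise the inputs pass through.
    """
    mono1, mono2 = _mono_allelic(d_one), _mono_allelic(d_two)
    if mono1 == mono2:
        return d_one, d_two, False
    mono, hetero = (d_one, d_two) if mono1 else (d_two, d_one)
    if mono.total_coverage() <= trigger_ratio * hetero.total_coverage():
        return d_one, d_two, False
    transplanted = [
        rep.relabel_to(ref_base, rep.call_bases != _ref_idx(ref_base))
        for rep in hetero.replicates
    ]
    new_mono = ReplicateSample(mono.label, transplanted)
    if mono1:
        return new_mono, d_two, True
    return d_one, new_mono, True


def _ref_idx(ref_base: str) -> int:
    from .pileup import BASE_INDEX

    return BASE_INDEX[ref_base]


def call_site(
    site: SiteCoordinate,
    ref_base: str,
    samples: dict[str, ReplicateSample],
    mode: str = "RDD",
    threshold: float | None = None,
    panel: FilterPanel | None = None,
    epsilon: float = DEFAULT_EPSILON,
    balance: bool = True,
    trigger_ratio: float = DEFAULT_TRIGGER_RATIO,
    gdna_label: str = "I",
) -> ComparisonResult:
    """Score and filter one site; deterministic given inputs and config."""
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[mode]
    d_one, d_two = samples["I"], samples["II"]
    counts_I = [r.counts.copy() for r in d_one.replicates]
    counts_II = [r.counts.copy() for r in d_two.replicates]

    balanced = False
    if balance and ref_base in "ACGT":
        d_one, d_two, balanced = balance_coverage(d_one, d_two, ref_base, trigger_ratio)
    z, (a1, a2, ap) = z_score(d_one, d_two, epsilon)

    flags: set[str] = set()
    if panel is not None:
        flags = apply_panel(samples, panel, mode=mode, gdna_label=gdna_label)
    passed = (not flags) and z >= threshold
    return ComparisonResult(
        site=site,
        ref_base=ref_base,
        z=z,
        alpha_I=a1,
        alpha_II=a2,
        alpha_pooled=ap,
        counts_I=counts_I,
        counts_II=counts_II,
        balanced=balanced,
        filter_flags=flags,
        passed=passed,
    )


def call_many(records, **kwargs) -> list[ComparisonResult]:
    """Call a stream of (site, ref_base, samples) records.

    Sites where any replicate has zero retained coverage are skipped (the
    model needs positive mass in every replicate).
    """
    out = []
    for site, ref_base, samples in records:
        if any(r.n == 0 for s in samples.values() for r in s.replicates):
            continue
        out.append(call_site(site, ref_base, samples, **kwargs))
    return out
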