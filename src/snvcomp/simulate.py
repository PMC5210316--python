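"""Synthetic benchmark generator and evaluation metrics.

Two scenarios are emulated at the count-stack level:

RDD (gDNA vs cDNA)
    One genomic sample, mono-allelic at the reference base apart from
    sequencing errors, against N cDNA replicates in which *variant* sites
    carry a non-reference base at a Beta-distributed frequency.  This is the
    classic RNA-editing design.

RRD (cDNA vs cDNA)
    Two cDNA replicate sets.  *Variant* sites have target frequencies that
    differ between the samples by Delta (default 0.1, the floor of the
    design); *SNP* sites carry the same target frequency in both samples and
    act as noise that a difference caller must not call.

Per-replicate realized frequencies are drawn from a Beta distribution with
mean equal to the site's target frequency and concentration beta
(beta in {10, 50, 100} spans high to low inter-replicate variability).
Counts are then multinomial with a uniform per-base sequencing error.
Coverage is uniform over ``coverage_range`` per replicate.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pileup import BASES, BaseCountVector, ReplicateSample, SiteCoordinate

DEFAULT_BETA = 100.0
DEFAULT_COVERAGE_RANGE = (5, 1000)
DEFAULT_ERROR_RATE = 0.001  # matches the default simulated quality q=30
DEFAULT_QUALITY = 30
DEFAULT_N_SITES = 2000


@dataclass
class SimulatedSite:
    """Ground truth for one benchmark site."""

    site: SiteCoordinate
    site_class: str  # variant | snp | clean
    scenario: str  # RDD | RRD
    ref_base: str
    variant_base: str
    target_freq_I: float
    target_freq_II: float
    realized_freqs_I: list[float]
    realized_freqs_II: list[float]
    beta_concentration: float


@dataclass
class SimulatedDataset:
    scenario: str
    sites: list[tuple[SiteCoordinate, str, dict[str, ReplicateSample]]]
    truth: pd.DataFrame
    seed: int

    def records(self):
        yield from self.sites


def sample_target_frequency(expected: float, beta_conc: float, rng) -> float:
    """One Beta draw with mean ``expected`` and concentration ``beta_conc``
    (shapes a = expected * beta, b = (1 - expected) * beta)."""
    if not 0.0 <= expected <= 1.0:
        raise ValueError("expected frequency must be in [0, 1]")
    if beta_conc <= 0:
        raise ValueError("beta concentration must be > 0")
    if expected in (0.0, 1.0):
        return expected
    return float(rng.beta(expected * beta_conc, (1.0 - expected) * beta_conc))


def _replicate_counts(
    coverage: int,
    ref_idx: int,
    var_idx: int,
    freq: float,
    error_rate: float,
    rng,
) -> np.ndarray:
    """Multinomial counts: true base is variant w.p. freq else reference,
    then a uniform sequencing error moves e of each base's mass to the other
    three channels (e/3 each)."""
    p = np.zeros(4)
    p[ref_idx] = 1.0 - freq
    p[var_idx] += freq
    p = p * (1.0 - error_rate) + (1.0 - p) * (error_rate / 3.0)
    return rng.multinomial(coverage, p / p.sum())


def simulate_dataset(
    scenario: str,
    n_sites: int = DEFAULT_N_SITES,
    n_variant: int | None = None,
    n_snp: int | None = None,
    replicates: int = 3,
    coverage_range: tuple[int, int] = DEFAULT_COVERAGE_RANGE,
    beta_conc: float = DEFAULT_BETA,
    base_error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
    delta: float = 0.1,
    freq_range: tuple[float, float] = (0.05, 0.95),
    quality: int = DEFAULT_QUALITY,
    contig: str = "sim1",
) -> SimulatedDataset:
    """Generate one benchmark dataset plus its truth table.

    Defaults mirror the in-silico study design at desk scale: half the sites
    carry implanted signal, coverage uniform in [5, 1000], replicate count
    1..5.  For RDD, sample I is the genomic sample (single replicate,
    variant frequency 0); for RRD both samples carry ``replicates`` cDNA
    stacks, variants separated by ``delta`` in target frequency and SNPs
    implanted at pairwise-equal frequencies.
    """
    if scenario not in ("RDD", "RRD"):
        raise ValueError("scenario must be 'RDD' or 'RRD'")
    if n_variant is None:
        n_variant = n_sites // 2
    if n_snp is None:
        n_snp = n_sites // 4 if scenario == "RRD" else 0
    if scenario == "RDD" and n_snp:
        raise ValueError("SNP sites are only implanted in the RRD scenario")
    if n_variant + n_snp > n_sites:
        raise ValueError("n_variant + n_snp must not exceed n_sites")
    if not 1 <= replicates <= 5:
        raise ValueError("replicate count must be in 1..5")
    lo, hi = coverage_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid coverage range")

    rng = np.random.default_rng(seed)
    classes = ["variant"] * n_variant + ["snp"] * n_snp + ["clean"] * (
        n_sites - n_variant - n_snp
    )
    rng.shuffle(classes)

    n_reps = {"I": 1 if scenario == "RDD" else replicates, "II": replicates}
    flo, fhi = freq_range

    sites = []
    truth_rows = []
    for pos, site_class in enumerate(classes):
        ref_idx = int(rng.integers(4))
        var_idx = int((ref_idx + 1 + rng.integers(3)) % 4)
        if site_class == "variant":
            if scenario == "RDD":
                f1, f2 = 0.0, float(rng.uniform(flo, fhi))
            else:
                low = float(rng.uniform(flo, max(flo, fhi - delta)))
                pair = (low, min(low + delta, 1.0))
                f1, f2 = pair if rng.random() < 0.5 else pair[::-1]
        elif site_class == "snp":
            f = float(rng.uniform(flo, fhi))
            f1, f2 = f, f
        else:
            f1, f2 = 0.0, 0.0

        coord = SiteCoordinate(contig, pos, ".")
        samples: dict[str, ReplicateSample] = {}
        realized: dict[str, list[float]] = {}
        for label, target in (("I", f1), ("II", f2)):
            reps = []
            freqs = []
            for _ in range(n_reps[label]):
                fr = sample_target_frequency(target, beta_conc, rng)
                cov = int(rng.integers(lo, hi + 1))
                counts = _replicate_counts(
                    cov, ref_idx, var_idx, fr, base_error_rate, rng
                )
                reps.append(BaseCountVector.from_counts(counts, quality=quality))
                freqs.append(fr)
            samples[label] = ReplicateSample(label, reps)
            realized[label] = freqs
        sites.append((coord, BASES[ref_idx], samples))
        truth_rows.append(
            {
                "contig": contig,
                "position": pos,
                "strand": ".",
                "site_class": site_class,
                "scenario": scenario,
                "ref_base": BASES[ref_idx],
                "variant_base": BASES[var_idx],
                "target_freq_I": f1,
                "target_freq_II": f2,
                "realized_freqs_I": ",".join(f"{v:.6f}" for v in realized["I"]),
                "realized_freqs_II": ",".join(f"{v:.6f}" for v in realized["II"]),
                "beta_concentration": beta_conc,
                "seed": seed,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(scenario, sites, truth, seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkReport:
    TP: int
    FP: int
    TN: int
    FN: int
    threshold: float
    scenario: str = ""

    @property
    def TPR(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")

    @property
    def precision(self) -> float:
        if self.TP + self.FP == 0:
            warnings.warn("no predicted positives; precision undefined")
            return float("nan")
        return self.TP / (self.TP + self.FP)

    @property
    def accuracy(self) -> float:
        total = self.TP + self.FP + self.TN + self.FN
        return (self.TP + self.TN) / total if total else float("nan")

    @property
    def F(self) -> float:
        p, t = self.precision, self.TPR
        if not np.isfinite(p) or not np.isfinite(t) or p + t == 0:
            return float("nan")
        return 2 * p * t / (p + t)

    def as_dict(self) -> dict:
        return {
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            "TPR": self.TPR,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "F": self.F,
            "threshold": self.threshold,
            "scenario": self.scenario,
        }


def evaluate(calls: pd.DataFrame, truth: pd.DataFrame, threshold: float | None = None) -> BenchmarkReport:
    """Score called sites against truth.

    ``calls`` needs columns contig, position and either ``passed`` (0/1) or
    ``z`` plus ``threshold``; truth sites classed 'variant' are positives,
    'snp' and 'clean' are negatives.  Site sets must match exactly.
    """
    key = ["contig", "position"]
    c = calls.set_index(key).sort_index()
    t = truth.set_index(key).sort_index()
    if not c.index.equals(t.index):
        raise ValueError("calls and truth cover different site sets")
    if "passed" in c.columns and threshold is None:
        predicted = c["passed"].astype(bool).to_numpy()
        thr = float(c["threshold"].iloc[0]) if "threshold" in c.columns else float("nan")
    else:
        if threshold is None:
            raise ValueError("need a threshold when calls carry no 'passed' column")
        clean = c["filter"].fillna(".").eq(".") if "filter" in c.columns else True
        predicted = (c["z"].to_numpy() >= threshold) & np.asarray(clean)
        thr = threshold
    is_variant = t["site_class"].eq("variant").to_numpy()
    tp = int(np.sum(predicted & is_variant))
    fp = int(np.sum(predicted & ~is_variant))
    fn = int(np.sum(~predicted & is_variant))
    tn = int(np.sum(~predicted & ~is_variant))
    scen = str(t["scenario"].iloc[0]) if "scenario" in t.columns else ""
    return BenchmarkReport(tp, fp, tn, fn, thr, scen)


def threshold_sweep(calls: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Metrics at every distinct z value (sites failing filters never count
    as predicted positives); used to pick operating thresholds."""
    key = ["contig", "position"]
    c = calls.set_index(key).sort_index()
    t = truth.set_index(key).sort_index()
    if not c.index.equals(t.index):
        raise ValueError("calls and truth cover different site sets")
    z = c["z"].to_numpy(dtype=float)
    clean = (
        c["filter"].fillna(".").eq(".").to_numpy()
        if "filter" in c.columns
        else np.ones(z.size, dtype=bool)
    )
    is_variant = t["site_class"].eq("variant").to_numpy()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for thr in np.unique(z):
            predicted = (z >= thr) & clean
            tp = int(np.sum(predicted & is_variant))
            fp = int(np.sum(predicted & ~is_variant))
            fn = int(np.sum(~predicted & is_variant))
            tn = int(np.sum(~predicted & ~is_variant))
            rep = BenchmarkReport(tp, fp, tn, fn, float(thr))
            rows.append(rep.as_dict())
    return pd.DataFrame(rows)


def tpr_at_fp_budget(calls: pd.DataFrame, truth: pd.DataFrame, max_fp: int) -> float:
    """Best achievable TPR over thresholds keeping FP <= max_fp."""
    sweep = threshold_sweep(calls, truth)
    ok = sweep[sweep["FP"] <= max_fp]
    return float(ok["TPR"].max()) if len(ok) else 0.0
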