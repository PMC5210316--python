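"""Two-sample likelihood-ratio score, coverage balancing, site calls."""

from itertools import product

import numpy as np
import pytest

from conftest import make_sample, random_sample
from snvcomp.compare import balance_coverage, call_site, z_score
from snvcomp.dirmult import log_likelihood
from snvcomp.filters import FilterPanel
from snvcomp.pileup import ReplicateSample, SiteCoordinate
from snvcomp.quality import adjust_matrix


def test_identity_null(rng):
    """z(D, D) vanishes for identical replicate sets."""
    for _ in range(25):
        d1 = random_sample(rng, "I")
        d2 = ReplicateSample("II", list(d1.replicates))
        z, _ = z_score(d1, d2)
        assert abs(z) <= 1e-4


def test_swap_symmetry_and_nonnegativity(rng):
    for _ in range(25):
        a, b = random_sample(rng, "I"), random_sample(rng, "II")
        z1, _ = z_score(a, b)
        z2, _ = z_score(
            ReplicateSample("I", b.replicates), ReplicateSample("II", a.replicates)
        )
        assert z1 >= -1e-4
        assert z1 == pytest.approx(z2, abs=1e-9)


def test_replicate_permutation_invariance(rng):
    a = random_sample(rng, "I", n_rep=3)
    b = random_sample(rng, "II", n_rep=3)
    z1, _ = z_score(a, b)
    z2, _ = z_score(ReplicateSample("I", a.replicates[::-1]), b)
    assert z1 == pytest.approx(z2, abs=1e-9)


def _grid_z(d1, d2, eps=0.01):
    """Independent z oracle: grid-search MLE instead of the iterative fit."""
    X1 = adjust_matrix(d1.replicates, eps)
    X2 = adjust_matrix(d2.replicates, eps)
    grid = [0.05, 0.2, 0.5, 1.0, 2.0, 5.0, 15.0, 60.0, 300.0]
    pts = [np.array(a) for a in product(grid, repeat=4)]
    ll1 = max(log_likelihood(X1, a) for a in pts)
    ll2 = max(log_likelihood(X2, a) for a in pts)
    llp = max(log_likelihood(X1, a) + log_likelihood(X2, a) for a in pts)
    return ll1 + ll2 - llp


def test_effect_size_ordering_matches_grid_oracle():
    """A 50% divergent sample scores higher than a 5% divergent one, in both
    the implementation and an independent grid-search MLE oracle."""
    d_one = make_sample("I", [[30, 0, 0, 0], [28, 0, 0, 0]])
    d_big = make_sample("II", [[15, 15, 0, 0], [14, 16, 0, 0]])
    d_small = make_sample("II", [[29, 1, 0, 0], [28, 2, 0, 0]])
    z_b, _ = z_score(d_one, d_big)
    z_s, _ = z_score(d_one, d_small)
    assert z_b > z_s
    assert _grid_z(d_one, d_big) > _grid_z(d_one, d_small)


def test_monotone_response_in_frequency_difference(rng):
    """Median z grows with the frequency difference at fixed coverage."""
    meds = []
    for delta in (0.0, 0.1, 0.4):
        zs = []
        for k in range(10):
            c = 100
            f = 0.05 + delta
            a = make_sample("I", [rng.multinomial(c, [0.95, 0.05, 0, 0]) for _ in range(3)])
            b = make_sample("II", [rng.multinomial(c, [1 - f, f, 0, 0]) for _ in range(3)])
            z, _ = z_score(a, b)
            zs.append(z)
        meds.append(np.median(zs))
    assert meds[0] <= meds[1] <= meds[2]


# -- coverage balancing ------------------------------------------------


def test_balance_replaces_deep_monoallelic_side():
    gdna = make_sample("I", [[500, 0, 0, 0]])
    cdna = make_sample("II", [[20, 10, 0, 0]])
    b1, b2, balanced = balance_coverage(gdna, cdna, "A", trigger_ratio=2.0)
    assert balanced
    np.testing.assert_array_equal(b1.replicates[0].counts, [30, 0, 0, 0])
    np.testing.assert_array_equal(b2.replicates[0].counts, [20, 10, 0, 0])
    assert b1.N == cdna.N  # inherits the hetero side's replicate structure


def test_balance_passthrough_poly_allelic():
    a = make_sample("I", [[20, 10, 0, 0]])
    b = make_sample("II", [[10, 20, 0, 0]])
    _, _, balanced = balance_coverage(a, b, "A")
    assert not balanced


def test_balance_threshold_not_triggered():
    a = make_sample("I", [[45, 0, 0, 0]])  # ratio 1.5 < 2
    b = make_sample("II", [[20, 10, 0, 0]])
    _, _, balanced = balance_coverage(a, b, "A", trigger_ratio=2.0)
    assert not balanced


def test_balance_preserves_qualities():
    gdna = make_sample("I", [[100, 0, 0, 0]], quality=37)
    cdna = make_sample("II", [[20, 10, 0, 0]], quality=22)
    b1, _, balanced = balance_coverage(gdna, cdna, "A")
    assert balanced
    assert (b1.replicates[0].call_quals == 22).all()


# -- site calls --------------------------------------------------------


def _fixed_site(z_target_high=True):
    site = SiteCoordinate("chr1", 100, "+")
    d1 = make_sample("I", [[40, 0, 0, 0], [38, 0, 0, 0]])
    if z_target_high:
        d2 = make_sample("II", [[20, 20, 0, 0], [19, 21, 0, 0]])
    else:
        d2 = make_sample("II", [[40, 0, 0, 0], [39, 1, 0, 0]])
    return site, {"I": d1, "II": d2}


def test_call_site_mode_thresholds():
    """A mid-range score passes the RDD default (1.15) but not RRD (1.56)."""
    site, samples = _fixed_site()
    rdd = call_site(site, "A", samples, mode="RDD")
    assert rdd.z >= 1.15 and rdd.passed
    # same score judged under the sterner RRD default
    rrd = call_site(site, "A", samples, mode="RRD", threshold=rdd.z + 0.1)
    assert not rrd.passed


def test_filter_flags_take_precedence():
    site, samples = _fixed_site()
    # force an M flag: three observed bases in the RNA sample
    samples["II"] = make_sample("II", [[20, 15, 5, 0], [19, 16, 6, 0]])
    panel = FilterPanel(enabled=frozenset("M"))
    res = call_site(site, "A", samples, mode="RDD", panel=panel)
    assert res.z > 1.15
    assert res.filter_flags == {"M"}
    assert not res.passed


def test_passed_implies_clean_and_above_threshold():
    site, samples = _fixed_site()
    res = call_site(site, "A", samples, mode="RDD", panel=FilterPanel())
    if res.passed:
        assert not res.filter_flags and res.z >= 1.15
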