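"""Artifact filter panel: distance, homozygosity, max-allele filters."""

import itertools
from math import inf

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sample
from snvcomp.filters import (
    FilterPanel,
    apply_panel,
    distance_filter,
    homozygous_filter,
    max_allele_filter,
    variant_fraction_screen,
)
from snvcomp.pileup import BaseCountVector, ReadContext, ReplicateSample


def ctx(edge=50, indel=None, splice=None, hp=None):
    return ReadContext(
        dist_to_read_start=edge,
        dist_to_read_end=edge,
        dist_to_nearest_indel=indel,
        dist_to_nearest_splice_junction=splice,
        in_homopolymer_within=hp,
    )


def test_distance_filter_threshold_cases():
    near, far = ctx(edge=3), ctx(edge=50)
    # 6/10 near read end with r=0.5 -> flagged
    assert distance_filter([near] * 6 + [far] * 4, "read_edge", d=5, r=0.5)
    # 4/10 near -> not flagged
    assert not distance_filter([near] * 4 + [far] * 6, "read_edge", d=5, r=0.5)


def test_distance_filter_missing_feature_is_infinite():
    calls = [ctx(indel=None)] * 10
    assert not distance_filter(calls, "indel", d=1000, r=0.1)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    dists=st.lists(st.one_of(st.none(), st.integers(0, 30)), min_size=1, max_size=40),
    d=st.integers(0, 30),
    r=st.floats(0.05, 1.0),
)
def test_distance_filter_matches_recount_oracle(dists, d, r):
    """Implementation agrees with a direct recount for any distances."""
    calls = [ctx(splice=v) for v in dists]
    expected = (
        sum(1 for v in dists if v is not None and v <= d) / len(dists) >= r
    )
    assert distance_filter(calls, "splice", d, r) == expected


def test_homozygous_filter_cases():
    assert not homozygous_filter(make_sample("I", [[20, 0, 0, 0]]), min_cov=10)
    # insufficient coverage
    assert homozygous_filter(make_sample("I", [[8, 0, 0, 0]]), min_cov=10)
    # heterozygote: minor fraction 0.25 > 0.05
    assert homozygous_filter(
        make_sample("I", [[15, 5, 0, 0]]), min_cov=10, max_minor_fraction=0.05
    )


@pytest.mark.parametrize(
    "pooled,flagged",
    [([10, 5, 0, 0], False), ([10, 5, 3, 0], True), ([10, 5, 1, 1], True)],
)
def test_max_allele_filter(pooled, flagged):
    assert max_allele_filter([make_sample("II", [pooled])]) == flagged


def test_variant_fraction_screen():
    assert variant_fraction_screen(np.array([5, 0, 0, 0]), "A", min_cov=10)
    assert variant_fraction_screen(np.array([95, 5, 0, 0]), "A", min_freq=0.1)
    assert not variant_fraction_screen(np.array([80, 20, 0, 0]), "A", min_freq=0.1)


def _site_samples(edge_dist):
    gdna = make_sample("I", [[20, 0, 0, 0]])
    calls = [(1, 30, ctx(edge=edge_dist))] * 6 + [(0, 30, ctx(edge=50))] * 4
    rep = BaseCountVector(
        [c[0] for c in calls], [c[1] for c in calls], [c[2] for c in calls]
    )
    return {"I": gdna, "II": ReplicateSample("II", [rep])}


def test_apply_panel_union_and_disabled():
    samples = _site_samples(edge_dist=2)
    assert apply_panel(samples, FilterPanel(enabled=frozenset())) == set()
    flags = apply_panel(samples, FilterPanel(enabled=frozenset("DBIYHM")), mode="RDD")
    assert "D" in flags  # 60% of calls within 5 nt of a read end


def test_apply_panel_order_invariance():
    """The flag set is a pure union; evaluation order cannot matter."""
    samples = _site_samples(edge_dist=2)
    samples["I"] = make_sample("I", [[8, 0, 0, 0]])  # also trips H
    ref = apply_panel(samples, FilterPanel(enabled=frozenset("DBIYHM")), mode="RDD")
    assert {"D", "H"} <= ref
    for perm in itertools.permutations("DH"):
        panel = FilterPanel(enabled=frozenset(perm))
        assert apply_panel(samples, panel, mode="RDD") == ref & set("DH")


def test_rrd_mode_has_no_h_filter():
    samples = _site_samples(edge_dist=2)
    samples["I"] = make_sample("I", [[8, 0, 0, 0]])
    flags = apply_panel(samples, FilterPanel(enabled=frozenset("H")), mode="RRD")
    assert flags == set()


def test_count_table_input_disables_distance_filters(caplog):
    samples = {
        "I": make_sample("I", [[20, 0, 0, 0]]),
        "II": make_sample("II", [[10, 10, 0, 0]]),
    }
    # from_counts leaves contexts=None -> distance filters silently skipped
    flags = apply_panel(samples, FilterPanel(enabled=frozenset("DBIY")), mode="RDD")
    assert flags == set()


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    dists=st.lists(st.integers(0, 20), min_size=2, max_size=30),
    d=st.integers(0, 19),
    r=st.floats(0.1, 0.9),
)
def test_monotone_in_d_and_r(dists, d, r):
    """Raising d can only add a flag; raising r can only remove it."""
    calls = [ctx(indel=v) for v in dists]
    base = distance_filter(calls, "indel", d, r)
    assert distance_filter(calls, "indel", d + 1, r) >= base
    if r + 0.1 <= 1.0:
        assert distance_filter(calls, "indel", d, r + 0.1) <= base
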