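"""Pileup construction from SAM fixtures and count tables."""

import numpy as np
import pytest

from snvcomp.pileup import (
    BaseCountVector,
    ReplicateSample,
    SiteCoordinate,
    build_pileup,
)
from snvcomp.samfixtures import build_fixture, make_read, random_reference


@pytest.fixture
def simple_fixture(tmp_path, rng):
    """One contig; sample I has 3 plain reads, sample II has 2."""
    ref = random_reference(400, rng)
    reads1 = [make_read(f"r{i}", 100, ref, rng) for i in range(3)]
    reads2 = [make_read(f"q{i}", 100, ref, rng) for i in range(2)]
    fa, bam1 = build_fixture(tmp_path, reads1, ref, name="s1")
    _, bam2 = build_fixture(tmp_path, reads2, ref, name="s2")
    return ref, fa, bam1, bam2


def test_direct_counting(simple_fixture):
    """Three reference-matching reads at a site give counts (3 at ref)."""
    ref, fa, bam1, bam2 = simple_fixture
    recs = list(build_pileup({"I": [bam1], "II": [bam2]}, fa, ("chrS", 100, 200)))
    assert len(recs) == 100
    site, samples = recs[0]
    rep = samples["I"].replicates[0]
    assert rep.n == 3
    assert rep.counts["ACGT".index(ref[site.position])] == 3


def test_mapq_threshold_excludes_reads(tmp_path, rng):
    ref = random_reference(400, rng)
    good = make_read("g", 100, ref, rng, mapq=60)
    bad = make_read("b", 100, ref, rng, mapq=10)
    fa, bam1 = build_fixture(tmp_path, [good, bad], ref, name="s1")
    _, bam2 = build_fixture(tmp_path, [make_read("q", 100, ref, rng)], ref, name="s2")
    recs = list(
        build_pileup({"I": [bam1], "II": [bam2]}, fa, ("chrS", 120, 121), min_mapq=20)
    )
    assert recs[0][1]["I"].replicates[0].n == 1


def test_duplicate_flag_excluded(tmp_path, rng):
    ref = random_reference(400, rng)
    dup = make_read("d", 100, ref, rng, flag=0x400)
    keep = make_read("k", 100, ref, rng)
    fa, bam1 = build_fixture(tmp_path, [dup, keep], ref, name="s1")
    _, bam2 = build_fixture(tmp_path, [make_read("q", 100, ref, rng)], ref, name="s2")
    recs = list(build_pileup({"I": [bam1], "II": [bam2]}, fa, ("chrS", 120, 121)))
    assert recs[0][1]["I"].replicates[0].n == 1


def test_splice_distance_from_cigar_walk(tmp_path, rng):
    """50M100N50M read: a site 3 nt left of the junction has distance 3."""
    ref = random_reference(600, rng)
    spliced = make_read("s", 100, ref, rng, event="splice", event_offset=50, event_len=100)
    fa, bam1 = build_fixture(tmp_path, [spliced], ref, name="s1")
    _, bam2 = build_fixture(tmp_path, [make_read("q", 100, ref, rng)], ref, name="s2")
    recs = {
        site.position: samples
        for site, samples in build_pileup({"I": [bam1], "II": [bam2]}, fa, ("chrS", 100, 200))
    }
    # junction starts at ref position 150; site 147 is 3 nt to its left
    ctx = recs[147]["I"].replicates[0].contexts[0]
    assert ctx.dist_to_nearest_splice_junction == 3
    assert recs[149]["I"].replicates[0].contexts[0].dist_to_nearest_splice_junction == 1


def test_base_quality_threshold_drops_calls(tmp_path, rng):
    ref = random_reference(400, rng)
    lowq = make_read("l", 100, ref, rng, quality=10)
    hiq = make_read("h", 100, ref, rng, quality=35)
    fa, bam1 = build_fixture(tmp_path, [lowq, hiq], ref, name="s1")
    _, bam2 = build_fixture(tmp_path, [make_read("q", 100, ref, rng)], ref, name="s2")
    recs = list(build_pileup({"I": [bam1], "II": [bam2]}, fa, ("chrS", 120, 121), min_bq=20))
    rep = recs[0][1]["I"].replicates[0]
    assert rep.n == 1 and (rep.call_quals == 35).all()


def test_counting_permutation_invariant(tmp_path, rng):
    """Read order in the file does not change the emitted counts."""
    ref = random_reference(400, rng)
    reads = [make_read(f"r{i}", 100 + 5 * i, ref, rng) for i in range(4)]
    fa, bam_a = build_fixture(tmp_path / "a", reads, ref, name="s1")
    _, bam_a2 = build_fixture(tmp_path / "a", reads, ref, name="s2")
    _, bam_b = build_fixture(tmp_path / "b", reads[::-1], ref, name="s1")
    rec_a = list(build_pileup({"I": [bam_a], "II": [bam_a2]}, fa, ("chrS", 120, 160)))
    rec_b = list(build_pileup({"I": [bam_b], "II": [bam_a2]}, fa, ("chrS", 120, 160)))
    for (sa, xa), (sb, xb) in zip(rec_a, rec_b):
        assert sa == sb
        np.testing.assert_array_equal(
            xa["I"].replicates[0].counts, xb["I"].replicates[0].counts
        )


def test_coverage_conservation(simple_fixture):
    """Each replicate's n equals its number of retained calls."""
    _, fa, bam1, bam2 = simple_fixture
    for _, samples in build_pileup({"I": [bam1], "II": [bam2]}, fa, ("chrS", 100, 200)):
        for s in samples.values():
            for rep in s.replicates:
                assert rep.n == rep.call_bases.size == len(rep.contexts)


def test_strand_complement_involution(rng):
    bc = BaseCountVector.from_counts([5, 3, 2, 1])
    twice = bc.complemented().complemented()
    np.testing.assert_array_equal(twice.counts, bc.counts)
    np.testing.assert_array_equal(
        bc.complemented().counts, [1, 2, 3, 5]
    )


def test_missing_contig_is_fatal(simple_fixture):
    _, fa, bam1, bam2 = simple_fixture
    with pytest.raises(ValueError, match="absent from reference"):
        list(build_pileup({"I": [bam1], "II": [bam2]}, fa, ("chrNOPE", 0, 10)))


def test_unindexed_bam_is_fatal(tmp_path, rng, simple_fixture):
    import os

    _, fa, bam1, bam2 = simple_fixture
    os.remove(bam1 + ".bai")
    with pytest.raises(RuntimeError, match="not indexed"):
        list(build_pileup({"I": [bam1], "II": [bam2]}, fa, ("chrS", 100, 200)))
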