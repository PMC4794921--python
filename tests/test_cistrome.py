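import inspect

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers_oracles import (
    brute_force_compare,
    brute_force_pairwise,
    brute_force_pattern_counts,
    brute_force_sharing,
    brute_force_unify,
    random_peaksets,
)
from nfkbmap import SUBUNITS
from nfkbmap import synthetic_data as sd
from nfkbmap.cistrome_combinatorics import (
    OccupancyMatrix,
    attach_profiles,
    build_occupancy_matrix,
    cluster_profiles,
    compare_cistromes,
    genomic_feature_annotation,
    pattern_code,
    pattern_frequencies,
    sharing_statistics,
    tss_distance_profile,
)
from nfkbmap.formats_io import GenomicRegion


def occ(codes_and_regions):
    """Helper: build an OccupancyMatrix from (code, region) pairs."""
    regions = [r for _, r in codes_and_regions]
    ind = np.array([[c[j] == "1" for j in range(4)]
                    for c, _ in codes_and_regions])
    return OccupancyMatrix(regions, ind)


class TestPatternCode:
    def test_subunit_order_codes(self):
        assert pattern_code([1, 1, 0, 0]) == "1100"   # p50+p52
        assert pattern_code([1, 0, 1, 0]) == "1010"   # p50+RelA
        assert pattern_code([0, 1, 0, 1]) == "0101"   # p52+RelB

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pattern_code([0, 0, 0, 0])


class TestBuildOccupancy:
    def test_identical_peak_in_all_four(self):
        r = GenomicRegion("chr1", 100, 200)
        m = build_occupancy_matrix({s: [r] for s in SUBUNITS})
        assert len(m) == 1 and m.codes == ["1111"]

    def test_disjoint_single_subunit_peaks(self):
        m = build_occupancy_matrix(
            {"p50": [GenomicRegion("chr1", 100, 200),
                     GenomicRegion("chr1", 300, 400)]}
        )
        assert m.codes == ["1000", "1000"]
        assert [(r.start, r.end) for r in m.regions] == [(100, 200), (300, 400)]

    def test_unknown_subunit_rejected(self):
        with pytest.raises(ValueError, match="unknown subunit"):
            build_occupancy_matrix({"p65": [GenomicRegion("chr1", 0, 10)]})

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_occupancy_matrix({"p50": []})

    def test_chain_merging_is_single_linkage(self):
        # 0-100 overlaps 90-200 overlaps 190-300: one region
        m = build_occupancy_matrix(
            {
                "p50": [GenomicRegion("chr1", 0, 100)],
                "p52": [GenomicRegion("chr1", 90, 200)],
                "RelA": [GenomicRegion("chr1", 190, 300)],
            }
        )
        assert len(m) == 1 and m.codes == ["1110"]
        assert (m.regions[0].start, m.regions[0].end) == (0, 300)

    def test_min_overlap_threshold(self):
        peaks = {
            "p50": [GenomicRegion("chr1", 0, 100)],
            "p52": [GenomicRegion("chr1", 95, 200)],
        }
        assert len(build_occupancy_matrix(peaks, min_overlap=1)) == 1
        assert len(build_occupancy_matrix(peaks, min_overlap=10)) == 2

    def test_summit_from_strongest_member(self):
        m = build_occupancy_matrix(
            {
                "p50": [GenomicRegion("chr1", 0, 100, summit=10, score=2.0)],
                "p52": [GenomicRegion("chr1", 50, 200, summit=100, score=9.0)],
            }
        )
        assert m.regions[0].abs_summit == 150  # summit of the 9.0-score peak

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        peaksets = random_peaksets(seed, n_per_subunit=40)
        m = build_occupancy_matrix(peaksets)
        intervals, codes = brute_force_unify(peaksets)
        assert [(r.chrom, r.start, r.end) for r in m.regions] == intervals
        assert m.codes == codes

    @pytest.mark.parametrize("seed", range(5))
    def test_merging_idempotence(self, seed):
        peaksets = random_peaksets(seed)
        m = build_occupancy_matrix(peaksets)
        again = build_occupancy_matrix({"p50": m.regions})
        assert [(r.chrom, r.start, r.end) for r in again.regions] == [
            (r.chrom, r.start, r.end) for r in m.regions
        ]


@st.composite
def interval_lists(draw):
    n = draw(st.integers(1, 30))
    out = []
    for _ in range(n):
        start = draw(st.integers(0, 5000))
        length = draw(st.integers(1, 300))
        out.append(GenomicRegion("chrS", start, start + length))
    return out


class TestMergeProperties:
    @given(p50=interval_lists(), p52=interval_lists())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_unified_regions_disjoint_and_covering(self, p50, p52):
        m = build_occupancy_matrix({"p50": p50, "p52": p52})
        # non-overlapping and sorted after merging
        for a, b in zip(m.regions, m.regions[1:]):
            assert a.end <= b.start or a.chrom != b.chrom
        # every input peak falls entirely inside one unified region
        for r in p50 + p52:
            assert any(
                u.start <= r.start and r.end <= u.end for u in m.regions
            )
        # conservation: each subunit's indicator count is bounded by its
        # peaks and every indicator is witnessed by at least one peak
        for j, peaks in ((0, p50), (1, p52)):
            assert m.indicators[:, j].sum() <= len(peaks)
            assert m.indicators[:, j].any() == bool(peaks)


class TestPatternStatistics:
    def test_frequencies_trivial(self):
        m = occ([
            ("1100", GenomicRegion("chr1", 0, 10)),
            ("1100", GenomicRegion("chr1", 20, 30)),
            ("1111", GenomicRegion("chr1", 40, 50)),
        ])
        tab = pattern_frequencies(m).table.set_index("code")
        assert tab.loc["1100", "count"] == 2
        assert tab.loc["1100", "pct"] == pytest.approx(200 / 3)
        assert tab["pct"].sum() == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_frequencies_match_naive_count(self, seed):
        m = build_occupancy_matrix(random_peaksets(seed))
        tab = pattern_frequencies(m).table.set_index("code")["count"]
        assert tab.to_dict() == brute_force_pattern_counts(m.codes)

    def test_pattern_conservation(self, small_sim):
        m = small_sim["m"]
        tab = pattern_frequencies(m).table.set_index("code")["count"]
        for j, s in enumerate(SUBUNITS):
            from_patterns = sum(c for code, c in tab.items() if code[j] == "1")
            assert from_patterns == int(m.indicators[:, j].sum())

    def test_sharing_trivial(self):
        m = occ([("1100", GenomicRegion("chr1", 0, 10))])
        st = sharing_statistics(m)
        assert st.shared["p50"] == 1.0
        assert st.pairwise.loc["p50", "p52"] == 1.0
        assert np.isnan(st.shared["RelA"])
        m2 = occ([("1000", GenomicRegion("chr1", 0, 10)),
                  ("1000", GenomicRegion("chr1", 20, 30))])
        assert sharing_statistics(m2).shared["p50"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_sharing_matches_set_algebra(self, seed):
        m = build_occupancy_matrix(random_peaksets(seed))
        st = sharing_statistics(m)
        expect_shared = brute_force_sharing(m.codes)
        expect_pair = brute_force_pairwise(m.codes)
        for s in SUBUNITS:
            assert st.shared[s] == pytest.approx(expect_shared[s], nan_ok=True)
            for t in SUBUNITS:
                assert st.pairwise.loc[s, t] == pytest.approx(
                    expect_pair[(s, t)], nan_ok=True
                )


class TestTssDistance:
    def test_summit_at_tss_in_central_bin(self, tiny_annotation):
        m = occ([("1000", GenomicRegion("chr1", 9_900, 10_100, summit=100))])
        prof = tss_distance_profile(m, tiny_annotation, window=1000, nbins=10)
        assert prof.counts.sum() + prof.overflow == 1
        central = np.argmax(prof.counts)
        assert prof.edges[central] <= 0 <= prof.edges[central + 1]

    def test_upstream_is_negative_by_strand(self, tiny_annotation):
        # 500 bp before gB's minus-strand TSS (larger coordinate) is upstream
        m = occ([("1000", GenomicRegion("chr1", 60_399, 60_599, summit=100))])
        prof = tss_distance_profile(m, tiny_annotation, window=2000, nbins=4)
        assert prof.distances[0] == -500

    def test_counts_conserved_with_overflow(self, small_sim):
        prof = tss_distance_profile(
            small_sim["m"], small_sim["ann"], window=3000, nbins=10
        )
        assert prof.counts.sum() + prof.overflow == len(small_sim["m"])

    def test_proximal_only_cistrome_peaks_centrally(self):
        ann = sd.simulate_genome(50, 2_000_000, seed=31)
        peaks, _, _ = sd.simulate_cistrome(
            ann, proximal_frac=1.0, n_regions=80, seed=32
        )
        m = build_occupancy_matrix(peaks)
        prof = tss_distance_profile(m, ann, window=10_000, nbins=10)
        # all summits within +-2 kb: the two central bins hold everything
        assert prof.counts[4] + prof.counts[5] == len(m)
        assert prof.overflow == 0


class TestFeatureAnnotation:
    def test_promoter_beats_gene_body(self, tiny_annotation):
        r = GenomicRegion("chr1", 9_400, 9_600, summit=100)  # 500 bp upstream
        assert genomic_feature_annotation(r, tiny_annotation) == "promoter"

    def test_intron_and_exon(self, tiny_annotation):
        intron = GenomicRegion("chr1", 12_900, 13_100, summit=100)
        assert genomic_feature_annotation(intron, tiny_annotation) == "intron"
        exon = GenomicRegion("chr1", 14_750, 14_950, summit=100)
        assert genomic_feature_annotation(exon, tiny_annotation) == "exon"

    def test_gene_desert_is_intergenic(self, tiny_annotation):
        r = GenomicRegion("chr1", 90_000, 90_200, summit=100)
        assert genomic_feature_annotation(r, tiny_annotation) == "intergenic"


class TestClusterProfiles:
    def test_default_k_is_eight(self):
        assert inspect.signature(cluster_profiles).parameters["k"].default == 8

    def test_planted_two_groups_recovered_exactly(self):
        # two well-separated profile groups (p50+p52 vs RelA+RelB)
        ann = sd.simulate_genome(60, 2_000_000, seed=41)
        peaks, profiles, truth = sd.simulate_cistrome(
            ann, pattern_freqs={"1100": 0.5, "0011": 0.5},
            n_regions=60, seed=42,
        )
        m = build_occupancy_matrix(peaks)
        attach_profiles(m, profiles)
        cp = cluster_profiles(m, k=2, seed=0)
        split = pd.crosstab(cp.labels, truth.regions["pattern"])
        # each cluster holds exactly one pattern
        assert ((split == 0).sum(axis=1) == 1).all()

    def test_k_larger_than_n_rejected(self, small_sim):
        m = small_sim["m"]
        attach_profiles(m, small_sim["profiles"])
        with pytest.raises(ValueError):
            cluster_profiles(m, k=len(m) + 1, seed=0)

    def test_requires_all_profiles(self, small_sim):
        m = build_occupancy_matrix(small_sim["peaks"])
        with pytest.raises(ValueError, match="profiles"):
            cluster_profiles(m, k=2, seed=0)

    def test_deterministic_and_row_order_invariant(self, small_sim):
        m = small_sim["m"]
        attach_profiles(m, small_sim["profiles"])
        a = cluster_profiles(m, k=4, seed=3)
        b = cluster_profiles(m, k=4, seed=3)
        assert np.array_equal(a.labels, b.labels)
        assert a.wcss == b.wcss


class TestCompareCistromes:
    def test_identity_is_100_percent(self, small_sim):
        cmp = compare_cistromes(small_sim["m"], small_sim["m"])
        for s, v in cmp.per_subunit.items():
            if not np.isnan(v):
                assert v == 1.0
        assert cmp.mean_overlap == 1.0

    def test_disjoint_is_zero(self):
        a = occ([("1111", GenomicRegion("chr1", 0, 100))])
        b = occ([("1111", GenomicRegion("chr1", 5_000, 5_100))])
        cmp = compare_cistromes(a, b)
        assert cmp.mean_overlap == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_interval_oracle(self, seed):
        ma = build_occupancy_matrix(random_peaksets(seed))
        mb = build_occupancy_matrix(random_peaksets(seed + 100))
        cmp = compare_cistromes(ma, mb)
        expect = brute_force_compare(ma.regions, ma.codes, mb.regions, mb.codes)
        for s in SUBUNITS:
            assert cmp.per_subunit[s] == pytest.approx(expect[s], nan_ok=True)
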