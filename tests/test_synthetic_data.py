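import numpy as np
import pandas as pd
import pytest

from nfkbmap import SUBUNITS
from nfkbmap import synthetic_data as sd
from nfkbmap.cistrome_combinatorics import ALL_PATTERNS


class TestSimulateGenome:
    def test_reproducible_and_sized(self):
        a = sd.simulate_genome(10, 1_000_000, seed=1)
        b = sd.simulate_genome(10, 1_000_000, seed=1)
        assert len(a) == 10
        assert a.to_frame().equals(b.to_frame())

    def test_no_tss_collisions_alternating_strands(self):
        ann = sd.simulate_genome(50, 2_000_000, seed=3)
        tss = [g.tss for g in ann.genes.values()]
        assert len(set(tss)) == 50
        strands = [ann.genes[g].strand for g in sorted(ann.genes)]
        assert strands[:4] == ["+", "-", "+", "-"]

    @pytest.mark.parametrize("n,length", [(0, 1_000_000), (1000, 1_000_000)])
    def test_invalid_or_too_small(self, n, length):
        with pytest.raises(ValueError):
            sd.simulate_genome(n, length, seed=0)


class TestSimulateCistrome:
    def test_all_subunits_colocated(self):
        ann = sd.simulate_genome(20, 1_000_000, seed=5)
        peaks, _, truth = sd.simulate_cistrome(
            ann, pattern_freqs={"1111": 1.0}, n_regions=5, seed=6
        )
        assert all(len(peaks[s]) == 5 for s in SUBUNITS)
        coords = {tuple((r.chrom, r.start, r.end) for r in sorted(peaks[s]))
                  for s in SUBUNITS}
        assert len(coords) == 1  # identical intervals in all four sets

    def test_absent_subunits_have_empty_sets(self):
        ann = sd.simulate_genome(20, 1_000_000, seed=5)
        peaks, _, _ = sd.simulate_cistrome(
            ann, pattern_freqs={"1100": 1.0}, n_regions=8, seed=6
        )
        assert len(peaks["RelA"]) == 0 and len(peaks["RelB"]) == 0
        assert len(peaks["p50"]) == 8 and len(peaks["p52"]) == 8

    def test_multinomial_pattern_frequencies(self):
        # uniform over the 15 patterns: each within 3 binomial SDs of 1/15
        ann = sd.simulate_genome(400, 8_000_000, seed=7)
        freqs = {p: 1 / 15 for p in ALL_PATTERNS}
        _, _, truth = sd.simulate_cistrome(
            ann, pattern_freqs=freqs, n_regions=2000, seed=8
        )
        counts = truth.regions["pattern"].value_counts()
        p = 1 / 15
        sd3 = 3 * np.sqrt(2000 * p * (1 - p))
        for pat in ALL_PATTERNS:
            assert abs(counts.get(pat, 0) - 2000 * p) <= sd3

    def test_conservation_and_membership(self, small_sim):
        truth, peaks = small_sim["truth"], small_sim["peaks"]
        assert len(truth.regions) == 200
        for j, s in enumerate(SUBUNITS):
            n_with = int((truth.regions["pattern"].str[j] == "1").sum())
            assert len(peaks[s]) == n_with

    def test_determinism(self):
        ann = sd.simulate_genome(30, 1_000_000, seed=9)
        out1 = sd.simulate_cistrome(ann, n_regions=40, seed=10)
        out2 = sd.simulate_cistrome(ann, n_regions=40, seed=10)
        assert out1[2].regions.equals(out2[2].regions)
        assert out1[1].equals(out2[1])
        assert out1[0] == out2[0]

    @pytest.mark.parametrize(
        "kwargs", [
            {"pattern_freqs": {"1111": 0.5}},
            {"proximal_frac": 1.5},
            {"pattern_freqs": {"0000": 1.0}},
        ]
    )
    def test_parameter_validation(self, kwargs):
        ann = sd.simulate_genome(10, 1_000_000, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_cistrome(ann, n_regions=5, seed=0, **kwargs)

    def test_profile_high_iff_present(self, small_sim):
        prof = small_sim["profiles"]
        truth = small_sim["truth"]
        bins = [c for c in prof.columns if c.startswith("b")]
        merged = prof.merge(
            truth.regions, on=["chrom", "start", "end"], how="left"
        )
        sub_idx = {s: j for j, s in enumerate(SUBUNITS)}
        present = merged.apply(
            lambda r: r["pattern"][sub_idx[r["subunit"]]] == "1", axis=1
        )
        peak_height = merged[bins].max(axis=1)
        assert peak_height[present].min() > 5.0
        assert peak_height[~present].max() < 1.0


class TestKnockdownExpression:
    def _forced_truth(self, ann, activated: bool):
        """Truth in which every bound gene is regulated by both pathways."""
        _, _, truth = sd.simulate_cistrome(ann, n_regions=10, seed=21)
        truth.intercept = {"canonical": 30.0, "noncanonical": 30.0}
        truth.activated_frac = 1.0 if activated else 0.0
        return truth

    def test_planted_activated_shift_recovered(self):
        ann = sd.simulate_genome(20, 1_000_000, seed=20)
        truth = self._forced_truth(ann, activated=True)
        expr = sd.simulate_knockdown_expression(
            ann, truth, n_reps=3, effect_log2=2.0, sigma=0.1, seed=22
        )
        reg = truth.genes[truth.genes["canonical_regulated"]]
        assert len(reg) >= 1
        g1 = expr.samples_in_group("Group1")
        g2 = expr.samples_in_group("Group2")
        for gene in reg.index:
            clusters = [tc for tc, g in ann.cluster_to_gene.items() if g == gene]
            d = (expr.values.loc[clusters, g1].mean(axis=1)
                 - expr.values.loc[clusters, g2].mean(axis=1))
            assert np.all(np.abs(d - 2.0) < 0.2)

    def test_null_case_no_shift(self):
        ann = sd.simulate_genome(20, 1_000_000, seed=20)
        truth = self._forced_truth(ann, activated=True)
        expr = sd.simulate_knockdown_expression(
            ann, truth, n_reps=5, effect_log2=0.0, sigma=0.2, seed=23
        )
        g1 = expr.samples_in_group("Group1")
        g2 = expr.samples_in_group("Group2")
        d = (expr.values[g1].mean(axis=1) - expr.values[g2].mean(axis=1))
        assert np.abs(d).max() < 6 * 0.2  # pure noise scale

    def test_repressed_shift_has_opposite_sign(self):
        ann = sd.simulate_genome(20, 1_000_000, seed=20)
        truth = self._forced_truth(ann, activated=False)
        expr = sd.simulate_knockdown_expression(
            ann, truth, n_reps=3, effect_log2=2.0, sigma=0.1, seed=24
        )
        reg = truth.genes[truth.genes["canonical_regulated"]]
        g1 = expr.samples_in_group("Group1")
        g2 = expr.samples_in_group("Group2")
        gene = reg.index[0]
        clusters = [tc for tc, g in ann.cluster_to_gene.items() if g == gene]
        d = (expr.values.loc[clusters, g1].mean(axis=1)
             - expr.values.loc[clusters, g2].mean(axis=1))
        assert np.all(d < -1.5)

    def test_determinism_and_design_shape(self):
        ann = sd.simulate_genome(15, 1_000_000, seed=25)
        _, _, truth = sd.simulate_cistrome(ann, n_regions=10, seed=26)
        e1 = sd.simulate_knockdown_expression(ann, truth, n_reps=3, seed=27)
        truth.genes = None
        e2 = sd.simulate_knockdown_expression(ann, truth, n_reps=3, seed=27)
        assert e1.values.equals(e2.values)
        assert e1.values.shape[1] == 4 * 6  # 4 groups x 2 siRNA x 3 reps
        assert sorted(set(e1.groups.values())) == [
            "Group1", "Group2", "Group3", "Group4"
        ]

    @pytest.mark.parametrize("kwargs", [{"sigma": 0.0}, {"n_reps": 1}])
    def test_parameter_validation(self, kwargs):
        ann = sd.simulate_genome(15, 1_000_000, seed=25)
        _, _, truth = sd.simulate_cistrome(ann, n_regions=10, seed=26)
        with pytest.raises(ValueError):
            sd.simulate_knockdown_expression(ann, truth, seed=0, **kwargs)


class TestLymphomaPanel:
    def _targets(self):
        return pd.DataFrame(
            {
                "canonical_regulated": [True] * 4 + [False] * 4,
                "canonical_direction": ["activated", "activated", "repressed",
                                        "repressed"] + ["none"] * 4,
                "noncanonical_regulated": [False] * 4 + [True] * 4,
                "noncanonical_direction": ["none"] * 4
                + ["activated", "activated", "repressed", "repressed"],
                "direct_canonical": [True] * 4 + [False] * 4,
                "direct_noncanonical": [False] * 4 + [True] * 4,
            },
            index=pd.Index([f"t{i}" for i in range(8)], name="gene"),
        )

    def test_concordant_frac_extremes(self):
        targets = self._targets()
        panel1, t1 = sd.simulate_lymphoma_panel(targets, concordant_frac=1.0,
                                                seed=1)
        assert sorted(t1.concordant) == sorted(targets.index)
        assert t1.discordant == []
        _, t0 = sd.simulate_lymphoma_panel(targets, concordant_frac=0.0, seed=1)
        assert t0.concordant == [] and sorted(t0.discordant) == sorted(
            targets.index
        )

    def test_shift_directions(self):
        targets = self._targets()
        panel, truth = sd.simulate_lymphoma_panel(
            targets, concordant_frac=1.0, seed=2, effect_log2=3.0, sigma=0.1
        )
        hl = [c for c in panel.values.columns if c.startswith("HL_")]
        rest = [c for c in panel.values.columns if not c.startswith("HL_")]
        d = panel.values[hl].mean(axis=1) - panel.values[rest].mean(axis=1)
        assert d.loc["t0"] > 2.0    # activated, concordant -> up in HL
        assert d.loc["t2"] < -2.0   # repressed, concordant -> down in HL

    def test_low_expression_planted_below_floor(self):
        panel, truth = sd.simulate_lymphoma_panel(
            self._targets(), seed=3, n_background=50, low_frac=0.2
        )
        assert len(truth.low_expressed) == 10
        means = panel.values.mean(axis=1)
        assert (means.loc[truth.low_expressed] < 6.0).all()
        assert (means.loc[[g for g in self._targets().index]] >= 6.0).all()

    @pytest.mark.parametrize(
        "kwargs", [{"n_hl": 1}, {"concordant_frac": 2.0}, {"sigma": 0.0}]
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ValueError):
            sd.simulate_lymphoma_panel(self._targets(), seed=0, **kwargs)
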