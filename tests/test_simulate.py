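"""Read simulator: determinism, error-rate calibration, mixtures, replicates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6acall import (
    ErrorModel,
    mix_read_sets,
    motif_array_reference,
    per_site_features,
    simulate_reads,
    simulate_replicates,
)


def random_reference(length, seed, with_a=True):
    rng = np.random.default_rng(seed)
    letters = list("ACGT") if with_a else list("CGT")
    return "".join(rng.choice(letters, size=length))


class TestSimulateReads:
    def test_deterministic_for_fixed_seed(self, calm_model):
        ref = random_reference(30, 1)
        a = simulate_reads(ref, 20, [], 0.0, calm_model, seed=5)
        b = simulate_reads(ref, 20, [], 0.0, calm_model, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        c = simulate_reads(ref, 20, [], 0.0, calm_model, seed=6)
        assert not a[0].equals(c[0])

    def test_every_read_covers_every_position_once(self, calm_model):
        ref = random_reference(25, 2)
        perbase, _ = simulate_reads(ref, 15, [], 0.0, calm_model, seed=1)
        counts = perbase.groupby(["read_id", "pos"]).size()
        assert (counts == 1).all()
        assert len(perbase) == 15 * 25

    @staticmethod
    def assert_binomial_rate(observed, p, n):
        """Each site within 3 binomial SDs up to the expected multiple-test
        exceedance (<=1% of sites), and the pooled rate within 3 pooled SDs."""
        observed = np.asarray(observed)
        sd = np.sqrt(p * (1 - p) / n)
        outside = np.abs(observed - p) > 3 * sd
        assert outside.mean() <= 0.01
        pooled_sd = sd / np.sqrt(len(observed))
        assert abs(observed.mean() - p) <= 3 * pooled_sd

    def test_baseline_rates_match_model(self, calm_model):
        # empirical frequencies at coverage 1e4 against binomial expectation
        ref = random_reference(40, 3)
        cov = 10_000
        perbase, _ = simulate_reads(ref, cov, [], 0.0, calm_model, seed=9)
        sites = per_site_features(perbase, reference=ref)
        for col, p in (
            ("mismatch_freq", calm_model.p_mismatch),
            ("deletion_freq", calm_model.p_deletion),
            ("insertion_freq", calm_model.p_insertion),
        ):
            self.assert_binomial_rate(sites[col], p, cov)

    def test_modified_sites_get_shifted_rates(self, calm_model):
        ref, centers = motif_array_reference(20, seed=4)
        cov = 10_000
        perbase, _ = simulate_reads(ref, cov, centers, 1.0, calm_model, seed=9)
        sites = per_site_features(perbase, reference=ref)
        at = sites["pos"].isin(centers)
        p_mod = calm_model.p_mismatch + calm_model.mismatch_delta
        self.assert_binomial_rate(sites.loc[at, "mismatch_freq"], p_mod, cov)
        # off-target sites stay at baseline (no neighbour bleed in calm model)
        self.assert_binomial_rate(
            sites.loc[~at, "mismatch_freq"], calm_model.p_mismatch, cov
        )

    def test_quality_shift_applied(self, calm_model):
        ref, centers = motif_array_reference(20, seed=4)
        perbase, _ = simulate_reads(ref, 2000, centers, 1.0, calm_model, seed=2)
        sites = per_site_features(perbase, reference=ref)
        at = sites["pos"].isin(centers)
        gap = sites.loc[~at, "mean_quality"].mean() - sites.loc[at, "mean_quality"].mean()
        assert gap == pytest.approx(-calm_model.quality_shift, abs=0.3)

    def test_zero_coverage_yields_empty_tables(self):
        perbase, events = simulate_reads("ACGT", 0, [], 0.0, seed=1)
        assert len(perbase) == 0 and len(events) == 0

    def test_modified_position_must_be_adenine(self):
        with pytest.raises(ValueError, match="adenine"):
            simulate_reads("ACGT", 5, [2], 1.0, seed=1)  # position 2 is C

    def test_exact_modified_read_count(self, calm_model):
        # round(coverage * fraction) reads carry the modification, exactly
        ref, centers = motif_array_reference(5, seed=1)
        model = ErrorModel(
            p_mismatch=0.0, p_deletion=0.0, p_insertion=0.0, mismatch_delta=1.0,
            deletion_delta=0.0, kmer_error_spread=0.0, kmer_delta_spread=0.0,
            neighbor_bleed=(0.0, 0.0),
        )
        perbase, _ = simulate_reads(ref, 10, centers, 0.31, model, seed=8)
        at = perbase[perbase["pos"] == centers[0]]
        assert (at["call"] != at["ref_base"]).sum() == round(10 * 0.31)

    def test_current_shift_in_modified_windows(self, calm_model):
        model = ErrorModel(
            p_mismatch=0.0, p_deletion=0.0, p_insertion=0.0,
            kmer_current_spread=0.0, neighbor_bleed=(0.0, 0.0),
            kmer_error_spread=0.0, kmer_delta_spread=0.0, kmer_quality_spread=0.0,
        )
        ref, centers = motif_array_reference(10, seed=2)
        _, ev_mod = simulate_reads(ref, 400, centers, 1.0, model, seed=3)
        _, ev_unm = simulate_reads(ref, 400, [], 0.0, model, seed=4)
        c = centers[0]
        win = ev_mod["window_start"].between(c - 4, c)  # windows covering c
        gap = ev_mod.loc[win, "mean_pA"].mean() - ev_unm.loc[win, "mean_pA"].mean()
        assert gap == pytest.approx(model.current_shift, abs=0.5)


class TestMixReadSets:
    @pytest.fixture()
    def pools(self, calm_model):
        ref, centers = motif_array_reference(5, seed=6)
        mod, _ = simulate_reads(ref, 60, centers, 1.0, calm_model, seed=1,
                                read_prefix="mod", emit_events=False)
        unm, _ = simulate_reads(ref, 60, [], 0.0, calm_model, seed=2,
                                read_prefix="unm", emit_events=False)
        return mod, unm

    def test_extreme_fractions(self, pools):
        mod, unm = pools
        all_unm = mix_read_sets(mod, unm, 0.0, 50, seed=1)
        assert all_unm["read_id"].str.startswith("unm").all()
        all_mod = mix_read_sets(mod, unm, 1.0, 50, seed=1)
        assert all_mod["read_id"].str.startswith("mod").all()

    def test_exact_mixture_counts(self, pools):
        mod, unm = pools
        mixed = mix_read_sets(mod, unm, 0.25, 40, seed=3)
        ids = mixed["read_id"].unique()
        assert len(ids) == 40
        assert sum(i.startswith("mod") for i in ids) == 10

    def test_shortfall_is_an_error(self, pools):
        mod, unm = pools
        with pytest.raises(ValueError, match="shortfall"):
            mix_read_sets(mod, unm, 1.0, 1000, seed=1)


class TestReplicates:
    def test_replicate_count_and_keys(self, calm_model):
        ref, centers = motif_array_reference(5, seed=1)
        data = simulate_replicates(ref, {"wt": 0.5, "ko": 0.0}, 3, 10,
                                   centers, calm_model, seed=1)
        assert len(data) == 6
        assert ("wt", 1) in data and ("ko", 3) in data

    def test_ko_indistinguishable_from_baseline(self, calm_model):
        # pooled two-sample proportion test at the modified positions
        ref, centers = motif_array_reference(30, seed=8)
        data = simulate_replicates(ref, {"ko": 0.0}, 1, 1000, centers,
                                   calm_model, seed=5)
        base, _ = simulate_reads(ref, 1000, [], 0.0, calm_model, seed=77)
        ko = data[("ko", 1)][0]

        def mismatches_at(table):
            at = table[table["pos"].isin(centers)]
            return ((at["call"] != at["ref_base"]) & (at["call"] != "DEL")).sum(), len(at)

        x1, n1 = mismatches_at(ko)
        x2, n2 = mismatches_at(base)
        p = (x1 + x2) / (n1 + n2)
        z = (x1 / n1 - x2 / n2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert 2 * stats.norm.sf(abs(z)) > 0.01

    def test_replicate_error_patterns_cluster_by_condition(self):
        # per-site mismatch at modified sites: wt-wt rank correlation beats
        # wt-ko, because the modification effect itself varies by k-mer; use
        # a random reference so the modified sites span many 5-mer contexts
        ref = random_reference(2000, 19)
        sites_a = [i + 1 for i, b in enumerate(ref) if b == "A" and 2 <= i < len(ref) - 2]
        data = simulate_replicates(ref, {"wt": 0.5, "ko": 0.0}, 2, 500,
                                   sites_a, seed=13)

        def site_mismatch(table):
            sites = per_site_features(table, reference=ref)
            return sites.set_index("pos").loc[sites_a, "mismatch_freq"]

        wt1 = site_mismatch(data[("wt", 1)][0])
        wt2 = site_mismatch(data[("wt", 2)][0])
        ko1 = site_mismatch(data[("ko", 1)][0])
        rho_ww = stats.spearmanr(wt1, wt2).statistic
        rho_wk = stats.spearmanr(wt1, ko1).statistic
        assert rho_ww > rho_wk

    def test_insertions_uninformative_across_conditions(self):
        # default insertion_delta = 0: insertion frequency carries no signal
        ref, centers = motif_array_reference(50, seed=2)
        wt, _ = simulate_reads(ref, 1000, centers, 1.0, seed=21)
        ko, _ = simulate_reads(ref, 1000, [], 0.0, seed=22)
        f_wt = per_site_features(wt, reference=ref).set_index("pos").loc[
            centers, "insertion_freq"]
        f_ko = per_site_features(ko, reference=ref).set_index("pos").loc[
            centers, "insertion_freq"]
        assert abs(f_wt.mean() - f_ko.mean()) < 0.005
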