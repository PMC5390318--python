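"""Blood-variable selection, matched correlations, permutation null,
distribution comparison and paired similarity."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from oculoconcord.core import AnalysisConfig
from oculoconcord.exceptions import ArgumentError
from oculoconcord.simulate import SimConfig, simulate_dataset
from oculoconcord.surrogate import (
    blood_variable_probes,
    common_correlated_probes,
    compare_to_null,
    matched_probe_correlation,
    paired_similarity,
    permutation_null,
)

from conftest import make_beta, make_sheet


def matched_sheet(n_donors=8, tissues=("blood", "retina")):
    donors = [f"D{i+1}" for i in range(n_donors)]
    ids, ds, ts = [], [], []
    for d in donors:
        for t in tissues:
            ids.append(f"{d}_{t}")
            ds.append(d)
            ts.append(t)
    return make_sheet(ids, ds, ts)


class TestBloodVariable:
    def test_constant_probe_excluded(self, acfg):
        sheet = matched_sheet(8, ("blood",))
        b = make_beta(np.full((1, 8), 0.1), sample_ids=sheet.sample_ids)
        assert len(blood_variable_probes(b, sheet, acfg)) == 0

    def test_boundary_range_exactly_5_percent_excluded(self, acfg):
        # 8 values with q90 - q10 exactly 0.05 under h = (n-1)p interpolation
        vals = np.array([0.10, 0.10, 0.10, 0.12, 0.12, 0.13, 0.15, 0.15])
        q10, q90 = np.quantile(vals, [0.1, 0.9])
        assert q90 - q10 == pytest.approx(0.05)
        sheet = matched_sheet(8, ("blood",))
        b = make_beta(vals.reshape(1, -1), sample_ids=sheet.sample_ids)
        assert len(blood_variable_probes(b, sheet, acfg)) == 0

    def test_interpolated_quantiles_hand_checked(self, acfg):
        vals = np.arange(0.1, 0.81, 0.1)
        sheet = matched_sheet(8, ("blood",))
        b = make_beta(vals.reshape(1, -1), sample_ids=sheet.sample_ids)
        vset = blood_variable_probes(b, sheet, acfg)
        row = vset.table.iloc[0]
        assert row["q_lo"] == pytest.approx(0.17)
        assert row["q_hi"] == pytest.approx(0.73)
        assert row["range"] == pytest.approx(0.56)

    def test_monotone_in_threshold(self, default_sim):
        sizes = [
            len(
                blood_variable_probes(
                    default_sim.beta,
                    default_sim.sheet,
                    AnalysisConfig(variability_range_min=r),
                )
            )
            for r in (0.02, 0.05, 0.10, 0.20)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_requires_two_blood_samples(self, acfg):
        sheet = matched_sheet(1, ("blood",))
        b = make_beta([[0.5]], sample_ids=sheet.sample_ids)
        with pytest.raises(ArgumentError):
            blood_variable_probes(b, sheet, acfg)


class TestMatchedCorrelation:
    def test_identical_vectors_give_rho_one(self, acfg):
        sheet = matched_sheet()
        v = np.linspace(0.1, 0.8, 8)
        b = make_beta(
            np.concatenate([np.repeat(v, 2)]).reshape(1, -1),
            sample_ids=sheet.sample_ids,
        )
        res = matched_probe_correlation(b, sheet, None, "retina", acfg)
        assert res["rho"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] == 0.0
        assert bool(res["selected"].iloc[0])

    def test_p_value_closed_form_against_incomplete_beta(self, acfg):
        # n = 8, rho = 0.5: t = 0.5*sqrt(6/0.75) = sqrt(2); two-sided p via
        # the regularised incomplete beta, an independent t-CDF route
        n, rho = 8, 0.5
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        assert t == pytest.approx(np.sqrt(2.0))
        p_oracle = special.betainc((n - 2) / 2, 0.5, (n - 2) / ((n - 2) + t**2))
        assert p_oracle == pytest.approx(0.2070, abs=2e-4)
        from oculoconcord.stats import spearman_p_t_approx

        assert spearman_p_t_approx(np.array([rho]), n)[0] == pytest.approx(
            p_oracle, abs=1e-12
        )

    def test_zero_rho_gives_p_one(self):
        from oculoconcord.stats import spearman_p_t_approx

        assert spearman_p_t_approx(np.array([0.0]), 8)[0] == pytest.approx(1.0)

    def test_exact_permutation_p_consistent_with_t_approximation(self, acfg):
        rng = np.random.default_rng(8)
        sheet = matched_sheet()
        vals = rng.uniform(0.1, 0.9, size=(40, 16))
        b = make_beta(vals, sample_ids=sheet.sample_ids)
        t_res = matched_probe_correlation(b, sheet, None, "retina", acfg, exact_p=False)
        e_res = matched_probe_correlation(b, sheet, None, "retina", acfg, exact_p=True)
        assert np.allclose(t_res["rho"], e_res["rho"])
        # both p variants order the probes near-identically
        rt = t_res["p_value"].rank().to_numpy()
        re = e_res["p_value"].rank().to_numpy()
        assert np.corrcoef(rt, re)[0, 1] > 0.99
        assert e_res.attrs["p_method"] == "exact_permutation"

    def test_too_few_donors_rejected(self, acfg):
        sheet = matched_sheet(3)
        b = make_beta(
            np.random.default_rng(0).uniform(size=(5, 6)), sample_ids=sheet.sample_ids
        )
        with pytest.raises(ArgumentError):
            matched_probe_correlation(b, sheet, None, "retina", acfg)

    def test_unmatched_donor_dropped_with_warning(self, acfg, caplog):
        sheet = matched_sheet(8)
        keep = [s for s in sheet.sample_ids if s != "D8_retina"]
        sub = sheet.table[sheet.table.sample_id.isin(keep)]
        from oculoconcord.core import SampleSheet

        sheet7 = SampleSheet(sub)
        rng = np.random.default_rng(1)
        b = make_beta(rng.uniform(size=(10, len(keep))), sample_ids=keep)
        with caplog.at_level("WARNING"):
            res = matched_probe_correlation(b, sheet7, None, "retina", acfg)
        assert res["n_donors"].iloc[0] == 7
        assert any("D8" in r.message for r in caplog.records)


class TestPermutationNull:
    def test_same_seed_reproduces_pooled_values(self, default_sim, acfg):
        args = (default_sim.beta, default_sim.sheet, None, "retina", acfg)
        a = permutation_null(*args)
        b = permutation_null(*args)
        assert np.array_equal(a.values, b.values)
        assert a.seed == acfg.rng_seed

    def test_null_mean_near_zero_without_donor_effects(self):
        sim = simulate_dataset(
            SimConfig(n_probes=3000, f_individual=0.0, seed=21)
        )
        cfg = AnalysisConfig(n_null_permutations=40, rng_seed=2)
        null = permutation_null(sim.beta, sim.sheet, None, "retina", cfg)
        assert null.values.size >= 1e5
        assert abs(null.values.mean()) < 0.02

    def test_values_bounded(self, default_sim, acfg):
        null = permutation_null(default_sim.beta, default_sim.sheet, None, "retina", acfg)
        assert np.all(np.abs(null.values) <= 1.0)


class TestCompareToNull:
    def test_identical_distributions_give_large_p(self, acfg):
        vals = np.linspace(-0.9, 0.9, 200)
        matched = pd.DataFrame({"rho": vals})
        from oculoconcord.surrogate import NullDistribution

        null = NullDistribution(values=vals.copy(), n_permutations=1, seed=0)
        _, z, p = compare_to_null(matched, null)
        assert abs(z) < 0.1 and p > 0.9

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        from oculoconcord.surrogate import NullDistribution

        base = rng.uniform(-0.5, 0.5, 1000)
        matched = pd.DataFrame({"rho": np.clip(base + 0.5, -1, 1)})
        null = NullDistribution(values=base, n_permutations=1, seed=0)
        _, _, p = compare_to_null(matched, null)
        assert p < 1e-15

    def test_statistic_matches_brute_force_rank_sum(self):
        from oculoconcord.stats import rank_sum_test
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        for _ in range(100):
            n1, n2 = rng.integers(3, 15, size=2)
            a = rng.choice(np.arange(6) / 5, size=n1)
            b = rng.choice(np.arange(6) / 5, size=n2)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            u, z, p = rank_sum_test(a, b)
            # oracle: explicit rank sums with tie-corrected normal variance
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            r1 = ranks[:n1].sum()
            u_oracle = r1 - n1 * (n1 + 1) / 2
            n = n1 + n2
            _, counts = np.unique(pooled, return_counts=True)
            sigma = np.sqrt(
                n1 * n2 / 12 * ((n + 1) - (counts**3 - counts).sum() / (n * (n - 1)))
            )
            z_oracle = (u_oracle - n1 * n2 / 2) / sigma
            p_oracle = 2 * sps.norm.sf(abs(z_oracle))
            assert u == pytest.approx(u_oracle, abs=1e-10)
            assert z == pytest.approx(z_oracle, abs=1e-10)
            assert p == pytest.approx(p_oracle, abs=1e-10)


class TestCommonCorrelated:
    def test_set_algebra(self):
        def res(sel):
            return pd.DataFrame(
                {"selected": sel}, index=[f"cg{i}" for i in range(len(sel))]
            )

        disjoint = {"a": res([True, False]), "b": res([False, True])}
        assert common_correlated_probes(disjoint) == set()
        same = {"a": res([True, True]), "b": res([True, True])}
        assert common_correlated_probes(same) == {"cg0", "cg1"}

    def test_individual_probes_enriched_in_intersection(self, acfg):
        sim = simulate_dataset(SimConfig(n_probes=3000, seed=17))
        var = blood_variable_probes(sim.beta, sim.sheet, acfg)
        res = {
            t: matched_probe_correlation(sim.beta, sim.sheet, var, t, acfg)
            for t in ("retina", "rpe_choroid", "optic_nerve")
        }
        common = common_correlated_probes(res)
        ind = set(sim.truth.probes_of_class("individual"))
        null = set(sim.truth.probes_of_class("none"))
        rate_ind = len(common & ind) / len(ind)
        rate_null = len(common & null) / len(null)
        assert rate_ind > 10 * max(rate_null, 1e-4)


class TestPairedSimilarity:
    def test_identical_tissues_flagged_similar(self, acfg):
        sheet = matched_sheet()
        v = np.linspace(0.2, 0.7, 8)
        b = make_beta(np.repeat(v, 2).reshape(1, -1), sample_ids=sheet.sample_ids)
        out = paired_similarity(b, sheet, "blood", "retina", acfg)
        assert out["mean_diff"].iloc[0] == 0.0
        assert bool(out["similar"].iloc[0])
        assert bool(out["zero_variance"].iloc[0])

    def test_t_statistic_matches_brute_force_formula(self, acfg):
        rng = np.random.default_rng(2)
        sheet = matched_sheet()
        vals = rng.uniform(0.2, 0.8, size=(50, 16))
        b = make_beta(vals, sample_ids=sheet.sample_ids)
        out = paired_similarity(b, sheet, "blood", "retina", acfg)
        blood_cols = [i for i, s in enumerate(sheet.sample_ids) if "blood" in s]
        ret_cols = [i for i, s in enumerate(sheet.sample_ids) if "retina" in s]
        d = vals[:, blood_cols] - vals[:, ret_cols]
        t_oracle = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(8))
        assert np.allclose(out["t"], t_oracle, atol=1e-12)

    def test_constant_shift_flagged_dissimilar(self, acfg):
        sheet = matched_sheet()
        rng = np.random.default_rng(9)
        blood = rng.uniform(0.2, 0.4, size=(30, 8))
        eye = blood + 0.3 + rng.normal(0, 0.005, size=blood.shape)
        vals = np.empty((30, 16))
        vals[:, ::2] = blood
        vals[:, 1::2] = eye
        b = make_beta(vals, sample_ids=sheet.sample_ids)
        out = paired_similarity(b, sheet, "blood", "retina", acfg)
        assert not out["similar"].any()
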