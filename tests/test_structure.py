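"""PCA, trait association, individual-exclusive components, moderated F."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oculoconcord.core import AnalysisConfig, MValueMatrix, beta_to_m
from oculoconcord.exceptions import ArgumentError
from oculoconcord.structure import (
    estimate_variance_prior,
    individual_exclusive_components,
    pc_associated_probes,
    pc_trait_association,
    run_pca,
    tissue_specific_probes,
)

from conftest import make_sheet


def mvm(values, probe_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:04d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return MValueMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))


class TestPCA:
    def test_single_variable_probe_gives_pc1_everything(self):
        vals = np.vstack([np.linspace(-2, 2, 6), np.zeros(6)])
        pca = run_pca(mvm(vals))
        assert pca.variance_explained[0] == pytest.approx(100.0)

    def test_variance_explained_sums_to_100(self, default_sim):
        pca = run_pca(beta_to_m(default_sim.beta))
        assert pca.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(pca.variance_explained) <= 1e-9)

    def test_reconstruction_and_orthogonality(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(60, 10))
        m = mvm(vals)
        pca = run_pca(m)
        centred = vals - vals.mean(axis=1, keepdims=True)
        recon = pca.loadings.to_numpy() @ pca.scores.to_numpy().T
        assert np.allclose(recon, centred, atol=1e-8)
        gram = pca.scores.to_numpy().T @ pca.scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-8)

    def test_pc1_separates_blood_from_eye(self, default_sim):
        pca = run_pca(beta_to_m(default_sim.beta))
        tissue = default_sim.sheet.tissue_of()
        pc1 = pca.scores["PC1"]
        blood = pc1[[s for s in pc1.index if tissue[s] == "blood"]]
        eye = pc1[[s for s in pc1.index if tissue[s] != "blood"]]
        assert blood.max() < eye.min() or blood.min() > eye.max()

    def test_probes_with_missing_values_dropped(self, caplog):
        vals = np.random.default_rng(0).normal(size=(5, 4))
        vals[0, 0] = np.nan
        with caplog.at_level("WARNING"):
            pca = run_pca(mvm(vals))
        assert pca.loadings.shape[0] == 4

    def test_needs_two_samples(self):
        with pytest.raises(ArgumentError):
            run_pca(mvm(np.zeros((3, 1))))


class TestTraitAssociation:
    def test_perfect_tissue_separation_gives_tiny_p(self):
        sheet = make_sheet(
            [f"D{d}_{t}" for d in (1, 2, 3) for t in ("blood", "retina")],
            [f"D{d}" for d in (1, 2, 3) for _ in range(2)],
            ["blood", "retina"] * 3,
        )
        vals = np.vstack([[1.0, -1.0] * 3] * 5) + np.random.default_rng(0).normal(
            0, 1e-3, size=(5, 6)
        )
        pca = run_pca(mvm(vals, sample_ids=sheet.sample_ids))
        assoc = pc_trait_association(pca, sheet, traits=["tissue"], n_components=1)
        assert assoc["p_value"].iloc[0] < 1e-8

    def test_anova_f_matches_sums_of_squares_oracle(self, default_sim):
        pca = run_pca(beta_to_m(default_sim.beta))
        assoc = pc_trait_association(pca, default_sim.sheet, traits=["tissue"])
        tissue = default_sim.sheet.tissue_of()
        labels = np.array([tissue[s] for s in pca.scores.index])
        for _, row in assoc.head(6).iterrows():
            scores = pca.scores.iloc[:, int(row.component) - 1].to_numpy()
            groups = [scores[labels == g] for g in np.unique(labels)]
            f_oracle, p_oracle = sps.f_oneway(*groups)
            assert row.statistic == pytest.approx(f_oracle, rel=1e-10, abs=1e-10)
            assert row.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_continuous_trait_uses_regression(self, default_sim):
        pca = run_pca(beta_to_m(default_sim.beta))
        assoc = pc_trait_association(pca, default_sim.sheet, traits=["age_at_death"])
        assert (assoc["test"] == "linear_regression").all()
        assert assoc["p_value"].between(0, 1).all()

    def test_single_level_trait_skipped_with_warning(self, caplog):
        sheet = make_sheet(
            ["a", "b", "c", "d"], ["D1", "D1", "D2", "D2"],
            ["blood", "retina", "blood", "retina"],
        )
        vals = np.random.default_rng(1).normal(size=(10, 4))
        pca = run_pca(mvm(vals, sample_ids=sheet.sample_ids))
        with caplog.at_level("WARNING"):
            assoc = pc_trait_association(pca, sheet, traits=["cause_of_death", "tissue"])
        assert set(assoc["trait"]) == {"tissue"}

    def test_null_calibration_of_anova_p(self):
        """Pure-noise scores vs a shuffled 4-level trait reject at ~5%."""
        rng = np.random.default_rng(12)
        n_rep, hits = 400, 0
        labels = np.repeat(np.arange(4), 8)
        for _ in range(n_rep):
            scores = rng.normal(size=32)
            perm = rng.permutation(labels)
            groups = [scores[perm == g] for g in range(4)]
            _, p = sps.f_oneway(*groups)
            hits += p < 0.05
        assert abs(hits / n_rep - 0.05) < 0.035


class TestExclusiveComponents:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["component", "trait", "p_value"])

    def test_component_with_tissue_association_excluded(self):
        assoc = self._assoc(
            [(1, "donor_id", 0.01), (1, "tissue", 0.001), (2, "donor_id", 0.01),
             (2, "tissue", 0.5)]
        )
        assert individual_exclusive_components(assoc) == [2]

    def test_alpha_threshold_respected(self):
        assoc = self._assoc([(1, "donor_id", 0.07), (1, "tissue", 0.5)])
        assert individual_exclusive_components(assoc, alpha=0.05) == []
        assert individual_exclusive_components(assoc, alpha=0.10) == [1]

    def test_simulation_yields_at_least_one_exclusive_component(self, default_sim):
        pca = run_pca(beta_to_m(default_sim.beta))
        assoc = pc_trait_association(pca, default_sim.sheet)
        assert len(individual_exclusive_components(assoc)) >= 1


class TestPCAssociatedProbes:
    def test_probe_equal_to_scores_selected(self, acfg):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(20, 10))
        pca = run_pca(mvm(base))
        s = pca.scores["PC1"].to_numpy()
        vals = np.vstack([base, s, rng.normal(size=10)])
        m = mvm(vals)
        probes = pc_associated_probes(m, run_pca(m), 1, acfg)
        assert f"cg{20:04d}" in probes  # the probe that IS the score vector

    def test_orthogonal_probe_excluded(self, acfg):
        # probe 0 dominates PC1; probe 1 is exactly orthogonal to it
        x = np.array([1.0, -1.0] * 4)
        y = np.array([1.0, 1.0, -1.0, -1.0] * 2)
        assert x @ y == 0
        m = mvm(np.vstack([10 * x, y]))
        pca = run_pca(m)
        probes = pc_associated_probes(m, pca, 1, acfg)
        assert "cg0000" in probes and "cg0001" not in probes

    def test_individual_probes_enriched(self, default_sim, acfg):
        m = beta_to_m(default_sim.beta)
        pca = run_pca(m)
        assoc = pc_trait_association(pca, default_sim.sheet)
        comp = individual_exclusive_components(assoc)[0]
        sel = set(pc_associated_probes(m, pca, comp, acfg))
        ind = set(default_sim.truth.probes_of_class("individual"))
        frac_sel = len(sel & ind) / len(sel)
        frac_all = len(ind) / default_sim.beta.shape[0]
        assert frac_sel / frac_all >= 5


class TestModeratedF:
    def test_zero_prior_df_recovers_ordinary_anova(self, default_sim, acfg):
        m = beta_to_m(default_sim.beta)
        res = tissue_specific_probes(m, default_sim.sheet, acfg, prior_df=0.0)
        tissue = default_sim.sheet.tissue_of()
        labels = np.array([tissue[s] for s in m.sample_ids])
        vals = m.data.to_numpy()
        for i in np.random.default_rng(0).choice(len(res), 25, replace=False):
            groups = [vals[i, labels == g] for g in np.unique(labels)]
            f_oracle, p_oracle = sps.f_oneway(*groups)
            assert res["F"].iloc[i] == pytest.approx(f_oracle, abs=1e-10)
            assert res["p_value"].iloc[i] == pytest.approx(p_oracle, abs=1e-10)

    def test_infinite_prior_df_pools_all_variances(self, default_sim, acfg):
        m = beta_to_m(default_sim.beta)
        res = tissue_specific_probes(m, default_sim.sheet, acfg, prior_df=np.inf)
        s0 = res.attrs["prior_variance"]
        # all posterior variances equal s0^2: F is proportional to the
        # between-tissue mean square alone
        tissue = default_sim.sheet.tissue_of()
        labels = np.array([tissue[s] for s in m.sample_ids])
        vals = m.data.to_numpy()
        i = 5
        groups = [vals[i, labels == g] for g in np.unique(labels)]
        grand = vals[i].mean()
        msb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (len(groups) - 1)
        assert res["F"].iloc[i] == pytest.approx(msb / s0, rel=1e-10)

    def test_posterior_variance_between_sample_and_prior(self, default_sim, acfg):
        m = beta_to_m(default_sim.beta)
        res = tissue_specific_probes(m, default_sim.sheet, acfg)
        d0, s0 = res.attrs["prior_df"], res.attrs["prior_variance"]
        tissue = default_sim.sheet.tissue_of()
        labels = np.array([tissue[s] for s in m.sample_ids])
        vals = m.data.to_numpy()
        k = len(np.unique(labels))
        ssw = np.zeros(vals.shape[0])
        for g in np.unique(labels):
            sub = vals[:, labels == g]
            ssw += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2 = ssw / (vals.shape[1] - k)
        d = vals.shape[1] - k
        post = (d0 * s0 + d * s2) / (d0 + d)
        lo, hi = np.minimum(s2, s0), np.maximum(s2, s0)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)
        # BH adjustment never decreases a p-value
        assert (res["p_adj"] >= res["p_value"] - 1e-15).all()

    def test_sensitivity_and_fdr_on_simulation(self, default_sim, acfg):
        m = beta_to_m(default_sim.beta)
        res = tissue_specific_probes(m, default_sim.sheet, acfg)
        tiss = set(default_sim.truth.probes_of_class("tissue"))
        sig = set(res.index[res["significant"]])
        assert len(sig & tiss) / len(tiss) >= 0.9
        assert len(sig - tiss) / max(len(sig), 1) <= 0.1

    def test_prior_estimation_recovers_known_hyperparameters(self):
        rng = np.random.default_rng(7)
        d0_true, s0_true, d = 8.0, 0.25, 28
        s2_true = s0_true * d0_true / rng.chisquare(d0_true, size=20000)
        s2_obs = s2_true * rng.chisquare(d, size=20000) / d
        d0_hat, s0_hat = estimate_variance_prior(s2_obs, d)
        assert d0_hat == pytest.approx(d0_true, rel=0.2)
        assert s0_hat == pytest.approx(s0_true, rel=0.05)
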