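"""Blood-as-surrogate covariation analysis.

The scientific question: at which CpG probes does inter-individual
variation measured in blood track inter-individual variation in an eye
tissue of the same donors?  The procedure:

1. restrict to *blood-variable* probes — inter-donor blood beta range
   between the 10th and 90th percentiles strictly greater than 5%;
2. per probe, Spearman-correlate the donor-ordered blood vector with the
   same donors' eye-tissue vector (n = number of matched donors); flag
   probes with |rho| above 0.5 and two-sided p below 0.05;
3. build a null by permuting donor labels of the eye samples (identity
   permutation excluded) and pooling the recomputed correlations, then
   compare matched vs null distributions with a rank-sum test;
4. intersect the flagged sets across eye tissues to find probes whose
   blood variation tracks all ocular tissues; and
5. separately, find the most similarly methylated probes between two
   tissues via donor-paired t-tests with BH correction plus an
   equivalence bound on the mean difference.

With n = 8 donors the Spearman null is discrete; the t approximation's
realised level at nominal p < 0.05 is 0.0576 (exact enumeration over 8!
orderings), and an exact-permutation p-value is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisConfig, BetaMatrix, SampleSheet
from .exceptions import ArgumentError, UndefinedResultError
from .stats import (
    bh_adjust,
    rank_sum_test,
    rowwise_spearman,
    spearman_p_exact,
    spearman_p_t_approx,
    spearman_rho,
)

__all__ = [
    "VariableProbeSet",
    "NullDistribution",
    "blood_variable_probes",
    "matched_probe_correlation",
    "permutation_null",
    "compare_to_null",
    "common_correlated_probes",
    "paired_similarity",
]

logger = logging.getLogger(__name__)


@dataclass
class VariableProbeSet:
    """Probes variable in blood, with their inter-donor quantile range."""

    table: pd.DataFrame  # index probe_id: q_lo, q_hi, range

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class NullDistribution:
    """Pooled correlations from permuted (unmatched) donor pairings."""

    values: np.ndarray
    n_permutations: int
    seed: int


def blood_variable_probes(
    b: BetaMatrix, sheet: SampleSheet, cfg: AnalysisConfig, tissue: str = "blood"
) -> VariableProbeSet:
    """Probes whose inter-donor blood beta range exceeds the threshold.

    Quantiles use linear interpolation between order statistics
    (``h = (n - 1) p``); inclusion is strict:
    ``q_hi - q_lo > cfg.variability_range_min``.
    """
    cols = sheet.samples_of_tissue(tissue)
    cols = [c for c in cols if c in b.sample_ids]
    if len(cols) < 2:
        raise ArgumentError(f"need >= 2 {tissue} samples, got {len(cols)}")
    lo, hi = cfg.variability_quantiles
    sub = b.data[cols]
    q = sub.quantile([lo, hi], axis=1, interpolation="linear").T
    q.columns = ["q_lo", "q_hi"]
    q["range"] = q["q_hi"] - q["q_lo"]
    keep = q["range"] > cfg.variability_range_min
    return VariableProbeSet(q.loc[keep])


def _matched_matrices(
    b: BetaMatrix,
    sheet: SampleSheet,
    probe_ids: Sequence[str] | None,
    eye_tissue: str,
    min_donors: int,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Donor-aligned (probes x donors) blood and eye beta arrays."""
    sheet.check_covers(b.sample_ids)
    donors, blood_cols, eye_cols = [], [], []
    for donor in sheet.donors:
        s_blood = sheet.sample_for(donor, "blood")
        s_eye = sheet.sample_for(donor, eye_tissue)
        if (
            s_blood is None
            or s_eye is None
            or s_blood not in b.sample_ids
            or s_eye not in b.sample_ids
        ):
            logger.warning(
                "donor %s lacks a matched blood/%s pair; dropped", donor, eye_tissue
            )
            continue
        donors.append(donor)
        blood_cols.append(s_blood)
        eye_cols.append(s_eye)
    if len(donors) < min_donors:
        raise ArgumentError(
            f"need >= {min_donors} donors with matched blood and {eye_tissue} "
            f"samples, got {len(donors)}"
        )
    probes = list(probe_ids) if probe_ids is not None else b.probe_ids
    sub = b.data.loc[probes]
    return (
        sub[blood_cols].to_numpy(),
        sub[eye_cols].to_numpy(),
        probes,
        donors,
    )


def matched_probe_correlation(
    b: BetaMatrix,
    sheet: SampleSheet,
    probes: VariableProbeSet | Sequence[str] | None,
    eye_tissue: str,
    cfg: AnalysisConfig,
    exact_p: bool = False,
) -> pd.DataFrame:
    """Per-probe Spearman correlation between matched blood and eye values.

    Donors lacking either sample are dropped with a warning; at least 4
    matched donors are required.  The two-sided p-value uses the
    ``t = rho * sqrt((n-2)/(1-rho^2))`` approximation with df = n - 2, or
    the exact permutation distribution when ``exact_p`` (n <= 9).
    ``selected`` flags ``|rho| > cfg.corr_r_min and p < cfg.corr_p_max``.
    """
    probe_ids = probes.probe_ids if isinstance(probes, VariableProbeSet) else probes
    blood, eye, probe_list, donors = _matched_matrices(
        b, sheet, probe_ids, eye_tissue, min_donors=4
    )
    n = len(donors)
    if np.isnan(blood).any() or np.isnan(eye).any():
        rho = np.full(len(probe_list), np.nan)
        for i in range(len(probe_list)):
            try:
                rho[i] = spearman_rho(blood[i], eye[i])
            except UndefinedResultError:
                pass
    else:
        rho = rowwise_spearman(blood, eye)
    if exact_p:
        p = spearman_p_exact(blood, eye, rho)
    else:
        p = spearman_p_t_approx(rho, n)
    with np.errstate(invalid="ignore"):
        selected = (np.abs(rho) > cfg.corr_r_min) & (p < cfg.corr_p_max)
    out = pd.DataFrame(
        {
            "probe_id": probe_list,
            "tissue": eye_tissue,
            "n_donors": n,
            "rho": rho,
            "p_value": p,
            "selected": np.where(np.isnan(rho), False, selected),
        }
    ).set_index("probe_id")
    out.attrs["p_method"] = "exact_permutation" if exact_p else "t_approximation"
    return out


def permutation_null(
    b: BetaMatrix,
    sheet: SampleSheet,
    probes: VariableProbeSet | Sequence[str] | None,
    eye_tissue: str,
    cfg: AnalysisConfig,
) -> NullDistribution:
    """Pooled per-probe correlations under permuted donor pairings.

    Draws ``cfg.n_null_permutations`` random non-identity permutations of
    the donor labels of the eye samples, recomputes every per-probe
    correlation for each, and pools them into one null distribution.
    Seeded by ``cfg.rng_seed``, hence reproducible.
    """
    probe_ids = probes.probe_ids if isinstance(probes, VariableProbeSet) else probes
    blood, eye, _, donors = _matched_matrices(b, sheet, probe_ids, eye_tissue, 3)
    n = len(donors)
    rng = np.random.default_rng(cfg.rng_seed)
    pooled = []
    for _ in range(int(cfg.n_null_permutations)):
        perm = rng.permutation(n)
        while np.array_equal(perm, np.arange(n)):
            perm = rng.permutation(n)
        if np.isnan(blood).any() or np.isnan(eye).any():
            vals = np.full(blood.shape[0], np.nan)
            for i in range(blood.shape[0]):
                try:
                    vals[i] = spearman_rho(blood[i], eye[i, perm])
                except UndefinedResultError:
                    pass
        else:
            vals = rowwise_spearman(blood, eye[:, perm])
        pooled.append(vals[~np.isnan(vals)])
    return NullDistribution(
        values=np.concatenate(pooled) if pooled else np.empty(0),
        n_permutations=int(cfg.n_null_permutations),
        seed=cfg.rng_seed,
    )


def compare_to_null(
    matched: pd.DataFrame, null: NullDistribution
) -> tuple[float, float, float]:
    """Two-sided rank-sum comparison of matched vs null correlations.

    Returns ``(U, z, p)`` from the Mann-Whitney test (normal approximation
    with tie correction) of the matched rho values against the pooled
    null values.
    """
    matched_vals = matched["rho"].dropna().to_numpy()
    if matched_vals.size == 0 or null.values.size == 0:
        raise ArgumentError("both matched and null distributions must be nonempty")
    return rank_sum_test(matched_vals, null.values)


def common_correlated_probes(
    results: Mapping[str, pd.DataFrame] | Iterable[pd.DataFrame],
) -> set[str]:
    """Probes selected in every supplied eye tissue (set intersection)."""
    frames = list(results.values()) if isinstance(results, Mapping) else list(results)
    if not frames:
        raise ArgumentError("no per-tissue results supplied")
    sets = [set(df.index[df["selected"]]) for df in frames]
    return set.intersection(*sets)


def paired_similarity(
    b: BetaMatrix,
    sheet: SampleSheet,
    tissue_a: str,
    tissue_b: str,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Donor-paired t-tests identifying similarly methylated probes.

    Per probe: paired t on donor-wise beta differences (tissue_a minus
    tissue_b), BH adjustment across probes, and a ``similar`` flag that
    requires BOTH non-significance (adjusted p >= cfg.fdr_q) AND a small
    mean difference (|mean diff| < cfg.equivalence_delta) — significance
    alone cannot certify similarity.  Probes with zero-variance
    differences have no t-statistic and are judged on the mean difference
    alone.
    """
    donors, a_cols, b_cols = [], [], []
    sheet.check_covers(b.sample_ids)
    for donor in sheet.donors:
        sa = sheet.sample_for(donor, tissue_a)
        sb = sheet.sample_for(donor, tissue_b)
        if sa in b.sample_ids and sb in b.sample_ids and sa and sb:
            donors.append(donor)
            a_cols.append(sa)
            b_cols.append(sb)
    if len(donors) < 3:
        raise ArgumentError(
            f"need >= 3 donors with both {tissue_a} and {tissue_b}, got {len(donors)}"
        )
    diffs = b.data[a_cols].to_numpy() - b.data[b_cols].to_numpy()
    n_eff = (~np.isnan(diffs)).sum(axis=1)
    mean_diff = np.nanmean(np.where(np.isnan(diffs), np.nan, diffs), axis=1)
    sd = np.full(diffs.shape[0], np.nan)
    ok = n_eff >= 2
    sd[ok] = np.nanstd(diffs[ok], axis=1, ddof=1)
    from scipy import stats as sps

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / (sd / np.sqrt(n_eff))
    t[(sd == 0) | (n_eff < 3)] = np.nan
    p = 2.0 * sps.t.sf(np.abs(t), df=np.maximum(n_eff - 1, 1))
    p[np.isnan(t)] = np.nan
    p_adj = bh_adjust(p)
    small_effect = np.abs(mean_diff) < cfg.equivalence_delta
    not_significant = np.where(np.isnan(p_adj), True, p_adj >= cfg.fdr_q)
    out = pd.DataFrame(
        {
            "probe_id": b.probe_ids,
            "n_donors": n_eff,
            "mean_diff": mean_diff,
            "t": t,
            "p_value": p,
            "p_adj": p_adj,
            "zero_variance": sd == 0,
            "similar": not_significant & small_effect,
        }
    ).set_index("probe_id")
    out.attrs["tissues"] = (tissue_a, tissue_b)
    return out
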