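"""Separating tissue-driven from individual-driven methylation variation.

PCA runs on M-values (probes centred across samples, samples as
observations); each component's scores are then screened against sample
traits — one-way ANOVA for categorical traits (tissue, donor, chip, cause
of death) and a simple-regression F-test for continuous ones (age,
preservation interval).  Components associated with donor identity but
with no other trait isolate inter-individual variation; the probes
driving such a component are picked by correlating each probe's M-values
with the component scores (|r| > 0.5 by default).

Tissue-specific probes are detected with a moderated one-way F-statistic:
per-probe residual variances are shrunk toward a common prior estimated
by empirical Bayes (moment matching on log s^2 via the digamma/trigamma
identities), which stabilises inference when per-group sample counts are
small.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .core import MValueMatrix, SampleSheet, AnalysisConfig
from .exceptions import ArgumentError
from .stats import bh_adjust

__all__ = [
    "PCAResult",
    "run_pca",
    "pc_trait_association",
    "individual_exclusive_components",
    "pc_associated_probes",
    "tissue_specific_probes",
    "estimate_variance_prior",
]

logger = logging.getLogger(__name__)

CATEGORICAL_TRAITS = ("tissue", "donor_id", "chip", "cause_of_death")
CONTINUOUS_TRAITS = ("age_at_death", "preservation_interval")


@dataclass
class PCAResult:
    """Scores (samples x components), loadings (probes x components) and
    percent variance explained, components ordered by decreasing variance."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray  # percent, sums to 100
    probe_means: pd.Series  # per-probe centring offsets

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(m: MValueMatrix) -> PCAResult:
    """Principal components of the centred M-value matrix via SVD.

    Probes with any missing value are dropped with a warning (PCA needs a
    complete matrix).  Sign convention: within each component the loading
    of largest magnitude is positive, so results are reproducible across
    SVD implementations.
    """
    if m.shape[1] < 2:
        raise ArgumentError("need at least 2 samples for PCA")
    data = m.data.dropna(axis=0)
    n_dropped = m.shape[0] - data.shape[0]
    if n_dropped:
        logger.warning("dropped %d probes with missing values before PCA", n_dropped)
    if data.shape[0] == 0:
        raise ArgumentError("no complete probes available for PCA")
    probe_means = data.mean(axis=1)
    centred = data.sub(probe_means, axis=0)  # probes x samples
    # samples as observations: SVD of the (samples x probes) centred matrix
    u, s, vt = np.linalg.svd(centred.to_numpy().T, full_matrices=False)
    k = len(s)
    # deterministic sign: largest-|loading| positive per component
    loadings = vt.T  # probes x k
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s  # samples x k
    total = (s**2).sum()
    var_pct = 100.0 * s**2 / total if total > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=data.index, columns=comp_names),
        variance_explained=var_pct,
        probe_means=probe_means,
    )


def _anova_f(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    groups = [scores[labels == g] for g in pd.unique(labels)]
    groups = [g for g in groups if g.size > 0]
    k = len(groups)
    n = scores.size
    if k < 2 or n - k < 1:
        raise ArgumentError("ANOVA needs >= 2 groups and residual df >= 1")
    grand = scores.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        return np.inf, 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(sps.f.sf(f, df_b, df_w))


def _regression_f(scores: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    ok = ~np.isnan(x)
    y, x = scores[ok], x[ok]
    n = y.size
    if n < 3 or np.ptp(x) == 0:
        raise ArgumentError("regression needs >= 3 observations and a variable trait")
    r = np.corrcoef(x, y)[0, 1]
    if np.isclose(abs(r), 1.0):
        return np.inf, 0.0
    f = r**2 * (n - 2) / (1.0 - r**2)
    return float(f), float(sps.f.sf(f, 1, n - 2))


def pc_trait_association(
    pca: PCAResult,
    sheet: SampleSheet,
    traits: list[str] | None = None,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Association of each component's scores with each sample trait.

    Categorical traits use one-way ANOVA of scores by level; continuous
    traits a simple linear-regression F-test.  Traits with a single
    observed level (or zero variance) are skipped with a warning.

    Traits that are constant within donor (age, cause of death,
    preservation interval, chip) are tested on donor-mean scores with the
    donor as the unit of replication: samples of one donor are not
    independent observations of a donor-level trait, and testing them as
    such would overstate significance for any donor-structured component.
    """
    sheet.check_covers(pca.scores.index)
    meta = sheet.table.set_index("sample_id").loc[pca.scores.index]
    if traits is None:
        traits = list(CATEGORICAL_TRAITS) + list(CONTINUOUS_TRAITS)
    unknown = set(traits) - set(meta.columns)
    if unknown:
        raise ArgumentError(f"unknown trait(s): {sorted(unknown)}")
    n_comp = n_components or pca.n_components
    donor = meta["donor_id"]
    rows = []
    for trait in traits:
        col = meta[trait]
        donor_level = trait != "donor_id" and (
            col.astype(str).groupby(donor).nunique().le(1).all()
        )
        if donor_level:
            col = col.groupby(donor).first()
        categorical = trait in CATEGORICAL_TRAITS or col.dtype == object
        if categorical:
            labels = col.astype(str).to_numpy()
            if len(pd.unique(labels)) < 2:
                logger.warning("trait %r has a single level; skipped", trait)
                continue
        else:
            x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            if np.ptp(x[~np.isnan(x)]) == 0 or (~np.isnan(x)).sum() < 3:
                logger.warning("trait %r has no usable variation; skipped", trait)
                continue
        for j in range(n_comp):
            scores_s = pca.scores.iloc[:, j]
            if donor_level:
                scores = scores_s.groupby(donor).mean().loc[col.index].to_numpy()
            else:
                scores = scores_s.to_numpy()
            if categorical:
                f, p = _anova_f(scores, labels)
                test = "ANOVA"
            else:
                f, p = _regression_f(scores, x)
                test = "linear_regression"
            rows.append(
                {
                    "component": j + 1,
                    "trait": trait,
                    "test": test,
                    "statistic": f,
                    "p_value": p,
                    "unit": "donor" if donor_level else "sample",
                }
            )
    return pd.DataFrame(rows)


def individual_exclusive_components(
    assoc: pd.DataFrame, alpha: float = 0.05, individual_trait: str = "donor_id"
) -> list[int]:
    """Components associated with donor identity and nothing else.

    A component qualifies when its individual-trait p < alpha while every
    other tested trait has p >= alpha.
    """
    if individual_trait not in set(assoc["trait"]):
        raise ArgumentError(f"no association results for trait {individual_trait!r}")
    out = []
    for comp, grp in assoc.groupby("component"):
        ind = grp.loc[grp["trait"] == individual_trait, "p_value"]
        others = grp.loc[grp["trait"] != individual_trait, "p_value"]
        if not ind.empty and (ind < alpha).all() and (others >= alpha).all():
            out.append(int(comp))
    return sorted(out)


def pc_associated_probes(
    m: MValueMatrix,
    pca: PCAResult,
    component: int,
    cfg: AnalysisConfig,
    use_loadings: bool = False,
) -> list[str]:
    """Probes whose M-values correlate with a component's score vector.

    Default: Pearson |r| > cfg.corr_r_min between each probe's M-values
    (across samples) and the scores.  ``use_loadings`` instead thresholds
    the normalised loading magnitudes — an alternative definition kept as
    an option.  Zero-variance probes are excluded (count logged).
    """
    if not (1 <= component <= pca.n_components):
        raise ArgumentError(f"component {component} out of range")
    name = f"PC{component}"
    if use_loadings:
        lo = pca.loadings[name]
        scale = np.sqrt((lo**2).mean())
        sel = lo.abs() > cfg.corr_r_min * scale * np.sqrt(len(lo))
        return list(lo.index[sel])
    data = m.data.loc[pca.loadings.index, pca.scores.index]
    x = data.to_numpy()
    s = pca.scores[name].to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    ss = np.sqrt((sc**2).sum())
    zero = sx == 0
    if zero.any():
        logger.warning("%d zero-variance probes excluded from PC correlation", zero.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ sc) / (sx * ss)
    r[zero] = np.nan
    with np.errstate(invalid="ignore"):
        keep = np.abs(r) > cfg.corr_r_min
    keep &= ~np.isnan(r)
    return list(data.index[keep])


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes hyperparameters (d0, s0^2) for variance shrinkage.

    Assumes per-probe sample variances follow a scaled F distribution
    around a common prior variance s0^2 with prior df d0.  Matching the
    mean and variance of log s^2 (digamma/trigamma identities) gives
    closed-form moment estimates; the trigamma equation is inverted by
    Newton iteration.  Returns ``d0 = inf`` when the observed spread of
    log-variances is no larger than pure chi-squared scatter.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ArgumentError("need >= 2 positive variances to estimate a prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = e.size
    e_mean = e.mean()
    excess = ((e - e_mean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = excess by Newton iteration (monotone decreasing)
    x = 0.5 + 1.0 / excess  # standard starting value
    for _ in range(60):
        tri = special.polygamma(1, x)
        delta = tri * (tri - excess) / special.polygamma(2, x)
        x = x - delta  # note polygamma(2) < 0: moves x the right way
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0_sq = np.exp(e_mean + special.digamma(x) - np.log(x))
    return float(d0), float(s0_sq)


def tissue_specific_probes(
    m: MValueMatrix,
    sheet: SampleSheet,
    cfg: AnalysisConfig,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated one-way F-test for tissue differences at every probe.

    Per probe: between-tissue mean square over a shrunken residual
    variance ``s~^2 = (d0 s0^2 + d s^2) / (d0 + d)`` with empirical-Bayes
    hyperparameters shared across probes; p from F(k-1, d0 + d) and BH
    adjustment.  ``prior_df`` overrides the estimated d0 (0 recovers the
    ordinary ANOVA F, ``inf`` full shrinkage to s0^2).
    """
    sheet.check_covers(m.sample_ids)
    tissue_of = sheet.tissue_of()
    labels = np.array([tissue_of[s] for s in m.sample_ids])
    tissues = pd.unique(labels)
    if len(tissues) < 2:
        raise ArgumentError("need >= 2 tissues")
    data = m.data.dropna(axis=0)
    if data.shape[0] < m.shape[0]:
        logger.warning(
            "dropped %d probes with missing values before moderated F",
            m.shape[0] - data.shape[0],
        )
    x = data.to_numpy()
    n = x.shape[1]
    k = len(tissues)
    df_resid = n - k
    if df_resid < 1:
        raise ArgumentError("no residual degrees of freedom for the tissue model")
    grand = x.mean(axis=1, keepdims=True)
    ss_between = np.zeros(x.shape[0])
    ss_within = np.zeros(x.shape[0])
    for t in tissues:
        cols = labels == t
        sub = x[:, cols]
        gm = sub.mean(axis=1, keepdims=True)
        ss_between += cols.sum() * (gm[:, 0] - grand[:, 0]) ** 2
        ss_within += ((sub - gm) ** 2).sum(axis=1)
    s2 = ss_within / df_resid
    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        # with a fixed prior df the prior variance is the corresponding
        # moment estimate (mean log-variance back-transformed)
        _, s0_sq = estimate_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df_resid
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    ms_between = ss_between / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_mod = ms_between / s2_post
    if np.isinf(df_total):
        p = sps.chi2.sf(f_mod * (k - 1), df=k - 1)
    else:
        p = sps.f.sf(f_mod, k - 1, df_total)
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "probe_id": data.index,
            "F": f_mod,
            "p_value": p,
            "p_adj": p_adj,
            "significant": p_adj < cfg.fdr_q,
        }
    ).set_index("probe_id")
    out.attrs["prior_df"] = d0
    out.attrs["prior_variance"] = s0_sq
    out.attrs["residual_df"] = df_resid
    return out
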