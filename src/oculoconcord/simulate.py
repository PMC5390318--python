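"""Synthetic matched multi-tissue methylation datasets with known truth.

The generator emulates the structure of an HM450K-like study of matched
post-mortem samples: a handful of donors, each contributing blood plus
several ocular tissues (neurosensory retina, RPE/choroid, optic nerve).
Each probe gets a bimodal baseline (most CpGs are strongly hypo- or
hypermethylated), and a disjoint subset of probes carries either

* **tissue effects** — per-tissue logit offsets whose pairwise separations
  follow a configurable tissue-distance matrix (default: blood most
  distant from every ocular tissue, RPE/choroid and optic nerve nearly
  indistinguishable), or
* **donor-shared effects** — a per-donor logit offset identical across
  that donor's tissues, emulating mQTL-like genetic control of
  methylation (optionally trimodal, like the three genotypes of a
  biallelic variant).

Independent Gaussian noise is added per sample on the logit scale and the
result mapped back to beta values, so betas never leave (0, 1).  Because
the inverse logit is monotone, rank-based statistics downstream see the
logit-scale structure unchanged.

Effect-class probe counts are exact (``round(f * n_probes)``), not
binomial, so tests against the returned :class:`SimTruth` are
deterministic.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    TISSUES,
    FEATURE_CLASSES,
    ISLAND_RELATIONS,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    read_beta_matrix,
    write_beta_matrix,
)
from .exceptions import ArgumentError

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "default_tissue_distance",
    "simulate_dataset",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

#: Default pairwise logit-scale separations between tissue methylation
#: profiles.  Blood is the most distinct tissue overall; among the
#: blood-eye pairs RPE/choroid is closest to blood, then optic nerve,
#: then retina; RPE/choroid and optic nerve are the most similar pair.
_DEFAULT_DISTANCE = {
    ("blood", "retina"): 3.4,
    ("blood", "rpe_choroid"): 2.6,
    ("blood", "optic_nerve"): 3.0,
    ("retina", "rpe_choroid"): 2.0,
    ("retina", "optic_nerve"): 1.8,
    ("rpe_choroid", "optic_nerve"): 0.8,
}

# HM450K-like marginal composition of probe annotation categories.
_FEATURE_WEIGHTS = (0.10, 0.14, 0.10, 0.05, 0.31, 0.04, 0.26)
_ISLAND_WEIGHTS = (0.31, 0.23, 0.10, 0.36)

_CAUSES = ("cardiac", "trauma", "respiratory", "cerebrovascular")


def default_tissue_distance(tissues: Sequence[str] = TISSUES) -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of expected logit separations."""
    t = list(tissues)
    mat = pd.DataFrame(0.0, index=t, columns=t)
    for (a, b), d in _DEFAULT_DISTANCE.items():
        if a in t and b in t:
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


@dataclass
class SimConfig:
    """Generator parameters; defaults encode the emulated study design
    (8 donors x 4 tissues, bimodal baselines, logit noise sd 0.3)."""

    n_probes: int = 2000
    donors: int = 8
    tissues: tuple[str, ...] = TISSUES
    class_weights: tuple[float, float, float] = (0.4, 0.2, 0.4)
    f_tissue: float = 0.2
    tissue_distance: pd.DataFrame | None = None
    f_individual: float = 0.05
    individual_effect_sd: float = 1.5
    trimodal_genotype: bool = False
    noise_sd: float = 0.3
    n_chips: int = 4
    f_detection_fail: float = 0.001
    f_cross_reactive: float = 0.05
    f_snp: float = 0.02
    individual_opensea_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.donors < 1 or self.n_chips < 1:
            raise ArgumentError("n_probes, donors and n_chips must be >= 1")
        if len(self.tissues) < 1 or len(set(self.tissues)) != len(self.tissues):
            raise ArgumentError("tissues must be a nonempty list of unique labels")
        w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ArgumentError("class_weights must be 3 nonnegative values summing to 1")
        for name in (
            "f_tissue",
            "f_individual",
            "f_detection_fail",
            "f_cross_reactive",
            "f_snp",
            "individual_opensea_bias",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ArgumentError(f"{name} must be in [0, 1], got {v}")
        if self.f_tissue + self.f_individual > 1.0 + 1e-12:
            raise ArgumentError("f_tissue + f_individual must not exceed 1")
        if self.noise_sd < 0 or self.individual_effect_sd < 0:
            raise ArgumentError("standard deviations must be nonnegative")
        if self.tissue_distance is None:
            self.tissue_distance = default_tissue_distance(self.tissues)
        else:
            d = pd.DataFrame(self.tissue_distance)
            d = d.loc[list(self.tissues), list(self.tissues)].astype(float)
            if not np.allclose(d.values, d.values.T):
                raise ArgumentError("tissue_distance must be symmetric")
            if np.any(np.diag(d.values) != 0):
                raise ArgumentError("tissue_distance diagonal must be zero")
            if np.any(d.values < 0):
                raise ArgumentError("tissue_distance must be nonnegative")
            self.tissue_distance = d

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        d["class_weights"] = list(self.class_weights)
        d["tissue_distance"] = {
            t: self.tissue_distance.loc[t].tolist() for t in self.tissues
        }
        return d


@dataclass
class SimTruth:
    """Ground-truth labels for parameter-recovery tests.

    ``probes`` has one row per probe with ``probe_effect_class`` in
    {none, tissue, individual}, ``baseline_class`` in {hypo, intermediate,
    hyper} and the baseline beta.  ``tissue_effects`` / ``donor_effects``
    hold the logit offsets, nonzero only for probes of the matching class.
    """

    probes: pd.DataFrame  # index probe_id: probe_effect_class, baseline_class, baseline_beta
    tissue_effects: pd.DataFrame  # probes x tissues, logit offsets
    donor_effects: pd.DataFrame  # probes x donors, logit offsets

    def probes_of_class(self, effect_class: str) -> list[str]:
        sel = self.probes.index[self.probes["probe_effect_class"] == effect_class]
        return list(sel)


@dataclass
class SimResult:
    """Bundle of everything :func:`simulate_dataset` produces."""

    beta: BetaMatrix
    sheet: SampleSheet
    annotation: ProbeAnnotation
    detection_p: pd.DataFrame  # probes x samples
    truth: SimTruth
    config: SimConfig


def _embed_tissues(distance: pd.DataFrame) -> np.ndarray:
    """Classical MDS embedding so that squared Euclidean separations of the
    returned coordinates reproduce the squared configured distances."""
    d2 = distance.values.astype(float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(gram)
    keep = w > 1e-10
    return v[:, keep] * np.sqrt(w[keep])  # (n_tissues, k), centered


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Draw one complete synthetic study from the generative model.

    Deterministic given ``cfg.seed``: running twice with the same config
    yields bitwise-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    tissues = list(cfg.tissues)
    n_t, n_d = len(tissues), cfg.donors

    probe_ids = [f"cg{i:07d}" for i in range(n)]
    donor_ids = [f"D{i + 1}" for i in range(n_d)]
    sample_ids = [f"{d}_{t}" for d in donor_ids for t in tissues]

    # --- baseline methylation state: bimodal mixture -----------------------
    baseline_class = rng.choice(
        ["hypo", "intermediate", "hyper"], size=n, p=cfg.class_weights
    )
    baseline_beta = np.empty(n)
    is_hypo = baseline_class == "hypo"
    is_hyper = baseline_class == "hyper"
    is_mid = baseline_class == "intermediate"
    baseline_beta[is_hypo] = rng.beta(1.5, 30.0, size=is_hypo.sum())
    baseline_beta[is_hyper] = 1.0 - rng.beta(1.5, 30.0, size=is_hyper.sum())
    baseline_beta[is_mid] = 0.2 + 0.6 * rng.beta(2.0, 2.0, size=is_mid.sum())
    baseline_beta = np.clip(baseline_beta, 1e-4, 1.0 - 1e-4)
    baseline_logit = np.log(baseline_beta / (1.0 - baseline_beta))

    # --- effect classes: exact, disjoint counts ----------------------------
    n_tissue_probes = int(round(cfg.f_tissue * n))
    n_indiv_probes = int(round(cfg.f_individual * n))
    order = rng.permutation(n)
    tissue_idx = order[:n_tissue_probes]
    indiv_idx = order[n_tissue_probes : n_tissue_probes + n_indiv_probes]
    effect_class = np.full(n, "none", dtype=object)
    effect_class[tissue_idx] = "tissue"
    effect_class[indiv_idx] = "individual"

    # --- tissue effects via a Euclidean embedding of the distance matrix ---
    tissue_offsets = np.zeros((n, n_t))
    if n_tissue_probes and n_t > 1:
        coords = _embed_tissues(cfg.tissue_distance)  # (n_t, k)
        g = rng.standard_normal((n_tissue_probes, coords.shape[1]))
        tissue_offsets[tissue_idx] = g @ coords.T

    # --- donor-shared (mQTL-like) effects ----------------------------------
    donor_offsets = np.zeros((n, n_d))
    if n_indiv_probes:
        if cfg.trimodal_genotype:
            levels = rng.choice(
                [-1.0, 0.0, 1.0], size=(n_indiv_probes, n_d), p=[0.25, 0.5, 0.25]
            )
            donor_offsets[indiv_idx] = levels * cfg.individual_effect_sd
        else:
            donor_offsets[indiv_idx] = rng.normal(
                0.0, cfg.individual_effect_sd, size=(n_indiv_probes, n_d)
            )

    # --- assemble logits: baseline + tissue + donor + noise ----------------
    # sample layout matches sample_ids: donor-major, tissue-minor
    logit = baseline_logit[:, None] + np.concatenate(
        [
            np.repeat(donor_offsets[:, [d]], n_t, axis=1) + tissue_offsets
            for d in range(n_d)
        ],
        axis=1,
    )
    if cfg.noise_sd > 0:
        logit = logit + rng.normal(0.0, cfg.noise_sd, size=logit.shape)
    beta_vals = 1.0 / (1.0 + np.exp(-logit))

    beta = BetaMatrix(pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids))

    # --- sample sheet: donors assigned to chips round-robin ----------------
    ages = np.round(rng.uniform(40.0, 80.0, size=n_d), 1)
    causes = rng.choice(_CAUSES, size=n_d)
    preserve = np.round(rng.uniform(2.0, 12.0, size=n_d), 1)
    rows = []
    for di, d in enumerate(donor_ids):
        chip = f"chip{di % cfg.n_chips + 1}"
        for t in tissues:
            rows.append(
                {
                    "sample_id": f"{d}_{t}",
                    "donor_id": d,
                    "tissue": t,
                    "chip": chip,
                    "age_at_death": ages[di],
                    "cause_of_death": causes[di],
                    "preservation_interval": preserve[di],
                }
            )
    sheet = SampleSheet(pd.DataFrame(rows))

    # --- detection p-values: near zero except sporadic failures ------------
    detp = np.zeros((n, len(sample_ids)))
    n_fail = int(round(cfg.f_detection_fail * detp.size))
    if n_fail:
        flat = rng.choice(detp.size, size=n_fail, replace=False)
        detp.flat[flat] = rng.uniform(0.01, 1.0, size=n_fail) + 1e-12
    detection_p = pd.DataFrame(detp, index=probe_ids, columns=sample_ids)
    detection_p.index.name = "probe_id"

    # --- annotation: categorical context plus disjoint QC flags ------------
    feature = rng.choice(FEATURE_CLASSES, size=n, p=_FEATURE_WEIGHTS)
    island = rng.choice(ISLAND_RELATIONS, size=n, p=_ISLAND_WEIGHTS)
    if cfg.individual_opensea_bias > 0 and n_indiv_probes:
        bias = rng.random(n_indiv_probes) < cfg.individual_opensea_bias
        island[indiv_idx[bias]] = "OpenSea"
        feature[indiv_idx[bias]] = "Intergenic"
    autosomes = [str(i) for i in range(1, 23)]
    chrom_labels = autosomes + ["X", "Y"]
    chrom_p = np.array([0.971 / 22] * 22 + [0.025, 0.004])
    chromosome = rng.choice(chrom_labels, size=n, p=chrom_p)
    flag_order = rng.permutation(n)
    n_cr = int(round(cfg.f_cross_reactive * n))
    n_snp = int(round(cfg.f_snp * n))
    cross_reactive = np.zeros(n, dtype=bool)
    snp_flag = np.zeros(n, dtype=bool)
    cross_reactive[flag_order[:n_cr]] = True
    snp_flag[flag_order[n_cr : n_cr + n_snp]] = True  # disjoint from cross-reactive
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "chromosome": chromosome,
                "feature_class": feature,
                "island_relation": island,
                "cross_reactive": cross_reactive,
                "snp_flag": snp_flag,
            }
        )
    )

    truth = SimTruth(
        probes=pd.DataFrame(
            {
                "probe_effect_class": effect_class,
                "baseline_class": baseline_class,
                "baseline_beta": baseline_beta,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        ),
        tissue_effects=pd.DataFrame(
            tissue_offsets, index=probe_ids, columns=tissues
        ),
        donor_effects=pd.DataFrame(
            donor_offsets, index=probe_ids, columns=donor_ids
        ),
    )
    return SimResult(beta, sheet, annotation, detection_p, truth, cfg)


# ---------------------------------------------------------------------------
# fixture bundles on disk


_BUNDLE_FILES = {
    "beta": "beta.tsv",
    "sheet": "samples.csv",
    "annotation": "annotation.tsv",
    "detection_p": "detection_p.tsv",
    "truth_probes": "truth_probes.tsv",
    "truth_tissue": "truth_tissue_effects.tsv",
    "truth_donor": "truth_donor_effects.tsv",
    "provenance": "provenance.yaml",
}


def write_fixture_bundle(result: SimResult, directory: str | Path) -> Path:
    """Write all simulator outputs as TSV/CSV plus a YAML provenance file
    recording the full config (including the seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tag = f"oculoconcord simulate seed={result.config.seed}"
    write_beta_matrix(result.beta, directory / _BUNDLE_FILES["beta"], tag)
    result.sheet.write_csv(directory / _BUNDLE_FILES["sheet"], tag)
    result.annotation.write_tsv(directory / _BUNDLE_FILES["annotation"], tag)
    result.detection_p.to_csv(
        directory / _BUNDLE_FILES["detection_p"], sep="\t", float_format="%.17g"
    )
    result.truth.probes.to_csv(
        directory / _BUNDLE_FILES["truth_probes"], sep="\t", float_format="%.17g"
    )
    result.truth.tissue_effects.rename_axis("probe_id").to_csv(
        directory / _BUNDLE_FILES["truth_tissue"], sep="\t", float_format="%.17g"
    )
    result.truth.donor_effects.rename_axis("probe_id").to_csv(
        directory / _BUNDLE_FILES["truth_donor"], sep="\t", float_format="%.17g"
    )
    with open(directory / _BUNDLE_FILES["provenance"], "w") as fh:
        yaml.safe_dump({"sim_config": result.config.to_dict()}, fh)
    return directory


def read_fixture_bundle(directory: str | Path) -> SimResult:
    """Read a bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    with open(directory / _BUNDLE_FILES["provenance"]) as fh:
        prov = yaml.safe_load(fh)["sim_config"]
    tissues = tuple(prov["tissues"])
    dist = pd.DataFrame(prov["tissue_distance"], index=list(tissues)).T
    dist = dist.loc[list(tissues), list(tissues)]
    prov = {
        **prov,
        "tissues": tissues,
        "class_weights": tuple(prov["class_weights"]),
        "tissue_distance": dist,
    }
    cfg = SimConfig(**prov)
    beta = read_beta_matrix(directory / _BUNDLE_FILES["beta"])
    sheet = SampleSheet.read_csv(directory / _BUNDLE_FILES["sheet"])
    annotation = ProbeAnnotation.read_tsv(directory / _BUNDLE_FILES["annotation"])
    detection_p = pd.read_csv(
        directory / _BUNDLE_FILES["detection_p"], sep="\t", index_col=0
    )
    probes = pd.read_csv(directory / _BUNDLE_FILES["truth_probes"], sep="\t", index_col=0)
    te = pd.read_csv(directory / _BUNDLE_FILES["truth_tissue"], sep="\t", index_col=0)
    de = pd.read_csv(directory / _BUNDLE_FILES["truth_donor"], sep="\t", index_col=0)
    truth = SimTruth(probes=probes, tissue_effects=te, donor_effects=de)
    return SimResult(beta, sheet, annotation, detection_p, truth, cfg)
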