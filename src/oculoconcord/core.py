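"""Core domain types, tabular I/O and the beta/M-value transforms.

The central container is :class:`BetaMatrix`, a probes x samples matrix of
methylation proportions (beta values) in [0, 1].  Linear modelling and PCA
operate on M-values, ``M = log2(beta / (1 - beta))``, which are closer to
homoscedastic; :func:`beta_to_m` / :func:`m_to_beta` convert between the two
scales.  Missing values are ``NaN`` in memory and the literal token ``NA``
on disk; every downstream operation states how it propagates missingness
(generally pairwise-complete, never imputed).

Sample metadata (donor, tissue, chip, age, ...) live in :class:`SampleSheet`
and per-probe genomic context (feature class, CpG-island relation, QC flags)
in :class:`ProbeAnnotation`.  All analysis thresholds are collected in
:class:`AnalysisConfig` so a run is fully described by one validated object.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, DataError, FormatError, ParseError

__all__ = [
    "TISSUES",
    "FEATURE_CLASSES",
    "ISLAND_RELATIONS",
    "BetaMatrix",
    "MValueMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "AnalysisConfig",
    "read_beta_matrix",
    "write_beta_matrix",
    "beta_to_m",
    "m_to_beta",
    "select_top_variable",
    "collapse_feature_annotations",
]

#: Canonical tissue labels of the study design (extensible: SampleSheet
#: accepts any label, these are the simulator defaults).
TISSUES = ("blood", "retina", "rpe_choroid", "optic_nerve")

#: Genomic feature classes in collapsing-priority order (promoter-proximal
#: classes win when a probe carries several manifest annotations).
FEATURE_CLASSES = (
    "TSS200",
    "TSS1500",
    "UTR5",
    "FirstExon",
    "Body",
    "UTR3",
    "Intergenic",
)

#: CpG-density annulus relative to CpG islands.
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

_VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_NA_TOKEN = "NA"
_BETA_TOL = 1e-9


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dup[:5]}")


class _ValueMatrix:
    """Shared behaviour of BetaMatrix / MValueMatrix: a labelled float
    matrix, probes as rows, samples as columns, NaN = missing."""

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise ArgumentError("data must be a pandas DataFrame")
        _check_unique(data.index, "probe")
        _check_unique(data.columns, "sample")
        data = data.astype(float)
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        data.index.name = "probe_id"
        self.data = data
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - overridden
        pass

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probe_ids: Iterable[str]):
        ids = list(probe_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise ArgumentError(f"unknown probe id(s): {sorted(missing)[:5]}")
        return type(self)(self.data.loc[ids])

    def subset_samples(self, sample_ids: Iterable[str]):
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise ArgumentError(f"unknown sample id(s): {sorted(missing)[:5]}")
        return type(self)(self.data[ids])

    def equals(self, other, tol: float = 0.0) -> bool:
        if self.probe_ids != other.probe_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values, other.values
        na_a, na_b = np.isnan(a), np.isnan(b)
        if not np.array_equal(na_a, na_b):
            return False
        mask = ~na_a
        return bool(np.all(np.abs(a[mask] - b[mask]) <= tol))

    def __repr__(self) -> str:
        n_p, n_s = self.shape
        return f"<{type(self).__name__} {n_p} probes x {n_s} samples>"


class BetaMatrix(_ValueMatrix):
    """Probes x samples matrix of methylation proportions in [0, 1].

    Invariants: unique probe and sample ids; every non-missing value in
    [0, 1] within a 1e-9 numerical tolerance (values inside the tolerance
    are clamped onto the boundary).
    """

    def _validate(self) -> None:
        vals = self.data.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < -_BETA_TOL) | (vals > 1.0 + _BETA_TOL)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                "beta value out of [0, 1]: "
                f"{vals[i, j]!r} at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        # clamp tolerance-level excursions so invariants hold exactly
        np.clip(vals, 0.0, 1.0, out=vals)
        self.data = pd.DataFrame(vals, index=self.data.index, columns=self.data.columns)
        self.data.index.name = "probe_id"


class MValueMatrix(_ValueMatrix):
    """Probes x samples matrix of M-values, ``log2(beta/(1-beta))``.

    All non-missing values must be finite (the beta -> M transform clips
    boundary betas first); NaN marks missingness, as in BetaMatrix.
    """

    def _validate(self) -> None:
        vals = self.data.to_numpy()
        finite_or_nan = np.isfinite(vals) | np.isnan(vals)
        if not np.all(finite_or_nan):
            i, j = np.argwhere(~finite_or_nan)[0]
            raise FormatError(
                f"non-finite M-value at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )


# ---------------------------------------------------------------------------
# sample sheet


_SHEET_COLUMNS = [
    "sample_id",
    "donor_id",
    "tissue",
    "chip",
    "age_at_death",
    "cause_of_death",
    "preservation_interval",
]


@dataclass
class SampleSheet:
    """Per-sample study traits.

    ``age_at_death`` is in years, ``preservation_interval`` in hours; both
    nonnegative.  ``cause_of_death`` and ``preservation_interval`` are
    optional (NaN/empty allowed).  ``(donor_id, tissue)`` pairs are unique:
    one sample per donor per tissue.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing column(s): {missing}")
        df = df[_SHEET_COLUMNS].reset_index(drop=True)
        for col in ("sample_id", "donor_id", "tissue", "chip"):
            df[col] = df[col].astype(str)
        for col in ("age_at_death", "preservation_interval"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        _check_unique(df["sample_id"], "sample")
        if df.duplicated(subset=["donor_id", "tissue"]).any():
            dup = df.loc[
                df.duplicated(subset=["donor_id", "tissue"]), ["donor_id", "tissue"]
            ]
            raise FormatError(
                f"duplicate (donor, tissue) pair(s): {dup.values[:3].tolist()}"
            )
        if (df["age_at_death"].dropna() < 0).any():
            raise FormatError("negative age_at_death")
        if (df["preservation_interval"].dropna() < 0).any():
            raise FormatError("negative preservation_interval")
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    @property
    def donors(self) -> list[str]:
        return sorted(self.table["donor_id"].unique())

    def samples_of_tissue(self, tissue: str) -> list[str]:
        sel = self.table.loc[self.table["tissue"] == tissue, "sample_id"]
        return list(sel)

    def tissue_of(self) -> pd.Series:
        """sample_id -> tissue mapping."""
        return self.table.set_index("sample_id")["tissue"]

    def donor_of(self) -> pd.Series:
        """sample_id -> donor_id mapping."""
        return self.table.set_index("sample_id")["donor_id"]

    def sample_for(self, donor: str, tissue: str) -> str | None:
        sel = self.table.loc[
            (self.table["donor_id"] == donor) & (self.table["tissue"] == tissue),
            "sample_id",
        ]
        return None if sel.empty else sel.iloc[0]

    def check_covers(self, sample_ids: Iterable[str]) -> None:
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise DataError(
                f"sample(s) absent from sample sheet: {sorted(missing)[:5]}"
            )

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, comment="#", dtype=str)
        return cls(df)

    def write_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, index=False, na_rep="")


# ---------------------------------------------------------------------------
# probe annotation


@dataclass
class ProbeAnnotation:
    """Per-probe genomic context and QC flags.

    One ``feature_class`` and one ``island_relation`` per probe (manifest
    multi-annotations must be collapsed first, see
    :func:`collapse_feature_annotations`); closed enums; boolean
    ``cross_reactive`` and ``snp_flag`` QC flags.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = [
            "probe_id",
            "chromosome",
            "feature_class",
            "island_relation",
            "cross_reactive",
            "snp_flag",
        ]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"probe annotation missing column(s): {missing}")
        df = df[required].reset_index(drop=True)
        df["probe_id"] = df["probe_id"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        _check_unique(df["probe_id"], "probe")
        bad_chrom = set(df["chromosome"]) - set(_VALID_CHROMOSOMES)
        if bad_chrom:
            raise FormatError(f"invalid chromosome label(s): {sorted(bad_chrom)[:5]}")
        bad_fc = set(df["feature_class"]) - set(FEATURE_CLASSES)
        if bad_fc:
            raise FormatError(f"invalid feature_class value(s): {sorted(bad_fc)[:5]}")
        bad_ir = set(df["island_relation"]) - set(ISLAND_RELATIONS)
        if bad_ir:
            raise FormatError(f"invalid island_relation value(s): {sorted(bad_ir)[:5]}")
        for col in ("cross_reactive", "snp_flag"):
            df[col] = _parse_bool_column(df[col], col)
        self.table = df.set_index("probe_id", drop=False)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def check_covers(self, probe_ids: Iterable[str]) -> None:
        missing = set(probe_ids) - set(self.table.index)
        if missing:
            raise DataError(f"probe(s) absent from annotation: {sorted(missing)[:5]}")

    def subset(self, probe_ids: Iterable[str]) -> "ProbeAnnotation":
        ids = list(probe_ids)
        self.check_covers(ids)
        return ProbeAnnotation(self.table.loc[ids].reset_index(drop=True))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProbeAnnotation":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(df)

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _parse_bool_column(col: pd.Series, name: str) -> pd.Series:
    if col.dtype == bool:
        return col
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = col.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = col[out.isna()].iloc[0]
        raise ParseError(f"cannot parse boolean {name} value {bad!r}")
    return out.astype(bool)


def collapse_feature_annotations(classes: Iterable[str]) -> str:
    """Collapse multiple manifest feature annotations to a single class.

    Fixed priority TSS200 > TSS1500 > UTR5 > FirstExon > Body > UTR3 >
    Intergenic: the most promoter-proximal annotation wins, so a probe
    overlapping both a gene body and a TSS is treated as promoter-associated.
    """
    classes = list(classes)
    if not classes:
        return "Intergenic"
    bad = set(classes) - set(FEATURE_CLASSES)
    if bad:
        raise ArgumentError(f"unknown feature class(es): {sorted(bad)}")
    return min(classes, key=FEATURE_CLASSES.index)


# ---------------------------------------------------------------------------
# analysis configuration


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis thresholds in one validated structure.

    Defaults follow standard methylation-array practice: beta <= 0.2 is
    hypomethylated and beta >= 0.8 hypermethylated; a probe is
    "blood variable" when its inter-donor beta range between the 10th and
    90th percentiles exceeds 0.05; per-probe matched correlations are
    selected at |rho| > 0.5 and p < 0.05; detection p-values above 0.01
    fail QC; multiple testing is controlled at FDR 0.05.
    """

    hypo_max: float = 0.2
    hyper_min: float = 0.8
    variability_range_min: float = 0.05
    variability_quantiles: tuple[float, float] = (0.10, 0.90)
    corr_r_min: float = 0.5
    corr_p_max: float = 0.05
    detection_p_max: float = 0.01
    fdr_q: float = 0.05
    equivalence_delta: float = 0.05
    n_null_permutations: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.hypo_max < self.hyper_min <= 1):
            raise ArgumentError(
                f"need 0 <= hypo_max < hyper_min <= 1, got "
                f"({self.hypo_max}, {self.hyper_min})"
            )
        lo, hi = self.variability_quantiles
        if not (0 <= lo < hi <= 1):
            raise ArgumentError(f"invalid variability_quantiles ({lo}, {hi})")
        if not (0 <= self.variability_range_min <= 1):
            raise ArgumentError("variability_range_min must be in [0, 1]")
        if not (0 <= self.corr_r_min <= 1):
            raise ArgumentError("corr_r_min must be in [0, 1]")
        for name in ("corr_p_max", "detection_p_max", "fdr_q"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ArgumentError(f"{name} must be in (0, 1), got {v}")
        if self.equivalence_delta <= 0:
            raise ArgumentError("equivalence_delta must be positive")
        if int(self.n_null_permutations) < 1:
            raise ArgumentError("n_null_permutations must be >= 1")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# beta-matrix I/O

_DIALECT_SEP = {"TSV": "\t", "CSV": ","}


def _infer_dialect(path: str | Path) -> str:
    return "CSV" if str(path).lower().endswith(".csv") else "TSV"


def read_beta_matrix(path: str | Path, dialect: str | None = None) -> BetaMatrix:
    """Read a probes x samples beta matrix from TSV/CSV.

    First column: probe ids; header row: sample ids; body: numeric values
    in [0, 1] with ``NA`` (or empty) marking missing cells.  Lines starting
    with ``#`` are provenance comments and are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = _DIALECT_SEP[dialect or _infer_dialect(path)]
    raw = pd.read_csv(
        path, sep=sep, comment="#", dtype=str, index_col=0,
        keep_default_na=False, na_values=[],
    )
    numeric = raw.replace({_NA_TOKEN: np.nan, "": np.nan}).apply(
        pd.to_numeric, errors="coerce"
    )
    # report the first truly unparseable cell with coordinates
    bad = numeric.isna() & ~raw.isin([_NA_TOKEN, ""])
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {raw.iat[i, j]!r} at probe {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}"
        )
    return BetaMatrix(numeric)


def write_beta_matrix(
    m: BetaMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a beta matrix as TSV/CSV (by extension), ``NA`` for missing.

    Uses repr-precision floats so ``read_beta_matrix`` round-trips values
    to better than 1e-12.
    """
    sep = _DIALECT_SEP[_infer_dialect(path)]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        m.data.to_csv(fh, sep=sep, na_rep=_NA_TOKEN, float_format="%.17g")


# ---------------------------------------------------------------------------
# transforms


def beta_to_m(b: BetaMatrix, clip_eps: float = 0.001) -> MValueMatrix:
    """Logit-like transform ``M = log2(beta / (1 - beta))``.

    Betas are first clipped to ``[clip_eps, 1 - clip_eps]`` so boundary
    values map to finite M; the transform is strictly monotone on the
    clipped range.  Missing cells stay missing.
    """
    if not (0 < clip_eps < 0.5):
        raise ArgumentError(f"clip_eps must be in (0, 0.5), got {clip_eps}")
    vals = np.clip(b.values, clip_eps, 1.0 - clip_eps)
    m = np.log2(vals / (1.0 - vals))
    return MValueMatrix(pd.DataFrame(m, index=b.data.index, columns=b.data.columns))


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse transform ``beta = 2^M / (1 + 2^M)``, numerically stable."""
    x = m.values
    with np.errstate(over="ignore"):
        beta = np.where(x >= 0, 1.0 / (1.0 + 2.0 ** (-x)), 2.0**x / (1.0 + 2.0**x))
    beta = np.where(np.isnan(x), np.nan, beta)
    return BetaMatrix(pd.DataFrame(beta, index=m.data.index, columns=m.data.columns))


def select_top_variable(b: BetaMatrix, k: int) -> list[str]:
    """Ids of the ``k`` probes with the largest across-sample beta standard
    deviation (ddof=1, pairwise-complete); ties broken by lexicographic
    probe id so the selection is deterministic."""
    n_probes = b.shape[0]
    if k > n_probes:
        raise ArgumentError(f"k={k} exceeds probe count {n_probes}")
    sd = b.data.std(axis=1, ddof=1, skipna=True).fillna(0.0)
    order = sorted(b.probe_ids, key=lambda p: (-sd[p], p))
    return order[:k]
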