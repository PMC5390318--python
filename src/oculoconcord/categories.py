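"""Three-class methylation categorisation and cross-tissue overlap counts.

Per tissue, each probe's mean beta across donors is classed as
hypomethylated (beta <= 0.2), intermediate (0.2 < beta < 0.8) or
hypermethylated (beta >= 0.8); boundary values belong to the outer classes
(closed inequalities).  Overlaps between tissues are reported as disjoint
exclusive-subset counts — the tabular form of an UpSet plot — so each
class-positive probe is counted in exactly one cell, the cell of the exact
tissue subset in which it carries that class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import AnalysisConfig, BetaMatrix, ProbeAnnotation, SampleSheet
from .exceptions import ArgumentError, DataError

__all__ = [
    "CLASSES",
    "tissue_mean_beta",
    "categorize_probes",
    "intersection_counts",
    "overlap_counts_frame",
    "joint_blood_eye_classes",
]

CLASSES = ("hypo", "intermediate", "hyper")


def tissue_mean_beta(b: BetaMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-probe arithmetic mean beta per tissue (probes x tissues).

    Means are over the samples of each tissue, skipping missing cells
    (pairwise-complete); a tissue must contribute at least one sample.
    """
    sheet.check_covers(b.sample_ids)
    tissue_of = sheet.tissue_of()
    out = {}
    for tissue in sheet.tissues:
        cols = [s for s in b.sample_ids if tissue_of[s] == tissue]
        if not cols:
            raise ArgumentError(f"tissue {tissue!r} has no samples in the matrix")
        out[tissue] = b.data[cols].mean(axis=1, skipna=True)
    means = pd.DataFrame(out)
    means.index.name = "probe_id"
    return means


def categorize_probes(means: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Class per probe and tissue with the closed boundary convention:
    ``beta <= hypo_max`` is hypo and ``beta >= hyper_min`` is hyper."""
    vals = means.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ArgumentError("mean betas must lie in [0, 1]")
    cls = np.full(vals.shape, "intermediate", dtype=object)
    cls[vals <= cfg.hypo_max] = "hypo"
    cls[vals >= cfg.hyper_min] = "hyper"
    cls[np.isnan(vals)] = None
    return pd.DataFrame(cls, index=means.index, columns=means.columns)


def intersection_counts(classes: pd.DataFrame, cls: str) -> dict[frozenset, int]:
    """Disjoint UpSet-style intersection counts for one methylation class.

    For every nonempty subset S of tissues, counts the probes that carry
    class ``cls`` in exactly the tissues of S.  The empty subset (probes
    never in the class) is not returned; the cells plus that remainder
    partition the probe set.
    """
    if cls not in CLASSES:
        raise ArgumentError(f"unknown methylation class {cls!r}")
    tissues = list(classes.columns)
    if not tissues:
        raise ArgumentError("need at least one tissue")
    member = classes.to_numpy() == cls  # probes x tissues
    counts: dict[frozenset, int] = {}
    for r in range(1, len(tissues) + 1):
        for subset in combinations(range(len(tissues)), r):
            in_sub = np.ones(member.shape[0], dtype=bool)
            for j in range(len(tissues)):
                in_sub &= member[:, j] if j in subset else ~member[:, j]
            counts[frozenset(tissues[j] for j in subset)] = int(in_sub.sum())
    return counts


def overlap_counts_frame(classes: pd.DataFrame, cls: str) -> pd.DataFrame:
    """Intersection counts as a flat table (UpSet input format): one row
    per nonempty tissue subset with indicator columns and the count."""
    tissues = list(classes.columns)
    counts = intersection_counts(classes, cls)
    rows = []
    for subset, n in sorted(
        counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    ):
        row = {t: int(t in subset) for t in tissues}
        row["degree"] = len(subset)
        row["count"] = n
        rows.append(row)
    out = pd.DataFrame(rows)
    out.insert(0, "methylation_class", cls)
    return out


def joint_blood_eye_classes(
    classes: pd.DataFrame,
    eye_tissue: str,
    ann: ProbeAnnotation,
    blood_tissue: str = "blood",
) -> pd.DataFrame:
    """Joint blood-class x eye-class percentages per annotation category.

    For each genomic feature class and, separately, each CpG-island
    relation, tabulates the percentage of probes in every combination of
    blood class (B1 = hypo, B2 = intermediate, B3 = hyper) and the
    equivalent eye-tissue class (E1-E3).  Percentages within one
    (scheme, category) panel sum to 100.
    """
    for t in (blood_tissue, eye_tissue):
        if t not in classes.columns:
            raise ArgumentError(f"tissue {t!r} not present in the class table")
    ann.check_covers(classes.index)
    table = ann.table.loc[classes.index]
    b_cls = classes[blood_tissue]
    e_cls = classes[eye_tissue]
    code = {c: i + 1 for i, c in enumerate(CLASSES)}

    rows = []
    for scheme, column in (
        ("feature_class", table["feature_class"]),
        ("island_relation", table["island_relation"]),
    ):
        for category in column.unique():
            in_cat = (column == category).to_numpy()
            total = int(in_cat.sum())
            for bc in CLASSES:
                for ec in CLASSES:
                    n = int(
                        (in_cat & (b_cls == bc).to_numpy() & (e_cls == ec).to_numpy()).sum()
                    )
                    rows.append(
                        {
                            "scheme": scheme,
                            "category": category,
                            "blood_class": f"B{code[bc]}",
                            "eye_class": f"E{code[ec]}",
                            "count": n,
                            "percent": 100.0 * n / total if total else np.nan,
                        }
                    )
    return pd.DataFrame(rows)
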