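"""Genomic-context enrichment of probe subsets.

Given a probe subset (e.g. blood-variable probes, or probes tracking an
individual-associated principal component) and a background set
(typically all post-QC probes), each genomic feature class and each
CpG-island relation is tested for over/under-representation with a
two-sided Fisher exact test on the 2x2 table (subset vs rest of
background) x (in category vs not), BH-corrected within each annotation
scheme.  A chi-square variant is available for large tables.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FEATURE_CLASSES, ISLAND_RELATIONS, ProbeAnnotation
from .exceptions import ArgumentError
from .stats import bh_adjust, fisher_exact_test

__all__ = ["category_distribution", "enrichment_test"]

_SCHEMES = {"feature_class": FEATURE_CLASSES, "island_relation": ISLAND_RELATIONS}


def category_distribution(probes: Iterable[str], ann: ProbeAnnotation) -> pd.DataFrame:
    """Counts and proportions of a probe set per annotation category.

    Covers both schemes (feature class and island relation); proportions
    sum to 1 within each scheme.  All listed levels appear, including
    empty ones.
    """
    ids = list(probes)
    if not ids:
        raise ArgumentError("empty probe set")
    ann.check_covers(ids)
    table = ann.table.loc[ids]
    rows = []
    for scheme, levels in _SCHEMES.items():
        counts = table[scheme].value_counts()
        total = len(ids)
        for level in levels:
            n = int(counts.get(level, 0))
            rows.append(
                {
                    "scheme": scheme,
                    "category": level,
                    "count": n,
                    "proportion": n / total,
                }
            )
    return pd.DataFrame(rows)


def enrichment_test(
    subset: Iterable[str],
    background: Iterable[str],
    ann: ProbeAnnotation,
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-category enrichment of ``subset`` against ``background``.

    ``subset`` must be contained in ``background``.  For each category the
    2x2 table is (in subset / in rest-of-background) x (in category /
    not); the odds ratio is the sample cross-product ratio (``inf``
    reported for zero cells); p-values are two-sided Fisher exact
    (``method='chi2'`` switches to the chi-square test without continuity
    correction) and are BH-adjusted within each scheme.
    """
    sub = set(subset)
    bg = set(background)
    if not sub:
        raise ArgumentError("empty subset")
    if not sub <= bg:
        raise ArgumentError("subset must be contained in the background")
    if method not in ("fisher", "chi2"):
        raise ArgumentError(f"unknown method {method!r}")
    ann.check_covers(bg)
    sub_ids = sorted(sub)
    rest_ids = sorted(bg - sub)
    sub_tab = ann.table.loc[sub_ids]
    rest_tab = ann.table.loc[rest_ids]
    rows = []
    for scheme, levels in _SCHEMES.items():
        sub_counts = sub_tab[scheme].value_counts()
        rest_counts = rest_tab[scheme].value_counts()
        for level in levels:
            a = int(sub_counts.get(level, 0))  # subset, in category
            b = len(sub_ids) - a
            c = int(rest_counts.get(level, 0))  # rest, in category
            d = len(rest_ids) - c
            if method == "fisher":
                oddsratio, p = fisher_exact_test([[a, b], [c, d]])
            else:
                oddsratio = (a * d) / (b * c) if b * c > 0 else (
                    np.nan if a * d == 0 else np.inf
                )
                table = np.array([[a, b], [c, d]], dtype=float)
                if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                    p = 1.0
                else:
                    _, p, _, _ = sps.chi2_contingency(table, correction=False)
            rows.append(
                {
                    "scheme": scheme,
                    "category": level,
                    "subset_count": a,
                    "subset_proportion": a / len(sub_ids),
                    "background_count": a + c,
                    "background_proportion": (a + c) / len(bg),
                    "odds_ratio": oddsratio,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for scheme in _SCHEMES:
        mask = out["scheme"] == scheme
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p_value"].to_numpy())
    return out
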