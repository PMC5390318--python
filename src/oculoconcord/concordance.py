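"""Sample-level concordance: pairwise Spearman correlations, per-tissue-pair
summaries, and average-linkage hierarchical clustering on 1 - rho.

These are the global "how similar are whole methylomes" views: every
unordered sample pair gets a Spearman correlation over all probes
(pairwise-complete over missing cells), pairs are summarised per tissue
pair (median / min / max), and the correlation matrix is clustered
agglomeratively to expose tissue-of-origin structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import BetaMatrix, SampleSheet
from .exceptions import ArgumentError
from .stats import spearman_rho

__all__ = [
    "sample_pairwise_spearman",
    "tissue_pair_summary",
    "hierarchical_cluster",
]


def sample_pairwise_spearman(b: BetaMatrix) -> pd.DataFrame:
    """Symmetric matrix of Spearman correlations between all sample pairs.

    Each pair is computed pairwise-complete over probes; the diagonal is
    exactly 1.
    """
    if b.shape[1] < 2:
        raise ArgumentError("need at least 2 samples")
    samples = b.sample_ids
    vals = b.values
    out = np.eye(len(samples))
    for i, j in combinations(range(len(samples)), 2):
        rho = spearman_rho(vals[:, i], vals[:, j])
        out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=samples, columns=samples)


def tissue_pair_summary(scm: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Median / min / max sample-pair correlation per tissue pair.

    Covers every unordered cross-tissue pair plus the within-tissue pairs
    of each tissue; the median uses the midpoint convention for even
    counts (numpy default).
    """
    sheet.check_covers(scm.index)
    tissue_of = sheet.tissue_of()
    samples = list(scm.index)
    buckets: dict[tuple[str, str], list[float]] = {}
    for i, j in combinations(range(len(samples)), 2):
        ta, tb = sorted((tissue_of[samples[i]], tissue_of[samples[j]]))
        buckets.setdefault((ta, tb), []).append(float(scm.iat[i, j]))
    rows = []
    for (ta, tb), vals in sorted(buckets.items()):
        arr = np.asarray(vals)
        rows.append(
            {
                "tissue_a": ta,
                "tissue_b": tb,
                "within": ta == tb,
                "n_pairs": arr.size,
                "median_rho": float(np.median(arr)),
                "min_rho": float(arr.min()),
                "max_rho": float(arr.max()),
            }
        )
    return pd.DataFrame(rows)


def hierarchical_cluster(scm: pd.DataFrame) -> str:
    """Average-linkage agglomerative clustering on distance 1 - rho.

    Samples are ordered lexicographically before linkage so exact ties
    resolve deterministically toward the lexicographically smallest
    members.  Returns a Newick string with branch lengths under an
    ultrametric convention: a node merged at distance h sits at height
    h / 2, and a branch length is the height difference to the parent.
    """
    if scm.shape[0] < 2:
        raise ArgumentError("need at least 2 samples to cluster")
    ids = sorted(scm.index)
    d = 1.0 - scm.loc[ids, ids].to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)  # enforce symmetry/nonnegativity
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    tree = hierarchy.to_tree(link)

    def newick(node, parent_height: float) -> str:
        height = 0.0 if node.is_leaf() else node.dist / 2.0
        length = max(parent_height - height, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.10g}"
        left = newick(node.get_left(), height)
        right = newick(node.get_right(), height)
        return f"({left},{right}):{length:.10g}"

    root_height = tree.dist / 2.0
    left = newick(tree.get_left(), root_height)
    right = newick(tree.get_right(), root_height)
    return f"({left},{right});"
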