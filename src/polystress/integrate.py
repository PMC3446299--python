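"""Cross-level integration of mRNA, translation, and protein regulation.

Direction calls on mRNA time courses, a deterministic discordance
classification across the three layers, Pearson/Spearman correlation
reports, hypergeometric gene-set enrichment, and average-linkage
clustering with a Spearman-correlation similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "call_mrna_direction",
    "collapse_protein_direction",
    "classify_discordance",
    "correlate",
    "combine_mrna_translation",
    "max_change",
    "hypergeom_enrichment",
    "cluster_genes",
    "tree_to_newick",
    "DISCORDANCE_CLASSES",
]


def call_mrna_direction(
    tables: list[pd.DataFrame] | pd.DataFrame,
    fold_cutoff: float = 1.5,
    min_timepoints: int = 4,
) -> pd.DataFrame:
    """Per-gene mRNA direction from pooled stress time points.

    A gene is called *up* if its log2 ratio exceeds ``log2(fold_cutoff)``
    (strictly) at at least ``min_timepoints`` of the stress time points
    pooled across the supplied experiments; *down* symmetrically below
    ``-log2(fold_cutoff)``; otherwise *none*. Columns at time 0 are the
    unstressed reference and are ignored; missing values never count as
    passing.

    Returns a DataFrame indexed by gene id with columns ``direction``,
    ``n_up``, ``n_down`` and ``n_timepoints`` (pooled stress columns).
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not tables:
        raise ValueError("at least one mRNA table is required")
    cut = np.log2(fold_cutoff)

    stress_cols = []
    for tab in tables:
        cols = [c for c in tab.columns if float(str(c).split(":")[1]) > 0]
        stress_cols.append(tab[cols])
    pooled = pd.concat(stress_cols, axis=1)
    values = pooled.to_numpy(dtype=float)
    n_up = (values > cut).sum(axis=1)
    n_down = (values < -cut).sum(axis=1)
    if np.isnan(values).all(axis=1).any():
        warnings.warn("genes with no finite mRNA values are called 'none'")
    direction = np.where(
        n_up >= min_timepoints,
        "up",
        np.where(n_down >= min_timepoints, "down", "none"),
    )
    return pd.DataFrame(
        {
            "direction": direction,
            "n_up": n_up,
            "n_down": n_down,
            "n_timepoints": values.shape[1],
        },
        index=pooled.index,
    )


#: Temporal-category to up/down/none collapse used for discordance calls.
PROTEIN_DIRECTION = {
    "linear_up": "up",
    "quadratic_concave": "up",  # transient rise within the window
    "linear_down": "down",
    "quadratic_convex": "down",  # transient dip within the window
    "unchanged": "none",
}

DISCORDANCE_CLASSES = (
    "mRNA_up_translation_down",
    "mRNA_down_translation_up",
    "protein_up_mRNA_down",
    "protein_down_mRNA_up",
    "protein_up_mRNA_flat",
    "protein_down_mRNA_flat",
    "concordant",
    "unclassified",
)


def collapse_protein_direction(category: str) -> str:
    """Collapse a temporal-fit category to an up/down/none direction."""
    return PROTEIN_DIRECTION.get(category, "none")


def _discordance_rule(m: str, t: str, p: str) -> str:
    """Fixed-order rule table mapping level directions to one class.

    Rules are evaluated top to bottom; the first match wins, making the
    classes mutually exclusive:

    1. mRNA up & translation down  -> ``mRNA_up_translation_down``
    2. mRNA down & translation up  -> ``mRNA_down_translation_up``
    3. protein up & mRNA down      -> ``protein_up_mRNA_down``
    4. protein down & mRNA up      -> ``protein_down_mRNA_up``
    5. protein up & mRNA flat      -> ``protein_up_mRNA_flat``
    6. protein down & mRNA flat    -> ``protein_down_mRNA_flat``
    7. any co-directional or single-level regulation -> ``concordant``
    8. nothing regulated anywhere  -> ``unclassified``
    """
    if m == "up" and t == "down":
        return "mRNA_up_translation_down"
    if m == "down" and t == "up":
        return "mRNA_down_translation_up"
    if p == "up" and m == "down":
        return "protein_up_mRNA_down"
    if p == "down" and m == "up":
        return "protein_down_mRNA_up"
    if p == "up" and m == "none":
        return "protein_up_mRNA_flat"
    if p == "down" and m == "none":
        return "protein_down_mRNA_flat"
    if m == "none" and t == "none" and p == "none":
        return "unclassified"
    return "concordant"


def classify_discordance(
    mrna_direction: pd.Series,
    translation_direction: pd.Series,
    protein_category: pd.Series,
) -> pd.DataFrame:
    """Classify every gene's cross-level concordance.

    Genes absent at a level are treated as ``none`` at that level and
    flagged in the ``missing_level`` column. The classes partition the
    union gene universe.
    """
    universe = mrna_direction.index.union(translation_direction.index).union(
        protein_category.index
    )
    m = mrna_direction.reindex(universe)
    t = translation_direction.reindex(universe)
    p_cat = protein_category.reindex(universe)
    missing = m.isna() | t.isna() | p_cat.isna()
    m = m.fillna("none")
    t = t.fillna("none")
    p = p_cat.fillna("unchanged").map(collapse_protein_direction)
    labels = [
        _discordance_rule(mi, ti, pi) for mi, ti, pi in zip(m, t, p)
    ]
    return pd.DataFrame(
        {
            "class": labels,
            "mrna_direction": m,
            "translation_direction": t,
            "protein_direction": p,
            "missing_level": missing,
        },
        index=universe,
    )


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-tailed p-value over paired values.

    Pairs with non-finite entries are dropped; at least three finite
    pairs and nonzero variance in both vectors are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


def combine_mrna_translation(mrna_fold, translation_ratio) -> np.ndarray:
    """Combined mRNA x translation change: product of linear-scale ratios."""
    m = np.asarray(mrna_fold, dtype=float)
    t = np.asarray(translation_ratio, dtype=float)
    if (m <= 0).any() or (t <= 0).any():
        raise ValueError("fold changes and translation ratios must be positive")
    return m * t


def max_change(trajectory) -> float:
    """Signed log2 change with the largest absolute magnitude."""
    a = np.asarray(trajectory, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("empty trajectory")
    return float(a[np.argmax(np.abs(a))])


@dataclass
class EnrichmentResult:
    set_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adjusted: float | None = None


def hypergeom_enrichment(
    query: set,
    annotation_sets: dict[str, set],
    universe: set,
    adjust: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query gene set.

    For each annotation set (intersected with the universe) of size K in
    a universe of size N, with query size n and overlap k, reports
    ``P(X >= k)`` for X ~ Hypergeometric(N, K, n). Benjamini-Hochberg
    adjustment across sets is available but off by default (raw tail
    probabilities are reported).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    N, n = len(universe), len(query)
    rows = []
    for name, genes in annotation_sets.items():
        members = set(genes) & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set_name")
    if adjust and len(out):
        m = len(out)
        order = np.argsort(out["p"].to_numpy())
        ranked = out["p"].to_numpy()[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        out["p_adjusted"] = adj
    return out


def _spearman_distance_matrix(values: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    corr = np.corrcoef(ranks)
    return 1.0 - corr


def cluster_genes(
    matrix: pd.DataFrame,
) -> tuple[np.ndarray, list[str], pd.Index, pd.Index]:
    """Average-linkage hierarchical clustering of gene rows.

    Distance between genes is ``1 - Spearman correlation`` of their
    ratio profiles, so the tree is invariant to monotone transforms of
    individual rows. Constant rows (undefined rank correlation) are
    dropped with a warning. Ties are broken deterministically by
    scipy's ordered linkage; leaves are reported in dendrogram order.

    Returns ``(linkage matrix, leaf order as gene ids, clustered index
    in linkage row order, dropped index)``.
    """
    values = matrix.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant rows from clustering")
    kept = matrix.loc[~constant]
    if kept.shape[0] < 2 or kept.shape[1] < 2:
        raise ValueError("need at least 2 non-constant genes and 2 columns")
    dist = _spearman_distance_matrix(kept.to_numpy(dtype=float))
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    leaves = [kept.index[i] for i in order]
    return Z, leaves, kept.index, matrix.index[constant]


def tree_to_newick(Z: np.ndarray, labels: pd.Index | list[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
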