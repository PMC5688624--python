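"""Cross-species IR integration: ortholog profile matrix, normalization,
clustering, intersection counts, and the IR-fraction vs gene-count
correlation.

The profile matrix has one row per ortholog group and one column per
species, holding gene-level IR ratios (missing where the ortholog is
absent or unmeasured). Columns are quantile normalized before k-means row
clustering (Euclidean); species columns are clustered hierarchically with
1 - Pearson average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

# Published genomic characteristics used by the complexity correlation:
# per species, protein-coding gene count, expressed-gene count in
# granulocytes where reported, and percent of expressed genes affected by
# IR.
SPECIES_SUMMARY = pd.DataFrame(
    [
        ("human", 20296, None, 17.4),
        ("mouse", 22547, None, 13.6),
        ("dog", 19856, None, 18.6),
        ("chicken", 15508, 8911, 40.8),
        ("zebrafish", 25642, 768, 7.8),
    ],
    columns=["species", "n_pc_genes", "n_expressed", "fraction_ir_genes"],
)


@dataclass
class SpeciesSummary:
    species: str
    n_pc_genes: int
    n_expressed: int | None
    fraction_ir_genes: float  # percent of expressed genes

    def __post_init__(self):
        if not 0 <= self.fraction_ir_genes <= 100:
            raise ValueError("fraction_ir_genes is a percentage in [0, 100]")


def build_profile_matrix(gene_irs_by_species: dict, ortholog_rows) -> pd.DataFrame:
    """Ortholog-group x species matrix of gene IR ratios.

    ``ortholog_rows`` is an iterable of (group_id, species, gene_id);
    many-to-many groups collapse to the maximum IR ratio per species.
    Rows with no observation in any species are dropped.
    """
    table: dict[str, dict[str, float]] = {}
    for group, species, gene in ortholog_rows:
        gir = gene_irs_by_species.get(species, {}).get(gene)
        if gir is None:
            continue
        val = gir.gene_ir_ratio if hasattr(gir, "gene_ir_ratio") else float(gir)
        row = table.setdefault(group, {})
        row[species] = max(row.get(species, -np.inf), val)
    species_names = sorted(gene_irs_by_species)
    mat = pd.DataFrame.from_dict(table, orient="index").reindex(
        columns=species_names
    )
    return mat.sort_index()


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution (mean of sorted
    columns); missing values stay missing, ranks are over observed entries.

    With missing values the reference distribution is built by
    interpolating each column's sorted observed values onto a common grid;
    each observed value is then replaced by the reference quantile at its
    (average-tie) rank. Idempotent.
    """
    m = matrix.to_numpy(dtype=float)
    n_rows, n_cols = m.shape
    grid = np.linspace(0, 1, n_rows)
    ref = np.zeros(n_rows)
    n_used = 0
    for j in range(n_cols):
        col = m[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            continue
        q = np.linspace(0, 1, obs.size)
        ref += np.interp(grid, q, obs)
        n_used += 1
    if n_used == 0:
        return matrix.copy()
    ref /= n_used
    out = m.copy()
    for j in range(n_cols):
        col = m[:, j]
        mask = ~np.isnan(col)
        k = mask.sum()
        if k == 0:
            continue
        # average ranks for ties so equal inputs map to equal outputs
        ranks = pd.Series(col[mask]).rank(method="average").to_numpy() - 1
        q = ranks / (k - 1) if k > 1 else np.array([0.5] * k)
        out[mask, j] = np.interp(q, grid, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def kmeans_rows(matrix: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10):
    """K-means (Euclidean) over complete rows; returns a Series of labels.

    Rows containing missing values are dropped (complete-profile rule).
    Deterministic under the seed; best of ``n_init`` restarts.
    """
    from sklearn.cluster import KMeans

    complete = matrix.dropna()
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(complete.to_numpy())
    return pd.Series(labels, index=complete.index, name="cluster")


def gap_statistic_k(matrix: pd.DataFrame, k_range=range(2, 11), seed: int = 0,
                    n_ref: int = 10):
    """Tibshirani-style gap statistic helper for choosing k."""
    from sklearn.cluster import KMeans

    x = matrix.dropna().to_numpy()
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    gaps = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(x)
        ref_inertia = []
        for _ in range(n_ref):
            xr = rng.uniform(lo, hi, size=x.shape)
            ref_inertia.append(
                KMeans(n_clusters=k, n_init=2, random_state=seed).fit(xr).inertia_
            )
        gaps[k] = float(np.log(np.mean(ref_inertia)) - np.log(km.inertia_))
    best = max(gaps, key=gaps.get)
    return best, gaps


def hcluster_species(matrix: pd.DataFrame):
    """Average-linkage clustering of species columns at 1 - Pearson distance.

    Correlations are pairwise-complete. Returns (linkage matrix, newick
    string, column order).
    """
    corr = matrix.corr(method="pearson", min_periods=2)
    dist = (1.0 - corr).to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0, None)
    z = hierarchy.average(squareform(dist, checks=False))
    newick = _tree_to_newick(hierarchy.to_tree(z), list(matrix.columns))
    return z, newick, list(matrix.columns)


def _tree_to_newick(node, labels) -> str:
    def rec(n, parent_dist):
        if n.is_leaf():
            return f"{labels[n.id]}:{parent_dist - n.dist:.6g}"
        left = rec(n.get_left(), n.dist)
        right = rec(n.get_right(), n.dist)
        return f"({left},{right}):{parent_dist - n.dist:.6g}"

    return rec(node, node.dist).rsplit(":", 1)[0] + ";"


def venn_counts(ir_gene_sets: dict[str, set], ortholog_rows) -> dict:
    """Counts per exclusive intersection region over ortholog groups.

    ``ir_gene_sets`` maps species -> set of IR gene ids. Regions are keyed
    by frozenset of species names; all 2^n - 1 regions are reported
    (exclusive counts). Also returns the full n-way inclusive intersection
    under key "all".
    """
    gene_to_group = {}
    group_species_genes: dict[str, dict[str, list[str]]] = {}
    for group, species, gene in ortholog_rows:
        gene_to_group[(species, gene)] = group
        group_species_genes.setdefault(group, {}).setdefault(species, []).append(gene)
    species_names = sorted(ir_gene_sets)
    group_pattern: dict[str, frozenset] = {}
    for group, per_sp in group_species_genes.items():
        members = frozenset(
            sp
            for sp in species_names
            if any(g in ir_gene_sets.get(sp, ()) for g in per_sp.get(sp, ()))
        )
        if members:
            group_pattern[group] = members
    regions: dict[frozenset, int] = {}
    for r in range(1, len(species_names) + 1):
        for combo in combinations(species_names, r):
            regions[frozenset(combo)] = 0
    for members in group_pattern.values():
        regions[members] += 1
    inclusive_all = sum(
        1 for m in group_pattern.values() if m == frozenset(species_names)
    )
    return {"regions": regions, "all": inclusive_all,
            "union": len(group_pattern)}


def correlate_ir_complexity(summaries) -> float:
    """Pearson r between IR-gene fraction and protein-coding gene count,
    rounded to 2 dp."""
    rows = list(summaries)
    if len(rows) < 3:
        raise ValueError("need >= 3 species")
    x = np.array([s.n_pc_genes for s in rows], float)
    y = np.array([s.fraction_ir_genes for s in rows], float)
    r = np.corrcoef(x, y)[0, 1]
    return float(round(r, 2))


def published_species_summaries() -> list[SpeciesSummary]:
    return [
        SpeciesSummary(
            species=row.species,
            n_pc_genes=int(row.n_pc_genes),
            n_expressed=None if pd.isna(row.n_expressed) else int(row.n_expressed),
            fraction_ir_genes=float(row.fraction_ir_genes),
        )
        for row in SPECIES_SUMMARY.itertuples(index=False)
    ]
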