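"""Two-colour expression normalization, Eisen-style clustering and
differential-expression reanalysis.

Normalization reuses the lowess log-ratio detrending of the ChIP module;
genes are filtered on mean channel intensity, clustered by agglomerative
centroid linkage under 1 - uncentered correlation (the Cluster program's
metric), and a knockout-vs-wild-type design is reanalysed with per-gene
Welch t-tests, Benjamini-Hochberg adjustment and a signed linear
fold-change cutoff. Gene-set enrichment is a one-sided Fisher
(hypergeometric) test against a background universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .chip import LowessNormalizer


@dataclass
class RatioMatrix:
    """Genes x replicates log2(treatment/control) ratios plus the mean
    channel intensities used for filtering."""

    ratios: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.ratios.index.equals(self.intensities.index):
            raise ValueError("ratios and intensities must share gene index")

    @property
    def genes(self) -> pd.Index:
        return self.ratios.index

    @property
    def replicates(self) -> list[str]:
        return list(self.ratios.columns)


def normalize_expression(tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
                         span: float = 0.3, id_col: str = "gene_id",
                         control_col: str = "ch_cy3",
                         treatment_col: str = "ch_cy5") -> RatioMatrix:
    """Per-array lowess-detrended log2 treatment/control ratios."""
    if not isinstance(tables, Mapping):
        tables = {f"rep{i + 1}": t for i, t in enumerate(tables)}
    ratio_cols, inten_cols = {}, {}
    for rep, table in tables.items():
        raw = table[[control_col, treatment_col]].to_numpy(dtype=float)
        ok = np.all(raw > 0, axis=1) & np.all(np.isfinite(raw), axis=1)
        xy = LowessNormalizer(span=span).fit_transform(raw[ok])
        ids = table.loc[ok, id_col].to_numpy()
        ratio_cols[rep] = pd.Series(xy[:, 1] - xy[:, 0], index=ids)
        inten_cols[rep] = pd.Series((xy[:, 0] + xy[:, 1]) / 2, index=ids)
    ratios = pd.DataFrame(ratio_cols)
    intensities = pd.DataFrame(inten_cols)
    ratios.index.name = intensities.index.name = "gene_id"
    return RatioMatrix(ratios, intensities)


def filter_low_intensity(matrix: RatioMatrix,
                         min_intensity: float | None = None) -> RatioMatrix:
    """Mask entries whose mean channel intensity falls below the threshold
    in that replicate; drop genes masked everywhere.

    Default threshold: 1st percentile of the pooled intensities.
    """
    if min_intensity is None:
        min_intensity = float(np.nanpercentile(
            matrix.intensities.to_numpy(float), 1))
    mask = matrix.intensities < min_intensity
    ratios = matrix.ratios.mask(mask)
    keep = ~ratios.isna().all(axis=1)
    return RatioMatrix(ratios.loc[keep], matrix.intensities.loc[keep])


def uncentered_correlation(x, y) -> float:
    """sum(x*y) / sqrt(sum(x^2) * sum(y^2)); undefined for a zero vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors of length >= 2")
    nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float((x * y).sum() / (nx * ny))


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy-style (n-1, 4): left, right, height, size
    assignments: pd.Series       # gene_id -> cluster id (1..n_clusters)
    n_clusters: int


class UncenteredCentroidClustering(BaseEstimator):
    """Agglomerative clustering with centroid linkage under the distance
    1 - uncentered correlation.

    A cluster's centroid is the mean profile of its genes. Heights may
    invert (centroid linkage is not monotone); the cut therefore breaks
    the ``n_clusters - 1`` merges with the greatest heights rather than
    assuming a monotone dendrogram. Genes are processed in sorted-id order
    so the result is invariant to input order; ties in the merge distance
    are broken by the smallest (cluster, cluster) pair in that order.
    Missing entries must be imputed (by convention to 0 = no change)
    before fitting.
    """

    def __init__(self, n_clusters: int = 7):
        self.n_clusters = n_clusters

    def fit(self, X, y=None) -> "UncenteredCentroidClustering":
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if isinstance(X, pd.DataFrame):
            ids = X.index.astype(str)
            order = np.argsort(ids)      # canonical order: sorted gene ids
            data = X.to_numpy(dtype=float)[order]
            names = ids[order]
        else:
            data = np.asarray(X, dtype=float)
            order = np.arange(len(data))
            names = pd.Index([str(i) for i in range(len(data))])
        n = len(data)
        if n < self.n_clusters:
            raise ValueError("fewer genes than clusters")
        data = np.nan_to_num(data, nan=0.0)
        norms = np.linalg.norm(data, axis=1)
        if np.any(norms == 0):
            raise ValueError("all-zero profile(s): uncentered correlation "
                             "is undefined; drop or impute these genes")

        sums = data.copy()
        sizes = np.ones(n)
        active = np.ones(2 * n - 1, dtype=bool)
        active[n:] = False
        # centroid rows for every node id (leaves + internals)
        cent = np.zeros((2 * n - 1, data.shape[1]))
        cent[:n] = data
        unit = np.zeros_like(cent)
        unit[:n] = data / norms[:, None]
        all_sums = np.zeros_like(cent)
        all_sums[:n] = data
        all_sizes = np.zeros(2 * n - 1)
        all_sizes[:n] = 1

        # pairwise distances among active nodes, maintained incrementally
        dist = np.full((2 * n - 1, 2 * n - 1), np.inf)
        d0 = 1.0 - unit[:n] @ unit[:n].T
        dist[:n, :n] = d0
        np.fill_diagonal(dist, np.inf)

        linkage = np.zeros((n - 1, 4))
        for step in range(n - 1):
            act = np.flatnonzero(active)
            sub = dist[np.ix_(act, act)]
            flat = np.argmin(sub)
            i_, j_ = divmod(flat, len(act))
            # np.argmin returns the first minimum in row-major order, which
            # realises the smallest-(i, j) tie-break in canonical order
            gi, gj = int(act[min(i_, j_)]), int(act[max(i_, j_)])
            h = dist[gi, gj]
            new = n + step
            all_sums[new] = all_sums[gi] + all_sums[gj]
            all_sizes[new] = all_sizes[gi] + all_sizes[gj]
            c = all_sums[new] / all_sizes[new]
            nc = np.linalg.norm(c)
            cent[new] = c
            unit[new] = c / nc if nc > 0 else 0.0
            active[gi] = active[gj] = False
            active[new] = True
            rest = np.flatnonzero(active[:new])
            if len(rest):
                d_new = 1.0 - unit[rest] @ unit[new]
                dist[new, rest] = d_new
                dist[rest, new] = d_new
            linkage[step] = (gi, gj, h, all_sizes[new])

        labels_sorted = self._cut(linkage, n, self.n_clusters)
        # map back to the caller's input order
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
        self.labels_ = labels
        self.linkage_ = linkage
        self.gene_order_ = names
        self.assignments_ = pd.Series(labels_sorted, index=names,
                                      name="cluster")
        return self

    @staticmethod
    def _cut(linkage: np.ndarray, n: int, n_clusters: int) -> np.ndarray:
        """Break the n_clusters - 1 largest merges (later merge wins ties)
        and label the remaining connected groups 1..n_clusters in order of
        first gene appearance."""
        n_break = min(n_clusters - 1, n - 1)
        heights = linkage[:, 2]
        by_height = sorted(range(len(heights)),
                           key=lambda i: (-heights[i], -i))
        broken = set(by_height[:n_break])
        parent = np.arange(2 * n - 1)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for step, (li, ri, _, _) in enumerate(linkage):
            if step in broken:
                continue
            new = n + step
            parent[find(int(li))] = new
            parent[find(int(ri))] = new
        roots: dict[int, int] = {}
        labels = np.zeros(n, dtype=int)
        for g in range(n):
            r = find(g)
            if r not in roots:
                roots[r] = len(roots) + 1
            labels[g] = roots[r]
        return labels

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cluster_genes(matrix: RatioMatrix | pd.DataFrame,
                  n_clusters: int = 7) -> ClusterResult:
    ratios = matrix.ratios if isinstance(matrix, RatioMatrix) else matrix
    model = UncenteredCentroidClustering(n_clusters=n_clusters).fit(ratios)
    return ClusterResult(linkage=model.linkage_,
                         assignments=model.assignments_,
                         n_clusters=n_clusters)


def select_variable_genes(matrix: RatioMatrix | pd.DataFrame,
                          min_sd: float = 0.5) -> pd.Index:
    """Genes whose ratio profile standard deviation exceeds min_sd — the
    'differentially expressed' genes that enter the clustering, mirroring
    a heatmap built from responsive genes only."""
    ratios = matrix.ratios if isinstance(matrix, RatioMatrix) else matrix
    sd = ratios.std(axis=1, ddof=0)
    return ratios.index[sd > min_sd]


def direction_counts(matrix: RatioMatrix | pd.DataFrame,
                     assignments: pd.Series | None = None) -> pd.DataFrame:
    """Up/down/zero gene counts, per cluster and overall, by the sign of
    each gene's mean log2 ratio (exact zeros counted separately)."""
    ratios = matrix.ratios if isinstance(matrix, RatioMatrix) else matrix
    mean = ratios.mean(axis=1, skipna=True)
    sign = np.sign(mean)
    frame = pd.DataFrame({"sign": sign})
    frame["cluster"] = (assignments.reindex(ratios.index)
                        if assignments is not None else "all")
    rows = []
    groups = list(frame.groupby("cluster", sort=True))
    if assignments is not None:
        groups.append(("overall", frame))
    for name, grp in groups:
        rows.append((name, int((grp["sign"] > 0).sum()),
                     int((grp["sign"] < 0).sum()),
                     int((grp["sign"] == 0).sum()), len(grp)))
    return pd.DataFrame(rows, columns=["cluster", "n_up", "n_down",
                                       "n_zero", "n_genes"]).set_index("cluster")


class DifferentialExpression(BaseEstimator):
    """Per-gene Welch t-test with BH adjustment and a signed fold-change rule.

    fit(X, y): X is a genes x samples matrix of log2 expression, y the
    two group labels. Fold change is the ratio of linear-scale group means
    (first group over second in sorted label order), reported as -1/r when
    r < 1. A gene is significant when BH-adjusted p <= alpha and
    |signed FC| >= fc_threshold.
    """

    def __init__(self, fc_threshold: float = 1.1, alpha: float = 0.05):
        self.fc_threshold = fc_threshold
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "DifferentialExpression":
        y = np.asarray(y)
        groups = sorted(set(y))
        if len(groups) != 2:
            raise ValueError("exactly two groups required")
        a = X.loc[:, y == groups[0]].to_numpy(float)
        b = X.loc[:, y == groups[1]].to_numpy(float)
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("need >= 2 samples per group")
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        degenerate = (var_a == 0) & (var_b == 0)
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
        p = np.where(np.isnan(p), 1.0, p)
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        ratio = np.power(2.0, a).mean(axis=1) / np.power(2.0, b).mean(axis=1)
        fc = np.where(ratio >= 1, ratio, -1.0 / ratio)
        significant = (p_adj <= self.alpha) & (np.abs(fc) >= self.fc_threshold)
        self.results_ = pd.DataFrame({
            "fold_change": fc, "p": p, "p_adj": p_adj,
            "significant": significant}, index=X.index)
        self.groups_ = groups
        return self


def differential_expression(X: pd.DataFrame, labels: Sequence[str],
                            fc_threshold: float = 1.1,
                            alpha: float = 0.05) -> pd.DataFrame:
    return DifferentialExpression(fc_threshold=fc_threshold,
                                  alpha=alpha).fit(X, labels).results_


# ---------------------------------------------------------------------------
# gene-set enrichment


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line, tab-separated: name, description, genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g.upper() for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na"] + sorted(genes)) + "\n")


def fisher_enrichment(gene_list, background, gene_sets: Mapping[str, set[str]],
                      min_genes: int = 3, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each category in gene_list.

    Enrichment is determined relative to the background universe (e.g. the
    genes on the array); categories hitting fewer than ``min_genes`` list
    genes are excluded.
    """
    background = {str(g).upper() for g in background}
    if not background:
        raise ValueError("background must be non-empty")
    gene_list = {str(g).upper() for g in gene_list}
    if not gene_list <= background:
        raise ValueError("gene list must be a subset of the background")
    N, n = len(background), len(gene_list)
    rows = []
    for name, members in gene_sets.items():
        cat = {m.upper() for m in members} & background
        K = len(cat)
        k = len(cat & gene_list)
        if k < min_genes:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, n, K, N, p, p <= alpha))
    out = pd.DataFrame(rows, columns=["category", "k", "n", "K", "N",
                                      "p", "significant"])
    return out.sort_values("p", kind="stable").reset_index(drop=True)
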