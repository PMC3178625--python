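"""Promoter-level aggregation of probe p-values and replicate combination.

A probe belongs to a gene's promoter when its midpoint falls in the
half-open window [-5500, +2500) bp around the TSS (strand-aware: upstream
means 5' of the TSS). Per gene and replicate the best (minimum) probe
p-value is taken; a gene is called bound when the geometric mean of its
per-replicate best p-values passes a global threshold AND enough single
replicates pass a per-replicate threshold. Two presets mirror the two
experimental settings: the cell-line rule (geometric mean <= 1e-4 with
p < 1e-3 in at least 2 of 3 replicates) and the brain rule (geometric
mean <= 1e-3, same per-replicate condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

PROMOTER_WINDOW = (-5500, 2500)


@dataclass(frozen=True)
class SelectionRule:
    t_geo: float
    t_rep: float
    k_min: int
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.t_geo < 1 and 0 < self.t_rep < 1):
            raise ValueError("thresholds must be in (0, 1)")
        if not 1 <= self.k_min <= self.n_replicates:
            raise ValueError("k_min must be in [1, n_replicates]")


N2A_RULE = SelectionRule(t_geo=1e-4, t_rep=1e-3, k_min=2, n_replicates=3)
BRAIN_RULE = SelectionRule(t_geo=1e-3, t_rep=1e-3, k_min=2, n_replicates=3)

RULE_PRESETS = {"n2a": N2A_RULE, "brain": BRAIN_RULE}


def compute_tss_offsets(midpoints, tss, strand) -> np.ndarray:
    """Signed offset of probe midpoints from the TSS along the direction of
    transcription (negative = upstream)."""
    midpoints = np.asarray(midpoints, dtype=float)
    tss = np.asarray(tss, dtype=float)
    sign = np.where(np.asarray(strand) == "-", -1.0, 1.0)
    return (midpoints - tss) * sign


def map_probes_to_promoters(annotation: pd.DataFrame,
                            window: tuple[int, int] = PROMOTER_WINDOW
                            ) -> dict[str, list[str]]:
    """gene_id -> probe ids whose midpoint offset lies in [window[0], window[1]).

    Probes with no gene are kept out of every promoter set (assigned to
    none); the annotation must carry strand-aware ``tss_offset``.
    """
    lo, hi = window
    ann = annotation.dropna(subset=["gene_id"])
    ann = ann[ann["gene_id"].astype(str).str.len() > 0]
    keep = (ann["tss_offset"] >= lo) & (ann["tss_offset"] < hi)
    mapping: dict[str, list[str]] = {}
    for gene, probe in zip(ann.loc[keep, "gene_id"], ann.loc[keep, "probe_id"]):
        mapping.setdefault(str(gene), []).append(str(probe))
    return mapping


def gene_level_p(probe_tables: Mapping[str, pd.DataFrame] | list[pd.DataFrame],
                 gene_to_probes: Mapping[str, list[str]]
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene per-replicate best (minimum) probe p-value.

    probe_tables maps replicate id to a table with probe_id and p. Returns
    (p matrix genes x replicates, matching best-probe-id matrix); genes
    with no probe in any replicate are absent.
    """
    if not isinstance(probe_tables, Mapping):
        probe_tables = {f"rep{i + 1}": t for i, t in enumerate(probe_tables)}
    p_cols, id_cols = {}, {}
    for rep, table in probe_tables.items():
        if table["p"].isna().any():
            raise ValueError(f"replicate {rep} has probes without p")
        p_by_probe = table.set_index("probe_id")["p"]
        best_p, best_id = {}, {}
        for gene, probes in gene_to_probes.items():
            present = p_by_probe.reindex(probes).dropna()
            if len(present):
                best = present.idxmin()
                best_p[gene], best_id[gene] = float(present.min()), best
        p_cols[rep], id_cols[rep] = best_p, best_id
    pmat = pd.DataFrame(p_cols).dropna()
    pmat.index.name = "gene_id"
    ids = pd.DataFrame(id_cols).reindex(pmat.index)
    return pmat, ids


def combine_replicates(p_matrix: pd.DataFrame, rule: SelectionRule,
                       descending: bool = False) -> pd.DataFrame:
    """Apply the geometric-mean / per-replicate-count selection rule.

    geo_mean uses <= (inclusive); the per-replicate count uses strict <.
    Output is sorted by geo_mean_p ascending (descending reproduces a
    decreasing-p rank-order listing). Replicate order is irrelevant.
    """
    p = p_matrix.to_numpy(dtype=float)
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if p_matrix.shape[1] != rule.n_replicates:
        raise ValueError(f"rule expects {rule.n_replicates} replicates, "
                         f"matrix has {p_matrix.shape[1]}")
    geo = np.exp(np.log(p).mean(axis=1))
    n_below = (p < rule.t_rep).sum(axis=1)
    positive = (geo <= rule.t_geo) & (n_below >= rule.k_min)
    out = p_matrix.copy()
    out["geo_mean_p"] = geo
    out["n_below"] = n_below
    out["positive"] = positive
    return out.sort_values("geo_mean_p", ascending=not descending,
                           kind="stable")


def call_genes(probe_tables, annotation: pd.DataFrame,
               rule: SelectionRule = N2A_RULE,
               window: tuple[int, int] = PROMOTER_WINDOW) -> pd.DataFrame:
    """Probe tables + annotation -> gene call table (one row per gene)."""
    mapping = map_probes_to_promoters(annotation, window=window)
    pmat, _ = gene_level_p(probe_tables, mapping)
    return combine_replicates(pmat, rule)


def positive_genes(gene_calls: pd.DataFrame) -> set[str]:
    return set(gene_calls.index[gene_calls["positive"]].astype(str))
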