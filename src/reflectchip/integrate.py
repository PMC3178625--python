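"""Overlap arithmetic between binding and expression gene lists, plus the
small lab-math utilities (qPCR percent-input, luciferase normalization)
and the end-to-end pipeline driver.

Gene identifiers are upper-cased before any set arithmetic; an optional
alias table maps synonyms onto canonical symbols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel


def _norm(genes: Iterable[str], aliases: Mapping[str, str] | None = None) -> set[str]:
    aliases = {k.upper(): v.upper() for k, v in (aliases or {}).items()}
    out = set()
    for g in genes:
        g = str(g).upper()
        out.add(aliases.get(g, g))
    return out


@dataclass(frozen=True)
class VennSummary:
    n_a: int
    n_b: int
    n_intersection: int
    label_a: str = "A"
    label_b: str = "B"

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_intersection

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_intersection) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_intersection > min(self.n_a, self.n_b):
            raise ValueError("intersection exceeds a set size")


def venn(set_a: Iterable[str], set_b: Iterable[str], label_a: str = "A",
         label_b: str = "B",
         aliases: Mapping[str, str] | None = None) -> VennSummary:
    """Exact two-set overlap after case normalization."""
    a, b = _norm(set_a, aliases), _norm(set_b, aliases)
    return VennSummary(len(a), len(b), len(a & b), label_a, label_b)


def round_percent(value: float, style: str = "one_decimal") -> float:
    """'one_decimal' for Results-style figures, 'integer' for
    Abstract-style approximations (half away from zero)."""
    if style == "one_decimal":
        return float(np.floor(value * 10 + 0.5) / 10)
    if style == "integer":
        return float(np.floor(value + 0.5))
    raise ValueError("style must be 'one_decimal' or 'integer'")


@dataclass(frozen=True)
class DirectionCrossTab:
    n_common: int
    n_same_direction: int
    n_opposite: int
    n_zero: int = 0

    def __post_init__(self) -> None:
        if self.n_same_direction + self.n_opposite != self.n_common:
            raise ValueError("same + opposite must equal n_common "
                             "(zero-change genes are counted separately)")


def direction_crosstab(directions_a: Mapping[str, float],
                       directions_b: Mapping[str, float]) -> DirectionCrossTab:
    """Cross-tabulate signed regulation directions of the genes deregulated
    in both comparisons. Genes with a zero change in either are excluded
    from the same/opposite split and counted separately."""
    a = {str(k).upper(): float(v) for k, v in directions_a.items()}
    b = {str(k).upper(): float(v) for k, v in directions_b.items()}
    common = set(a) & set(b)
    zero = {g for g in common if a[g] == 0 or b[g] == 0}
    same = sum(1 for g in common - zero if np.sign(a[g]) == np.sign(b[g]))
    opposite = len(common - zero) - same
    return DirectionCrossTab(n_common=len(common - zero),
                             n_same_direction=same, n_opposite=opposite,
                             n_zero=len(zero))


def deregulated_fraction(bound: Iterable[str],
                         deregulated: Mapping[str, Iterable[str]],
                         aliases: Mapping[str, str] | None = None) -> dict:
    """Fraction of bound genes deregulated in any comparison.

    Returns the per-comparison overlaps plus the union fraction
    100 * |bound & union(deregulated)| / |bound|, raw and rounded both
    one-decimal and integer style.
    """
    bound_set = _norm(bound, aliases)
    if not bound_set:
        raise ValueError("bound gene set must be non-empty")
    per = {}
    union: set[str] = set()
    for name, genes in deregulated.items():
        d = _norm(genes, aliases)
        inter = bound_set & d
        union |= d
        per[name] = {"n_overlap": len(inter),
                     "pct": 100.0 * len(inter) / len(bound_set)}
    n_union = len(bound_set & union)
    pct = 100.0 * n_union / len(bound_set)
    return {"n_bound": len(bound_set), "per_comparison": per,
            "n_union_overlap": n_union, "pct_raw": pct,
            "pct_one_decimal": round_percent(pct, "one_decimal"),
            "pct_integer": round_percent(pct, "integer")}


def qpcr_percent_input(records: pd.DataFrame) -> pd.DataFrame:
    """%input = 100 * 2^-(Ct(IP) - (Ct(input) - dilution_factor))."""
    for col in ("ct_ip", "ct_input", "dilution_factor"):
        if not np.isfinite(records[col]).all():
            raise ValueError(f"non-finite values in {col}")
    out = records.copy()
    delta_ct = out["ct_ip"] - (out["ct_input"] - out["dilution_factor"])
    out["percent_input"] = 100.0 * np.power(2.0, -delta_ct)
    return out


def luciferase_relative_activity(records: pd.DataFrame,
                                 control_label: str = "control",
                                 group_col: str = "group") -> pd.DataFrame:
    """Firefly/Renilla ratios as percent of the mean control-well ratio."""
    if (records["renilla"] <= 0).any():
        raise ValueError("renilla activity must be positive")
    controls = records[records[group_col] == control_label]
    if controls.empty:
        raise ValueError(f"no wells labelled {control_label!r}")
    ratio = records["firefly"] / records["renilla"]
    ctrl_mean = float((controls["firefly"] / controls["renilla"]).mean())
    out = records.copy()
    out["relative_activity"] = 100.0 * ratio / ctrl_mean
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline


class PipelineReport(BaseModel):
    """Schema of the end-to-end report (validated on construction)."""

    seed: int
    package_version: str
    chip: dict
    gene_calls: dict
    motif: dict
    expression: dict
    integration: dict


@dataclass
class PipelineConfig:
    """Simulation-backed end-to-end run, scaled to desktop size."""

    seed: int = 0
    n_genes: int = 800
    probes_per_gene: int = 14
    frac_enriched: float = 0.05
    effect_delta: float = 2.0
    n_replicates: int = 3
    rule: str = "n2a"
    motif_consensus: str = "TAATTA"
    plant_fraction: float = 0.8
    n_control_sequences: int = 200
    n_expr_clusters: int = 7
    genes_per_cluster: int = 40
    n_null_genes: int = 520
    span: float = 0.3
    null_quantile: float = 0.999
    outdir: str | Path | None = None


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate inputs, run every stage, and return a validated report.

    Stage order: probe calling -> gene selection -> motif analysis ->
    expression clustering -> integration. Any stage failure aborts with
    the stage name. The report's percentages are recomputable from the
    emitted gene lists.
    """
    from . import __version__
    from . import chip as chip_mod
    from . import expression as expr_mod
    from . import genes as genes_mod
    from . import motifs as motifs_mod
    from . import simulate as sim

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    report: dict = {"seed": cfg.seed, "package_version": __version__}
    outdir = Path(cfg.outdir) if cfg.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _Stage:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return _Stage()

    with stage("chip_calling"):
        chip_sim = sim.simulate_chip_arrays(sim.ChipSimConfig(
            n_genes=cfg.n_genes, probes_per_gene=cfg.probes_per_gene,
            frac_enriched=cfg.frac_enriched, effect_delta=cfg.effect_delta,
            n_replicates=cfg.n_replicates, seed=int(rng.integers(2 ** 31))))
        probe_tables = {}
        for r, tab in enumerate(chip_sim.intensities, start=1):
            table, _ = chip_mod.call_probes(tab, span=cfg.span,
                                            q=cfg.null_quantile)
            probe_tables[f"rep{r}"] = table
        report["chip"] = {
            "n_probes": int(len(chip_sim.annotation)),
            "n_replicates": cfg.n_replicates,
            "positive_probes_per_replicate": {
                r: int(t["positive"].sum()) for r, t in probe_tables.items()},
        }

    with stage("gene_selection"):
        rule = genes_mod.RULE_PRESETS[cfg.rule]
        calls = genes_mod.call_genes(probe_tables, chip_sim.annotation, rule)
        called = {g.upper() for g in genes_mod.positive_genes(calls)}
        truth_bound = set(chip_sim.truth.genes.loc[
            chip_sim.truth.genes["bound"], "gene_id"].str.upper())
        recall = (len(called & truth_bound) / len(truth_bound)
                  if truth_bound else float("nan"))
        report["gene_calls"] = {
            "rule": cfg.rule, "n_called": len(called),
            "n_true_bound": len(truth_bound),
            "recall": recall,
            "false_positives": len(called - truth_bound),
        }
        if outdir is not None:
            calls.to_csv(outdir / "gene_calls.tsv", sep="\t")
            pd.Series(sorted(called)).to_csv(
                outdir / "positive_genes.txt", index=False, header=False)

    with stage("motif_analysis"):
        mat = motifs_mod.FrequencyMatrix.from_consensus(cfg.motif_consensus)
        n_pos = max(len(called), 50)
        pos_sim = sim.simulate_promoter_sequences(sim.SeqSimConfig(
            n_sequences=n_pos, planted_matrix=mat,
            plant_fraction=cfg.plant_fraction, seed=int(rng.integers(2 ** 31))))
        ctl_sim = sim.simulate_promoter_sequences(sim.SeqSimConfig(
            n_sequences=cfg.n_control_sequences, plant_fraction=0.0,
            seed=int(rng.integers(2 ** 31))))
        result = motifs_mod.discover_and_test(
            pos_sim.sequences, ctl_sim.sequences,
            seed=int(rng.integers(2 ** 31)), width=len(cfg.motif_consensus))
        scan_hits, scan_summary = motifs_mod.profit_scan(
            pos_sim.sequences, motifs_mod.taatta_matrix(), 75.0)
        report["motif"] = {
            "discovered_consensus": (result["motif"].consensus
                                     if result["motif"] else None),
            "enrichment_chi2": result["chi2"], "enrichment_p": result["p"],
            "n_sequences_with_hit": scan_summary.n_with_hit,
            "pct_sequences_with_hit": 100.0 * scan_summary.n_with_hit
                                      / scan_summary.n_sequences,
        }

    with stage("expression_analysis"):
        expr_sim = sim.simulate_expression(sim.ExprSimConfig(
            n_clusters=cfg.n_expr_clusters,
            genes_per_cluster=cfg.genes_per_cluster,
            n_null_genes=cfg.n_null_genes, seed=int(rng.integers(2 ** 31))))
        # expression probes interrogate the same gene universe as the array
        n_expr = len(expr_sim.tables[0])
        shared_ids = rng.choice(chip_sim.truth.genes["gene_id"].to_numpy(),
                                size=min(n_expr, cfg.n_genes), replace=False)
        id_map = dict(zip(expr_sim.tables[0]["gene_id"], shared_ids))
        tables = [t.assign(gene_id=t["gene_id"].map(id_map).fillna(t["gene_id"]))
                  for t in expr_sim.tables]
        ratio = expr_mod.normalize_expression(tables, span=cfg.span)
        ratio = expr_mod.filter_low_intensity(ratio)
        variable = expr_mod.select_variable_genes(ratio)
        clusters = expr_mod.cluster_genes(
            expr_mod.RatioMatrix(ratio.ratios.loc[variable],
                                 ratio.intensities.loc[variable]),
            n_clusters=cfg.n_expr_clusters)
        directions = expr_mod.direction_counts(
            expr_mod.RatioMatrix(ratio.ratios.loc[variable],
                                 ratio.intensities.loc[variable]),
            clusters.assignments)
        dereg_genes = {str(g).upper() for g in variable}
        mean_ratio = ratio.ratios.loc[variable].mean(axis=1)
        report["expression"] = {
            "n_genes_after_filter": int(len(ratio.genes)),
            "n_clustered": int(len(variable)),
            "n_clusters": cfg.n_expr_clusters,
            "n_up": int(directions.loc["overall", "n_up"]),
            "n_down": int(directions.loc["overall", "n_down"]),
        }
        if outdir is not None:
            clusters.assignments.to_csv(outdir / "cluster_assignments.tsv",
                                        sep="\t")

    with stage("integration"):
        v = venn(called, dereg_genes, "chip_bound", "deregulated")
        frac = deregulated_fraction(called, {"overexpression": dereg_genes}) \
            if called else None
        report["integration"] = {
            "venn": {"n_a": v.n_a, "n_b": v.n_b,
                     "n_intersection": v.n_intersection, "n_union": v.n_union},
            "deregulated_fraction": frac,
            "direction_convention": (
                "overexpression direction = sign of mean log2 ratio; "
                "knockout direction = sign of the DE fold change; "
                "'same regulation' compares these signed directions"),
        }
        if outdir is not None:
            pd.Series(sorted(dereg_genes)).to_csv(
                outdir / "deregulated_genes.txt", index=False, header=False)

    PipelineReport(**report)   # schema validation
    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
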