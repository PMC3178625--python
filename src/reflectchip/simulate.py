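"""Synthetic data generators with known ground truth.

Every pipeline stage is exercised on data from these generators, which
emulate the statistical structure the analysis assumes:

* two-channel promoter-array probes whose null log-intensity pairs are
  symmetric about the x = y diagonal, with an optional intensity-dependent
  spread (the familiar low-intensity funnel of two-colour arrays), and a
  small fraction of gene promoters carrying probes shifted toward the IP
  channel, identically in every replicate;
* promoter-sized sequences over a Markov background with a frequency-matrix
  site planted in a recorded subset;
* an 8-replicate two-colour expression design with co-regulated gene
  clusters sharing replicate-wise sign patterns;
* qPCR Ct tables exactly consistent with a known percent-input.

All generators are bit-reproducible under a fixed seed, and every emitted
entity carries a truth label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import BASES, FrequencyMatrix, MarkovBackground, encode

PROMOTER_WINDOW = (-5500, 2500)   # bp around the TSS covered by the array
PROBE_LENGTH = 60                  # 60-mer oligo probes


def _check_finite(cfg) -> None:
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, (int, float)) and not np.isfinite(v):
            raise ValueError(f"{f.name} must be finite, got {v!r}")


# ---------------------------------------------------------------------------
# ChIP-chip arrays


@dataclass
class ChipSimConfig:
    """Conditions for the promoter-array simulation.

    ``noise_scale`` is the base spread (log2 units) of the signed
    perpendicular distance of null probes to the diagonal; ``effect_delta``
    is the mean shift of that distance for enriched probes. With
    ``heteroscedastic`` the spread follows
    s(a) = noise_scale * (1 + hetero_c * exp(-a / hetero_tau)), the funnel
    shape typical of two-colour arrays.
    """

    n_genes: int = 1000
    probes_per_gene: int = 14
    frac_enriched: float = 0.05
    effect_delta: float = 2.0
    noise_scale: float = 0.35
    heteroscedastic: bool = False
    hetero_c: float = 50.0
    hetero_tau: float = 2.0
    noise_family: str = "gaussian"        # or "laplace"
    n_replicates: int = 3
    enriched_probes_per_gene: int = 3
    intensity_mean: float = 11.0
    intensity_sd: float = 1.2
    intensity_range: tuple[float, float] = (8.0, 14.0)
    replicate_jitter: float = 0.1
    dye_bias_coeffs: tuple[float, ...] | None = None   # polynomial in a, added to y - x
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self)
        if not 0 <= self.frac_enriched <= 1:
            raise ValueError("frac_enriched must be in [0, 1]")
        if self.effect_delta <= 0:
            raise ValueError("effect_delta must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_family not in ("gaussian", "laplace"):
            raise ValueError("noise_family must be 'gaussian' or 'laplace'")
        if self.probes_per_gene * 100 > PROMOTER_WINDOW[1] - PROMOTER_WINDOW[0]:
            raise ValueError("probes_per_gene does not fit the promoter window "
                             "at 100 bp minimum spacing")

    def scale_at(self, a: np.ndarray) -> np.ndarray:
        base = np.full_like(np.asarray(a, dtype=float), self.noise_scale)
        if self.heteroscedastic:
            base = self.noise_scale * (1 + self.hetero_c * np.exp(-np.asarray(a) / self.hetero_tau))
        return base


@dataclass
class TruthTable:
    """Ground-truth labels for one simulation (one row per entity)."""

    probes: pd.DataFrame | None = None       # probe_id, gene_id, enriched
    genes: pd.DataFrame | None = None        # gene_id, bound
    sequences: pd.DataFrame | None = None    # seq_id, planted, offset, strand
    expression: pd.DataFrame | None = None   # gene_id, cluster, regulated, low_intensity


@dataclass
class ChipSimResult:
    annotation: pd.DataFrame
    intensities: list[pd.DataFrame]
    truth: TruthTable
    config: ChipSimConfig


def simulate_chip_arrays(config: ChipSimConfig) -> ChipSimResult:
    """Simulate probe annotation plus per-replicate two-channel intensities.

    Null probes have signed perpendicular distance to the x = y diagonal
    drawn symmetric about 0; enriched probes (same identity in every
    replicate) are shifted by +effect_delta. Every probe midpoint lies in
    the promoter window around its gene's TSS.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo, hi = PROMOTER_WINDOW

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    tss = 100_000 + 20_000 * np.arange(cfg.n_genes)

    n_bound = int(round(cfg.frac_enriched * cfg.n_genes))
    bound_idx = set(rng.choice(cfg.n_genes, size=n_bound, replace=False).tolist())

    rows, enriched_flags = [], []
    for gi, gene in enumerate(gene_ids):
        offsets = []
        off = lo + int(rng.integers(0, 100))
        while len(offsets) < cfg.probes_per_gene:
            offsets.append(off)
            off += int(rng.integers(100, 301))
            if off >= hi:   # wrap to an unused part of the window
                off = lo + int(rng.integers(0, 50))
        offsets = sorted(set(offsets))[: cfg.probes_per_gene]
        while len(offsets) < cfg.probes_per_gene:   # extremely unlikely fill
            offsets.append(offsets[-1] + 100)
        k = min(cfg.enriched_probes_per_gene, cfg.probes_per_gene)
        start = int(rng.integers(0, cfg.probes_per_gene - k + 1))
        enr_local = set(range(start, start + k)) if gi in bound_idx else set()
        for j, offset in enumerate(offsets):
            if strands[gi] == "+":
                mid = tss[gi] + offset
            else:
                mid = tss[gi] - offset
            rows.append((f"{gene}_p{j:02d}", "chr1", int(mid - PROBE_LENGTH // 2),
                         int(mid + PROBE_LENGTH // 2), strands[gi], gene, offset))
            enriched_flags.append(j in enr_local)
    annotation = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end",
                                             "strand", "gene_id", "tss_offset"])
    enriched = np.asarray(enriched_flags)

    n_probes = len(annotation)
    a0 = np.clip(rng.normal(cfg.intensity_mean, cfg.intensity_sd, n_probes),
                 *cfg.intensity_range)
    intensities = []
    for _ in range(cfg.n_replicates):
        a = a0 + rng.normal(0, cfg.replicate_jitter, n_probes)
        s = cfg.scale_at(a)
        if cfg.noise_family == "gaussian":
            d = rng.normal(0, 1, n_probes) * s
        else:
            d = rng.laplace(0, 1 / np.sqrt(2), n_probes) * s
        d = d + cfg.effect_delta * enriched
        m = d * np.sqrt(2)
        if cfg.dye_bias_coeffs is not None:
            m = m + np.polyval(cfg.dye_bias_coeffs, a)
        x, y = a - m / 2, a + m / 2
        intensities.append(pd.DataFrame({
            "probe_id": annotation["probe_id"],
            "ch_input": np.power(2.0, x),
            "ch_ip": np.power(2.0, y),
        }))

    truth = TruthTable(
        probes=pd.DataFrame({"probe_id": annotation["probe_id"],
                             "gene_id": annotation["gene_id"],
                             "enriched": enriched}),
        genes=pd.DataFrame({"gene_id": gene_ids,
                            "bound": [i in bound_idx for i in range(cfg.n_genes)]}),
    )
    return ChipSimResult(annotation, intensities, truth, cfg)


def write_chip_outputs(result: ChipSimResult, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"annotation": outdir / "annotation.tsv"}
    result.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    for r, df in enumerate(result.intensities, start=1):
        p = outdir / f"intensities_rep{r}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths[f"rep{r}"] = p
    paths["truth_probes"] = outdir / "truth_probes.tsv"
    result.truth.probes.to_csv(paths["truth_probes"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    result.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return paths


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_intensities(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# promoter sequences


@dataclass
class SeqSimConfig:
    n_sequences: int = 200
    length: int = 450
    background_order: int = 0
    gc_content: float = 0.5
    planted_matrix: FrequencyMatrix | None = None
    plant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.plant_fraction <= 1:
            raise ValueError("plant_fraction must be in [0, 1]")
        if self.plant_fraction > 0 and self.planted_matrix is None:
            raise ValueError("plant_fraction > 0 requires a planted_matrix")
        if (self.planted_matrix is not None
                and self.length < self.planted_matrix.width):
            raise ValueError("length must be >= planted matrix width")


@dataclass
class SeqSimResult:
    sequences: dict[str, str]
    truth: TruthTable
    config: SeqSimConfig


def simulate_promoter_sequences(config: SeqSimConfig) -> SeqSimResult:
    """Background sequences with a matrix-sampled site planted in a
    recorded fraction, at a recorded offset and strand."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bg = MarkovBackground.from_gc(cfg.background_order, cfg.gc_content)
    seqs = bg.sample(cfg.n_sequences, cfg.length, rng)
    ids = [f"s{i:05d}" for i in range(cfg.n_sequences)]

    n_plant = int(round(cfg.plant_fraction * cfg.n_sequences))
    planted_idx = rng.choice(cfg.n_sequences, size=n_plant, replace=False)
    planted = np.zeros(cfg.n_sequences, dtype=bool)
    offsets = np.full(cfg.n_sequences, -1)
    strands = np.full(cfg.n_sequences, ".", dtype=object)
    if n_plant:
        mat = cfg.planted_matrix
        w = mat.width
        for i in planted_idx:
            site = "".join(BASES[int(rng.choice(4, p=mat.probs[:, j]))]
                           for j in range(w))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                from .motifs import revcomp
                site = revcomp(site)
            off = int(rng.integers(0, cfg.length - w + 1))
            seqs[i] = seqs[i][:off] + site + seqs[i][off + w:]
            planted[i], offsets[i], strands[i] = True, off, strand
    truth = TruthTable(sequences=pd.DataFrame(
        {"seq_id": ids, "planted": planted, "offset": offsets, "strand": strands}))
    return SeqSimResult(dict(zip(ids, seqs)), truth, cfg)


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# expression arrays


@dataclass
class ExprSimConfig:
    """An 8-replicate two-colour design with co-regulated clusters.

    Cluster k's genes share a replicate-wise sign pattern of amplitude
    ``pattern_amplitude`` (log2) plus Gaussian noise; null genes have
    zero-mean ratios. Patterns are drawn with pairwise uncentered
    correlation <= 0.5 and a non-zero mean, so clusters are separable and
    carry a direction.
    """

    n_clusters: int = 7
    genes_per_cluster: int = 50
    n_null_genes: int = 6000
    n_replicates: int = 8
    pattern_amplitude: float = 1.0
    noise_sd: float = 0.2
    low_intensity_fraction: float = 0.05
    intensity_mean: float = 10.0
    intensity_sd: float = 1.5
    low_intensity_mean: float = 5.5
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self)
        for name in ("n_clusters", "genes_per_cluster", "n_null_genes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ExprSimResult:
    tables: list[pd.DataFrame]      # per replicate: gene_id, ch_cy3, ch_cy5
    truth: TruthTable
    patterns: np.ndarray            # (n_clusters, n_replicates) sign patterns
    config: ExprSimConfig


def _draw_sign_patterns(n: int, r: int, rng: np.random.Generator,
                        max_corr: float = 0.5) -> np.ndarray:
    """Distinct +-1 patterns with non-zero sum and pairwise uncentered
    correlation bounded by max_corr."""
    patterns: list[np.ndarray] = []
    attempts = 0
    while len(patterns) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not draw enough separated sign patterns; "
                               "reduce n_clusters or increase n_replicates")
        cand = rng.choice([-1.0, 1.0], size=r)
        if abs(cand.sum()) in (0, r):
            continue
        if all(abs(cand @ p) / r <= max_corr for p in patterns):
            patterns.append(cand)
    return np.vstack(patterns)


def simulate_expression(config: ExprSimConfig) -> ExprSimResult:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_pat = cfg.n_clusters * cfg.genes_per_cluster
    n_genes = n_pat + cfg.n_null_genes
    gene_ids = [f"e{i:05d}" for i in range(n_genes)]

    patterns = _draw_sign_patterns(cfg.n_clusters, cfg.n_replicates, rng)
    cluster = np.zeros(n_genes, dtype=int)
    cluster[:n_pat] = np.repeat(np.arange(1, cfg.n_clusters + 1),
                                cfg.genes_per_cluster)
    order = rng.permutation(n_genes)
    cluster = cluster[order]

    ratios = rng.normal(0, cfg.noise_sd, (n_genes, cfg.n_replicates))
    for k in range(1, cfg.n_clusters + 1):
        ratios[cluster == k] += cfg.pattern_amplitude * patterns[k - 1]

    low = rng.random(n_genes) < cfg.low_intensity_fraction
    base = np.where(low,
                    rng.normal(cfg.low_intensity_mean, 0.5, n_genes),
                    rng.normal(cfg.intensity_mean, cfg.intensity_sd, n_genes))

    tables = []
    for r in range(cfg.n_replicates):
        log_cy3 = base + rng.normal(0, 0.1, n_genes)
        log_cy5 = log_cy3 + ratios[:, r]
        tables.append(pd.DataFrame({"gene_id": gene_ids,
                                    "ch_cy3": np.power(2.0, log_cy3),
                                    "ch_cy5": np.power(2.0, log_cy5)}))
    truth = TruthTable(expression=pd.DataFrame({
        "gene_id": gene_ids, "cluster": cluster,
        "regulated": cluster > 0, "low_intensity": low}))
    return ExprSimResult(tables, truth, patterns, cfg)


def simulate_two_group(n_genes: int = 1000, n_per_group: int = 6,
                       frac_de: float = 0.10, effect_sds: float = 2.0,
                       noise_sd: float = 0.3, seed: int = 0,
                       gene_ids: list[str] | None = None
                       ) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Two-group log2 expression matrix for differential-expression
    reanalysis: frac_de genes shifted by effect_sds * noise_sd (random
    sign) in group B. Returns (matrix, group labels, truth)."""
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"e{i:05d}" for i in range(n_genes)]
    n_genes = len(gene_ids)
    de = rng.random(n_genes) < frac_de
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    baseline = rng.normal(8, 1, n_genes)
    data = {}
    for j in range(n_per_group):
        data[f"A{j + 1}"] = baseline + rng.normal(0, noise_sd, n_genes)
    shift = de * sign * effect_sds * noise_sd
    for j in range(n_per_group):
        data[f"B{j + 1}"] = baseline + shift + rng.normal(0, noise_sd, n_genes)
    mat = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    truth = pd.DataFrame({"gene_id": gene_ids, "de": de,
                          "direction": np.where(de, sign, 0.0)})
    return mat, labels, truth


def write_expression_outputs(result: ExprSimResult, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for r, df in enumerate(result.tables, start=1):
        p = outdir / f"expression_rep{r}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths[f"rep{r}"] = p
    paths["truth"] = outdir / "truth_expression.tsv"
    result.truth.expression.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(n: int, seed: int = 0, dilution_factor: float = 2.0) -> pd.DataFrame:
    """Ct table exactly consistent with a known true percent-input via
    %input = 100 * 2^-(Ct(IP) - (Ct(input) - dilution_factor))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    true_pct = np.power(10.0, rng.uniform(-1, np.log10(20), n))
    ct_input = rng.uniform(20, 30, n)
    delta_ct = -np.log2(true_pct / 100.0)
    ct_ip = ct_input - dilution_factor + delta_ct
    return pd.DataFrame({
        "sample_id": [f"q{i:03d}" for i in range(n)],
        "ct_ip": ct_ip,
        "ct_input": ct_input,
        "dilution_factor": dilution_factor,
        "true_percent_input": true_pct,
    })
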