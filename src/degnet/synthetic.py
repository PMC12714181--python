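"""Synthetic data with the statistical structure the analysis chain assumes.

The default configuration mirrors the study design the pipeline targets:
three tumor/healthy cohorts (43+43, 20+20, 21+21 samples) of
negative-binomial counts with a per-cohort batch effect, planted
direction-consistent DE genes, one hub transcription factor with a large
regulon, a small two-group knockdown experiment in which a subset of the
tumor-DE genes reverses sign, uniform-background promoters with planted
motif occurrences, and exponential survival times under proportional
hazards tied to the hub gene's expression.

Every generator is a pure function of (config, seed): per-stage random
substreams are derived from the one global seed, so identical inputs give
identical outputs and stages stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection, TFPrior, make_metadata
from .motif import PFM, encode, reverse_complement
from .survival import SurvivalRecord

_STAGE_KEYS = {"cohorts": 0, "knockdown": 1, "promoters": 2, "survival": 3, "prior": 4, "annotation": 5}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],)))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with study-scale defaults.

    Counts follow NB(mean, variance = mean + dispersion * mean^2) with
    log-normal baseline means (natural-log mean 5, sd 2), uniform library
    factors and an optional per-cohort multiplicative gene-wise batch
    jitter (log2-normal, sd ``batch_sd``).
    """

    n_genes: int = 2000
    cohorts: tuple = (("TCGA", 43, 43), ("GSE_A", 20, 20), ("GSE_B", 21, 21))
    de_fraction: float = 0.05
    lfc_magnitude: float = 2.0
    dispersion: float = 0.1
    library_size_range: tuple = (0.5, 2.0)
    batch_sd: float = 0.2
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 2.0
    n_reversal: int = 40
    regulon_size: int = 40
    kd_n_control: int = 3
    kd_n_perturbed: int = 3
    kd_tf_lfc: float = -3.0
    promoter_length: int = 2000
    planted_site_offsets: tuple = (-1800, -1250, -400)
    survival_hr: float = 2.0
    baseline_hazard: float = 0.05
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not self.cohorts:
            raise ConfigError("at least one cohort required")
        for name, n_h, n_t in self.cohorts:
            if n_h < 2 or n_t < 2:
                raise ConfigError(f"cohort {name!r} needs >= 2 samples per group")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if 0 < self.de_fraction * self.n_genes < 1:
            raise ConfigError("de_fraction * n_genes rounds to zero planted genes")
        if self.lfc_magnitude <= 0 or self.dispersion <= 0:
            raise ConfigError("lfc_magnitude and dispersion must be positive")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ConfigError("library_size_range must be a positive interval")
        if self.n_reversal > self.n_de:
            raise ConfigError(
                f"n_reversal={self.n_reversal} exceeds the {self.n_de} planted DE genes"
            )
        if self.regulon_size > 0 and self.regulon_size > max(self.n_de - 1, 0):
            raise ConfigError(
                f"regulon_size={self.regulon_size} exceeds available DE targets ({max(self.n_de - 1, 0)})"
            )
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if self.promoter_length <= 0:
            raise ConfigError("promoter_length must be positive")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass
class SyntheticTruth:
    """Ledger of everything the generators planted.

    Sufficient to score every downstream recovery test: DE genes with true
    log2 fold changes, the hub TF and its regulon, the reversal genes with
    their planted knockdown effects, motif offsets per gene, and the
    survival gene with its hazard ratio. ``gene_ids`` and ``baseline_mean``
    record the shared gene universe and baselines the knockdown generator
    reuses.
    """

    gene_ids: list
    de_genes_up: dict  # gene -> true log2FC (> 0)
    de_genes_down: dict  # gene -> true log2FC (< 0)
    hub_tf: str | None
    regulon: frozenset  # (hub, target) edges
    reversal_genes: dict  # gene -> planted knockdown log2FC (sign opposite to tumor)
    motif_offsets_by_gene: dict  # gene -> list of (tss_offset, strand)
    survival_gene: str | None
    survival_hr: float
    baseline_mean: np.ndarray  # per-gene NB baseline mean

    @property
    def de_genes(self) -> set:
        return set(self.de_genes_up) | set(self.de_genes_down)


def generate_cohorts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw the multi-cohort tumor/healthy count matrix and its truth ledger.

    Counts for gene g in sample j are NB with mean
    s_j * mu_g * jitter_cg * 2^(x_j * beta_g), where x_j indicates tumor and
    beta_g is the planted log2FC (0 for non-DE genes, +/- lfc_magnitude for
    planted genes, direction-consistent across cohorts).
    """
    rng = _stage_rng(config.seed, "cohorts")
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    mu = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)

    n_de = config.n_de
    beta = np.zeros(config.n_genes)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    n_up = (n_de + 1) // 2
    up_idx, down_idx = de_idx[:n_up], de_idx[n_up:]
    beta[up_idx] = config.lfc_magnitude
    beta[down_idx] = -config.lfc_magnitude
    de_up = {genes[i]: config.lfc_magnitude for i in up_idx}
    de_down = {genes[i]: -config.lfc_magnitude for i in down_idx}

    hub_tf = None
    regulon: frozenset = frozenset()
    if n_de and config.regulon_size > 0:
        hub_tf = genes[up_idx[0]] if len(up_idx) else genes[down_idx[0]]
        candidates = [genes[i] for i in de_idx if genes[i] != hub_tf]
        targets = rng.choice(candidates, size=config.regulon_size, replace=False)
        regulon = frozenset((hub_tf, str(t)) for t in targets)

    reversal: dict = {}
    if n_de and config.n_reversal > 0:
        pool = [genes[i] for i in de_idx if genes[i] != hub_tf]
        chosen = rng.choice(pool, size=min(config.n_reversal, len(pool)), replace=False)
        true_lfc = {**de_up, **de_down}
        reversal = {str(g): -np.sign(true_lfc[str(g)]) * config.lfc_magnitude for g in chosen}

    motif_offsets: dict = {}
    if config.planted_site_offsets:
        motif_gene = None
        if regulon:
            motif_gene = sorted(t for _, t in regulon)[0]
        elif n_de:
            motif_gene = genes[de_idx[0]]
        if motif_gene is not None:
            motif_offsets = {motif_gene: [(int(off), "+") for off in config.planted_site_offsets]}

    blocks = []
    meta_rows = []
    lo, hi = config.library_size_range
    size = 1.0 / config.dispersion
    for name, n_h, n_t in config.cohorts:
        jitter = np.exp2(rng.normal(0.0, config.batch_sd, config.n_genes)) if config.batch_sd > 0 else 1.0
        s = rng.uniform(lo, hi, n_h + n_t)
        x = np.concatenate([np.zeros(n_h), np.ones(n_t)])
        mean = (mu * (jitter if np.ndim(jitter) else 1.0))[:, None] * s[None, :] * np.exp2(
            beta[:, None] * x[None, :]
        )
        p_nb = size / (size + mean)
        counts = rng.negative_binomial(size, p_nb)
        ids = [f"{name}_H{i + 1:02d}" for i in range(n_h)] + [f"{name}_T{i + 1:02d}" for i in range(n_t)]
        blocks.append(pd.DataFrame(counts, index=genes, columns=ids))
        meta_rows += [(sid, name, "healthy" if xi == 0 else "tumor") for sid, xi in zip(ids, x)]

    matrix = ExpressionMatrix(pd.concat(blocks, axis=1), "counts")
    metadata = make_metadata(meta_rows)
    truth = SyntheticTruth(
        gene_ids=genes,
        de_genes_up=de_up,
        de_genes_down=de_down,
        hub_tf=hub_tf,
        regulon=regulon,
        reversal_genes=reversal,
        motif_offsets_by_gene=motif_offsets,
        survival_gene=hub_tf,
        survival_hr=config.survival_hr,
        baseline_mean=mu,
    )
    return matrix, metadata, truth


def generate_knockdown(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the two-group knockdown experiment on a tumor-like baseline.

    Reversal genes carry a planted perturbation log2FC opposite in sign to
    their tumor effect; the hub TF itself is planted strongly down
    (``kd_tf_lfc``) in the perturbed group; every other gene is null.
    """
    if config.n_reversal > len(truth.de_genes):
        raise ConfigError("n_reversal exceeds the planted DE genes in truth")
    rng = _stage_rng(config.seed, "knockdown")
    genes = truth.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    tumor_lfc = np.zeros(len(genes))
    for g, b in {**truth.de_genes_up, **truth.de_genes_down}.items():
        tumor_lfc[gene_index[g]] = b
    kd_lfc = np.zeros(len(genes))
    for g, b in truth.reversal_genes.items():
        kd_lfc[gene_index[g]] = b
    if truth.hub_tf is not None:
        kd_lfc[gene_index[truth.hub_tf]] = config.kd_tf_lfc

    n_c, n_p = config.kd_n_control, config.kd_n_perturbed
    lo, hi = config.library_size_range
    s = rng.uniform(lo, hi, n_c + n_p)
    x = np.concatenate([np.zeros(n_c), np.ones(n_p)])
    baseline = truth.baseline_mean * np.exp2(tumor_lfc)  # tumor-like cell line
    mean = baseline[:, None] * s[None, :] * np.exp2(kd_lfc[:, None] * x[None, :])
    size = 1.0 / config.dispersion
    counts = rng.negative_binomial(size, size / (size + mean))
    ids = [f"KD_C{i + 1:02d}" for i in range(n_c)] + [f"KD_P{i + 1:02d}" for i in range(n_p)]
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=ids), "counts")
    metadata = make_metadata(
        [(sid, "KD", "control" if xi == 0 else "perturbed") for sid, xi in zip(ids, x)]
    )
    return matrix, metadata


def generate_promoters(
    config: SimulationConfig,
    truth: SyntheticTruth,
    pfm: PFM,
    genes: Sequence[str] | None = None,
) -> dict[str, str]:
    """Uniform-background promoters with the PFM consensus planted at truth offsets.

    Minus-strand plantings write the reverse complement of the consensus
    into the forward sequence. Offsets are TSS-relative starts of the
    half-open site interval; overlapping plantings are a config error.
    """
    rng = _stage_rng(config.seed, "promoters")
    L = config.promoter_length
    w = pfm.width
    if L < w:
        raise ConfigError("promoter_length shorter than motif width")
    consensus = pfm.consensus()
    if genes is None:
        genes = truth.gene_ids
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    for gene in genes:
        seq = bases[rng.integers(0, 4, L)]
        plantings = truth.motif_offsets_by_gene.get(gene, [])
        intervals = sorted((off, off + w) for off, _ in plantings)
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise ConfigError(f"overlapping planted offsets for {gene}: {a0} and {b0}")
        for off, strand in plantings:
            if off < -L or off > -w:
                raise ConfigError(f"planted offset {off} outside [-{L}, -{w}]")
            word = consensus if strand == "+" else reverse_complement(consensus)
            seq[off + L : off + L + w] = list(word)
        promoters[gene] = "".join(seq)
    return promoters


def generate_survival(
    config: SimulationConfig,
    truth: SyntheticTruth,
    expression: Mapping[str, float] | pd.Series,
) -> list[SurvivalRecord]:
    """Exponential survival under proportional hazards tied to one gene.

    The hazard is h0 * HR^z with z = 1 for samples above the median of the
    designated gene's expression. With probability ``censor_rate`` a record
    is censored at a Uniform(0, T) time, so the expected censored fraction
    equals the configured rate.
    """
    series = pd.Series(dict(expression)) if not isinstance(expression, pd.Series) else expression
    values = series.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ConfigError("expression values must be non-negative")
    rng = _stage_rng(config.seed, "survival")
    median = float(np.median(values))
    z = values > median
    hazard = config.baseline_hazard * config.survival_hr**z.astype(float)
    times = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=len(series)) < config.censor_rate
    obs_times = np.where(censored, times * rng.uniform(size=len(series)), times)
    obs_times = np.maximum(obs_times, 1e-12)
    return [
        SurvivalRecord(
            sample_id=str(sid),
            time=float(t),
            event=0 if c else 1,
            stratum="high" if zi else "low",
        )
        for sid, t, c, zi in zip(series.index, obs_times, censored, z)
    ]


def generate_tf_prior(
    config: SimulationConfig,
    truth: SyntheticTruth,
    n_decoys: int = 10,
    max_decoy_size: int = 10,
) -> TFPrior:
    """Hub regulon plus decoy TFs with small regulons, as the network prior.

    Decoy TFs and their targets are drawn from the planted DE genes so they
    survive the DEG filter but stay far below the hub's out-degree.
    """
    rng = _stage_rng(config.seed, "prior")
    edges = set(truth.regulon)
    de_genes = sorted(truth.de_genes - {truth.hub_tf})
    if de_genes and n_decoys > 0:
        decoys = rng.choice(de_genes, size=min(n_decoys, len(de_genes)), replace=False)
        for tf in decoys:
            tf = str(tf)
            pool = [g for g in de_genes if g != tf]
            k = int(rng.integers(1, max_decoy_size + 1))
            for t in rng.choice(pool, size=min(k, len(pool)), replace=False):
                edges.add((tf, str(t)))
    return TFPrior(edges=frozenset(edges))


def generate_annotation(
    config: SimulationConfig,
    truth: SyntheticTruth,
    n_terms: int = 20,
    term_size: int = 15,
) -> GeneSetCollection:
    """Random gene sets plus one term that is exactly the planted reversal genes."""
    rng = _stage_rng(config.seed, "annotation")
    sets = []
    genes = np.array(truth.gene_ids)
    for i in range(n_terms):
        members = rng.choice(genes, size=min(term_size, len(genes)), replace=False)
        sets.append(GeneSet(f"T{i + 1:04d}", f"random term {i + 1}", frozenset(members)))
    if truth.reversal_genes:
        sets.append(
            GeneSet("REVERSAL", "planted knockdown-reversal genes", frozenset(truth.reversal_genes))
        )
    return GeneSetCollection(sets)


def split_by_cohort(
    matrix: ExpressionMatrix, metadata: pd.DataFrame
) -> dict[str, ExpressionMatrix]:
    """Split a combined matrix into per-cohort matrices (cohort order preserved)."""
    out = {}
    for cohort in metadata["cohort"].drop_duplicates():
        ids = metadata.loc[metadata["cohort"] == cohort, "sample_id"]
        out[str(cohort)] = matrix.subset_samples(list(ids))
    return out
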