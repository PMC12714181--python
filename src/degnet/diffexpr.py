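"""Normalization, two-group differential expression, FDR control and PCA.

Two test modes cover the two kinds of deposited matrices:

``nb_wald``
    Median-of-ratios size factors, per-gene negative-binomial model with
    moderated method-of-moments dispersion on normalized counts, Wald
    statistic log2FC / SE against the normal reference. Intended for
    integer count matrices.
``welch_log``
    Welch t-test on log2(x + 1); log2FC is the difference of group means of
    log2(x + 1). Intended for continuous matrices (e.g. RPKM); counts are
    size-factor normalized before the log transform.

Fold changes are reported for the second contrast group over the first
(tumor over healthy, perturbed over control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import ExpressionMatrix

LN2_SQ = np.log(2.0) ** 2
_VAR_FLOOR = 1e-8
_DISP_FLOOR = 1e-8
_DISP_PRIOR_DF = 20  # fixed prior weight (residual df) for dispersion moderation
_PSEUDOCOUNT = 0.5

TEST_MODES = ("nb_wald", "welch_log")


def compute_size_factors(
    matrix: ExpressionMatrix, fallback_pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with all counts positive; each sample's factor
    is the median over reference genes of count / geometric-mean(count across
    samples). With ``fallback_pseudo_reference`` the geometric mean is taken
    over positive counts only and zero-count cells are excluded from the
    median, for sparse matrices without any all-positive gene.
    """
    if matrix.value_kind != "counts":
        raise ValidationError("size factors are defined for count matrices")
    K = matrix.values
    positive = K > 0
    all_pos = positive.all(axis=1)
    if not all_pos.any():
        if not fallback_pseudo_reference:
            raise ValidationError(
                "no gene has positive counts in every sample; rerun with "
                "fallback_pseudo_reference=True to use a positive-count pseudo-reference"
            )
        with np.errstate(divide="ignore"):
            logK = np.where(positive, np.log(K, where=positive, out=np.full_like(K, -np.inf)), -np.inf)
        n_pos = positive.sum(axis=1)
        usable = n_pos > 0
        lgm = np.full(K.shape[0], -np.inf)
        lgm[usable] = np.where(positive[usable], logK[usable], 0.0).sum(axis=1) / n_pos[usable]
        factors = np.empty(K.shape[1])
        for j in range(K.shape[1]):
            mask = positive[:, j] & usable
            if not mask.any():
                raise ValidationError(f"sample {matrix.sample_ids[j]!r} has no positive counts")
            factors[j] = np.median(K[mask, j] / np.exp(lgm[mask]))
    else:
        geo = np.exp(np.log(K[all_pos]).mean(axis=1))
        factors = np.median(K[all_pos] / geo[:, None], axis=0)
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def _resolve_groups(
    matrix: ExpressionMatrix, metadata: pd.DataFrame, contrast: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    group_a, group_b = contrast
    meta = metadata.set_index("sample_id").loc[matrix.sample_ids]
    labels = meta["group"].to_numpy()
    known = set(labels)
    for g in contrast:
        if g not in known:
            raise ValidationError(f"unknown group label {g!r}; metadata has {sorted(known)}")
    idx_a = np.flatnonzero(labels == group_a)
    idx_b = np.flatnonzero(labels == group_b)
    for name, idx in ((group_a, idx_a), (group_b, idx_b)):
        if idx.size < 2:
            raise ValidationError(f"group {name!r} has {idx.size} sample(s); need at least 2")
    return idx_a, idx_b


def _welch_log(values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    L = np.log2(values + 1.0)
    a, b = L[:, idx_a], L[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    log2fc = mean_b - mean_a
    degenerate = (var_a == 0) & (var_b == 0) & (mean_a == mean_b)
    va = np.maximum(var_a, _VAR_FLOOR) / na
    vb = np.maximum(var_b, _VAR_FLOOR) / nb
    se = np.sqrt(va + vb)
    t = log2fc / se
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate] = 1.0
    log2fc = np.where(degenerate, 0.0, log2fc)
    base_mean = L.mean(axis=1)
    return base_mean, log2fc, np.minimum(p, 1.0)


def _nb_wald_from_normalized(q: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    """NB Wald test on size-factor-normalized counts.

    Dispersion is per-gene method-of-moments, pooled across the two groups
    after removing group means (alpha = (s^2 - xbar) / xbar^2), then
    moderated toward the across-genes median with a fixed prior weight of
    ``_DISP_PRIOR_DF`` residual degrees of freedom. Moderation stabilizes
    the plug-in SE enough that the Wald statistic can be referred to the
    normal distribution at small group sizes (see methods note).
    """
    a, b = q[:, idx_a], q[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    resid_ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = resid_ss / (na + nb - 2)
    xbar = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(xbar > 0, (s2 - xbar) / xbar**2, 0.0)
    alpha = np.maximum(alpha, _DISP_FLOOR)
    d_g = na + nb - 2
    prior = float(np.median(alpha))
    alpha = (d_g * alpha + _DISP_PRIOR_DF * prior) / (d_g + _DISP_PRIOR_DF)
    log2fc = np.log2((mean_b + _PSEUDOCOUNT) / (mean_a + _PSEUDOCOUNT))
    var_mean_a = (mean_a + alpha * mean_a**2) / na
    var_mean_b = (mean_b + alpha * mean_b**2) / nb
    se2 = (
        var_mean_a / (mean_a + _PSEUDOCOUNT) ** 2 + var_mean_b / (mean_b + _PSEUDOCOUNT) ** 2
    ) / LN2_SQ
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    degenerate = (se == 0) | ((s2 == 0) & (mean_a == mean_b))
    p = np.where(degenerate, 1.0, p)
    log2fc = np.where((s2 == 0) & (mean_a == mean_b), 0.0, log2fc)
    base_mean = xbar
    return base_mean, log2fc, np.minimum(p, 1.0)


def de_test(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    mode: str | None = None,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group differential expression test.

    ``contrast`` is (reference, treatment); log2FC is treatment over
    reference. Returns a table with columns gene, base_mean, log2fc, p,
    padj and test_mode, one row per gene in matrix order.
    """
    if mode is None:
        mode = "nb_wald" if matrix.value_kind == "counts" else "welch_log"
    if mode not in TEST_MODES:
        raise ValidationError(f"unknown test mode {mode!r}")
    if mode == "nb_wald" and matrix.value_kind != "counts":
        raise ValidationError("nb_wald requires a count matrix")
    idx_a, idx_b = _resolve_groups(matrix, metadata, contrast)
    values = matrix.values
    if matrix.value_kind == "counts":
        if size_factors is None:
            size_factors = compute_size_factors(matrix)
        values = values / size_factors.loc[matrix.sample_ids].to_numpy()[None, :]
    if mode == "welch_log":
        base_mean, log2fc, p = _welch_log(values, idx_a, idx_b)
    else:
        base_mean, log2fc, p = _nb_wald_from_normalized(values, idx_a, idx_b)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "test_mode": mode,
        }
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEGSets:
    """Up/down DEG calls at fixed effect-size and FDR thresholds."""

    up: frozenset
    down: frozenset
    lfc_min: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValidationError("a gene cannot be both up and down")


def call_degs(results: pd.DataFrame, lfc_min: float = 0.5, alpha: float = 0.05) -> DEGSets:
    """Call DEGs with strict inequalities: |log2FC| > lfc_min and padj < alpha."""
    sig = results["padj"].to_numpy() < alpha
    lfc = results["log2fc"].to_numpy()
    genes = results["gene"].to_numpy()
    up = frozenset(genes[sig & (lfc > lfc_min)])
    down = frozenset(genes[sig & (lfc < -lfc_min)])
    return DEGSets(up=up, down=down, lfc_min=lfc_min, alpha=alpha)


def pca(
    matrix: ExpressionMatrix,
    n_components: int = 2,
    top_n_variable_genes: int = 2000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(x+1) expression of the most variable genes.

    Genes are centered (no unit-variance scaling); scores come from the SVD
    of the centered sample x gene matrix. Returns (scores, variance
    fractions); fractions are relative to the total variance of the selected
    genes and are non-increasing.
    """
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    L = np.log2(matrix.values + 1.0)
    variances = L.var(axis=1)
    k_genes = min(top_n_variable_genes, L.shape[0])
    order = np.argsort(-variances, kind="mergesort")[:k_genes]
    if n_components > min(k_genes, matrix.n_samples):
        raise ValidationError(
            f"n_components={n_components} exceeds min(genes used={k_genes}, samples={matrix.n_samples})"
        )
    X = L[np.sort(order)]  # keep gene order stable
    X = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(X.T, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    total = (S**2).sum()
    fractions = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=matrix.sample_ids, columns=cols), fractions
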