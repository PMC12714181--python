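"""Cross-cohort meta-intersection of differential expression calls.

Each cohort is tested separately, then all samples are pooled for a "meta"
contrast over the shared gene universe. The common DEG sets are the
direction-consistent intersection: a gene is commonly up if it is up in the
meta contrast and up in at least ``min_cohorts`` per-cohort contrasts
(default: all of them), mirroring "consistently dysregulated across all
datasets".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DEGSets, _nb_wald_from_normalized, bh_adjust, call_degs, compute_size_factors, de_test
from .errors import ValidationError
from .io_formats import ExpressionMatrix


@dataclass
class MetaDEGReport:
    """Per-cohort and pooled DEG calls plus their direction-consistent intersection."""

    per_study: dict  # cohort -> DEGSets
    meta: DEGSets
    common_up: frozenset
    common_down: frozenset
    venn: dict  # quadrant counts for up and down
    per_study_results: dict  # cohort -> DE result table
    meta_results: pd.DataFrame


def _cohort_centered_normalized(
    matrices: dict[str, ExpressionMatrix], shared: list[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Pooled size-factor-normalized counts with cohort means ratioed out.

    Each gene's values within a cohort are rescaled by grand-mean /
    cohort-mean, removing the multiplicative cohort effect while leaving
    within-cohort group contrasts intact (exact for balanced cohorts).
    """
    blocks = []
    sample_ids: list[str] = []
    pooled = pd.concat([m.data.loc[shared] for m in matrices.values()], axis=1)
    pooled_matrix = ExpressionMatrix(pooled, "counts")
    factors = compute_size_factors(pooled_matrix)
    q_all = pooled.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    col_cohort = np.concatenate(
        [np.full(m.n_samples, i) for i, m in enumerate(matrices.values())]
    )
    grand = q_all.mean(axis=1)
    q_centered = q_all.copy()
    for i in range(len(matrices)):
        cols = col_cohort == i
        cmean = q_all[:, cols].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(cmean > 0, grand / cmean, 1.0)
        q_centered[:, cols] = q_all[:, cols] * factor[:, None]
    return q_centered, list(pooled.columns), grand


def run_meta_contrast(
    matrices: dict[str, ExpressionMatrix],
    metadata: pd.DataFrame,
    contrast: tuple[str, str] = ("healthy", "tumor"),
    mode: str | None = None,
    lfc_min: float = 0.5,
    alpha: float = 0.05,
    min_cohorts: int | None = None,
) -> MetaDEGReport:
    """Per-cohort + pooled DE and the direction-consistent common DEG sets.

    Genes missing from any cohort are dropped before all contrasts. In
    nb_wald mode the pooled contrast removes a multiplicative cohort effect
    by per-cohort mean centering of normalized counts; welch_log pools raw
    values (documented limitation).
    """
    if not matrices:
        raise ValidationError("no cohort matrices supplied")
    gene_sets = [m.gene_ids for m in matrices.values()]
    shared = [g for g in gene_sets[0] if all(g in set(gs) for gs in gene_sets[1:])]
    shared_set = set(gene_sets[0])
    for gs in gene_sets[1:]:
        shared_set &= set(gs)
    shared = [g for g in gene_sets[0] if g in shared_set]
    if not shared:
        raise ValidationError("cohorts share no genes")
    if min_cohorts is None:
        min_cohorts = len(matrices)
    if not 1 <= min_cohorts <= len(matrices):
        raise ValidationError(f"min_cohorts must lie in [1, {len(matrices)}]")

    if mode is None:
        kinds = {m.value_kind for m in matrices.values()}
        mode = "nb_wald" if kinds == {"counts"} else "welch_log"

    per_study_results: dict[str, pd.DataFrame] = {}
    per_study: dict[str, DEGSets] = {}
    for cohort, matrix in matrices.items():
        sub = matrix.subset_genes(shared)
        res = de_test(sub, metadata, contrast, mode=mode)
        per_study_results[cohort] = res
        per_study[cohort] = call_degs(res, lfc_min, alpha)

    # pooled ("meta") contrast
    first_kind = next(iter(matrices.values())).value_kind
    if mode == "nb_wald":
        q, sample_ids, grand = _cohort_centered_normalized(
            {c: m.subset_genes(shared) for c, m in matrices.items()}, shared
        )
        meta_meta = metadata.set_index("sample_id").loc[sample_ids]
        labels = meta_meta["group"].to_numpy()
        idx_a = np.flatnonzero(labels == contrast[0])
        idx_b = np.flatnonzero(labels == contrast[1])
        base_mean, log2fc, p = _nb_wald_from_normalized(q, idx_a, idx_b)
        meta_results = pd.DataFrame(
            {
                "gene": shared,
                "base_mean": base_mean,
                "log2fc": log2fc,
                "p": p,
                "padj": bh_adjust(p),
                "test_mode": mode,
            }
        )
    else:
        pooled = pd.concat([m.data.loc[shared] for m in matrices.values()], axis=1)
        pooled_matrix = ExpressionMatrix(pooled, first_kind)
        meta_results = de_test(pooled_matrix, metadata, contrast, mode=mode)
    meta_sets = call_degs(meta_results, lfc_min, alpha)

    def _consistent(direction: str) -> frozenset:
        meta_set = getattr(meta_sets, direction)
        counts: dict[str, int] = {}
        for sets in per_study.values():
            for g in getattr(sets, direction):
                counts[g] = counts.get(g, 0) + 1
        consistent = {g for g, c in counts.items() if c >= min_cohorts}
        return frozenset(meta_set & consistent)

    common_up = _consistent("up")
    common_down = _consistent("down")

    def _venn(direction: str, common: frozenset) -> dict:
        meta_set = getattr(meta_sets, direction)
        counts: dict[str, int] = {}
        for sets in per_study.values():
            for g in getattr(sets, direction):
                counts[g] = counts.get(g, 0) + 1
        single = {g for g, c in counts.items() if c >= min_cohorts}
        return {
            f"single_only_{direction}": len(single - meta_set),
            f"meta_only_{direction}": len(meta_set - single),
            f"common_{direction}": len(common),
        }

    venn = {**_venn("up", common_up), **_venn("down", common_down)}
    return MetaDEGReport(
        per_study=per_study,
        meta=meta_sets,
        common_up=common_up,
        common_down=common_down,
        venn=venn,
        per_study_results=per_study_results,
        meta_results=meta_results,
    )
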