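"""TF-target networks over common DEGs, knockdown-rescue classification and ORA.

The network admits a prior edge when the TF is itself a DEG (in the common
sets) and a member of the TF universe, and the target is a DEG; node
directions are inherited from the up/down sets. The hub is the TF with the
largest out-degree. A "rescue" gene is significantly changed in the
tumor contrast and significantly changed with the opposite sign after
knockdown of the hub.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ValidationError
from .io_formats import GeneSetCollection, TFPrior

RESCUE_CLASSES = ("tumor_up_rescued", "tumor_down_rescued", "none")


@dataclass
class TFNetwork:
    """Directed TF -> target edges restricted to a DEG universe.

    ``nodes`` maps symbol -> (role, direction); role is "tf", "target" or
    "both"; direction is "up", "down" or None (TF admitted by the relaxed
    flag without being a DEG).
    """

    nodes: dict
    edges: frozenset

    def out_degree(self, tf: str) -> int:
        return sum(1 for a, _ in self.edges if a == tf)


def _common_sets(common) -> tuple[frozenset, frozenset]:
    if hasattr(common, "common_up"):
        return frozenset(common.common_up), frozenset(common.common_down)
    return frozenset(common.up), frozenset(common.down)


def build_tf_network(
    common,
    prior: TFPrior,
    tf_universe: Iterable[str],
    require_tf_deg: bool = True,
) -> TFNetwork:
    """Restrict the prior to DEG-supported edges.

    ``common`` is a MetaDEGReport (common_up/common_down) or any object with
    up/down sets. With ``require_tf_deg`` (default) a TF must itself be a
    DEG; relaxing admits any TF in ``tf_universe`` whose target is a DEG.
    Isolated nodes are excluded.
    """
    if not prior.edges:
        raise ValidationError("empty TF prior")
    up, down = _common_sets(common)
    degs = up | down
    tf_universe = set(tf_universe)
    edges = set()
    for tf, target in prior.edges:
        if tf == target:
            continue
        if tf not in tf_universe or target not in degs:
            continue
        if require_tf_deg and tf not in degs:
            continue
        edges.add((tf, target))
    nodes: dict = {}
    tf_side = {a for a, _ in edges}
    target_side = {b for _, b in edges}
    for symbol in tf_side | target_side:
        role = "both" if symbol in tf_side and symbol in target_side else (
            "tf" if symbol in tf_side else "target"
        )
        direction = "up" if symbol in up else ("down" if symbol in down else None)
        nodes[symbol] = (role, direction)
    return TFNetwork(nodes=nodes, edges=frozenset(edges))


def rank_tfs(network: TFNetwork) -> list[tuple[str, int]]:
    """TFs by out-degree, descending; ties broken lexicographically.

    The first entry is the hub. Empty network gives an empty list.
    """
    degrees: dict[str, int] = {}
    for tf, _ in network.edges:
        degrees[tf] = degrees.get(tf, 0) + 1
    return sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))


def classify_rescue(
    tumor: pd.DataFrame,
    kd: pd.DataFrame,
    lfc_min: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify genes by opposite-sign significance in the two contrasts.

    tumor_up_rescued: tumor log2FC > lfc_min and padj < alpha, knockdown
    log2FC < -lfc_min and padj < alpha; tumor_down_rescued by the mirrored
    inequalities; everything else "none". Genes outside the shared universe
    are dropped.
    """
    merged = tumor[["gene", "log2fc", "padj"]].merge(
        kd[["gene", "log2fc", "padj"]], on="gene", suffixes=("_tumor", "_kd")
    )
    t_lfc = merged["log2fc_tumor"].to_numpy()
    t_padj = merged["padj_tumor"].to_numpy()
    k_lfc = merged["log2fc_kd"].to_numpy()
    k_padj = merged["padj_kd"].to_numpy()
    sig_t = t_padj < alpha
    sig_k = k_padj < alpha
    up_rescued = sig_t & sig_k & (t_lfc > lfc_min) & (k_lfc < -lfc_min)
    down_rescued = sig_t & sig_k & (t_lfc < -lfc_min) & (k_lfc > lfc_min)
    rescue_class = np.where(up_rescued, "tumor_up_rescued", np.where(down_rescued, "tumor_down_rescued", "none"))
    return pd.DataFrame(
        {
            "gene": merged["gene"],
            "tumor_log2fc": t_lfc,
            "tumor_padj": t_padj,
            "kd_log2fc": k_lfc,
            "kd_padj": k_padj,
            "rescue_class": rescue_class,
        }
    )


def ora_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    annotation: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set against term sets.

    p = P(X >= k) for X ~ Hypergeometric(N, K, n) with N the universe size,
    K the (universe-restricted) term size, n the query size and k the
    overlap. BH adjustment is across terms; result sorted by (padj, p,
    term_id). Query genes outside the universe are dropped.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    query = set(query) & universe
    N, n = len(universe), len(query)
    rows = []
    for gs in annotation:
        members = gs.members & universe
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((gs.term_id, gs.term_name, k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    table["padj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table.sort_values(["padj", "p", "term_id"], kind="mergesort").reset_index(drop=True)


def build_rescue_network(
    rescue: pd.DataFrame,
    annotation: GeneSetCollection,
    alpha: float = 0.05,
    universe: Iterable[str] | None = None,
) -> tuple[list[tuple[str, str]], dict, pd.DataFrame]:
    """Bipartite gene-term network over enriched terms of the rescue genes.

    Both rescue classes are pooled as the ORA query; the universe defaults
    to the shared gene universe of the rescue table. Edges connect each
    rescue gene to every enriched term (padj < alpha) containing it; a
    term's color is the majority rescue class among its connected genes,
    ties labeled "mixed". Returns (edges, term colors, enrichment table).
    """
    rescue_genes = rescue.loc[rescue["rescue_class"] != "none"]
    classes = dict(zip(rescue_genes["gene"], rescue_genes["rescue_class"]))
    if universe is None:
        universe = set(rescue["gene"])
    if not classes:
        return [], {}, pd.DataFrame()
    enrichment = ora_enrichment(classes.keys(), universe, annotation)
    enriched = set(enrichment.loc[enrichment["padj"] < alpha, "term_id"])
    members_by_term = {gs.term_id: gs.members for gs in annotation}
    edges: list[tuple[str, str]] = []
    colors: dict[str, str] = {}
    for term_id in sorted(enriched):
        connected = sorted(set(classes) & members_by_term[term_id])
        for gene in connected:
            edges.append((gene, term_id))
        n_up = sum(classes[g] == "tumor_up_rescued" for g in connected)
        n_down = sum(classes[g] == "tumor_down_rescued" for g in connected)
        colors[term_id] = (
            "tumor_up_rescued" if n_up > n_down else "tumor_down_rescued" if n_down > n_up else "mixed"
        )
    return edges, colors, enrichment
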