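"""Post-hoc characterization of a discovered signature.

Three diagnostics: (1) a correlation null — are the signature genes more
tightly co-correlated within a sample group than random gene sets of the
same size drawn from the whole matrix?  Reported as the location shift of
the observed pairwise-correlation distribution against the pooled random
null, with the per-set median distribution kept for a Monte-Carlo band;
(2) hierarchical clustering of the signature genes into coexpression
modules; (3) hypergeometric over-representation of each module against a
user-supplied gene-set collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_data import ExpressionMatrix, GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "GroupCorrelation",
    "CorrelationNullReport",
    "correlation_null",
    "ClusterAssignment",
    "cluster_signature",
    "hypergeom_enrichment",
]


@dataclass
class GroupCorrelation:
    observed: np.ndarray        # signature pairwise correlations, one group
    null: np.ndarray            # pooled correlations over all random sets
    null_set_medians: np.ndarray  # median correlation per random set
    location_shift: float       # median(observed) - median(null)
    n_dropped_pairs: int        # pairs excluded for a constant gene


@dataclass
class CorrelationNullReport:
    groups: dict[str, GroupCorrelation]
    n_random: int
    signature_size: int
    seed: int | None


def _pairwise_correlations(block: np.ndarray) -> tuple[np.ndarray, int]:
    """Upper-triangle Pearson correlations; pairs with a constant gene drop."""
    sd = block.std(axis=1)
    keep = sd > 0
    n_const = int((~keep).sum())
    sub = block[keep]
    m = sub.shape[0]
    total_pairs = block.shape[0] * (block.shape[0] - 1) // 2
    if m < 2:
        return np.empty(0), total_pairs
    corr = np.corrcoef(sub)
    vals = corr[np.triu_indices(m, k=1)]
    return vals, total_pairs - len(vals)


def correlation_null(
    matrix: ExpressionMatrix,
    sig,
    groups: Mapping[str, Sequence[str]],
    n_random: int = 1000,
    seed: int | None = None,
    exclude_signature: bool = False,
    _random_sets: Sequence[Sequence[str]] | None = None,
) -> CorrelationNullReport:
    """Compare signature gene-gene correlations with random-set nulls.

    For each sample group, all m(m-1)/2 pairwise Pearson correlations of
    the signature genes are computed, alongside the pooled correlations of
    ``n_random`` same-size gene sets drawn uniformly without replacement
    from the whole matrix (signature genes included unless
    ``exclude_signature``).  Pairs involving a within-group-constant gene
    are excluded with a logged count.  ``_random_sets`` overrides the
    drawn sets (testing hook).
    """
    sig_ids = list(getattr(sig, "gene_ids", sig))
    if len(sig_ids) < 2:
        raise ValueError("signature must contain at least two genes")
    universe = matrix.feature_ids
    pool = [g for g in universe if g not in set(sig_ids)] if exclude_signature else universe
    if len(pool) <= len(sig_ids):
        raise ValueError("gene universe must exceed the signature size")
    for name, members in groups.items():
        if len(members) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 samples")

    if _random_sets is not None:
        random_sets = [list(s) for s in _random_sets]
    else:
        rng = np.random.default_rng(seed)
        pool_arr = np.asarray(pool)
        random_sets = [
            list(rng.choice(pool_arr, size=len(sig_ids), replace=False))
            for _ in range(n_random)
        ]
    if not random_sets:
        raise ValueError("n_random must be positive")

    report_groups: dict[str, GroupCorrelation] = {}
    for name, members in groups.items():
        cols = list(members)
        obs_block = matrix.data.loc[sig_ids, cols].to_numpy()
        observed, n_dropped = _pairwise_correlations(obs_block)
        if n_dropped:
            log.info("correlation_null[%s]: dropped %d constant-gene pairs",
                     name, n_dropped)
        null_parts = []
        set_medians = []
        group_block = matrix.data.loc[:, cols]
        for gene_set in random_sets:
            vals, _ = _pairwise_correlations(group_block.loc[gene_set].to_numpy())
            null_parts.append(vals)
            set_medians.append(np.median(vals) if len(vals) else np.nan)
        null = np.concatenate(null_parts) if null_parts else np.empty(0)
        shift = float(np.median(observed) - np.median(null))
        report_groups[name] = GroupCorrelation(
            observed=observed,
            null=null,
            null_set_medians=np.asarray(set_medians),
            location_shift=shift,
            n_dropped_pairs=n_dropped,
        )
    return CorrelationNullReport(
        groups=report_groups,
        n_random=len(random_sets),
        signature_size=len(sig_ids),
        seed=seed,
    )


@dataclass
class ClusterAssignment:
    assignments: dict[str, int]  # gene id -> module index in 1..k
    k: int
    linkage: str
    normalization: str

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, m in self.assignments.items():
            out.setdefault(m, []).append(g)
        return out


def _normalize_rows(block: np.ndarray, mode: str, gene_ids: Sequence[str],
                    drop_constant: bool) -> tuple[np.ndarray, list[str]]:
    if mode == "zscore":
        sd = block.std(axis=1)
        const = np.flatnonzero(sd == 0)
        if len(const):
            if not drop_constant:
                raise ValueError(
                    f"zero-variance gene under zscore: {gene_ids[const[0]]!r}"
                )
            keep = sd > 0
            log.info("cluster_signature: dropped %d constant genes", len(const))
            block, gene_ids = block[keep], [g for g, k_ in zip(gene_ids, keep) if k_]
            sd = sd[keep]
        return (block - block.mean(axis=1, keepdims=True)) / sd[:, None], list(gene_ids)
    if mode == "quantile":
        ranks = stats.rankdata(block, axis=1, method="average")
        return ranks / block.shape[1], list(gene_ids)
    raise ValueError(f"unknown normalization {mode!r}")


def cluster_signature(
    matrix: ExpressionMatrix,
    sig,
    k: int = 4,
    normalization: str = "zscore",
    linkage: str = "complete",
    drop_constant: bool = False,
) -> ClusterAssignment:
    """Cut a hierarchical clustering of the signature genes into k modules.

    Gene rows are individually normalized (z-score by default, per-gene
    quantile ranks as the alternative), clustered agglomeratively with
    Euclidean distance, and the dendrogram is cut into k modules.  Module
    labels are renumbered by dendrogram left-to-right leaf order so the
    output is deterministic and invariant to the input row order.
    """
    sig_ids = list(getattr(sig, "gene_ids", sig))
    missing = [g for g in sig_ids if g not in matrix.data.index]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing[:5]}")
    if not 1 <= k <= len(sig_ids):
        raise ValueError(f"k={k} infeasible for signature of size {len(sig_ids)}")
    # canonical row order: lexicographic by gene id, so the linkage (and any
    # within-tie merge order) is independent of how the caller ordered genes
    sig_sorted = sorted(sig_ids)
    block = matrix.data.loc[sig_sorted].to_numpy()
    norm_block, kept_ids = _normalize_rows(block, normalization, sig_sorted,
                                           drop_constant)
    if k > len(kept_ids):
        raise ValueError(f"k={k} infeasible after dropping constant genes")
    if len(kept_ids) == 1:
        return ClusterAssignment({kept_ids[0]: 1}, k, linkage, normalization)
    z = hierarchy.linkage(pdist(norm_block), method=linkage)
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    leaf_order = hierarchy.leaves_list(z)
    relabel: dict[int, int] = {}
    for leaf in leaf_order:
        lab = int(flat[leaf])
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    assignments = {g: relabel[int(lab)] for g, lab in zip(kept_ids, flat)}
    return ClusterAssignment(assignments, k, linkage, normalization)


def hypergeom_enrichment(
    module_genes: Sequence[str],
    universe: Sequence[str],
    collection: GeneSetCollection,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a module against gene sets.

    For each set, p = P(X >= k) with k the module/set overlap, drawing the
    module's n genes from a universe of N containing K set members (sets
    are intersected with the universe first).  Rows sort ascending by p;
    Benjamini-Hochberg q-values are added on request.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    module = [g for g in dict.fromkeys(module_genes)]
    outside = [g for g in module if g not in universe_set]
    if outside:
        raise ValueError(f"module genes outside the universe: {outside[:5]}")
    n = len(module)
    n_universe = len(universe_set)
    module_set = set(module)
    rows = []
    for name, members in collection.sets.items():
        in_universe = [g for g in members if g in universe_set]
        k_cap = len(in_universe)
        overlap = len(module_set & set(in_universe))
        if overlap == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, n_universe, k_cap, n))
        rows.append({
            "set_name": name, "overlap": overlap, "set_size": k_cap,
            "module_size": n, "universe_size": n_universe, "p": p,
        })
    table = pd.DataFrame(rows).sort_values(
        by=["p", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
    if bh_correct and len(table):
        table["q"] = stats.false_discovery_control(table["p"], method="bh")
    return table
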