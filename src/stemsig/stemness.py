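"""The PC1 stemness index and its downstream evaluations.

Restricting the expression matrix to a signature's genes and taking the
leading eigenvector of the gene-gene covariance matrix gives a single
weight vector; each sample's projection onto it — the *stemness index* —
summarizes the signature's coordinated activity in that sample.  Gene rows
are mean-centered but not variance-scaled (the covariance, not the
correlation, matrix is decomposed), and PC1's sign is fixed by forcing a
chosen orientation group's mean index positive.

The index is evaluated by how well it recovers known orderings: staged
differentiation time courses (Spearman rho against stage) and graded
tumor series (pairwise rank-sum AUC between grades).  For external data
series the PCA is refit inside each series, never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ExpressionMatrix, OrthologMap, PhenotypeTable

log = logging.getLogger(__name__)

__all__ = [
    "StemnessResult",
    "compute_stemness",
    "stemness_per_series",
    "SeriesOutcome",
    "OrderedSeparation",
    "ordered_separation",
    "cross_species_index",
]

#: Minimum fraction of signature genes that must be present in a matrix.
COVERAGE_THRESHOLD = 0.5


@dataclass
class StemnessResult:
    loadings: pd.Series            # unit-norm weight per signature gene used
    index: pd.Series               # per-sample projection, centered at 0
    variance_explained: np.ndarray  # fractions, non-increasing, sum <= 1
    orientation_group: str | None
    oriented_by: str               # "group" or "loading"
    genes_used: list[str]
    genes_missing: list[str]


def _signature_ids(sig) -> list[str]:
    return list(getattr(sig, "gene_ids", sig))


def compute_stemness(
    matrix: ExpressionMatrix,
    sig,
    orientation_group: str | None = None,
    pheno: PhenotypeTable | None = None,
) -> StemnessResult:
    """Project samples onto PC1 of the signature genes' covariance.

    Gene rows are mean-centered (no variance scaling) and the leading
    left-singular vector of the centered block gives the loadings; the
    per-sample index is the projection onto it, so it is centered at 0 by
    construction.  If ``orientation_group`` names a nonempty sample group,
    the sign is flipped so that group's mean index is non-negative;
    otherwise the gene with the largest |loading| gets a positive loading.

    Raises when fewer than half the signature genes are present (listing
    the missing ones) or when the centered block is identically zero.
    """
    sig_ids = _signature_ids(sig)
    if not sig_ids:
        raise ValueError("empty signature")
    present = [g for g in sig_ids if g in matrix.data.index]
    missing = [g for g in sig_ids if g not in matrix.data.index]
    coverage = len(present) / len(sig_ids)
    if coverage < COVERAGE_THRESHOLD:
        raise ValueError(
            f"signature coverage {coverage:.2f} below {COVERAGE_THRESHOLD}; "
            f"missing genes: {missing}"
        )
    if matrix.shape[1] < 3:
        raise ValueError("at least three samples are required")

    block = matrix.data.loc[present].to_numpy()
    centered = block - block.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("zero covariance matrix: no variance in signature genes")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = u[:, 0]
    index = s[0] * vt[0]
    var_explained = s**2 / np.sum(s**2)

    oriented_by = "loading"
    flip = False
    if orientation_group is not None and pheno is not None:
        members = [
            sid for sid in matrix.sample_ids
            if sid in pheno.data.index and pheno.data.loc[sid, "group"] == orientation_group
        ]
        if members:
            cols = [matrix.sample_ids.index(sid) for sid in members]
            flip = index[cols].mean() < 0
            oriented_by = "group"
        else:
            log.warning(
                "orientation group %r has no samples here; falling back to "
                "largest-|loading| sign rule", orientation_group,
            )
    if oriented_by == "loading":
        flip = loadings[np.argmax(np.abs(loadings))] < 0
    if flip:
        loadings = -loadings
        index = -index

    return StemnessResult(
        loadings=pd.Series(loadings, index=present, name="loading"),
        index=pd.Series(index, index=matrix.sample_ids, name="stemness_index"),
        variance_explained=var_explained,
        orientation_group=orientation_group if oriented_by == "group" else None,
        oriented_by=oriented_by,
        genes_used=present,
        genes_missing=missing,
    )


@dataclass
class SeriesOutcome:
    result: StemnessResult | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.result is not None


def stemness_per_series(
    series: Sequence[ExpressionMatrix],
    sig,
    orientation_group: str | None = None,
    phenos: Sequence[PhenotypeTable | None] | None = None,
) -> list[SeriesOutcome]:
    """Refit the stemness PCA independently inside each data series.

    Loadings are never pooled across series — each series gets its own
    PC1, matching the per-dataset treatment of external graded-tumor
    sets.  A series that fails (e.g. insufficient signature coverage) is
    reported as an error while the others proceed.
    """
    outcomes: list[SeriesOutcome] = []
    for i, mat in enumerate(series):
        ph = phenos[i] if phenos is not None else None
        try:
            res = compute_stemness(mat, sig, orientation_group, ph)
            outcomes.append(SeriesOutcome(result=res))
        except ValueError as exc:
            log.warning("series %d failed: %s", i, exc)
            outcomes.append(SeriesOutcome(result=None, error=str(exc)))
    return outcomes


@dataclass
class OrderedSeparation:
    rho_abs: float                 # |Spearman| of index vs ordered level codes
    medians: pd.Series             # per-level median index
    auc: pd.DataFrame              # pairwise rank-sum AUC, folded to >= 0.5


def ordered_separation(
    index: pd.Series | Sequence[float],
    labels: Sequence,
    levels: Sequence | None = None,
) -> OrderedSeparation:
    """How well a per-sample index recovers an ordered labeling.

    ``levels`` fixes the label order (low to high); if omitted it is taken
    from an ordered Categorical or, failing that, the sorted unique labels.
    All outputs are orientation-free: the Spearman correlation is reported
    in absolute value and each pairwise AUC is folded to >= 0.5.
    """
    index = np.asarray(index, dtype=float)
    labels = pd.Series(list(labels))
    if levels is None:
        if isinstance(labels.dtype, pd.CategoricalDtype) and labels.cat.ordered:
            levels = list(labels.cat.categories)
        else:
            levels = sorted(labels.unique())
            log.info("ordered_separation: inferring level order %s", levels)
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("at least two levels are required")
    unknown = set(labels) - set(levels)
    if unknown:
        raise ValueError(f"labels outside the declared levels: {sorted(unknown)}")
    codes = labels.map({lev: i for i, lev in enumerate(levels)}).to_numpy()
    for i, lev in enumerate(levels):
        if not np.any(codes == i):
            raise ValueError(f"level {lev!r} has no samples")

    rho = stats.spearmanr(index, codes).statistic
    rho_abs = float(abs(rho)) if np.isfinite(rho) else 0.0
    medians = pd.Series(
        [float(np.median(index[codes == i])) for i in range(len(levels))],
        index=levels, name="median_index",
    )
    auc = pd.DataFrame(np.nan, index=levels, columns=levels)
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            xi, xj = index[codes == i], index[codes == j]
            u = stats.mannwhitneyu(xj, xi, alternative="two-sided").statistic
            a = u / (len(xi) * len(xj))
            folded = float(max(a, 1.0 - a))
            auc.iloc[i, j] = folded
            auc.iloc[j, i] = folded
    return OrderedSeparation(rho_abs=rho_abs, medians=medians, auc=auc)


def cross_species_index(
    matrix_target: ExpressionMatrix,
    sig_source,
    ortholog_map: OrthologMap | Mapping[str, str],
    orientation_group: str | None = None,
    pheno: PhenotypeTable | None = None,
) -> StemnessResult:
    """Translate a signature through an ortholog map, then score the target.

    Source genes without a map entry are ignored; if two signature genes
    collapse onto one target the whole collision group is excluded.  The
    translated-and-present fraction of the original signature must reach
    the coverage threshold.
    """
    pairs = ortholog_map.pairs if isinstance(ortholog_map, OrthologMap) else dict(ortholog_map)
    sig_ids = _signature_ids(sig_source)
    mapped = {g: pairs[g] for g in sig_ids if g in pairs}
    target_counts: dict[str, int] = {}
    for t in mapped.values():
        target_counts[t] = target_counts.get(t, 0) + 1
    translated = [t for g, t in mapped.items() if target_counts[t] == 1]
    n_collided = len(mapped) - len(translated)
    if n_collided:
        log.info("cross_species_index: excluded %d colliding signature genes", n_collided)
    present = [t for t in translated if t in matrix_target.data.index]
    coverage = len(present) / len(sig_ids)
    if coverage < COVERAGE_THRESHOLD:
        raise ValueError(
            f"mapped signature coverage {coverage:.2f} below {COVERAGE_THRESHOLD} "
            f"({len(mapped)} mapped, {len(sig_ids) - len(mapped)} unmapped, "
            f"{n_collided} collided, {len(translated) - len(present)} absent "
            f"from target matrix)"
        )
    return compute_stemness(matrix_target, present, orientation_group, pheno)
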