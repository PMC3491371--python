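"""Sliding-window (FIR) specificity scoring and signature selection.

The core statistic: for one gene, sort all samples by expression and slide
a window of width W (by default the number of anchor samples) along the
sorted list.  The gene's score is the maximum fraction of anchor samples
found in any window.  A gene scores highly when the anchor population is
*localized* anywhere along its expression range — including the middle of
the range, where the non-anchor samples may straddle the anchor band from
both sides and a mean-difference t-test sees nothing.

Binomial tail probabilities (k anchors in a window of n draws at the
database-wide anchor proportion p) are reported descriptively alongside
the scores; selection is by score.  A one-way ANOVA sweep over the number
of top-ranked genes evaluates how well each candidate signature's
stemness index separates a chosen set of phenotype groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ExpressionMatrix, PhenotypeTable

log = logging.getLogger(__name__)

__all__ = [
    "FIRConfig",
    "FIRScore",
    "SignatureGeneSet",
    "fir_score",
    "binomial_tail",
    "rank_genes",
    "score_percentile",
    "t_statistics",
    "t_percentile",
    "select_signature",
    "one_way_f",
    "threshold_sweep",
    "SweepResult",
]

#: Columns of a gene-score table, in output order.
SCORE_COLUMNS = ["gene_id", "score", "k_best", "window_start", "p_value", "rank"]


@dataclass(frozen=True)
class FIRConfig:
    """Scoring configuration.

    window_size
        Width W of the sliding window; ``None`` means "equal to the number
        of anchor samples", the default interpretation under which a score
        of 1.0 means every anchor fits in one frame.
    anchor_group
        If given, samples whose ``group`` equals this label are the
        anchors; otherwise the phenotype table's ``is_anchor`` flag is
        used.
    """

    window_size: int | None = None
    anchor_group: str | None = None


@dataclass(frozen=True)
class FIRScore:
    score: float
    k_best: int
    window_start: int  # 1-based position in the value-sorted sample order


@dataclass
class SignatureGeneSet:
    """An ordered signature: gene ids by rank plus selection provenance."""

    gene_ids: list[str]
    selection_rule: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


def _anchor_vector(
    pheno: PhenotypeTable, sample_ids: Sequence[str], cfg: FIRConfig
) -> np.ndarray:
    if cfg.anchor_group is not None:
        missing = [s for s in sample_ids if s not in pheno.data.index]
        if missing:
            raise ValueError(f"samples absent from phenotype table: {missing[:5]}")
        return (
            pheno.data.loc[list(sample_ids), "group"].to_numpy() == cfg.anchor_group
        )
    return pheno.anchor_mask(sample_ids)


def _window_counts(anchor_sorted: np.ndarray, w: int) -> np.ndarray:
    """Anchor counts in every width-w window of a 0/1 vector (last axis)."""
    cs = np.cumsum(anchor_sorted, axis=-1, dtype=np.int64)
    pad = np.zeros(anchor_sorted.shape[:-1] + (1,), dtype=np.int64)
    cs = np.concatenate([pad, cs], axis=-1)
    return cs[..., w:] - cs[..., :-w]


def fir_score(
    values: Sequence[float] | np.ndarray,
    is_anchor: Sequence[bool] | np.ndarray,
    w: int,
) -> FIRScore:
    """Score one gene: maximum anchor fraction over all width-``w`` windows.

    Samples are sorted ascending by value; ties keep their original
    positions (stable sort), so the score is deterministic and invariant
    to strictly monotone transforms of the values.  Only full windows are
    considered (S - w + 1 positions); the earliest window attaining the
    maximum is reported, 1-based.
    """
    values = np.asarray(values, dtype=float)
    is_anchor = np.asarray(is_anchor, dtype=bool)
    s = values.shape[0]
    if is_anchor.shape[0] != s:
        raise ValueError("values and is_anchor must have equal length")
    if not 1 <= w <= s:
        raise ValueError(f"window size {w} outside [1, {s}]")
    if not is_anchor.any():
        raise ValueError("at least one anchor sample is required")
    order = np.argsort(values, kind="stable")
    counts = _window_counts(is_anchor[order].astype(np.int64), w)
    k_best = int(counts.max())
    start = int(counts.argmax()) + 1
    return FIRScore(score=k_best / w, k_best=k_best, window_start=start)


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def rank_genes(
    matrix: ExpressionMatrix,
    pheno: PhenotypeTable,
    cfg: FIRConfig = FIRConfig(),
) -> pd.DataFrame:
    """Score every gene and return the ranked gene-score table.

    Returns a DataFrame with columns gene_id, score, k_best, window_start,
    p_value and rank, sorted by descending score with ties broken by
    ascending p-value then gene id; ranks are dense over distinct scores.
    The matrix may contain extra samples; scoring is restricted to the
    phenotype table's samples.
    """
    sample_ids = [s for s in pheno.sample_ids if s in matrix.data.columns]
    if len(sample_ids) < len(pheno):
        missing = sorted(set(pheno.sample_ids) - set(matrix.sample_ids))
        raise ValueError(f"phenotype samples missing from matrix: {missing[:5]}")
    values = matrix.data.loc[:, sample_ids].to_numpy()
    anchors = _anchor_vector(pheno, sample_ids, cfg)
    n_anchor = int(anchors.sum())
    s = len(sample_ids)
    if n_anchor == 0 or n_anchor == s:
        raise ValueError("need at least one anchor and one non-anchor sample")
    w = cfg.window_size if cfg.window_size is not None else n_anchor
    if not 1 <= w <= s:
        raise ValueError(f"window size {w} outside [1, {s}]")

    order = np.argsort(values, axis=1, kind="stable")
    counts = _window_counts(anchors[order].astype(np.int64), w)
    k_best = counts.max(axis=1)
    window_start = counts.argmax(axis=1) + 1
    score = k_best / w
    p_anchor = n_anchor / s
    p_value = stats.binom.sf(k_best - 1, w, p_anchor)
    p_value = np.where(k_best == 0, 1.0, p_value)

    table = pd.DataFrame(
        {
            "gene_id": matrix.feature_ids,
            "score": score,
            "k_best": k_best.astype(int),
            "window_start": window_start.astype(int),
            "p_value": p_value,
        }
    )
    table = table.sort_values(
        by=["score", "p_value", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = (
        table["score"].rank(method="dense", ascending=False).astype(int)
    )
    return table[SCORE_COLUMNS]


def score_percentile(table: pd.DataFrame, gene_id: str) -> float:
    """Percentile of a gene's FIR score among all genes (100 = strongest)."""
    scores = table.set_index("gene_id")["score"]
    if gene_id not in scores.index:
        raise KeyError(gene_id)
    return float(100.0 * np.mean(scores.to_numpy() <= scores[gene_id]))


def t_statistics(
    matrix: ExpressionMatrix, pheno: PhenotypeTable, equal_var: bool = True
) -> pd.Series:
    """Two-sample t statistic per gene: anchors vs all non-anchor samples.

    Pooled variance by default ("standard Student's"); Welch via
    ``equal_var=False``.  Genes with zero variance in both groups get t=0.
    """
    sample_ids = [s for s in pheno.sample_ids if s in matrix.data.columns]
    anchors = pheno.anchor_mask(sample_ids)
    if anchors.sum() < 2 or (~anchors).sum() < 2:
        raise ValueError("need at least two anchor and two non-anchor samples")
    values = matrix.data.loc[:, sample_ids].to_numpy()
    t, _ = stats.ttest_ind(
        values[:, anchors], values[:, ~anchors], axis=1, equal_var=equal_var
    )
    t = np.nan_to_num(t, nan=0.0)
    return pd.Series(t, index=matrix.feature_ids, name="t")


def t_percentile(
    matrix: ExpressionMatrix,
    pheno: PhenotypeTable,
    gene_id: str,
    equal_var: bool = True,
) -> float:
    """Percentile of a gene's |t| among all genes (100 = strongest)."""
    t = t_statistics(matrix, pheno, equal_var=equal_var)
    if gene_id not in t.index:
        raise KeyError(gene_id)
    abs_t = t.abs().to_numpy()
    return float(100.0 * np.mean(abs_t <= abs(t[gene_id])))


def select_signature(
    table: pd.DataFrame,
    top_n: int | None = None,
    min_score: float | None = None,
) -> SignatureGeneSet:
    """Take the top-n ranked genes, or every gene meeting a score floor."""
    if (top_n is None) == (min_score is None):
        raise ValueError("give exactly one of top_n or min_score")
    if top_n is not None:
        if not 1 <= top_n <= len(table):
            raise ValueError(f"top_n={top_n} infeasible for {len(table)} genes")
        chosen = table.head(top_n)
        rule = f"top_n={top_n}"
    else:
        chosen = table[table["score"] >= min_score]
        rule = f"min_score={min_score}"
    return SignatureGeneSet(list(chosen["gene_id"]), rule)


def one_way_f(
    values: Sequence[float] | np.ndarray, groups: Sequence
) -> tuple[float, int, int]:
    """Classic one-way fixed-effects ANOVA F with its degrees of freedom.

    Returns (F, df_between, df_within).  A fully degenerate input (zero
    total variance) yields F = 0 so that sweeps over flat synthetic inputs
    complete; zero within-group variance with distinct means yields inf.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(groups)
    k = len(labels)
    n = values.shape[0]
    if k < 2:
        raise ValueError("at least two groups are required")
    df_between, df_within = k - 1, n - k
    if df_within < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lab in labels:
        sub = values[groups == lab]
        ss_between += len(sub) * (sub.mean() - grand) ** 2
        ss_within += float(((sub - sub.mean()) ** 2).sum())
    if ss_between + ss_within == 0.0:
        return 0.0, df_between, df_within
    if ss_within == 0.0:
        return float("inf"), df_between, df_within
    f = (ss_between / df_between) / (ss_within / df_within)
    return float(f), df_between, df_within


@dataclass
class SweepResult:
    table: pd.DataFrame  # columns n_genes, f_stat, df_between, df_within
    best_n: int


def threshold_sweep(
    matrix: ExpressionMatrix,
    pheno: PhenotypeTable,
    cfg: FIRConfig,
    n_grid: Sequence[int],
    eval_groups: Sequence[str],
    score_table: pd.DataFrame | None = None,
) -> SweepResult:
    """Evaluate candidate signature sizes by multi-group ANOVA separation.

    For each n on the grid: take the top-n FIR genes, compute the stemness
    index over the full matrix, and measure the one-way F of the index
    across ``eval_groups``.  The window never varies across the sweep —
    only the number of genes does.  ``score_table`` lets a precomputed
    ranking be reused.
    """
    from .stemness import compute_stemness  # local import; stemness builds on us

    present = set(pheno.group)
    missing = [g for g in eval_groups if g not in present]
    if missing:
        raise ValueError(f"eval groups absent from phenotypes: {missing}")
    if score_table is None:
        score_table = rank_genes(matrix, pheno, cfg)
    rows = []
    for n in n_grid:
        sig = select_signature(score_table, top_n=int(n))
        res = compute_stemness(matrix, sig)
        keep = pheno.group.isin(eval_groups)
        idx = res.index.loc[pheno.data.index[keep]]
        grp = pheno.group[keep]
        f, df_b, df_w = one_way_f(idx.to_numpy(), grp.to_numpy())
        rows.append({"n_genes": int(n), "f_stat": f,
                     "df_between": df_b, "df_within": df_w})
    table = pd.DataFrame(rows)
    best_n = int(table.loc[table["f_stat"].idxmax(), "n_genes"])
    return SweepResult(table=table, best_n=best_n)
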