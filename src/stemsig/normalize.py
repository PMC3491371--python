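"""Probe summarization and per-sample rank normalization.

Probe-level intensities are averaged into gene-centric values, then each
sample (column) is replaced by fractional ranks r/G — r the 1-based rank
with ties averaged, G the number of features — so every sample occupies
the same (0, 1] scale regardless of the series it came from.  Rank
normalization makes every downstream rank-based statistic invariant to
monotone distortions of the raw intensity scale.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .core_data import ExpressionMatrix, ProbeGeneMap

log = logging.getLogger(__name__)

__all__ = ["summarize_probes", "rank_normalize"]


def summarize_probes(
    probe_matrix: ExpressionMatrix, probe_map: ProbeGeneMap | Mapping[str, str]
) -> ExpressionMatrix:
    """Average probe rows into one row per mapped gene.

    Unmapped probes are dropped (count logged); gene rows come out sorted
    lexicographically.  Raises if no probe maps to any gene.
    """
    pairs = probe_map.pairs if isinstance(probe_map, ProbeGeneMap) else dict(probe_map)
    frame = probe_matrix.data
    mapped = [p for p in frame.index if p in pairs]
    if not mapped:
        raise ValueError("no probe in the matrix maps to a gene")
    n_dropped = len(frame.index) - len(mapped)
    if n_dropped:
        log.info("summarize_probes: dropped %d unmapped probes", n_dropped)
    gene_of = [pairs[p] for p in mapped]
    summarized = frame.loc[mapped].groupby(gene_of, sort=True).mean()
    return ExpressionMatrix.from_frame(summarized)


def rank_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each column with fractional ranks r/G in (0, 1].

    Ties receive the average of their ranks; within-column ordering is
    preserved, and the transform is idempotent on tie-free data.
    """
    values = matrix.values
    n_features = values.shape[0]
    if n_features < 1:
        raise ValueError("matrix must have at least one feature")
    ranks = rankdata(values, axis=0, method="average") / n_features
    return ExpressionMatrix(ranks, matrix.feature_ids, matrix.sample_ids)
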