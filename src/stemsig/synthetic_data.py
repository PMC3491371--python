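"""Seeded generators for synthetic expression landscapes with planted truth.

Three generators mirror the data shapes the analysis targets:

``simulate_landscape``
    A phenotypically diverse compendium: a minority anchor (stem-cell)
    population plus several non-anchor groups arranged along a 1-D latent
    stemness gradient.  Planted genes come in two kinds — *gradient* genes
    driven linearly by the latent stemness, and *band* genes whose anchor
    samples sit in a narrow expression band while non-anchor samples
    spread broadly around it, optionally as a symmetric two-component
    mixture straddling the band (so group means match and a t-test is
    nearly blind, while a window statistic sees the tight anchor band).

``simulate_time_course``
    Staged differentiation: latent stemness decreases across stages and
    gradient genes track it with per-sample noise.

``simulate_graded_tumors``
    Graded tumor series: latent stemness increases with grade, with
    inflated variance for the mid grades so adjacent grades overlap — the
    pattern that makes mid-grade calls harder than extreme-grade calls.

All generators are pure functions of (config, seed): identical inputs give
bit-identical outputs.  Every planted quantity is returned in a
``PlantedTruth`` so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, PhenotypeTable

__all__ = [
    "LandscapeConfig",
    "PlantedTruth",
    "simulate_landscape",
    "simulate_time_course",
    "simulate_graded_tumors",
]


def _default_group_sizes() -> dict[str, int]:
    return {"pluripotent": 40, "multipotent": 40, "progenitor": 40,
            "cancer": 120, "normal": 160}


def _default_group_stemness() -> dict[str, float]:
    return {"pluripotent": 1.0, "multipotent": 0.75, "progenitor": 0.55,
            "cancer": 0.4, "normal": 0.1}


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of a synthetic expression compendium.

    The defaults emulate a diverse compendium dominated by differentiated
    tissue with a ~10% pluripotent anchor minority, a latent stemness
    ordering pluripotent > multipotent > progenitor > cancer > normal, and
    planted band genes one order of magnitude tighter for anchors
    (band_width 0.1 of the unit value range) than the non-anchor spread.
    """

    n_genes: int = 2000
    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    group_stemness: Mapping[str, float] = field(default_factory=_default_group_stemness)
    anchor_group: str = "pluripotent"
    n_planted_gradient: int = 60
    n_planted_band: int = 60
    band_width: float = 0.1
    bimodal_fraction: float = 0.5
    bimodal_offset: float = 0.25   # component distance from the band center
    bimodal_sd: float = 0.05
    gradient_snr: float = 4.0      # per-gene signal sd / noise sd
    noise_sd: float = 1.0
    latent_jitter: float = 0.02    # per-sample sd around the group stemness
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes.values()))

    def validate(self) -> None:
        if self.n_planted_gradient + self.n_planted_band > self.n_genes:
            raise ValueError("more planted genes than total genes")
        if not 0.0 < self.band_width < 1.0:
            raise ValueError("band_width must lie in (0, 1)")
        if not 0.0 <= self.bimodal_fraction <= 1.0:
            raise ValueError("bimodal_fraction must lie in [0, 1]")
        if self.anchor_group not in self.group_sizes:
            raise ValueError(f"anchor group {self.anchor_group!r} has no size")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        missing = set(self.group_sizes) - set(self.group_stemness)
        if missing:
            raise ValueError(f"groups without a stemness level: {sorted(missing)}")


@dataclass
class PlantedTruth:
    gradient_genes: list[str]
    band_genes: list[str]          # all band genes, bimodal included
    bimodal_genes: list[str]
    latent_s: pd.Series            # per-sample latent stemness
    effects: pd.Series             # per planted gene: amplitude or band width


def _sample_frame(group_sizes: Mapping[str, int]) -> tuple[list[str], list[str]]:
    sample_ids, groups = [], []
    i = 0
    for group, n in group_sizes.items():
        for _ in range(int(n)):
            sample_ids.append(f"s{i:04d}")
            groups.append(group)
            i += 1
    return sample_ids, groups


def _gradient_rows(
    rng: np.random.Generator, s: np.ndarray, n_rows: int,
    snr: float, noise_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rows = amplitude * (s - mean(s)) + noise, signal sd = snr * noise sd.

    The latent term is centered so gradient genes straddle the background
    intensity distribution rather than sitting uniformly above it — high
    in stem-like samples, low in differentiated ones — which keeps the
    signal visible after per-sample rank normalization.
    """
    sd_s = float(np.std(s))
    if n_rows and sd_s == 0 and noise_sd > 0:
        raise ValueError("latent stemness has zero variance; gradient genes infeasible")
    amplitude = snr * noise_sd / sd_s if (noise_sd > 0 and sd_s > 0) else 1.0
    centered = s - s.mean()
    rows = amplitude * centered[None, :] + rng.normal(
        0.0, noise_sd, size=(n_rows, len(s))
    )
    return rows, np.full(n_rows, amplitude)


def simulate_landscape(
    cfg: LandscapeConfig,
) -> tuple[ExpressionMatrix, PhenotypeTable, PlantedTruth]:
    """Generate a compendium with planted gradient and band genes."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sample_ids, groups = _sample_frame(cfg.group_sizes)
    n = len(sample_ids)
    is_anchor = np.array([g == cfg.anchor_group for g in groups])
    s = np.array([cfg.group_stemness[g] for g in groups])
    s = s + rng.normal(0.0, cfg.latent_jitter, size=n)

    n_bimodal = int(round(cfg.bimodal_fraction * cfg.n_planted_band))
    grad_ids = [f"g_grad_{i:03d}" for i in range(cfg.n_planted_gradient)]
    bimd_ids = [f"g_bimd_{i:03d}" for i in range(n_bimodal)]
    band_ids = [f"g_band_{i:03d}" for i in range(cfg.n_planted_band - n_bimodal)]
    n_bg = cfg.n_genes - cfg.n_planted_gradient - cfg.n_planted_band
    bg_ids = [f"g_bg_{i:04d}" for i in range(n_bg)]

    grad_rows, amplitudes = _gradient_rows(
        rng, s, cfg.n_planted_gradient, cfg.gradient_snr, cfg.noise_sd
    )

    half = cfg.band_width / 2.0
    n_anchor = int(is_anchor.sum())
    n_non = n - n_anchor

    def band_row(bimodal: bool) -> np.ndarray:
        center = rng.uniform(half + cfg.bimodal_offset * bimodal,
                             1.0 - half - cfg.bimodal_offset * bimodal)
        row = np.empty(n)
        row[is_anchor] = rng.uniform(center - half, center + half, size=n_anchor)
        if bimodal:
            side = rng.choice([-1.0, 1.0], size=n_non)
            row[~is_anchor] = (center + side * cfg.bimodal_offset
                               + rng.normal(0.0, cfg.bimodal_sd, size=n_non))
        else:
            row[~is_anchor] = rng.uniform(0.0, 1.0, size=n_non)
        return row

    bimd_rows = np.array([band_row(True) for _ in bimd_ids]).reshape(len(bimd_ids), n)
    band_rows = np.array([band_row(False) for _ in band_ids]).reshape(len(band_ids), n)
    bg_rows = rng.normal(0.0, 1.0, size=(n_bg, n))

    feature_ids = grad_ids + bimd_ids + band_ids + bg_ids
    values = np.concatenate([grad_rows, bimd_rows, band_rows, bg_rows], axis=0)
    matrix = ExpressionMatrix(values, feature_ids, sample_ids)
    pheno = PhenotypeTable.from_records(sample_ids, list(is_anchor), groups)
    effects = pd.Series(
        np.concatenate([amplitudes, np.full(len(bimd_ids) + len(band_ids),
                                            cfg.band_width)]),
        index=grad_ids + bimd_ids + band_ids, name="effect",
    )
    truth = PlantedTruth(
        gradient_genes=grad_ids,
        band_genes=bimd_ids + band_ids,
        bimodal_genes=bimd_ids,
        latent_s=pd.Series(s, index=sample_ids, name="latent_s"),
        effects=effects,
    )
    return matrix, pheno, truth


def simulate_time_course(
    stages: Sequence[str] = ("day00", "day04", "day08", "day14"),
    per_stage_n: int = 6,
    stemness_levels: Sequence[float] = (1.0, 0.7, 0.4, 0.1),
    n_genes: int = 500,
    n_planted_gradient: int = 60,
    gradient_snr: float = 4.0,
    noise_sd: float = 1.0,
    latent_jitter: float = 0.02,
    gene_prefix: str = "g",
    seed: int = 0,
) -> tuple[ExpressionMatrix, PhenotypeTable, PlantedTruth]:
    """Generate a staged differentiation time course.

    Latent stemness decreases strictly across stages; gradient genes track
    it with per-sample noise.  With ``noise_sd`` and ``latent_jitter``
    both zero, all samples within a stage are identical.  Samples of the
    first (most stem-like) stage carry the anchor flag.
    """
    stages = list(stages)
    levels = [float(x) for x in stemness_levels]
    if len(stages) < 2:
        raise ValueError("at least two stages are required")
    if len(levels) != len(stages):
        raise ValueError("stemness_levels must match stages")
    if not all(a > b for a, b in zip(levels, levels[1:])):
        raise ValueError("stemness_levels must be strictly decreasing")
    if n_planted_gradient > n_genes:
        raise ValueError("more planted genes than total genes")

    rng = np.random.default_rng(seed)
    sample_ids, stage_of = _sample_frame({st: per_stage_n for st in stages})
    n = len(sample_ids)
    level_of = dict(zip(stages, levels))
    s = np.array([level_of[st] for st in stage_of])
    s = s + rng.normal(0.0, latent_jitter, size=n)

    grad_ids = [f"{gene_prefix}_grad_{i:03d}" for i in range(n_planted_gradient)]
    bg_ids = [f"{gene_prefix}_bg_{i:04d}" for i in range(n_genes - n_planted_gradient)]
    grad_rows, amplitudes = _gradient_rows(rng, s, n_planted_gradient,
                                           gradient_snr, noise_sd)
    # background: per-gene baseline plus the same noise scale, so zero noise
    # gives stage-identical samples
    baselines = rng.normal(0.0, 1.0, size=(len(bg_ids), 1))
    bg_rows = baselines + rng.normal(0.0, noise_sd, size=(len(bg_ids), n))

    matrix = ExpressionMatrix(
        np.concatenate([grad_rows, bg_rows], axis=0), grad_ids + bg_ids, sample_ids
    )
    pheno = PhenotypeTable.from_records(
        sample_ids,
        [st == stages[0] for st in stage_of],
        [f"stage:{st}" for st in stage_of],
        stage=stage_of,
    )
    truth = PlantedTruth(
        gradient_genes=grad_ids, band_genes=[], bimodal_genes=[],
        latent_s=pd.Series(s, index=sample_ids, name="latent_s"),
        effects=pd.Series(amplitudes, index=grad_ids, name="effect"),
    )
    return matrix, pheno, truth


def simulate_graded_tumors(
    grades: Sequence[str] = ("G1", "G2", "G3"),
    per_grade_n: int = 20,
    grade_stemness: Sequence[float] = (0.2, 0.5, 0.8),
    overlap: float = 0.1,
    mid_variance_factor: float = 2.0,
    n_genes: int = 500,
    n_planted_gradient: int = 60,
    gradient_snr: float = 4.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PhenotypeTable, PlantedTruth]:
    """Generate a graded tumor series with overlapping mid grades.

    Each sample's latent stemness is its grade mean plus ``overlap``-scaled
    noise; mid grades (every grade except the first and last) get their
    noise inflated by ``mid_variance_factor``, so adjacent-grade
    distributions overlap more than the extremes do.
    """
    grades = list(grades)
    levels = [float(x) for x in grade_stemness]
    if len(grades) < 2:
        raise ValueError("at least two grades are required")
    if len(levels) != len(grades):
        raise ValueError("grade_stemness must match grades")
    if not all(a < b for a, b in zip(levels, levels[1:])):
        raise ValueError("grade_stemness must be strictly increasing")
    if n_planted_gradient > n_genes:
        raise ValueError("more planted genes than total genes")

    rng = np.random.default_rng(seed)
    sample_ids, grade_of = _sample_frame({g: per_grade_n for g in grades})
    n = len(sample_ids)
    level_of = dict(zip(grades, levels))
    mid = set(grades[1:-1])
    scale = np.array([overlap * (mid_variance_factor if g in mid else 1.0)
                      for g in grade_of])
    s = np.array([level_of[g] for g in grade_of]) + scale * rng.normal(size=n)

    grad_ids = [f"g_grad_{i:03d}" for i in range(n_planted_gradient)]
    bg_ids = [f"g_bg_{i:04d}" for i in range(n_genes - n_planted_gradient)]
    grad_rows, amplitudes = _gradient_rows(rng, s, n_planted_gradient,
                                           gradient_snr, noise_sd)
    bg_rows = rng.normal(0.0, 1.0, size=(len(bg_ids), n))

    matrix = ExpressionMatrix(
        np.concatenate([grad_rows, bg_rows], axis=0), grad_ids + bg_ids, sample_ids
    )
    pheno = PhenotypeTable.from_records(
        sample_ids,
        [False] * n,
        [f"tumor:{g}" for g in grade_of],
        grade=grade_of,
    )
    truth = PlantedTruth(
        gradient_genes=grad_ids, band_genes=[], bimodal_genes=[],
        latent_s=pd.Series(s, index=sample_ids, name="latent_s"),
        effects=pd.Series(amplitudes, index=grad_ids, name="effect"),
    )
    return matrix, pheno, truth
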