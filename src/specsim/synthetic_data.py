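"""Synthetic TFR cohorts with planted representational structure.

The generator emulates the statistical structure the similarity pipeline
assumes: a repeated-presentation design (C object categories x 2
exemplars x 2 presentations), a 1/f-shaped log-power background, and
stimulus-locked spectral signatures that are shared within a category
(weight ``w_cat``), unique to an exemplar (weight ``w_item``), and
corrupted by independent trial noise (``sigma_noise``).

Signal is planted in LOG-power space,

    log10 P = B(f) + w_cat * g_cat(c) + w_item * g_item(c, e) + sigma * eps,

with B(f) = intercept + slope * log10(f) and the g fields independent
standard-normal over (signal channel, frequency), shared across the
presentations (and, for g_cat, exemplars) of a category. Because
background removal subtracts a per-channel frequency vector from
log-power, it is exactly linear in this model and the planted population
correlations at signal samples have closed form:

    rho_item = (w_cat^2 + w_item^2) / (w_cat^2 + w_item^2 + sigma^2)
    rho_cat  =  w_cat^2              / (w_cat^2 + w_item^2 + sigma^2)
    rho_between = 0

Outside the signal window (and outside the signal channels) the tensor is
background plus noise only, so every similarity level has population
correlation zero there.

Default configuration matches the reference study design: 40 categories,
2 x 2 presentations, a 31-bin frequency grid (2-20 Hz in steps of 2 Hz
plus 25-125 Hz in steps of 5 Hz), 326 time points from -0.6 to 2 s at
8 ms, 60 channels, and 10 subjects per group. ``SynthConfig.reduced()``
shrinks the time axis (40 ms steps, 66 points) and channel count (8) for
desk-scale simulation studies while keeping the design intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior_assoc import BehaviorTable
from .tfr_data import (
    ChannelTable,
    FrequencyGrid,
    TFRDataset,
    TimeGrid,
    TrialTable,
    build_frequency_grid,
    build_time_grid,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_subject_tfr",
    "generate_group_dataset",
    "generate_memory_scores",
    "expected_population_correlation",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    Weights are in log10-power units; ``sigma_noise`` is the standard
    deviation of the i.i.d. cell noise on the same scale. The signal
    window is in seconds relative to stimulus onset; the default
    0.3-1.2 s covers the bulk of the 1.5 s stimulus presentation after
    the early sensory transient. ``background`` is (intercept, slope) of
    log10 power against log10 frequency; slope -2 approximates the 1/f^2
    falloff of broadband EEG power.
    """

    n_subjects: int = 10
    n_categories: int = 40
    n_exemplars: int = 2
    n_presentations: int = 2
    freq_low: tuple[float, float, float] = (2.0, 20.0, 2.0)
    freq_high: tuple[float, float, float] = (25.0, 125.0, 5.0)
    time_span: tuple[float, float, float] = (-0.6, 2.0, 0.008)
    n_channels: int = 60
    background: tuple[float, float] = (2.0, -2.0)
    w_cat: float = 1.0
    w_item: float = 1.0
    sigma_noise: float = 1.0
    signal_window: tuple[float, float] = (0.3, 1.2)
    signal_channels: tuple[int, ...] | None = None  # None = all channels
    group: str = "other"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.w_cat, self.w_item, self.sigma_noise) < 0:
            raise ValueError("weights and noise sd must be >= 0")
        if self.n_exemplars != 2 or self.n_presentations != 2:
            raise ValueError("the design uses exactly 2 exemplars x 2 presentations")

    @classmethod
    def reduced(cls, **overrides) -> "SynthConfig":
        """Desk-scale variant: same design, 40 ms time steps, 8 channels."""
        base = dict(time_span=(-0.6, 2.0, 0.04), n_channels=8)
        base.update(overrides)
        return cls(**base)

    def grids(self) -> tuple[FrequencyGrid, TimeGrid]:
        return (
            build_frequency_grid(self.freq_low, self.freq_high),
            build_time_grid(*self.time_span),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Planted population correlations and signal support of one dataset."""

    rho_item: float
    rho_cat: float
    rho_between: float
    signal_time_indices: np.ndarray
    signal_channel_indices: np.ndarray
    w_cat: float
    w_item: float
    sigma_noise: float


def expected_population_correlation(cfg: SynthConfig) -> tuple[float, float]:
    """Closed-form planted correlations (rho_item, rho_cat) at signal samples."""
    denom = cfg.w_cat**2 + cfg.w_item**2 + cfg.sigma_noise**2
    if denom == 0:
        raise ValueError("w_cat, w_item and sigma_noise are all zero")
    return (
        (cfg.w_cat**2 + cfg.w_item**2) / denom,
        cfg.w_cat**2 / denom,
    )


def _signal_support(
    cfg: SynthConfig, time_grid: TimeGrid
) -> tuple[np.ndarray, np.ndarray]:
    t0, t1 = cfg.signal_window
    times = time_grid.times_s
    if t0 >= t1 or t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError(
            f"signal window {cfg.signal_window} not inside time axis "
            f"[{times[0]}, {times[-1]}]"
        )
    tidx = np.flatnonzero((times >= t0 - 1e-9) & (times <= t1 + 1e-9))
    if cfg.signal_channels is None:
        cidx = np.arange(cfg.n_channels)
    else:
        cidx = np.asarray(cfg.signal_channels, dtype=int)
        if cidx.size and (cidx.min() < 0 or cidx.max() >= cfg.n_channels):
            raise ValueError("signal_channels out of range")
    return tidx, cidx


def _channel_table(n_channels: int) -> ChannelTable:
    # ring layout: gives every channel exactly two distance-1 neighbors
    theta = 2 * np.pi * np.arange(n_channels) / n_channels
    radius = 1.0 / (2 * np.sin(np.pi / n_channels)) if n_channels > 1 else 1.0
    pos = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    labels = tuple(f"CH{i + 1:02d}" for i in range(n_channels))
    return ChannelTable(labels, pos)


def generate_subject_tfr(
    cfg: SynthConfig, subject_index: int, group_key: int = 0
) -> tuple[TFRDataset, GroundTruth]:
    """One subject's linear-power TFR dataset plus its ground truth.

    Deterministic given (cfg.seed, group_key, subject_index): the same
    arguments always produce a bit-identical dataset. Patterns are
    subject-specific; the planted correlation structure is the same for
    every subject of a config.
    """
    freq_grid, time_grid = cfg.grids()
    F, T = len(freq_grid), len(time_grid)
    C = cfg.n_categories
    tidx, cidx = _signal_support(cfg, time_grid)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(group_key), int(subject_index)])
    )

    # trial table: full 2x2 design per category, order shuffled
    cat, ex, pres = np.meshgrid(
        np.arange(1, C + 1), [1, 2], [1, 2], indexing="ij"
    )
    cat, ex, pres = cat.ravel(), ex.ravel(), pres.ravel()
    order = rng.permutation(cat.size)
    trials = TrialTable(
        category=cat[order],
        exemplar=ex[order],
        presentation=pres[order],
        orig_index=np.arange(cat.size),
    )

    intercept, slope = cfg.background
    bg = intercept + slope * np.log10(freq_grid.freqs_hz)  # (F,)

    g_cat = rng.standard_normal((C, cidx.size, F))
    g_item = rng.standard_normal((C, 2, cidx.size, F))

    logpow = np.empty((cat.size, cfg.n_channels, F, T))
    logpow[:] = bg[np.newaxis, np.newaxis, :, np.newaxis]
    logpow += cfg.sigma_noise * rng.standard_normal(logpow.shape)
    if tidx.size and cidx.size:
        c0 = trials.category - 1
        e0 = trials.exemplar - 1
        signal = cfg.w_cat * g_cat[c0] + cfg.w_item * g_item[c0, e0]  # (trial, sig_ch, F)
        logpow[np.ix_(np.arange(cat.size), cidx, np.arange(F), tidx)] += signal[
            :, :, :, np.newaxis
        ]

    power = (10.0 ** logpow).astype(np.float32)
    rho_item, rho_cat = expected_population_correlation(cfg)
    ds = TFRDataset(
        subject_id=f"sub-{group_key}{subject_index:03d}",
        group=cfg.group,
        power=power,
        scale="linear",
        freq_grid=freq_grid,
        time_grid=time_grid,
        channels=_channel_table(cfg.n_channels),
        trials=trials,
    )
    gt = GroundTruth(
        rho_item=rho_item,
        rho_cat=rho_cat,
        rho_between=0.0,
        signal_time_indices=tidx,
        signal_channel_indices=cidx,
        w_cat=cfg.w_cat,
        w_item=cfg.w_item,
        sigma_noise=cfg.sigma_noise,
    )
    return ds, gt


def generate_group_dataset(
    cfg_a: SynthConfig, cfg_b: SynthConfig
) -> tuple[list[tuple[TFRDataset, GroundTruth]], list[tuple[TFRDataset, GroundTruth]]]:
    """Two independent groups of subjects with a shared frequency/time grid.

    Channel counts may differ between groups (as when different EEG
    systems are used per age group); grids must match so similarity
    matrices are comparable. The between-group effect size is the
    difference of the planted (rho_item - rho_cat).
    """
    ga, _ = cfg_a.grids()
    gb, _ = cfg_b.grids()
    if ga != gb or cfg_a.time_span != cfg_b.time_span:
        raise ValueError("groups must share the frequency and time grids")
    group_a = [generate_subject_tfr(cfg_a, i, group_key=0) for i in range(cfg_a.n_subjects)]
    group_b = [generate_subject_tfr(cfg_b, i, group_key=1) for i in range(cfg_b.n_subjects)]
    return group_a, group_b


def generate_memory_scores(
    specificity: np.ndarray,
    r_target: float,
    seed: int,
    subject_ids: tuple[str, ...] | None = None,
    group: str = "other",
) -> BehaviorTable:
    """Memory scores with a target correlation to item specificity.

    Scores are ``r * z(delta) + sqrt(1 - r^2) * noise`` with z(delta) the
    standardized specificity, so the sample correlation converges to
    ``r_target`` as n grows (and equals it exactly at |r_target| = 1).
    """
    if abs(r_target) > 1:
        raise ValueError("|r_target| must be <= 1")
    delta = np.asarray(specificity, dtype=float)
    sd = delta.std()
    if sd == 0:
        raise ValueError("specificity has zero variance; target correlation undefined")
    z = (delta - delta.mean()) / sd
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(delta.size)
    scores = r_target * z + np.sqrt(1 - r_target**2) * noise
    if subject_ids is None:
        subject_ids = tuple(f"sub-{i:03d}" for i in range(delta.size))
    return BehaviorTable(
        pd.DataFrame(
            {
                "subject_id": list(subject_ids),
                "group": group,
                "item_memory": scores,
            }
        )
    )
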