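"""Spectral preprocessing before pattern correlation.

EEG power falls off roughly as a power law of frequency (the 1/f
background). If left in, every pair of spectral patterns shares this
background shape and all pattern correlations are inflated toward 1.
Power is therefore log-transformed and a per-channel background spectrum
is subtracted from every frequency vector before any similarity is
computed.

Two background estimators are provided:

``mean_spectrum``
    the mean log10 power over all trials and time points, per channel and
    frequency (the default);
``loglog_fit``
    an ordinary least-squares line fit of that mean log-power on
    log10(frequency), evaluated at each grid frequency — the background
    model used by the better-oscillation-detection (BOSC) family of
    methods, which removes only the power-law trend and leaves narrowband
    structure in place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .tfr_data import TFRDataset

__all__ = [
    "BackgroundSpectrum",
    "log_power",
    "estimate_background",
    "remove_background",
]

MODES = ("mean_spectrum", "loglog_fit")


@dataclass(frozen=True)
class BackgroundSpectrum:
    """Per-channel background log10-power over the frequency grid.

    ``background_log_power`` has shape (n_channels, n_freqs). For
    ``loglog_fit`` the per-channel ``fit_params`` hold (intercept, slope)
    of log10 power vs log10 frequency.
    """

    background_log_power: np.ndarray
    mode: str
    fit_params: np.ndarray | None = None  # (n_channels, 2) for loglog_fit

    def __post_init__(self) -> None:
        bg = np.asarray(self.background_log_power, dtype=float)
        if bg.ndim != 2:
            raise ValueError("background must be (n_channels, n_freqs)")
        if not np.all(np.isfinite(bg)):
            raise ValueError("background spectrum must be finite")
        object.__setattr__(self, "background_log_power", bg)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


def log_power(ds: TFRDataset) -> TFRDataset:
    """Elementwise log10 of a linear-power dataset."""
    if ds.scale != "linear":
        raise ValueError(f"expected linear-scale dataset, got scale={ds.scale!r}")
    bad = np.argwhere(ds.power <= 0)
    if bad.size:
        idx = tuple(int(i) for i in bad[0])
        raise ValueError(
            f"nonpositive power at (trial,channel,freq,time)={idx}; "
            "cannot log-transform"
        )
    return replace(ds, power=np.log10(ds.power), scale="log10")


def estimate_background(ds: TFRDataset, mode: str = "mean_spectrum") -> BackgroundSpectrum:
    """Estimate the per-channel background spectrum of a log-power dataset.

    The estimate pools all trials and the full epoch (baseline included):
    no analysis window is singled out, which maximizes the number of
    samples entering the estimate.
    """
    if ds.scale != "log10":
        raise ValueError("background is estimated on log10 power; call log_power first")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    # mean over trials (axis 0) and time (last axis) -> (channel, freq)
    mean_spec = ds.power.mean(axis=(0, 3))
    if mode == "mean_spectrum":
        return BackgroundSpectrum(mean_spec, mode=mode)
    if len(ds.freq_grid) < 2:
        raise ValueError("loglog_fit needs at least 2 frequencies")
    logf = np.log10(ds.freq_grid.freqs_hz)
    X = np.column_stack([np.ones_like(logf), logf])
    # OLS per channel: mean_spec.T is (freq, channel)
    coef, *_ = np.linalg.lstsq(X, mean_spec.T, rcond=None)  # (2, channel)
    fitted = (X @ coef).T  # (channel, freq)
    return BackgroundSpectrum(fitted, mode=mode, fit_params=coef.T.copy())


def remove_background(ds: TFRDataset, bg: BackgroundSpectrum) -> TFRDataset:
    """Subtract the background from every (trial, channel, time) frequency vector.

    The residual log-power may be negative; this is the signal that enters
    the pattern correlations. The operation is linear and exactly
    invertible given ``bg``.
    """
    if ds.scale != "log10":
        raise ValueError("background removal applies to log10 power")
    expected = (ds.n_channels, ds.n_freqs)
    if bg.background_log_power.shape != expected:
        raise ValueError(
            f"background shape {bg.background_log_power.shape} does not match "
            f"dataset (channels, freqs) = {expected}"
        )
    resid = ds.power - bg.background_log_power[np.newaxis, :, :, np.newaxis]
    return replace(ds, power=resid)
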