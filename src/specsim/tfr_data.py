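"""Containers and I/O for single-subject time-frequency representations (TFRs).

A TFR dataset holds the 4-D spectral power of one subject
(trial x channel x frequency x time) together with its axes: the frequency
grid of the spectral decomposition, the trial time axis relative to stimulus
onset, the channel labels/positions, and a trial table recording which
stimulus (category, exemplar, presentation) each trial showed.

Datasets are persisted to an HDF5 container with a fixed layout and can be
imported from FieldTrip-style MAT files (v7 and v7.3 dialects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "InvalidGridError",
    "FormatError",
    "FieldTripImportError",
    "FrequencyGrid",
    "TimeGrid",
    "ChannelTable",
    "TrialTable",
    "TFRDataset",
    "ValidationReport",
    "build_frequency_grid",
    "build_time_grid",
    "save_dataset",
    "load_dataset",
    "import_fieldtrip_mat",
    "select_trials",
    "validate_dataset",
]

GROUPS = ("children", "adults", "other")
SCALES = ("linear", "log10")

#: similarity levels used throughout the package
LEVELS = ("within_item", "within_category", "between_category")


class InvalidGridError(ValueError):
    """Raised for band/axis specifications that cannot form a valid grid."""


class FormatError(ValueError):
    """Raised when a stored container is missing required fields."""


class FieldTripImportError(ValueError):
    """Raised when a MAT file does not contain a usable FieldTrip TFR struct."""


# ---------------------------------------------------------------------------
# axis types


@dataclass(frozen=True)
class FrequencyGrid:
    """Center frequencies (Hz) of the spectral decomposition.

    Built from two non-overlapping bands (a low band with fine steps and a
    high band with coarser steps), concatenated in ascending order.
    """

    freqs_hz: np.ndarray
    low_band: tuple[float, float, float] | None = None
    high_band: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        object.__setattr__(self, "freqs_hz", f)
        if f.ndim != 1 or f.size == 0:
            raise InvalidGridError("frequency grid must be a non-empty 1-D array")
        if np.any(f <= 0):
            raise InvalidGridError("frequencies must be strictly positive")
        if np.any(np.diff(f) <= 0):
            raise InvalidGridError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return self.freqs_hz.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return np.array_equal(self.freqs_hz, other.freqs_hz)


@dataclass(frozen=True)
class TimeGrid:
    """Uniformly sampled trial time axis in seconds, onset at 0.0."""

    times_s: np.ndarray
    step_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        if t.ndim != 1 or t.size < 2:
            raise InvalidGridError("time grid needs at least two samples")
        d = np.diff(t)
        if np.any(d <= 0):
            raise InvalidGridError("time axis must be strictly increasing")
        if np.max(np.abs(d - self.step_s)) > 1e-9:
            raise InvalidGridError("time axis must be uniform within 1e-9 s")

    def __len__(self) -> int:
        return self.times_s.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeGrid):
            return NotImplemented
        return np.array_equal(self.times_s, other.times_s)


@dataclass(frozen=True)
class ChannelTable:
    """Channel labels and (optional) 2-D layout or 3-D sensor positions."""

    labels: tuple[str, ...]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.shape[0] != len(labels) or pos.ndim != 2 or pos.shape[1] not in (2, 3):
                raise ValueError("positions must be (n_channels, 2 or 3)")
            if not np.all(np.isfinite(pos)):
                raise ValueError("channel positions must be finite")
            object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChannelTable):
            return NotImplemented
        if self.labels != other.labels:
            return False
        if (self.positions is None) != (other.positions is None):
            return False
        return self.positions is None or np.array_equal(self.positions, other.positions)


@dataclass(frozen=True)
class TrialTable:
    """Per-trial stimulus metadata.

    ``category`` is the object-category id (1..C), ``exemplar`` and
    ``presentation`` index the two exemplars per category and the two
    presentations per exemplar, ``orig_index`` preserves the trial's
    position in the original recording.
    """

    category: np.ndarray
    exemplar: np.ndarray
    presentation: np.ndarray
    orig_index: np.ndarray

    def __post_init__(self) -> None:
        cols = {}
        n = None
        for name in ("category", "exemplar", "presentation", "orig_index"):
            v = np.asarray(getattr(self, name), dtype=np.int64)
            if v.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if n is None:
                n = v.size
            elif v.size != n:
                raise ValueError("trial table columns must have equal length")
            cols[name] = v
            object.__setattr__(self, name, v)

    def __len__(self) -> int:
        return self.category.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, c), getattr(other, c))
            for c in ("category", "exemplar", "presentation", "orig_index")
        )

    @property
    def n_categories(self) -> int:
        return int(np.unique(self.category).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.category,
                "exemplar": self.exemplar,
                "presentation": self.presentation,
                "orig_index": self.orig_index,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        return cls(
            category=df["category"].to_numpy(),
            exemplar=df["exemplar"].to_numpy(),
            presentation=df["presentation"].to_numpy(),
            orig_index=df["orig_index"].to_numpy(),
        )

    def take(self, idx: np.ndarray) -> "TrialTable":
        return TrialTable(
            self.category[idx],
            self.exemplar[idx],
            self.presentation[idx],
            self.orig_index[idx],
        )


@dataclass
class TFRDataset:
    """One subject's 4-D spectral power with axes and trial metadata.

    ``power`` has shape (trial, channel, frequency, time); ``scale`` records
    whether values are linear power or log10 power.
    """

    subject_id: str
    group: str
    power: np.ndarray
    scale: str
    freq_grid: FrequencyGrid
    time_grid: TimeGrid
    channels: ChannelTable
    trials: TrialTable

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        p = np.asarray(self.power)
        expected = (
            len(self.trials),
            len(self.channels),
            len(self.freq_grid),
            len(self.time_grid),
        )
        if p.shape != expected:
            raise ValueError(
                f"power shape {p.shape} does not match axes {expected} "
                "(trial, channel, frequency, time)"
            )
        self.power = p

    # convenience sizes
    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    @property
    def n_channels(self) -> int:
        return self.power.shape[1]

    @property
    def n_freqs(self) -> int:
        return self.power.shape[2]

    @property
    def n_times(self) -> int:
        return self.power.shape[3]

    def equals(self, other: "TFRDataset") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.group == other.group
            and self.scale == other.scale
            and np.array_equal(self.power, other.power)
            and self.freq_grid == other.freq_grid
            and self.time_grid == other.time_grid
            and self.channels == other.channels
            and self.trials == other.trials
        )


# ---------------------------------------------------------------------------
# grid construction


def _band_sequence(band: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = (float(x) for x in band)
    if step <= 0:
        raise InvalidGridError(f"band step must be > 0, got {step}")
    if start > stop:
        raise InvalidGridError(f"band start {start} exceeds stop {stop}")
    n = int(round((stop - start) / step))
    if abs((stop - start) - n * step) > 1e-6 * max(step, 1.0):
        raise InvalidGridError(
            f"band span {stop - start} is not an integral multiple of step {step}"
        )
    return start + step * np.arange(n + 1)


def build_frequency_grid(
    low: tuple[float, float, float], high: tuple[float, float, float]
) -> FrequencyGrid:
    """Concatenate two inclusive arithmetic frequency bands into one grid.

    Parameters
    ----------
    low, high
        ``(start, stop, step)`` in Hz. Bands must not overlap and the high
        band must lie above the low band.
    """
    lo = _band_sequence(low)
    hi = _band_sequence(high)
    if hi[0] <= lo[-1]:
        raise InvalidGridError(
            f"bands overlap or are out of order: low ends at {lo[-1]} Hz, "
            f"high starts at {hi[0]} Hz"
        )
    return FrequencyGrid(
        np.concatenate([lo, hi]), low_band=tuple(low), high_band=tuple(high)
    )


def build_time_grid(start_s: float, stop_s: float, step_s: float) -> TimeGrid:
    """Inclusive uniform time axis from ``start_s`` to ``stop_s`` (seconds)."""
    if step_s <= 0:
        raise InvalidGridError("time step must be > 0")
    if start_s >= stop_s:
        raise InvalidGridError("time start must precede stop")
    n = int(round((stop_s - start_s) / step_s))
    if abs((stop_s - start_s) - n * step_s) > 1e-6 * step_s:
        raise InvalidGridError(
            f"span {stop_s - start_s} s is not an integral multiple of step {step_s} s"
        )
    return TimeGrid(start_s + step_s * np.arange(n + 1), step_s=float(step_s))


# ---------------------------------------------------------------------------
# HDF5 container


def save_dataset(ds: TFRDataset, path: str | Path) -> None:
    """Write a dataset to the package's HDF5 container layout.

    Layout: ``/power`` (trial x channel x freq x time), ``/freqs``,
    ``/times``, ``/channels/{labels,pos}``, ``/trials/{category,exemplar,
    presentation,orig_index}``; root attrs ``subject_id``, ``group``,
    ``scale``, ``time_step_s``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=ds.power)
        f.create_dataset("freqs", data=ds.freq_grid.freqs_hz)
        if ds.freq_grid.low_band is not None:
            f["freqs"].attrs["low_band"] = np.asarray(ds.freq_grid.low_band)
        if ds.freq_grid.high_band is not None:
            f["freqs"].attrs["high_band"] = np.asarray(ds.freq_grid.high_band)
        f.create_dataset("times", data=ds.time_grid.times_s)
        ch = f.create_group("channels")
        ch.create_dataset(
            "labels", data=np.array([s.encode() for s in ds.channels.labels])
        )
        if ds.channels.positions is not None:
            ch.create_dataset("pos", data=ds.channels.positions)
        tr = f.create_group("trials")
        for col in ("category", "exemplar", "presentation", "orig_index"):
            tr.create_dataset(col, data=getattr(ds.trials, col))
        f.attrs["subject_id"] = ds.subject_id
        f.attrs["group"] = ds.group
        f.attrs["scale"] = ds.scale
        f.attrs["time_step_s"] = ds.time_grid.step_s


def _require(f: h5py.File, name: str):
    if name not in f:
        raise FormatError(f"container is missing required field {name!r}")
    return f[name]


def load_dataset(path: str | Path) -> TFRDataset:
    """Read a dataset written by :func:`save_dataset` (lossless round trip)."""
    with h5py.File(path, "r") as f:
        for attr in ("subject_id", "group", "scale", "time_step_s"):
            if attr not in f.attrs:
                raise FormatError(f"container is missing required attribute {attr!r}")
        power = _require(f, "power")[()]
        freqs = _require(f, "freqs")
        low = freqs.attrs.get("low_band")
        high = freqs.attrs.get("high_band")
        fg = FrequencyGrid(
            freqs[()],
            low_band=tuple(low) if low is not None else None,
            high_band=tuple(high) if high is not None else None,
        )
        tg = TimeGrid(_require(f, "times")[()], step_s=float(f.attrs["time_step_s"]))
        chg = _require(f, "channels")
        if "labels" not in chg:
            raise FormatError("container is missing required field 'channels/labels'")
        labels = [b.decode() for b in chg["labels"][()]]
        pos = chg["pos"][()] if "pos" in chg else None
        trg = _require(f, "trials")
        cols = {}
        for col in ("category", "exemplar", "presentation", "orig_index"):
            if col not in trg:
                raise FormatError(f"container is missing required field 'trials/{col}'")
            cols[col] = trg[col][()]
        return TFRDataset(
            subject_id=str(f.attrs["subject_id"]),
            group=str(f.attrs["group"]),
            power=power,
            scale=str(f.attrs["scale"]),
            freq_grid=fg,
            time_grid=tg,
            channels=ChannelTable(tuple(labels), pos),
            trials=TrialTable(**cols),
        )


# ---------------------------------------------------------------------------
# FieldTrip MAT import

_FT_FIELDS = ("powspctrm", "label", "freq", "time", "trialinfo")
_TRIALINFO_KEYS = ("category", "exemplar", "presentation", "orig_index")


def _is_mat73(path: Path) -> bool:
    with open(path, "rb") as fh:
        header = fh.read(128)
    return b"MATLAB 7.3" in header or header[:8] == b"\x89HDF\r\n\x1a\n"


def _read_mat7(path: Path) -> dict:
    from scipy.io import loadmat

    raw = loadmat(path, squeeze_me=True, struct_as_record=False)
    top = {k: v for k, v in raw.items() if not k.startswith("__")}
    # the TFR struct may be a single top-level variable or spread over vars
    for v in top.values():
        if all(hasattr(v, fieldname) for fieldname in _FT_FIELDS[:4]):
            out = {fn: getattr(v, fn) for fn in _FT_FIELDS if hasattr(v, fn)}
            return out
    if all(fn in top for fn in _FT_FIELDS[:4]):
        return {fn: top[fn] for fn in _FT_FIELDS if fn in top}
    raise FieldTripImportError(
        f"no FieldTrip TFR struct (fields {_FT_FIELDS[:4]}) found in {path}"
    )


def _mat73_strings(f: h5py.File, node) -> list[str]:
    """Decode a MATLAB v7.3 cellstr (array of object references to char arrays)."""
    arr = node[()]
    out = []
    for ref in np.ravel(arr):
        chars = f[ref][()]
        out.append("".join(chr(c) for c in np.ravel(chars)))
    return out


def _read_mat73(path: Path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        grp = None
        for key, val in f.items():
            if key.startswith("#"):
                continue
            if isinstance(val, h5py.Group) and all(
                fn in val for fn in _FT_FIELDS[:4]
            ):
                grp = val
                break
        if grp is None and all(fn in f for fn in _FT_FIELDS[:4]):
            grp = f
        if grp is None:
            raise FieldTripImportError(
                f"no FieldTrip TFR struct (fields {_FT_FIELDS[:4]}) found in {path}"
            )
        for fn in _FT_FIELDS:
            if fn not in grp:
                continue
            node = grp[fn]
            if fn == "label":
                if node[()].dtype == object or h5py.check_ref_dtype(node.dtype):
                    out[fn] = _mat73_strings(f, node)
                else:
                    out[fn] = ["".join(chr(c) for c in col) for col in node[()].T]
            else:
                # MATLAB stores arrays transposed relative to row-major order
                out[fn] = np.asarray(node[()]).T
    return out


def import_fieldtrip_mat(
    path: str | Path,
    column_map: Mapping[str, int],
    subject_id: str = "",
    group: str = "other",
    scale: str = "linear",
) -> TFRDataset:
    """Import a FieldTrip-style TFR struct from a MAT file.

    Parameters
    ----------
    path
        MAT file (v7 or v7.3) containing a struct with fields ``powspctrm``
        (trial x channel x freq x time), ``label``, ``freq``, ``time`` and
        ``trialinfo``.
    column_map
        Maps trial-table fields to 0-based ``trialinfo`` column indices.
        Required keys: ``category``, ``exemplar``, ``presentation``;
        ``orig_index`` is optional (defaults to the trial's row number).
        Trial-selection conventions differ between experiments, so the
        mapping is always supplied by the caller.
    """
    path = Path(path)
    unknown = set(column_map) - set(_TRIALINFO_KEYS)
    if unknown:
        raise FieldTripImportError(
            f"unknown trialinfo map keys {sorted(unknown)}; expected keys from "
            f"{_TRIALINFO_KEYS}"
        )
    missing_keys = {"category", "exemplar", "presentation"} - set(column_map)
    if missing_keys:
        raise FieldTripImportError(
            f"trialinfo map is missing required keys {sorted(missing_keys)}"
        )

    data = _read_mat73(path) if _is_mat73(path) else _read_mat7(path)
    missing = [fn for fn in _FT_FIELDS if fn not in data]
    if missing:
        raise FieldTripImportError(f"MAT struct is missing fields {missing}")

    pow_ = np.asarray(data["powspctrm"], dtype=float)
    if pow_.ndim != 4:
        raise FieldTripImportError(
            f"powspctrm must be 4-D (trial x channel x freq x time), got {pow_.ndim}-D"
        )
    trialinfo = np.atleast_2d(np.asarray(data["trialinfo"]))
    if trialinfo.size == 0:
        raise FieldTripImportError("trialinfo is empty")
    if trialinfo.shape[0] != pow_.shape[0] and trialinfo.shape[1] == pow_.shape[0]:
        trialinfo = trialinfo.T
    if trialinfo.shape[0] != pow_.shape[0]:
        raise FieldTripImportError(
            f"trialinfo rows ({trialinfo.shape[0]}) do not match trials "
            f"({pow_.shape[0]})"
        )

    def col(key: str, default: np.ndarray | None = None) -> np.ndarray:
        if key not in column_map:
            return default
        j = int(column_map[key])
        if j >= trialinfo.shape[1]:
            raise FieldTripImportError(
                f"trialinfo has {trialinfo.shape[1]} columns; map key {key!r} "
                f"points at column {j}"
            )
        return trialinfo[:, j].astype(np.int64)

    n = pow_.shape[0]
    trials = TrialTable(
        category=col("category"),
        exemplar=col("exemplar"),
        presentation=col("presentation"),
        orig_index=col("orig_index", default=np.arange(n, dtype=np.int64)),
    )
    labels = [str(s) for s in np.ravel(np.asarray(data["label"], dtype=object))]
    freqs = np.ravel(np.asarray(data["freq"], dtype=float))
    times = np.ravel(np.asarray(data["time"], dtype=float))
    step = float(np.median(np.diff(times)))
    return TFRDataset(
        subject_id=subject_id or path.stem,
        group=group,
        power=pow_,
        scale=scale,
        freq_grid=FrequencyGrid(freqs),
        time_grid=TimeGrid(times, step_s=step),
        channels=ChannelTable(tuple(labels)),
        trials=trials,
    )


# ---------------------------------------------------------------------------
# selection and validation


def select_trials(ds: TFRDataset, selector: Mapping[str, int] | None = None) -> TFRDataset:
    """Subset a dataset by trial metadata, preserving trial order.

    ``selector`` maps trial-table columns (``category``, ``exemplar``,
    ``presentation``) to required values; an empty selector returns all
    trials. A selector matching nothing returns an empty dataset and emits
    a warning rather than raising.
    """
    selector = dict(selector or {})
    allowed = {"category", "exemplar", "presentation"}
    bad = set(selector) - allowed
    if bad:
        raise ValueError(f"unknown selector keys {sorted(bad)}; allowed: {sorted(allowed)}")
    mask = np.ones(ds.n_trials, dtype=bool)
    for key, val in selector.items():
        mask &= getattr(ds.trials, key) == int(val)
    if selector and not mask.any():
        warnings.warn(f"selector {selector} matched no trials", stacklevel=2)
    idx = np.flatnonzero(mask)
    return replace(ds, power=ds.power[idx], trials=ds.trials.take(idx))


@dataclass
class ValidationReport:
    """Machine-readable dataset health report; never raises by itself."""

    issues: list[dict] = field(default_factory=list)
    #: categories usable per similarity level (all required trials present)
    usable_categories: dict[str, list[int]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, kind: str, message: str, **info) -> None:
        self.issues.append({"kind": kind, "message": message, **info})


def _has_trial(tt: TrialTable, c: int, e: int, p: int) -> bool:
    return bool(
        np.any((tt.category == c) & (tt.exemplar == e) & (tt.presentation == p))
    )


def usable_categories(trials: TrialTable, level: str) -> list[int]:
    """Categories for which the trials a similarity level needs all exist."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    cats = np.unique(trials.category)
    need = {
        "within_item": [(1, 1), (1, 2)],  # exemplar 1, presentations 1+2
        "within_category": [(1, 1), (2, 1)],  # exemplars 1+2, presentation 1
        "between_category": [(1, 1)],
    }[level]
    return [int(c) for c in cats if all(_has_trial(trials, c, e, p) for e, p in need)]


def validate_dataset(ds: TFRDataset) -> ValidationReport:
    """Report NaNs, nonpositive linear power, duplicate stimulus triples and
    categories missing the trials a similarity level needs.

    The report is informational: nothing here raises, so pipelines can log
    the issues and decide how to proceed.
    """
    rep = ValidationReport()
    nan_idx = np.argwhere(np.isnan(ds.power))
    for idx in nan_idx[:20]:
        rep.add("nan", f"NaN power at (trial,channel,freq,time)={tuple(idx)}", index=[int(i) for i in idx])
    if len(nan_idx) > 20:
        rep.add("nan", f"... and {len(nan_idx) - 20} more NaN cells")
    if ds.scale == "linear":
        bad = np.argwhere(ds.power <= 0)
        for idx in bad[:20]:
            rep.add(
                "nonpositive",
                f"nonpositive linear power at (trial,channel,freq,time)={tuple(idx)}",
                index=[int(i) for i in idx],
            )
        if len(bad) > 20:
            rep.add("nonpositive", f"... and {len(bad) - 20} more nonpositive cells")
    df = ds.trials.to_frame()
    dup = df.duplicated(subset=["category", "exemplar", "presentation"], keep=False)
    for _, row in df[dup].iterrows():
        rep.add(
            "duplicate_triple",
            "duplicate (category, exemplar, presentation) = "
            f"({row.category}, {row.exemplar}, {row.presentation})",
        )
    all_cats = [int(c) for c in np.unique(ds.trials.category)]
    for level in LEVELS:
        usable = usable_categories(ds.trials, level)
        rep.usable_categories[level] = usable
        for c in sorted(set(all_cats) - set(usable)):
            rep.add(
                "unusable_category",
                f"category {c} lacks trials required for {level}",
                category=c,
                level=level,
            )
    return rep
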