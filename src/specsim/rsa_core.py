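"""Time-time pattern similarity: pair enumeration, correlation, averaging.

The core computation correlates two spectral patterns (frequency x time
matrices) column by column: the frequency vector of pattern 1 at time t1
with the frequency vector of pattern 2 at time t2, for every (t1, t2)
combination, yielding a time x time correlation matrix per channel. The
correlations are Fisher-z transformed (atanh) before any averaging so
that means and t-tests operate on an approximately variance-stabilized
scale.

Three similarity levels are supported, mirroring a repeated-presentation
design with two exemplars per object category:

within_item
    presentation 1 vs presentation 2 of the same exemplar (exemplar 1 of
    each category) — representational stability;
within_category
    exemplar 1 vs exemplar 2 of the same category (first presentations) —
    similarity of related but non-identical stimuli;
between_category
    every ordered pair of distinct categories (first exemplar, first
    presentation) — the baseline similarity of unrelated stimuli, whose
    inverse indexes distinctiveness.

Between-category pairs are enumerated ORDERED, i.e. both (X, Y) and
(Y, X) are computed. The two matrices are transposes of each other, so
the mean over all ordered pairs is exactly symmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .tfr_data import (
    LEVELS,
    ChannelTable,
    TFRDataset,
    TimeGrid,
    TrialTable,
    usable_categories,
)

__all__ = [
    "PairList",
    "SimilarityTensor",
    "SubjectSimilarity",
    "GroupSimilarity",
    "enumerate_pairs",
    "time_time_correlation",
    "fisher_z",
    "compute_subject_similarity",
    "average_subject",
    "grand_average",
    "extract_diagonal",
]

#: correlations are clipped to +-(1 - R_CLIP) before atanh
R_CLIP = 1e-12

METHODS = ("pearson", "spearman")


@dataclass(frozen=True)
class PairList:
    """Trial pairs to correlate for one similarity level.

    Each pair is ``(trial_index_a, trial_index_b, unit_id)`` where the unit
    is the averaging unit: the category id for within-item/within-category,
    or the ordered category pair ``(cat_a, cat_b)`` for between-category.
    Categories lacking a required trial are skipped and listed in
    ``skipped_categories``.
    """

    level: str
    pairs: tuple[tuple[int, int, object], ...]
    skipped_categories: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        for a, b, _ in self.pairs:
            if a == b:
                raise ValueError(f"pair correlates a trial with itself (index {a})")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SimilarityTensor:
    """Fisher-z time-time similarity per averaging unit and channel.

    ``z`` has shape (n_units, n_channels, T, T); entry (u, c, t1, t2) is
    the Fisher-z correlation of pattern a at time t1 with pattern b at
    time t2 in channel c for unit u.
    """

    z: np.ndarray
    level: str
    subject_id: str
    unit_ids: tuple
    time_grid: TimeGrid
    channels: ChannelTable
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.z)
        if z.ndim != 4 or z.shape[2] != z.shape[3]:
            raise ValueError("z must be (units, channels, T, T)")
        if z.shape[0] != len(self.unit_ids):
            raise ValueError("unit axis does not match unit_ids")
        self.z = z

    @property
    def n_units(self) -> int:
        return self.z.shape[0]


@dataclass
class SubjectSimilarity:
    """Per-subject mean similarity: channel x time x time."""

    z_mean: np.ndarray
    n_units: int
    level: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        z = np.asarray(self.z_mean)
        if z.ndim != 3 or z.shape[1] != z.shape[2]:
            raise ValueError("z_mean must be (channels, T, T)")
        self.z_mean = z


@dataclass
class GroupSimilarity:
    """Stack of per-subject mean similarities: subject x channel x time x time."""

    stack: np.ndarray
    group: str
    level: str
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.stack)
        if s.ndim != 4 or s.shape[2] != s.shape[3]:
            raise ValueError("stack must be (subjects, channels, T, T)")
        if s.shape[0] != len(self.subject_ids):
            raise ValueError("subject axis does not match subject_ids")
        self.stack = s

    @property
    def n_subjects(self) -> int:
        return self.stack.shape[0]


# ---------------------------------------------------------------------------
# pair enumeration


def _find_trial(tt: TrialTable, c: int, e: int, p: int) -> int | None:
    hits = np.flatnonzero(
        (tt.category == c) & (tt.exemplar == e) & (tt.presentation == p)
    )
    return int(hits[0]) if hits.size else None


def enumerate_pairs(trials: TrialTable, level: str) -> PairList:
    """List the trial pairs a similarity level correlates.

    within_item: per category, (exemplar 1, presentation 1) vs
    (exemplar 1, presentation 2). within_category: per category,
    (exemplar 1, presentation 1) vs (exemplar 2, presentation 1).
    between_category: all ordered pairs of distinct usable categories,
    (exemplar 1, presentation 1) on both sides.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    cats = [int(c) for c in np.unique(trials.category)]
    usable = usable_categories(trials, level)
    skipped = tuple(sorted(set(cats) - set(usable)))
    pairs: list[tuple[int, int, object]] = []
    if level == "within_item":
        for c in usable:
            pairs.append((_find_trial(trials, c, 1, 1), _find_trial(trials, c, 1, 2), c))
    elif level == "within_category":
        for c in usable:
            pairs.append((_find_trial(trials, c, 1, 1), _find_trial(trials, c, 2, 1), c))
    else:  # between_category: ordered pairs -> n(n-1) units
        first = {c: _find_trial(trials, c, 1, 1) for c in usable}
        for ca in usable:
            for cb in usable:
                if ca != cb:
                    pairs.append((first[ca], first[cb], (ca, cb)))
    if not pairs:
        raise ValueError(f"no usable categories for level {level!r}")
    return PairList(level=level, pairs=tuple(pairs), skipped_categories=skipped)


# ---------------------------------------------------------------------------
# correlation core


def _normalize_columns(pattern: np.ndarray) -> tuple[np.ndarray, int]:
    """Center and unit-scale each column (frequency vector); zero-variance
    columns become all-zero so their correlations are 0 by convention."""
    x = np.asarray(pattern, dtype=float)
    xc = x - x.mean(axis=-2, keepdims=True)
    norm = np.sqrt(np.sum(xc * xc, axis=-2, keepdims=True))
    zero = norm == 0
    n_zero = int(np.count_nonzero(zero))
    norm = np.where(zero, 1.0, norm)
    return xc / norm, n_zero


def _rank_columns(pattern: np.ndarray) -> np.ndarray:
    return rankdata(pattern, axis=-2)


def time_time_correlation(
    pattern_a: np.ndarray, pattern_b: np.ndarray, method: str = "pearson"
) -> np.ndarray:
    """Correlate every time column of one F x T pattern with every column
    of another, returning a T x T correlation matrix.

    Entry (t1, t2) is the correlation over frequencies of column t1 of
    ``pattern_a`` with column t2 of ``pattern_b``. Zero-variance columns
    yield r = 0 with a warning.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    a = np.asarray(pattern_a, dtype=float)
    b = np.asarray(pattern_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("patterns must be 2-D (freq x time)")
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"frequency axes differ: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 frequencies to correlate")
    if method == "spearman":
        a, b = _rank_columns(a), _rank_columns(b)
    an, nza = _normalize_columns(a)
    bn, nzb = _normalize_columns(b)
    if nza or nzb:
        warnings.warn(
            f"{nza + nzb} zero-variance frequency vector(s); their correlations "
            "are set to 0",
            stacklevel=2,
        )
    r = an.T @ bn
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z transform, z' = atanh(r), with |r| clipped to 1 - 1e-12.

    Clipping keeps z' finite when patterns are identical (r = +-1); clip
    events are reported via a warning so perfect correlations do not pass
    silently.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-9):
        raise ValueError("correlation magnitude exceeds 1 beyond tolerance")
    n_clip = int(np.count_nonzero(np.abs(r_arr) > 1 - R_CLIP))
    if n_clip:
        warnings.warn(f"clipped {n_clip} correlation(s) at |r| = 1 - 1e-12", stacklevel=2)
    z = np.arctanh(np.clip(r_arr, -(1 - R_CLIP), 1 - R_CLIP))
    return z if isinstance(r, np.ndarray) else float(z)


def compute_subject_similarity(
    ds: TFRDataset, level: str, method: str = "pearson"
) -> SimilarityTensor:
    """Fisher-z time-time similarity for every averaging unit and channel.

    ``ds`` must be log-transformed (and normally background-removed);
    patterns are correlated per channel for every pair from
    :func:`enumerate_pairs`, giving a tensor of shape
    (n_units, n_channels, T, T).
    """
    if ds.scale != "log10":
        raise ValueError(
            "similarity is computed on log10 background-removed power; "
            "run spectral_preproc first"
        )
    pl = enumerate_pairs(ds.trials, level)
    T = ds.n_times
    n_ch = ds.n_channels
    z = np.empty((len(pl), n_ch, T, T), dtype=np.float64)
    n_zero = 0
    n_clip = 0
    for u, (ia, ib, _unit) in enumerate(pl.pairs):
        pa = ds.power[ia]  # (channel, F, T)
        pb = ds.power[ib]
        if method == "spearman":
            pa, pb = _rank_columns(pa), _rank_columns(pb)
        an, nza = _normalize_columns(pa)
        bn, nzb = _normalize_columns(pb)
        n_zero += nza + nzb
        r = np.clip(np.einsum("cft,cfs->cts", an, bn), -1.0, 1.0)
        n_clip += int(np.count_nonzero(np.abs(r) > 1 - R_CLIP))
        z[u] = np.arctanh(np.clip(r, -(1 - R_CLIP), 1 - R_CLIP))
    return SimilarityTensor(
        z=z,
        level=level,
        subject_id=ds.subject_id,
        unit_ids=tuple(unit for _, _, unit in pl.pairs),
        time_grid=ds.time_grid,
        channels=ds.channels,
        provenance={
            "method": method,
            "n_zero_variance_columns": n_zero,
            "n_clipped_correlations": n_clip,
            "skipped_categories": list(pl.skipped_categories),
        },
    )


def average_subject(st: SimilarityTensor) -> SubjectSimilarity:
    """Arithmetic mean of the similarity tensor over averaging units."""
    return SubjectSimilarity(
        z_mean=st.z.mean(axis=0),
        n_units=st.n_units,
        level=st.level,
        subject_id=st.subject_id,
    )


def grand_average(
    subjects: list[SubjectSimilarity], group: str = "other"
) -> tuple[GroupSimilarity, np.ndarray]:
    """Stack per-subject mean similarities and return the grand-mean matrix.

    Returns the (subject x channel x T x T) stack plus the T x T matrix
    averaged over channels and subjects (the display quantity).
    """
    if not subjects:
        raise ValueError("need at least one subject")
    levels = {s.level for s in subjects}
    if len(levels) != 1:
        raise ValueError(f"subjects mix similarity levels {sorted(levels)}")
    shapes = {s.z_mean.shape for s in subjects}
    if len(shapes) != 1:
        raise ValueError(
            f"subjects have mismatching (channels, T, T) shapes {sorted(shapes)}; "
            "channel counts may differ between groups but not within"
        )
    stack = np.stack([s.z_mean for s in subjects])
    gs = GroupSimilarity(
        stack=stack,
        group=group,
        level=subjects[0].level,
        subject_ids=tuple(s.subject_id for s in subjects),
    )
    return gs, stack.mean(axis=(0, 1))


def extract_diagonal(matrix: np.ndarray) -> np.ndarray:
    """Diagonal of a time x time similarity matrix: similarity of the two
    patterns at identical time points."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    return np.diagonal(m).copy()
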