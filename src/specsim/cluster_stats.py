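"""Three-level inference on similarity tensors.

First level (within subject): at every (channel, t1, t2) sample, a paired
t-test over categories contrasts within-item against within-category
Fisher-z similarity. The resulting t-maps are pointwise effect sizes of
item specificity.

Second level (within group): the subject t-maps are tested against zero
with a cluster-based sign-flip permutation test. Samples whose one-sample
t exceeds the two-sided critical value at the sample alpha are grouped
into connected clusters (adjacent in t1 OR t2 within a channel, or the
same (t1, t2) sample in neighboring channels — no diagonal moves), the
cluster statistic is the summed t (cluster mass), and the Monte-Carlo
reference distribution is built by randomly flipping the sign of whole
subject maps. This controls the family-wise error over the full
channel x time x time volume.

Third level (between groups): significant clusters define a mask per
group; the mean within-item and within-category z inside the mask give a
per-subject item-specificity score delta, compared between groups with an
independent-samples t-test. Only the scalar delta crosses groups, so
groups may have different channel layouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .rsa_core import GroupSimilarity, SimilarityTensor
from .tfr_data import ChannelTable

__all__ = [
    "Adjacency",
    "TMapStack",
    "ClusterResult",
    "SpecificitySummary",
    "first_level_tmap",
    "first_level_tmaps",
    "build_adjacency",
    "find_clusters",
    "cluster_permutation_test",
    "extract_cluster_means",
    "compare_groups",
]

#: 4-connectivity in the (t1, t2) plane — no diagonal moves
_PLANE_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class Adjacency:
    """Undirected channel neighborhood graph.

    ``pairs`` holds index pairs (i < j) into ``labels``; built either by
    thresholding Euclidean distances between sensor positions or from an
    explicit list of label pairs.
    """

    labels: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...]
    source: str = "distance_threshold"
    threshold: float | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        norm = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError("adjacency must be irreflexive")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("adjacency pair out of range")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "pairs", tuple(sorted(norm)))

    def neighbor_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in self.labels]
        for i, j in self.pairs:
            out[i].append(j)
            out[j].append(i)
        return out


@dataclass
class TMapStack:
    """Per-subject first-level t-maps, stacked (subject x channel x T x T)."""

    t: np.ndarray
    df: int
    contrast: str = "within_item - within_category"
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.t, dtype=float)
        if arr.ndim != 4 or arr.shape[2] != arr.shape[3]:
            raise ValueError("t must be (subjects, channels, T, T)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("t-maps must be finite")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        self.t = arr


@dataclass
class ClusterResult:
    """Labeled supra-threshold clusters with permutation p-values.

    ``labels_pos``/``labels_neg`` assign a cluster id (> 0) to each sample
    of the channel x T x T volume, separately per sign. ``clusters`` holds
    one record per cluster: id, sign, mass (summed t), sample count,
    channel set and p-value. ``ref_pos``/``ref_neg`` are the permutation
    reference distributions of the extreme cluster masses (the observed
    labeling counts as one draw).
    """

    labels_pos: np.ndarray
    labels_neg: np.ndarray
    clusters: list[dict]
    ref_pos: np.ndarray
    ref_neg: np.ndarray
    n_permutations: int
    sample_threshold: float
    sample_alpha: float
    cluster_alpha: float
    seed: int | None = None
    group_tmap: np.ndarray | None = None

    def significant(self, alpha: float | None = None) -> list[dict]:
        a = self.cluster_alpha if alpha is None else alpha
        return [c for c in self.clusters if c["p_value"] < a]

    def mask(self, alpha: float | None = None) -> np.ndarray:
        """Union of significant clusters of both signs (channel x T x T bool)."""
        m = np.zeros(self.labels_pos.shape, dtype=bool)
        for c in self.significant(alpha):
            lab = self.labels_pos if c["sign"] > 0 else self.labels_neg
            m |= lab == c["id"]
        return m


@dataclass
class SpecificitySummary:
    """Per-subject mean similarity inside the significant-cluster mask.

    ``specificity`` is exactly ``mean_within_item_z - mean_within_category_z``
    per subject (item specificity delta).
    """

    subject_ids: tuple[str, ...]
    mean_within_item_z: np.ndarray
    mean_within_category_z: np.ndarray
    specificity: np.ndarray
    group: str
    n_mask_samples: int
    significant_cluster_ids: tuple = ()


class NoSignificantClusters(RuntimeError):
    """No cluster survived; there is no mask to extract similarity from."""


# ---------------------------------------------------------------------------
# first level


def first_level_tmap(
    wi: SimilarityTensor, wc: SimilarityTensor
) -> tuple[np.ndarray, int]:
    """Paired t-map contrasting within-item vs within-category similarity.

    Units (categories) are intersected between the two tensors; at each
    (channel, t1, t2) sample the paired t over the C_used category
    differences d_c = z_wi - z_wc is returned, df = C_used - 1. Samples
    with zero mean and zero spread get t = 0.
    """
    common = sorted(set(wi.unit_ids) & set(wc.unit_ids))
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 shared categories for a paired t-map, got {len(common)}"
        )
    ia = [wi.unit_ids.index(u) for u in common]
    ib = [wc.unit_ids.index(u) for u in common]
    d = wi.z[ia] - wc.z[ib]  # (C_used, channel, T, T)
    c_used = len(common)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(c_used))
    t[~np.isfinite(t)] = 0.0  # 0/0 convention; sd=0 with mean!=0 also zeroed
    return t, c_used - 1


def first_level_tmaps(
    wi_tensors: list[SimilarityTensor], wc_tensors: list[SimilarityTensor]
) -> TMapStack:
    """Stack first-level t-maps for a group of subjects."""
    if len(wi_tensors) != len(wc_tensors):
        raise ValueError("within-item and within-category tensor lists differ in length")
    maps, dfs, ids = [], [], []
    for wi, wc in zip(wi_tensors, wc_tensors):
        if wi.subject_id != wc.subject_id:
            raise ValueError(
                f"subject mismatch: {wi.subject_id!r} vs {wc.subject_id!r}"
            )
        t, df = first_level_tmap(wi, wc)
        maps.append(t)
        dfs.append(df)
        ids.append(wi.subject_id)
    return TMapStack(
        t=np.stack(maps), df=int(min(dfs)), subject_ids=tuple(ids)
    )


# ---------------------------------------------------------------------------
# adjacency


def build_adjacency(
    channels: ChannelTable,
    mode: str = "distance_threshold",
    param: float | str | Path | list | None = None,
) -> Adjacency:
    """Channel neighborhood graph.

    ``distance_threshold``: channels are neighbors iff the Euclidean
    distance between their positions is <= ``param``. ``explicit_list``:
    ``param`` is a list of (label_a, label_b) pairs, or a path to a text
    file with one whitespace-separated pair per line.
    """
    if mode == "distance_threshold":
        if channels.positions is None:
            raise ValueError("distance_threshold adjacency needs channel positions")
        thr = float(param)
        pos = channels.positions
        n = len(channels)
        pairs = []
        for i in range(n):
            d = np.linalg.norm(pos[i + 1 :] - pos[i], axis=1)
            for off in np.flatnonzero(d <= thr):
                pairs.append((i, i + 1 + int(off)))
        return Adjacency(channels.labels, tuple(pairs), source=mode, threshold=thr)
    if mode == "explicit_list":
        if isinstance(param, (str, Path)):
            entries = []
            for line in Path(param).read_text().splitlines():
                line = line.strip()
                if line and not line.startswith("#"):
                    a, b = line.split()
                    entries.append((a, b))
        else:
            entries = list(param)
        index = {lab: i for i, lab in enumerate(channels.labels)}
        missing = {a for a, b in entries for a in (a, b)} - set(index)
        if missing:
            raise ValueError(f"adjacency references unknown channels {sorted(missing)}")
        pairs = tuple((index[a], index[b]) for a, b in entries)
        return Adjacency(channels.labels, pairs, source=mode)
    raise ValueError(f"unknown adjacency mode {mode!r}")


# ---------------------------------------------------------------------------
# cluster formation


def _label_volume(
    mask: np.ndarray, values: np.ndarray, neighbor_lists: list[list[int]]
) -> tuple[np.ndarray, list[dict]]:
    """Connected components of a (channel, T, T) boolean volume.

    Within a channel, samples connect via 4-neighborhood in the (t1, t2)
    plane; across channels, the same (t1, t2) sample connects neighboring
    channels. Returns a label volume (0 = background, clusters numbered
    from 1 by decreasing |mass|) and per-cluster records.
    """
    n_ch = mask.shape[0]
    labels = np.zeros(mask.shape, dtype=np.int64)
    offset = 0
    n_per_channel = []
    for c in range(n_ch):
        lab, n = ndimage.label(mask[c], structure=_PLANE_STRUCTURE)
        labels[c] = np.where(lab > 0, lab + offset, 0)
        n_per_channel.append(n)
        offset += n

    # union-find over provisional labels to merge across neighboring channels
    parent = np.arange(offset + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for c, nbrs in enumerate(neighbor_lists):
        for d in nbrs:
            if d <= c:
                continue
            both = mask[c] & mask[d]
            if not both.any():
                continue
            la = labels[c][both]
            lb = labels[d][both]
            for x, y in set(zip(la.tolist(), lb.tolist())):
                union(x, y)

    if offset:
        roots = np.array([find(x) for x in range(offset + 1)])
        labels = roots[labels]

    ids = np.unique(labels)
    ids = ids[ids > 0]
    records = []
    for cid in ids:
        sel = labels == cid
        records.append(
            {
                "id": int(cid),
                "mass": float(values[sel].sum()),
                "n_samples": int(sel.sum()),
                "channels": tuple(int(c) for c in np.unique(np.nonzero(sel)[0])),
            }
        )
    # renumber by decreasing |mass| for stable reporting
    records.sort(key=lambda r: -abs(r["mass"]))
    remap = np.zeros(int(labels.max()) + 1 if records else 1, dtype=np.int64)
    for new_id, r in enumerate(records, start=1):
        remap[r["id"]] = new_id
        r["id"] = new_id
    labels = remap[labels]
    return labels, records


def find_clusters(
    stat_map: np.ndarray, sample_threshold: float, adjacency: Adjacency
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Label supra-threshold clusters of a (channel, T, T) statistic map.

    Positive (t > threshold) and negative (t < -threshold) samples are
    clustered separately. Returns (labels_pos, labels_neg, clusters) with
    each cluster's summed-t mass.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.ndim != 3:
        raise ValueError("stat_map must be (channel, T, T)")
    if stat_map.shape[0] != len(adjacency.labels):
        raise ValueError("stat_map channel axis does not match adjacency")
    nbrs = adjacency.neighbor_lists()
    labels_pos, rec_pos = _label_volume(stat_map > sample_threshold, stat_map, nbrs)
    labels_neg, rec_neg = _label_volume(stat_map < -sample_threshold, stat_map, nbrs)
    clusters = [dict(r, sign=+1) for r in rec_pos] + [dict(r, sign=-1) for r in rec_neg]
    return labels_pos, labels_neg, clusters


# ---------------------------------------------------------------------------
# second level: sign-flip permutation test


def _one_sample_tmap(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _independent_tmap(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t map over the subject axes of a and b."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    t[~np.isfinite(t)] = 0.0
    return t


def _extreme_masses(
    tmap: np.ndarray, threshold: float, nbrs: list[list[int]]
) -> tuple[float, float]:
    _, rec_pos = _label_volume(tmap > threshold, tmap, nbrs)
    _, rec_neg = _label_volume(tmap < -threshold, tmap, nbrs)
    max_pos = max((r["mass"] for r in rec_pos), default=0.0)
    min_neg = min((r["mass"] for r in rec_neg), default=0.0)
    return max_pos, min_neg


def cluster_permutation_test(
    tmaps: TMapStack,
    adjacency: Adjacency,
    n_perm: int = 500,
    cluster_alpha: float = 0.025,
    sample_alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    mode: str = "sign_flip",
) -> ClusterResult:
    """Cluster-based Monte-Carlo test of first-level t-maps against zero.

    The observed statistic map is the one-sample t of the subject maps
    versus 0 (df = n_subjects - 1); clusters are formed at the two-sided
    critical value for ``sample_alpha``. The null is built by randomly
    sign-flipping whole subject maps (``mode='sign_flip'``), recording the
    maximum positive and minimum negative cluster mass per draw. The
    observed labeling counts as one of the ``n_perm`` draws, so p-values
    are k / n_perm with k >= 1 (floor 1/n_perm; 0.002 at 500 draws).
    Clusters with p < ``cluster_alpha`` per tail are significant.

    ``mode='zero_group'`` instead contrasts the subject maps against an
    equal-sized all-zero group with an independent-samples t and permutes
    the group assignment — the construction some toolboxes use to phrase a
    one-sample test in independent-samples machinery.
    """
    if tmaps.t.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 1.0 / cluster_alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot reject at cluster_alpha={cluster_alpha} "
            f"(p floor is {1.0 / n_perm:.4g})",
            stacklevel=2,
        )
    if mode not in ("sign_flip", "zero_group"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    maps = tmaps.t
    n_subj = maps.shape[0]
    nbrs = adjacency.neighbor_lists()

    if mode == "sign_flip":
        df = n_subj - 1
        observed_map = _one_sample_tmap(maps)
    else:
        zeros = np.zeros_like(maps)
        df = 2 * n_subj - 2
        observed_map = _independent_tmap(maps, zeros)
    threshold = float(stats.t.ppf(1 - sample_alpha / 2, df))

    labels_pos, labels_neg, clusters = find_clusters(observed_map, threshold, adjacency)

    ref_pos = np.empty(n_perm)
    ref_neg = np.empty(n_perm)
    # draw 0 is the observed labeling itself
    ref_pos[0], ref_neg[0] = _extreme_masses(observed_map, threshold, nbrs)
    for k in range(1, n_perm):
        if mode == "sign_flip":
            signs = rng.choice([-1.0, 1.0], size=n_subj)
            perm_map = _one_sample_tmap(signs[:, None, None, None] * maps)
        else:
            both = np.concatenate([maps, zeros], axis=0)
            order = rng.permutation(2 * n_subj)
            perm_map = _independent_tmap(both[order[:n_subj]], both[order[n_subj:]])
        ref_pos[k], ref_neg[k] = _extreme_masses(perm_map, threshold, nbrs)

    for c in clusters:
        if c["sign"] > 0:
            c["p_value"] = float(np.count_nonzero(ref_pos >= c["mass"])) / n_perm
        else:
            c["p_value"] = float(np.count_nonzero(ref_neg <= c["mass"])) / n_perm

    return ClusterResult(
        labels_pos=labels_pos,
        labels_neg=labels_neg,
        clusters=clusters,
        ref_pos=ref_pos,
        ref_neg=ref_neg,
        n_permutations=n_perm,
        sample_threshold=threshold,
        sample_alpha=sample_alpha,
        cluster_alpha=cluster_alpha,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        group_tmap=observed_map,
    )


# ---------------------------------------------------------------------------
# third level


def extract_cluster_means(
    group_wi: GroupSimilarity,
    group_wc: GroupSimilarity,
    result: ClusterResult,
    alpha: float | None = None,
) -> SpecificitySummary:
    """Mean similarity of each subject inside the significant-cluster mask.

    The mask is the union over significant clusters of both signs. Raises
    :class:`NoSignificantClusters` when nothing survived, so callers can
    skip downstream group steps with a clear message.
    """
    sig = result.significant(alpha)
    if not sig:
        raise NoSignificantClusters(
            "no cluster below cluster_alpha; there is no volume to average over"
        )
    mask = result.mask(alpha)
    if mask.shape != group_wi.stack.shape[1:]:
        raise ValueError("mask shape does not match similarity stacks")
    if group_wi.stack.shape != group_wc.stack.shape:
        raise ValueError("within-item and within-category stacks differ in shape")
    wi_means = group_wi.stack[:, mask].mean(axis=1)
    wc_means = group_wc.stack[:, mask].mean(axis=1)
    return SpecificitySummary(
        subject_ids=group_wi.subject_ids,
        mean_within_item_z=wi_means,
        mean_within_category_z=wc_means,
        specificity=wi_means - wc_means,
        group=group_wi.group,
        n_mask_samples=int(mask.sum()),
        significant_cluster_ids=tuple((c["sign"], c["id"]) for c in sig),
    )


def compare_groups(spec_a: np.ndarray, spec_b: np.ndarray) -> tuple[float, float]:
    """Two-sided independent-samples Student t-test on item specificity.

    Pooled-variance t with n_a + n_b - 2 df; degenerate zero-variance
    samples with equal means give (t, p) = (0, 1).
    """
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    with warnings.catch_warnings():
        # degenerate zero-variance input is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise FloatingPointError("zero pooled variance with unequal means")
    return t, p
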