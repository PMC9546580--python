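"""Root tip-angle phenotyping from image stacks and trajectory statistics.

Image pipeline (classical, fully deterministic): Otsu threshold, largest
connected component, skeletonization, and a line fit to the terminal
skeleton segment.  Angle convention: the signed angle of the tip's growth
direction relative to the image horizontal, in (-180, 180], with image y
pointing down — a root growing straight down reads 90 degrees.  The seed is
assumed at the top of the frame (kernels are suspended tip-down), so the
tip endpoint is the skeleton endpoint geodesically farthest from the
topmost endpoint.

Trajectory handling mirrors the assay protocol: the angle at the first
retained time is subtracted from the whole series to remove the initial
offset, seedlings are averaged per line (mean +/- SEM), and genotype groups
are compared per time point by one-way ANOVA with Tukey HSD letters
(alpha = 0.1 in the mutant assays) or an equal-variance two-sample t test.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "TipAngleSeries",
    "GroupComparison",
    "NoRootError",
    "segment_root",
    "measure_tip_angle",
    "build_series",
    "subtract_initial",
    "average_by_line",
    "compare_groups",
    "tukey_letters",
]

OK, NO_ROOT, INTERPOLATED, TINY_SKELETON, SUBSTITUTED_T0 = (
    "ok",
    "no_root",
    "interpolated",
    "tiny_skeleton",
    "substituted_t0",
)


class NoRootError(ValueError):
    """Raised when no sufficiently large object is found in a frame."""


@dataclass
class TipAngleSeries:
    """Tip angle (degrees) vs. time (minutes) for one seedling or line mean."""

    seedling_id: str
    line: str
    times: np.ndarray
    angles: np.ndarray  # NaN where missing
    flags: list = field(default_factory=list)
    initial_subtracted: bool = False
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise ValueError("times and angles must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.flags:
            self.flags = [OK if np.isfinite(a) else NO_ROOT for a in self.angles]


@dataclass
class GroupComparison:
    """Per-time-point group means/SEM and test results."""

    method: str
    alpha: float
    means: pd.DataFrame  # groups x times
    sems: pd.DataFrame
    tests: pd.DataFrame  # per test time: statistic, p, letters/decision


# ---------------------------------------------------------------------------
# Image pipeline
# ---------------------------------------------------------------------------

def segment_root(image: np.ndarray, min_area_px: int = 50) -> np.ndarray:
    """Otsu threshold then keep the largest connected component.

    Raises NoRootError when no component reaches ``min_area_px`` (blank or
    hopeless frames are flagged upstream rather than crashing a series).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if np.ptp(img) == 0.0:
        raise NoRootError("blank image")
    mask = img > threshold_otsu(img)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise NoRootError("no foreground object")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area_px:
        raise NoRootError(f"largest component {int(sizes[best - 1])} px < {min_area_px}")
    return labels == best


def _skeleton_adjacency(coords: np.ndarray) -> dict:
    index = {tuple(c): i for i, c in enumerate(coords)}
    adj = {i: [] for i in range(len(coords))}
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    adj[i].append(j)
    return adj


def _bfs_dist(adj: dict, start: int) -> tuple[np.ndarray, dict]:
    dist = np.full(len(adj), -1, dtype=int)
    parent = {start: None}
    dist[start] = 0
    q = deque([start])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                parent[v] = u
                q.append(v)
    return dist, parent


def measure_tip_angle(mask: np.ndarray, px_per_mm: float = 10.0, tail_mm: float = 0.5) -> float:
    """Signed tip angle (deg) of the root's terminal growth direction.

    Skeletonizes the mask and takes the skeleton endpoint geodesically
    farthest from the endpoint nearest the top edge (seed side) as the tip.
    The growth direction is then estimated from the mask alone, at
    sub-pixel precision: the tip apex (centroid of the rounded tip cap)
    minus the centroid of a thin cross-section band one tail-length
    (``tail_mm``) further back along the root.  The local tube half-width
    that sizes the cap and offsets the band comes from the distance
    transform near the tip, so a seed blob elsewhere in the mask cannot
    distort it.  Returns the angle of the tipward direction vector vs. the
    image horizontal with y down, in (-180, 180]: straight-down growth
    reads 90.
    """
    mask = np.asarray(mask, dtype=bool)
    skel = skeletonize(mask)
    coords = np.argwhere(skel)  # (row, col)
    if len(coords) < 3:
        raise NoRootError("skeleton has fewer than 3 pixels")
    adj = _skeleton_adjacency(coords)
    endpoints = [i for i, nb in adj.items() if len(nb) <= 1]
    if not endpoints:  # a loop; fall back to the lowest pixel
        endpoints = [int(np.argmax(coords[:, 0]))]
    seed_end = min(endpoints, key=lambda i: coords[i][0])  # nearest top edge
    dist, parent = _bfs_dist(adj, seed_end)
    reachable = [i for i in endpoints if dist[i] >= 0]
    tip = max(reachable, key=lambda i: dist[i])
    # local half-width from the distance transform just behind the tip cap
    edt = ndimage.distance_transform_edt(mask)
    node, chain = tip, []
    while node is not None and len(chain) < 10:
        chain.append(node)
        node = parent[node]
    half_width = float(max(edt[tuple(coords[c])] for c in chain))
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([ys, xs]).astype(float)
    d2tip = ((pts - coords[tip]) ** 2).sum(axis=1)
    apex = pts[d2tip <= (half_width + 2.0) ** 2].mean(axis=0)
    tail_d = max(tail_mm * px_per_mm, 3.0)
    d = np.sqrt(((pts - apex) ** 2).sum(axis=1))
    lo = tail_d + half_width
    band = pts[(d >= lo) & (d <= lo + 2.0)]
    if len(band) < 2:
        raise NoRootError("terminal segment too short")
    dr, dc = apex - band.mean(axis=0)
    angle = math.degrees(math.atan2(dr, dc))  # y down: down = +90
    if angle <= -180.0:
        angle += 360.0
    return angle


def build_series(
    frames: list,
    times,
    seedling_id: str = "s0",
    line: str = "line0",
    px_per_mm: float = 10.0,
    min_area_px: int = 50,
) -> TipAngleSeries:
    """Measure every frame and assemble a series, patching single-frame gaps.

    ``frames`` may be images (2-D arrays) or already-measured angles/None.
    Frames where segmentation or skeletonization fails are flagged; isolated
    single-frame gaps are linearly interpolated, runs of >= 2 flagged frames
    stay missing.  Fewer than 2 valid frames rejects the series.
    """
    times = np.asarray(times, dtype=float)
    if len(frames) != times.size:
        raise ValueError("frames and times must have the same length")
    angles = np.full(times.size, np.nan)
    flags = []
    for k, fr in enumerate(frames):
        if fr is None:
            flags.append(NO_ROOT)
            continue
        if np.isscalar(fr) or (isinstance(fr, np.ndarray) and fr.ndim == 0):
            angles[k] = float(fr)
            flags.append(OK)
            continue
        try:
            mask = segment_root(np.asarray(fr), min_area_px=min_area_px)
            angles[k] = measure_tip_angle(mask, px_per_mm=px_per_mm)
            flags.append(OK)
        except NoRootError:
            flags.append(NO_ROOT)
    valid = np.isfinite(angles)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid frames")
    # interpolate isolated gaps only
    for k in range(times.size):
        if valid[k]:
            continue
        left_ok = k > 0 and valid[k - 1]
        right_ok = k < times.size - 1 and valid[k + 1]
        if left_ok and right_ok:
            w = (times[k] - times[k - 1]) / (times[k + 1] - times[k - 1])
            angles[k] = (1 - w) * angles[k - 1] + w * angles[k + 1]
            flags[k] = INTERPOLATED
    return TipAngleSeries(seedling_id, line, times, angles, flags)


# ---------------------------------------------------------------------------
# Trajectory handling
# ---------------------------------------------------------------------------

def subtract_initial(series: TipAngleSeries) -> TipAngleSeries:
    """Subtract the t = 0 angle so every response starts at zero.

    Idempotent.  If the first frame is missing, the earliest valid frame is
    used instead and the substitution is flagged.
    """
    if series.initial_subtracted:
        return series
    angles = series.angles.copy()
    flags = list(series.flags)
    valid = np.isfinite(angles)
    if not valid.any():
        raise ValueError("series has no valid frames")
    k0 = int(np.argmax(valid))
    if k0 != 0:
        flags[k0] = SUBSTITUTED_T0
    return replace(
        series,
        angles=angles - angles[k0],
        flags=flags,
        initial_subtracted=True,
    )


def average_by_line(series_list: list, line_of: dict | None = None):
    """Per-line pointwise mean and SEM over seedlings.

    ``line_of`` optionally remaps seedling id -> line.  Missing values are
    excluded pairwise; SEM = SD/sqrt(n) with ddof=1, missing where n < 2.
    Returns a dict line -> TipAngleSeries (mean, with ``sem`` attached).
    """
    groups: dict = {}
    for s in series_list:
        line = line_of.get(s.seedling_id, s.line) if line_of else s.line
        groups.setdefault(line, []).append(s)
    out = {}
    for line, members in groups.items():
        times = members[0].times
        for m in members[1:]:
            if not np.array_equal(m.times, times):
                raise ValueError(f"time grids differ within line {line}")
        mat = np.vstack([m.angles for m in members])
        n = np.isfinite(mat).sum(axis=0)
        import warnings as _warnings

        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(np.where(np.isfinite(mat), mat, np.nan), axis=0)
            sd = np.nanstd(mat, axis=0, ddof=1)
        sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        out[line] = TipAngleSeries(
            seedling_id=f"mean:{line}",
            line=line,
            times=times,
            angles=mean,
            initial_subtracted=all(m.initial_subtracted for m in members),
            sem=sem,
        )
    return out


# ---------------------------------------------------------------------------
# Group comparison statistics
# ---------------------------------------------------------------------------

def tukey_letters(groups: list, reject: dict) -> dict:
    """Compact letter display from pairwise Tukey decisions.

    ``reject[(a, b)]`` is True when groups a and b differ significantly.
    Groups sharing a letter are not significantly different (insert-and-
    absorb algorithm).
    """
    letters_sets = [set(groups)]
    for (a, b), rej in reject.items():
        if not rej:
            continue
        for s in list(letters_sets):
            if a in s and b in s:
                letters_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                if not any(sa <= t for t in letters_sets):
                    letters_sets.append(sa)
                if not any(sb <= t for t in letters_sets):
                    letters_sets.append(sb)
    # absorb subsets
    letters_sets = [s for s in letters_sets if not any(s < t for t in letters_sets)]
    letters_sets.sort(key=lambda s: sorted(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letters_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def _values_at_time(series_list: list, t: float) -> np.ndarray:
    vals = []
    for s in series_list:
        k = int(np.argmin(np.abs(s.times - t)))
        if np.isfinite(s.angles[k]):
            vals.append(s.angles[k])
    return np.asarray(vals, dtype=float)


def compare_groups(
    group_series: dict,
    test_times,
    alpha: float = 0.1,
    method: str = "anova_tukey",
) -> GroupComparison:
    """Per-time-point group comparison of tip-angle trajectories.

    ``group_series`` maps group label -> list of TipAngleSeries.  At each
    test time the seedling values are compared by one-way ANOVA with Tukey
    HSD letters, or (for exactly two groups) an equal-variance two-sample
    t test.  All-zero within-group variance is handled exactly: p = 1 when
    the means tie, else p = 0.
    """
    names = list(group_series)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if method == "ttest" and len(names) != 2:
        raise ValueError("ttest method requires exactly 2 groups")
    for g, members in group_series.items():
        if len(members) < 2:
            raise ValueError(f"group {g} has fewer than 2 seedlings")

    all_times = group_series[names[0]][0].times
    means = pd.DataFrame(
        {
            g: np.nanmean(np.vstack([s.angles for s in group_series[g]]), axis=0)
            for g in names
        },
        index=all_times,
    ).T
    sems = pd.DataFrame(
        {
            g: stats.sem(np.vstack([s.angles for s in group_series[g]]), axis=0, nan_policy="omit")
            for g in names
        },
        index=all_times,
    ).T

    rows = []
    for t in np.atleast_1d(np.asarray(test_times, dtype=float)):
        samples = [_values_at_time(group_series[g], t) for g in names]
        if any(v.size < 2 for v in samples):
            continue
        degenerate = all(v.std(ddof=1) == 0.0 for v in samples)
        if method == "ttest":
            a, b = samples
            if degenerate:
                stat = math.inf if a.mean() != b.mean() else 0.0
                p = 0.0 if a.mean() != b.mean() else 1.0
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append({"time": t, "statistic": float(stat), "p": float(p),
                         "significant": p < alpha, "letters": None})
        else:
            if degenerate:
                distinct = len({v.mean() for v in samples}) > 1
                stat = math.inf if distinct else 0.0
                p = 0.0 if distinct else 1.0
                reject = {
                    (a, b): samples[i].mean() != samples[j].mean()
                    for i, a in enumerate(names)
                    for j, b in enumerate(names)
                    if i < j
                }
            else:
                stat, p = stats.f_oneway(*samples)
                tk = stats.tukey_hsd(*samples)
                reject = {
                    (names[i], names[j]): tk.pvalue[i, j] < alpha
                    for i in range(len(names))
                    for j in range(len(names))
                    if i < j
                }
            letters = tukey_letters(names, reject)
            rows.append({"time": t, "statistic": float(stat), "p": float(p),
                         "significant": p < alpha,
                         "letters": ";".join(f"{g}:{letters[g]}" for g in names)})
    tests = pd.DataFrame(rows)
    return GroupComparison(method=method, alpha=alpha, means=means, sems=sems, tests=tests)
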