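"""Simulated traditional diver transect surveys.

The whole-site image census supplies the conceptual "true" mean cover.
Contiguous 50 x 1 m sections of the dive track are drawn at random
(non-overlapping within a draw), and the disagreement between the sampled
quadrat covers and the site truth is scored as an absolute one-sample
t-value.  Sweeping the number of transects n and repeating each design with
fresh random placements maps how quickly a traditional design converges on
the whole-site value, and how that depends on the site's spatial structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from kelpscape._seeds import as_rng, rng_for
from kelpscape.errors import CapacityError, SiteTooSmallError
from kelpscape.io import SurveyTrack

DEFAULT_LENGTH = 50.0
DEFAULT_MIN_QUADRATS = 5
DEFAULT_T_THRESHOLD = 2.0


@dataclass
class TransectSection:
    """One contiguous along-track section of fixed length."""

    site_id: str
    start_dist: float
    end_dist: float
    indices: np.ndarray  # positional indices into the track
    covers: np.ndarray  # k/m per contained quadrat

    @property
    def n_quadrats(self) -> int:
        return len(self.indices)


def enumerate_candidate_starts(
    track: SurveyTrack, length: float = DEFAULT_LENGTH
) -> list[tuple[float, float]]:
    """Closed intervals of feasible along-track start distances.

    A start s is feasible when the window [s, s + length] lies inside a
    single gap-free track segment.  Raises :class:`SiteTooSmallError` when no
    segment is long enough.
    """
    intervals = []
    for a, b in track.segments():
        seg_lo = float(track.cum_dist[a])
        seg_hi = float(track.cum_dist[b - 1])
        if seg_hi - seg_lo >= length:
            intervals.append((seg_lo, seg_hi - length))
    if not intervals:
        raise SiteTooSmallError(
            f"site {track.site_id}: no gap-free segment of >= {length} m "
            f"(longest segment {max((track.cum_dist[b-1]-track.cum_dist[a]) for a, b in track.segments()):.1f} m)"
        )
    return intervals


def max_feasible_transects(track: SurveyTrack, length: float = DEFAULT_LENGTH) -> int:
    """Upper bound on non-overlapping sections: sum of floor(segment/length)."""
    total = 0
    for a, b in track.segments():
        seg = float(track.cum_dist[b - 1] - track.cum_dist[a])
        total += int(seg // length)
    return total


def _section_at(track: SurveyTrack, start: float, length: float) -> TransectSection:
    # half-open window on cumulative distance; ties at the upper edge go to
    # the following section
    lo = np.searchsorted(track.cum_dist, start, side="left")
    hi = np.searchsorted(track.cum_dist, start + length, side="left")
    idx = np.arange(lo, hi)
    return TransectSection(
        site_id=track.site_id,
        start_dist=float(start),
        end_dist=float(start + length),
        indices=idx,
        covers=track.covers[idx],
    )


def _packed_starts(
    intervals: list[tuple[float, float]],
    n: int,
    length: float,
    rng: np.random.Generator,
) -> list[float] | None:
    """Constructive placement of n non-overlapping sections.

    Sections are allocated to segments sequentially with probability
    proportional to remaining segment capacity, then placed within each
    segment by the order-statistics trick: with n_s sections on a start
    interval of width w, draw n_s sorted uniforms on the slack
    w - (n_s - 1) * length and offset them by multiples of the length —
    an exact uniform sample of the non-overlapping configurations, valid
    down to zero slack (tight packing).
    """
    caps = np.array([int((hi - lo) // length) + 1 for lo, hi in intervals])
    if caps.sum() < n:
        return None
    alloc = np.zeros(len(intervals), dtype=int)
    for _ in range(n):
        remaining = caps - alloc
        probs = remaining / remaining.sum()
        alloc[rng.choice(len(intervals), p=probs)] += 1
    starts: list[float] = []
    for (lo, hi), n_s in zip(intervals, alloc):
        if n_s == 0:
            continue
        slack = (hi - lo) - (n_s - 1) * length
        u = np.sort(rng.uniform(0.0, slack, size=n_s)) if slack > 0 else np.zeros(n_s)
        starts.extend(lo + u + np.arange(n_s) * length)
    return starts


def draw_design(
    track: SurveyTrack,
    n_transects: int,
    length: float = DEFAULT_LENGTH,
    seed=None,
    min_quadrats: int = DEFAULT_MIN_QUADRATS,
    occupied: list[tuple[float, float]] | None = None,
    max_tries_per_section: int = 1000,
) -> list[TransectSection]:
    """Draw ``n_transects`` mutually non-overlapping sections at random over
    the feasible starts.

    Placement is by rejection sampling (uniform over feasible starts) with a
    retry budget; near track capacity, where independent uniform placements
    essentially never avoid each other, a constructive order-statistics
    packing takes over, so any design up to the capacity bound is drawable.
    ``occupied`` optionally carries (start, end) windows from previous draws
    that must also be avoided (the strict no-reuse-across-repeats mode).
    Raises :class:`CapacityError` (reporting the maximum feasible n) when the
    design cannot be placed.
    """
    rng = as_rng(seed)
    intervals = enumerate_candidate_starts(track, length)
    cap = max_feasible_transects(track, length)
    if n_transects > cap:
        raise CapacityError(
            f"site {track.site_id}: cannot place {n_transects} non-overlapping "
            f"{length} m sections (max feasible {cap})",
            max_feasible=cap,
        )
    widths = np.array([hi - lo for lo, hi in intervals])
    # intervals are closed; give zero-width intervals (segment exactly one
    # transect long) a small sampling mass
    probs = (widths + 1e-9) / (widths + 1e-9).sum()

    def _rejection() -> list[TransectSection] | None:
        placed = list(occupied or [])
        secs: list[TransectSection] = []
        budget = max_tries_per_section * n_transects
        tries = 0
        while len(secs) < n_transects:
            if tries >= budget:
                return None
            tries += 1
            i = rng.choice(len(intervals), p=probs)
            lo, hi = intervals[i]
            start = rng.uniform(lo, hi) if hi > lo else lo
            window = (start, start + length)
            if any(window[0] < e and w < window[1] for w, e in placed):
                continue
            sec = _section_at(track, start, length)
            if sec.n_quadrats < min_quadrats:
                continue
            placed.append(window)
            secs.append(sec)
        return secs

    def _packed() -> list[TransectSection] | None:
        for _ in range(50):
            starts = _packed_starts(intervals, n_transects, length, rng)
            if starts is None:
                return None
            secs = [_section_at(track, s, length) for s in starts]
            if any(sec.n_quadrats < min_quadrats for sec in secs):
                continue
            if occupied and any(
                s.start_dist < e and w < s.end_dist for s in secs for w, e in occupied
            ):
                continue
            return secs
        return None

    sections = _rejection() or _packed()
    if sections is None:
        raise CapacityError(
            f"site {track.site_id}: failed to place {n_transects} sections "
            f"(max feasible {cap})",
            max_feasible=cap,
        )
    return sections


def t_statistic(sample_covers: np.ndarray, true_mean: float) -> float:
    """Absolute one-sample t of quadrat covers against the fixed site truth.

    Returns +inf when the sample is constant but off-truth, and 0.0 when it
    is constant and exactly on it.
    """
    x = np.asarray(sample_covers, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 cover values for a t statistic")
    s = x.std(ddof=1)
    diff = abs(x.mean() - true_mean)
    if s == 0:
        return 0.0 if diff == 0 else math.inf
    return float(diff / (s / math.sqrt(len(x))))


def run_design_sweep(
    track: SurveyTrack,
    n_range,
    repeats: int = 5,
    length: float = DEFAULT_LENGTH,
    seed: int = 0,
    true_mean: float | None = None,
    min_quadrats: int = DEFAULT_MIN_QUADRATS,
    pooled: bool = True,
    no_reuse_across_repeats: bool = False,
) -> pd.DataFrame:
    """Sweep designs of n transects over ``n_range`` with ``repeats``
    independent placements each.

    The truth is the mean cover over all site quadrats unless overridden.
    ``pooled=True`` computes t over the pooled quadrat covers of a draw (the
    default; quadrats are the measurement unit); ``pooled=False`` computes t
    over the per-transect mean covers.  n values beyond capacity are skipped
    with a warning.  Returns one tidy row per (n, repeat).
    """
    n_range = list(n_range)
    if not n_range:
        raise ValueError("empty n_range")
    if true_mean is None:
        true_mean = float(track.covers.mean())
    rows = []
    for n in n_range:
        occupied: list[tuple[float, float]] = []
        for rep in range(repeats):
            rng = rng_for(seed, "design", track.site_id, n, rep)
            try:
                sections = draw_design(
                    track,
                    n,
                    length=length,
                    seed=rng,
                    min_quadrats=min_quadrats,
                    occupied=occupied if no_reuse_across_repeats else None,
                )
            except CapacityError as err:
                warnings.warn(
                    f"site {track.site_id}: skipping n={n} repeat {rep}: {err}",
                    stacklevel=2,
                )
                continue
            if no_reuse_across_repeats:
                occupied.extend((s.start_dist, s.end_dist) for s in sections)
            if pooled:
                values = np.concatenate([s.covers for s in sections])
            else:
                values = np.array([s.covers.mean() for s in sections])
            t = t_statistic(values, true_mean) if len(values) >= 2 else math.nan
            rows.append(
                {
                    "site_id": track.site_id,
                    "n_transects": n,
                    "repeat": rep,
                    "mean_cover": float(np.mean(values)),
                    "se": float(np.std(values, ddof=1) / math.sqrt(len(values)))
                    if len(values) >= 2
                    else math.nan,
                    "t_value": t,
                    "n_quadrats": int(sum(s.n_quadrats for s in sections)),
                }
            )
    return pd.DataFrame(rows)


def required_transects(
    results: pd.DataFrame, t_threshold: float = DEFAULT_T_THRESHOLD
) -> int | None:
    """Smallest n such that every repeat at n *and at every larger tested n*
    stays below the t threshold; None when never satisfied."""
    if results.empty:
        return None
    ok_by_n = (
        results.assign(ok=results["t_value"] < t_threshold)
        .groupby("n_transects")["ok"]
        .all()
        .sort_index()
    )
    # suffix-AND: n qualifies only if all larger tested n also pass
    ns = ok_by_n.index.to_numpy()
    ok = ok_by_n.to_numpy()
    suffix_ok = np.logical_and.accumulate(ok[::-1])[::-1]
    winners = ns[suffix_ok]
    return int(winners[0]) if len(winners) else None
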