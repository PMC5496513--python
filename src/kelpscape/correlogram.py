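"""Omnidirectional Moran's I correlograms with randomization null envelopes.

Moran's I within successive distance bands describes how similar cover
values are as a function of separation: values near +1 at short lags mean
distinct patches, values near the permutation expectation -1/(n-1) mean
spatial randomness.  The x-intercept of the correlogram — where positive
autocorrelation first vanishes — is an effective patch scale.  The null
envelope is built by recomputing I after randomly reassigning the observed
covers among the fixed quadrat locations (or, optionally, drawing i.i.d.
uniform covers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import pdist

from kelpscape._seeds import as_rng
from kelpscape.errors import (
    DegenerateInputError,
    EmptyBandError,
    InsufficientDataError,
)

DEFAULT_BIN_WIDTH = 5.0
DEFAULT_MAX_DIST = 100.0
DEFAULT_MIN_PAIRS = 30


def distance_band_weights(
    positions: np.ndarray, d_lo: float, d_hi: float
) -> sparse.csr_matrix:
    """Symmetric binary spatial weights: w_ij = 1 iff d_lo <= dist(i,j) < d_hi.

    Raises :class:`EmptyBandError` when no pair falls in the band.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if d_lo >= d_hi:
        raise ValueError("d_lo must be < d_hi")
    d = pdist(positions)
    iu, ju = np.triu_indices(n, k=1)
    mask = (d >= d_lo) & (d < d_hi)
    if not mask.any():
        raise EmptyBandError(f"no pairs at distances [{d_lo}, {d_hi})")
    i, j = iu[mask], ju[mask]
    data = np.ones(2 * len(i))
    w = sparse.csr_matrix(
        (data, (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n)
    )
    return w


def morans_i(values: np.ndarray, weights) -> float:
    """Global Moran's I for a binary (or general) symmetric weight matrix:

        I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise DegenerateInputError("need >= 2 values")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise DegenerateInputError("zero variance in values")
    if sparse.issparse(weights):
        w_sum = float(weights.sum())
        num = float(xc @ (weights @ xc))
    else:
        w = np.asarray(weights, dtype=float)
        w_sum = float(w.sum())
        num = float(xc @ w @ xc)
    if w_sum == 0:
        raise EmptyBandError("weight matrix sums to zero")
    return (n / w_sum) * num / denom


@dataclass
class CorrelogramResult:
    site_id: str
    bin_edges: np.ndarray  # length n_bins + 1, all candidate bins
    midpoints: np.ndarray  # reported bins only
    I: np.ndarray  # Moran's I per reported bin
    pair_count: np.ndarray  # pairs per reported bin
    null_low: np.ndarray | None = None
    null_high: np.ndarray | None = None
    x_intercept: float | None = None

    def to_frame(self) -> pd.DataFrame:
        bw = self.bin_edges[1] - self.bin_edges[0]
        df = pd.DataFrame(
            {
                "site_id": self.site_id,
                "bin_lo": self.midpoints - bw / 2,
                "bin_hi": self.midpoints + bw / 2,
                "midpoint": self.midpoints,
                "I": self.I,
                "pair_count": self.pair_count,
            }
        )
        df["null_low"] = self.null_low if self.null_low is not None else np.nan
        df["null_high"] = self.null_high if self.null_high is not None else np.nan
        df["x_intercept"] = self.x_intercept if self.x_intercept is not None else np.nan
        return df


class _BinnedPairs:
    """Pair indices per distance band, shared by the correlogram and its
    permutation null so pairwise distances are computed once."""

    def __init__(self, positions, bin_width, max_dist):
        positions = np.asarray(positions, dtype=float)
        self.n = len(positions)
        d = pdist(positions)
        iu, ju = np.triu_indices(self.n, k=1)
        edges = np.arange(0.0, max_dist + bin_width, bin_width)
        self.edges = edges
        self.pairs: list[tuple[np.ndarray, np.ndarray]] = []
        which = np.digitize(d, edges) - 1  # bin index; outside -> >= len-1
        for b in range(len(edges) - 1):
            m = which == b
            self.pairs.append((iu[m], ju[m]))

    def morans_per_bin(self, values: np.ndarray, keep: np.ndarray) -> np.ndarray:
        xc = values - values.mean()
        denom = float(xc @ xc)
        out = np.full(len(self.pairs), np.nan)
        for b in np.flatnonzero(keep):
            i, j = self.pairs[b]
            num = 2.0 * float(xc[i] @ xc[j])
            out[b] = (self.n / (2.0 * len(i))) * num / denom
        return out


def _x_intercept(midpoints: np.ndarray, I: np.ndarray) -> float | None:
    """Linear interpolation of the first positive-to-nonpositive crossing."""
    if len(I) == 0 or I[0] <= 0:
        return None
    for b in range(1, len(I)):
        if I[b] <= 0:
            m1, m2 = midpoints[b - 1], midpoints[b]
            return float(m1 + (m2 - m1) * I[b - 1] / (I[b - 1] - I[b]))
    return None


def correlogram(
    positions: np.ndarray,
    values: np.ndarray,
    site_id: str = "",
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_dist: float = DEFAULT_MAX_DIST,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    _pairs: _BinnedPairs | None = None,
) -> CorrelogramResult:
    """Moran's I per half-open distance band [k*bw, (k+1)*bw).

    Bands with fewer than ``min_pairs`` pairs are omitted.  Requires >= 30
    quadrats and at least two reportable bands.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 30:
        raise InsufficientDataError(
            f"site {site_id or '?'}: need >= 30 quadrats, got {len(values)}"
        )
    if values.std() == 0:
        raise DegenerateInputError(f"site {site_id or '?'}: constant cover")
    bp = _pairs or _BinnedPairs(positions, bin_width, max_dist)
    counts = np.array([len(i) for i, _ in bp.pairs])
    keep = counts >= min_pairs
    if keep.sum() < 2:
        raise InsufficientDataError(
            f"site {site_id or '?'}: fewer than 2 bands with >= {min_pairs} pairs"
        )
    I_all = bp.morans_per_bin(values, keep)
    mids = (bp.edges[:-1] + bp.edges[1:]) / 2
    I = I_all[keep]
    midpoints = mids[keep]
    return CorrelogramResult(
        site_id=site_id,
        bin_edges=bp.edges,
        midpoints=midpoints,
        I=I,
        pair_count=counts[keep],
        x_intercept=_x_intercept(midpoints, I),
    )


def null_envelope(
    positions: np.ndarray,
    values: np.ndarray,
    result: CorrelogramResult,
    n_reps: int = 199,
    mode: str = "permute",
    seed=None,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> CorrelogramResult:
    """Attach a randomization null envelope to a correlogram.

    ``permute`` reassigns the observed covers among the fixed locations;
    ``uniform`` draws i.i.d. Uniform(0, 1) covers.  The envelope is the
    (2.5, 97.5) percentile band of I per bin over ``n_reps`` replicates.
    """
    if mode not in ("permute", "uniform"):
        raise ValueError(f"unknown null mode {mode!r}")
    if n_reps < 19:
        warnings.warn(f"n_reps={n_reps} gives coarse percentile estimates", stacklevel=2)
    rng = as_rng(seed)
    values = np.asarray(values, dtype=float)
    bw = result.bin_edges[1] - result.bin_edges[0]
    bp = _BinnedPairs(positions, bw, result.bin_edges[-1])
    counts = np.array([len(i) for i, _ in bp.pairs])
    mids = (bp.edges[:-1] + bp.edges[1:]) / 2
    keep = np.isin(mids, result.midpoints) & (counts > 0)
    sims = np.empty((n_reps, int(keep.sum())))
    for r in range(n_reps):
        sim = rng.permutation(values) if mode == "permute" else rng.uniform(size=len(values))
        sims[r] = bp.morans_per_bin(sim, keep)[keep]
    low = np.percentile(sims, lower_pct, axis=0)
    high = np.percentile(sims, upper_pct, axis=0)
    return replace(result, null_low=low, null_high=high)


def site_correlograms(
    records: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_dist: float = DEFAULT_MAX_DIST,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    n_reps: int = 199,
    null_mode: str = "permute",
    seed: int = 0,
) -> list[CorrelogramResult]:
    """Correlogram + null envelope for every site in a projected quadrat
    table (skipping sites the estimator cannot support)."""
    from kelpscape._seeds import rng_for

    out = []
    for sid, grp in records.groupby("site_id", sort=True):
        pos = grp[["x", "y"]].to_numpy(float)
        vals = (grp["k"] / grp["m"]).to_numpy(float)
        try:
            res = correlogram(
                pos, vals, site_id=str(sid), bin_width=bin_width,
                max_dist=max_dist, min_pairs=min_pairs,
            )
            res = null_envelope(
                pos, vals, res, n_reps=n_reps, mode=null_mode,
                seed=rng_for(seed, "null", sid),
            )
        except (InsufficientDataError, DegenerateInputError) as err:
            warnings.warn(f"skipping correlogram for site {sid}: {err}", stacklevel=2)
            continue
        out.append(res)
    return out
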