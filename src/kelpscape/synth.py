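"""Synthetic multi-site photo-quadrat surveys with controlled spatial structure.

Each site is generated as: (1) a dive track of quadrat positions with
realistic along-track spacing; (2) a zero-mean latent Gaussian field over
the positions with exponential covariance

    C(h) = sill * exp(-h / range_m) + nugget * 1{h = 0}

controlling how patchy the cover is; (3) cover probabilities
p = logit^-1(alpha + beta_depth * depth + z); and (4) per-quadrat binomial
point counts k out of m (default 25) with optional symmetric per-point
classifier label error.  Generative truth (true p per quadrat and all site
parameters) is retained separately so parameter-recovery tests can compare
estimates against it; analysis modules never read it.

The bundled ``paperlike`` preset emulates a dense multi-site harbour survey:
8 sites of 735 quadrats (5,880 in total), site mean covers spanning
2%-38%, two spatially near-random sites and six patchy ones with
correlation ranges of 15-40 m.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit, logit, roots_hermitenorm

from kelpscape import io as kio
from kelpscape._seeds import as_rng, rng_for
from kelpscape.errors import ConfigError
from kelpscape.raster import EnvironmentRasters, Raster

#: default survey origin (lon, lat) for mapping planar meters back to
#: geographic coordinates; any temperate-coast origin works.
DEFAULT_ORIGIN = (151.25, -33.84)


@dataclass
class SiteConfig:
    """Generative parameters for one synthetic site."""

    site_id: str
    n_quadrats: int
    spacing_mean: float = 3.8  # m, mean along-track quadrat spacing
    spacing_sd: float = 1.0
    track_style: str = "meander"  # or "straight"
    alpha: float = 0.0  # logit-scale intercept
    range_m: float = 20.0  # exponential-covariance correlation range
    sill: float = 1.0  # structured latent variance
    nugget: float = 0.1  # uncorrelated latent variance
    beta_depth: float = 0.0  # logit-scale effect per meter of depth
    m_points: int = 25
    label_error: float = 0.0  # per-point symmetric misclassification rate
    target_cover: float | None = None  # if set, alpha is calibrated to it

    def __post_init__(self):
        if self.n_quadrats < 2:
            raise ConfigError(f"{self.site_id}: n_quadrats must be >= 2")
        if self.spacing_mean <= 0:
            raise ConfigError(f"{self.site_id}: spacing_mean must be positive")
        if self.spacing_sd < 0:
            raise ConfigError(f"{self.site_id}: spacing_sd must be >= 0")
        if self.track_style not in ("straight", "meander"):
            raise ConfigError(f"{self.site_id}: unknown track_style {self.track_style!r}")
        if self.range_m < 0 or self.sill < 0 or self.nugget < 0:
            raise ConfigError(f"{self.site_id}: range_m, sill, nugget must be >= 0")
        if not 0 <= self.label_error < 0.5:
            raise ConfigError(f"{self.site_id}: label_error must be in [0, 0.5)")
        if self.m_points < 1:
            raise ConfigError(f"{self.site_id}: m_points must be >= 1")


def generate_track(config: SiteConfig, seed) -> pd.DataFrame:
    """Quadrat positions (x, y, track_order) along a simulated dive track.

    Spacings are gamma-distributed with the configured mean and sd (constant
    when sd = 0); a ``meander`` track follows a smooth heading random walk,
    a ``straight`` track a fixed heading.
    """
    rng = as_rng(seed)
    n = config.n_quadrats
    if config.spacing_sd == 0:
        spacing = np.full(n - 1, config.spacing_mean)
    else:
        shape = (config.spacing_mean / config.spacing_sd) ** 2
        scale = config.spacing_sd**2 / config.spacing_mean
        spacing = rng.gamma(shape, scale, size=n - 1)
    if config.track_style == "straight":
        heading = np.zeros(n - 1)
    else:
        h0 = rng.uniform(0, 2 * np.pi)
        heading = h0 + np.cumsum(rng.normal(0.0, 0.25, size=n - 1))
    dx = spacing * np.cos(heading)
    dy = spacing * np.sin(heading)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    return pd.DataFrame({"x": x, "y": y, "track_order": np.arange(n)})


def generate_latent_field(
    x: np.ndarray,
    y: np.ndarray,
    range_m: float,
    sill: float,
    nugget: float,
    seed,
    max_n: int = 5000,
) -> np.ndarray:
    """Exact simulation of the latent Gaussian field at the given positions.

    Dense Cholesky factorization of C(h) = sill*exp(-h/range_m) + nugget*I;
    adequate up to a few thousand positions per site.  range_m = 0 degrades
    to pure (sill + nugget) white noise.
    """
    rng = as_rng(seed)
    n = len(x)
    if n > max_n:
        raise ConfigError(f"{n} positions exceed the dense-factorization limit {max_n}")
    if sill == 0 and nugget == 0:
        return np.zeros(n)
    if sill == 0 or range_m == 0:
        return rng.normal(0.0, math.sqrt(sill + nugget), size=n)
    pts = np.column_stack([x, y])
    h = squareform(pdist(pts))
    cov = sill * np.exp(-h / range_m)
    cov[np.diag_indices(n)] += nugget
    jitter = 0.0
    for attempt in range(4):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * (sill + nugget))
    else:  # pragma: no cover - pathological inputs only
        evals = np.linalg.eigvalsh(cov)
        raise ConfigError(
            "latent covariance not positive definite after jitter "
            f"(min eigenvalue {evals.min():.3e}, max {evals.max():.3e})"
        )
    return chol @ rng.standard_normal(n)


def cover_probabilities(
    z: np.ndarray, depth: np.ndarray, alpha: float, beta_depth: float
) -> np.ndarray:
    """p = logit^-1(alpha + beta_depth*depth + z), elementwise in (0, 1)."""
    return expit(alpha + beta_depth * np.asarray(depth, float) + np.asarray(z, float))


def observed_probability(p, label_error: float):
    """Per-point probability of an observed focal-taxon label after symmetric
    misclassification at rate ``label_error``."""
    p = np.asarray(p, dtype=float)
    return p * (1 - label_error) + (1 - p) * label_error


def sample_counts(p: np.ndarray, m_points: int, label_error: float, seed) -> np.ndarray:
    """Binomial point counts k ~ Bin(m, p*(1-e) + (1-p)*e) per quadrat.

    Flipping each of the m point labels independently with probability e is
    exactly equivalent to a single binomial draw at the flipped probability.
    """
    if not 0 <= label_error < 0.5:
        raise ConfigError("label_error must be in [0, 0.5)")
    rng = as_rng(seed)
    return rng.binomial(m_points, observed_probability(p, label_error))


# -- alpha calibration ------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = roots_hermitenorm(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def expected_cover(alpha: float, offsets: np.ndarray, latent_sd: float) -> float:
    """Mean cover E[logit^-1(alpha + offset_i + Z)], Z ~ N(0, latent_sd^2),
    averaged over the per-quadrat fixed offsets (e.g. beta_depth * depth_i),
    by Gauss-Hermite quadrature."""
    eta = alpha + np.add.outer(np.atleast_1d(np.asarray(offsets, float)), latent_sd * _GH_NODES)
    return float((expit(eta) @ _GH_WEIGHTS).mean())


def calibrate_alpha(target_cover: float, offsets: np.ndarray, latent_sd: float = 0.0) -> float:
    """Intercept alpha such that the site mean cover equals ``target_cover``.

    ``offsets`` are the per-quadrat non-intercept contributions to the logit
    (depth effect, and the realized latent field when calibrating a concrete
    site); ``latent_sd`` > 0 additionally marginalizes over an unrealized
    N(0, latent_sd^2) component by Gauss-Hermite quadrature."""
    if not 0 < target_cover < 1:
        raise ConfigError("target_cover must be in (0, 1)")
    f = lambda a: expected_cover(a, offsets, latent_sd) - target_cover
    lo, hi = logit(target_cover) - 12, logit(target_cover) + 12
    return float(brentq(f, lo, hi, xtol=1e-10))


# -- environment ------------------------------------------------------------


def generate_environment(
    tracks: dict[str, pd.DataFrame],
    resolution: float = 5.0,
    seed=None,
    reef_buffer: float = 15.0,
    margin: float = 30.0,
) -> EnvironmentRasters:
    """Bathymetry and reef-mask grids consistent with the generated tracks.

    Bathymetry is a smooth onshore-offshore gradient (shoreline along the
    northern edge) plus low-amplitude smooth variation; the reef mask is a
    corridor of width ``reef_buffer`` around the surveyed positions.
    """
    rng = as_rng(seed)
    all_x = np.concatenate([t["x"].to_numpy(float) for t in tracks.values()])
    all_y = np.concatenate([t["y"].to_numpy(float) for t in tracks.values()])
    if len(all_x) == 0:
        raise ConfigError("no track positions supplied")
    xmin = math.floor((all_x.min() - margin) / resolution) * resolution
    ymin = math.floor((all_y.min() - margin) / resolution) * resolution
    xmax = math.ceil((all_x.max() + margin) / resolution) * resolution
    ymax = math.ceil((all_y.max() + margin) / resolution) * resolution
    if xmax <= xmin or ymax <= ymin:
        raise ConfigError("degenerate raster extent")
    ncols = int(round((xmax - xmin) / resolution))
    nrows = int(round((ymax - ymin) / resolution))
    template = Raster(xmin, ymin, resolution, np.zeros((nrows, ncols)))
    X, Y = template.cell_centers()

    # gently shoaling toward the northern (ymax) "shoreline"; ~0.03 m/m slope
    depth = 1.5 + 0.03 * (ymax - Y)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    wavelens = rng.uniform(120.0, 400.0, size=2)
    depth = depth + 0.8 * np.sin(2 * np.pi * X / wavelens[0] + phases[0]) * np.cos(
        2 * np.pi * Y / wavelens[1] + phases[1]
    )
    depth = depth + 0.4 * np.sin(2 * np.pi * (X + Y) / 180.0 + phases[2])
    depth = np.clip(depth, 0.5, None)

    tree = cKDTree(np.column_stack([all_x, all_y]))
    dist, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]), k=1)
    reef = (dist.reshape(X.shape) <= reef_buffer).astype(float)

    return EnvironmentRasters(
        bathymetry=template.copy_with(depth),
        reef_mask=template.copy_with(reef),
    )


# -- whole-study generation -------------------------------------------------


@dataclass
class StudyTruth:
    """Generative ground truth, stored apart from the survey data."""

    quadrats: pd.DataFrame  # quadrat_id, site_id, p_true
    sites: pd.DataFrame  # one row per site: parameters + realized summaries

    def write(self, directory, prefix: str = "truth_") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.quadrats.to_csv(directory / f"{prefix}quadrats.csv", index=False, float_format="%.9g")
        self.sites.to_csv(directory / f"{prefix}sites.csv", index=False, float_format="%.9g")

    @classmethod
    def read(cls, directory, prefix: str = "truth_") -> "StudyTruth":
        directory = Path(directory)
        return cls(
            quadrats=pd.read_csv(directory / f"{prefix}quadrats.csv"),
            sites=pd.read_csv(directory / f"{prefix}sites.csv"),
        )


def generate_study(
    configs: list[SiteConfig],
    seed: int,
    resolution: float = 5.0,
    site_offset_m: float = 400.0,
    origin: tuple[float, float] = DEFAULT_ORIGIN,
    altitude_outlier_rate: float = 0.04,
) -> tuple[pd.DataFrame, EnvironmentRasters, StudyTruth]:
    """Generate a full multi-site survey: records, rasters and truth.

    Sites are laid out along the coast at ``site_offset_m`` intervals.  Camera
    altitudes are mostly within the usable window with a small fraction of
    out-of-range outliers so the QC stage has work to do.  Records carry
    lon/lat (via the local projection about ``origin``) and planar x/y.
    """
    if len(configs) == 0:
        raise ConfigError("at least one SiteConfig required")
    ids = [c.site_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate site_id in configs")

    tracks: dict[str, pd.DataFrame] = {}
    for i, cfg in enumerate(configs):
        t = generate_track(cfg, rng_for(seed, "track", cfg.site_id))
        t["x"] = t["x"] + i * site_offset_m
        tracks[cfg.site_id] = t

    env = generate_environment(tracks, resolution=resolution, seed=rng_for(seed, "environment"))

    frames = []
    truth_q = []
    truth_s = []
    for cfg in configs:
        t = tracks[cfg.site_id]
        x = t["x"].to_numpy(float)
        y = t["y"].to_numpy(float)
        depth = env.bathymetry.sample(x, y)
        z = generate_latent_field(
            x, y, cfg.range_m, cfg.sill, cfg.nugget, rng_for(seed, "field", cfg.site_id)
        )
        if cfg.target_cover is not None:
            # calibrate against the realized field so the site mean cover
            # hits the target exactly (up to binomial sampling noise)
            alpha = calibrate_alpha(cfg.target_cover, cfg.beta_depth * depth + z)
        else:
            alpha = cfg.alpha
        p = cover_probabilities(z, depth, alpha, cfg.beta_depth)
        k = sample_counts(p, cfg.m_points, cfg.label_error, rng_for(seed, "counts", cfg.site_id))

        rng_alt = rng_for(seed, "altitude", cfg.site_id)
        alt = rng_alt.uniform(0.6, 4.5, size=cfg.n_quadrats)
        outlier = rng_alt.random(cfg.n_quadrats) < altitude_outlier_rate
        n_out = int(outlier.sum())
        if n_out:
            low = rng_alt.random(n_out) < 0.5
            alt_out = np.where(
                low, rng_alt.uniform(0.05, 0.39, n_out), rng_alt.uniform(5.01, 7.0, n_out)
            )
            alt[outlier] = alt_out

        lon, lat = kio.unproject_coordinates(x, y, origin)
        qid = [f"{cfg.site_id}_q{j:04d}" for j in range(cfg.n_quadrats)]
        frames.append(
            pd.DataFrame(
                {
                    "quadrat_id": qid,
                    "site_id": cfg.site_id,
                    "lon": lon,
                    "lat": lat,
                    "x": x,
                    "y": y,
                    "altitude_m": alt,
                    "k": k,
                    "m": cfg.m_points,
                    "depth_m": depth,
                    "reef": True,
                    "track_order": t["track_order"].to_numpy(),
                }
            )
        )
        truth_q.append(pd.DataFrame({"quadrat_id": qid, "site_id": cfg.site_id, "p_true": p}))
        row = dataclasses.asdict(cfg)
        row["alpha_used"] = alpha
        row["mean_p_true"] = float(p.mean())
        row["mean_cover_obs"] = float((k / cfg.m_points).mean())
        truth_s.append(row)

    records = pd.concat(frames, ignore_index=True)
    truth = StudyTruth(quadrats=pd.concat(truth_q, ignore_index=True), sites=pd.DataFrame(truth_s))
    return records, env, truth


# -- presets ----------------------------------------------------------------


def paperlike_configs() -> list[SiteConfig]:
    """Eight-site preset emulating a dense temperate-harbour kelp survey:
    735 quadrats per site (5,880 total), target mean covers 2%-38%, two
    spatially near-random sites and six patchy sites (ranges 15-40 m).

    Per-point label error is left off here: a symmetric flip rate e floors
    the observable mean cover at e, which would contradict a 2%-cover site;
    classifier noise stays available via ``label_error`` for studies whose
    site means exceed it."""
    covers = [0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.38]
    # near-random sites: the low-cover site and one mid-cover site
    ranges = [1.0, 15.0, 20.0, 1.0, 25.0, 30.0, 35.0, 40.0]
    sills = [0.3, 1.2, 1.2, 0.3, 1.2, 1.2, 1.2, 1.2]
    nuggets = [0.3, 0.2, 0.2, 0.3, 0.2, 0.2, 0.2, 0.2]
    configs = []
    for i, (cov, rng_m, sill, nug) in enumerate(zip(covers, ranges, sills, nuggets), start=1):
        configs.append(
            SiteConfig(
                site_id=f"S{i}",
                n_quadrats=735,
                spacing_mean=3.8,
                spacing_sd=1.0,
                track_style="meander",
                target_cover=cov,
                range_m=rng_m,
                sill=sill,
                nugget=nug,
                beta_depth=-0.08,
                m_points=25,
                label_error=0.0,
            )
        )
    return configs


PRESETS = {"paperlike": paperlike_configs}


def configs_from_file(path) -> list[SiteConfig]:
    """Read site configs from a plain-text INI-style file (one section per
    site; keys match :class:`SiteConfig` fields)."""
    import configparser

    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    configs = []
    for section in parser.sections():
        kwargs: dict = {"site_id": section}
        for key, val in parser[section].items():
            if key == "site_id":
                kwargs["site_id"] = val
            elif key in ("n_quadrats", "m_points"):
                kwargs[key] = int(val)
            elif key == "track_style":
                kwargs[key] = val
            elif key == "target_cover" and val.lower() in ("", "none"):
                continue
            else:
                kwargs[key] = float(val)
        configs.append(SiteConfig(**kwargs))
    if not configs:
        raise ConfigError(f"no site sections found in {path}")
    return configs


def configs_to_file(configs: list[SiteConfig], path) -> None:
    import configparser

    parser = configparser.ConfigParser()
    for cfg in configs:
        d = dataclasses.asdict(cfg)
        sid = d.pop("site_id")
        parser[sid] = {k: repr(v) if not isinstance(v, str) else v for k, v in d.items() if v is not None}
    with open(path, "w") as fh:
        parser.write(fh)
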