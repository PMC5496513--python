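"""Summary figures for a completed pipeline run.

Draws the four standard panels from the run directory's tables: t-value
vs number of transects per site (with the t = 2 reference), per-site
correlograms with null envelope and x-intercept, the predicted-cover and
standard-error map pair, and the learning curve with its full-data error
reference.  Panels whose stage output is missing are skipped with a notice.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from kelpscape.raster import Raster


def _binned_mean(x: np.ndarray, y: np.ndarray, nbins: int = 12):
    order = np.argsort(x)
    x, y = x[order], y[order]
    edges = np.unique(np.quantile(x, np.linspace(0, 1, nbins + 1)))
    mids, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (x >= lo) & (x <= hi)
        if m.any():
            mids.append(x[m].mean())
            means.append(np.median(y[m]))
    return np.array(mids), np.array(means)


def report(run_dir, out_dir=None) -> list[Path]:
    """Render figures for a run directory; returns the files written."""
    run_dir = Path(run_dir)
    out_dir = Path(out_dir) if out_dir else run_dir / "figures"
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    ts_path = run_dir / "transect_sim.csv"
    if ts_path.exists():
        ts = pd.read_csv(ts_path)
        sites = sorted(ts["site_id"].unique())
        ncols = min(4, len(sites))
        nrows = -(-len(sites) // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False)
        for ax, sid in zip(axes.ravel(), sites):
            sub = ts[ts["site_id"] == sid]
            finite = sub[np.isfinite(sub["t_value"])]
            ax.scatter(finite["n_transects"], finite["t_value"], s=8, alpha=0.4)
            mids, med = _binned_mean(
                finite["n_transects"].to_numpy(float), finite["t_value"].to_numpy(float)
            )
            ax.plot(mids, med, color="gray")
            ax.axhline(2.0, ls=":", color="k")
            ax.set_title(sid, fontsize=9)
            ax.set_xlabel("n transects")
            ax.set_ylabel("|t|")
        for ax in axes.ravel()[len(sites):]:
            ax.axis("off")
        fig.tight_layout()
        p = out_dir / "transect_design.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("transect_sim.csv missing; panel skipped", stacklevel=2)

    corr_path = run_dir / "correlogram.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path)
        sites = sorted(corr["site_id"].unique())
        ncols = min(4, len(sites))
        nrows = -(-len(sites) // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False)
        for ax, sid in zip(axes.ravel(), sites):
            sub = corr[corr["site_id"] == sid].sort_values("midpoint")
            ax.fill_between(sub["midpoint"], sub["null_low"], sub["null_high"], color="0.85")
            ax.plot(sub["midpoint"], sub["I"], marker="o", ms=3)
            xi = sub["x_intercept"].iloc[0]
            if np.isfinite(xi):
                ax.axvline(xi, ls=":", color="k")
            ax.axhline(0, color="0.5", lw=0.5)
            ax.set_title(sid, fontsize=9)
            ax.set_xlabel("distance (m)")
            ax.set_ylabel("Moran's I")
        for ax in axes.ravel()[len(sites):]:
            ax.axis("off")
        fig.tight_layout()
        p = out_dir / "correlograms.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("correlogram.csv missing; panel skipped", stacklevel=2)

    pred_path = run_dir / "prediction.asc"
    if pred_path.exists():
        pred = Raster.read_ascii(pred_path)
        se = Raster.read_ascii(run_dir / "prediction_se.asc")
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
        for ax, r, title in ((ax1, pred, "predicted cover"), (ax2, se, "standard error")):
            data = np.ma.masked_equal(r.data, r.nodata)
            im = ax.imshow(data, extent=(r.xmin, r.xmax, r.ymin, r.ymax), origin="upper")
            fig.colorbar(im, ax=ax, shrink=0.8)
            ax.set_title(title)
        fig.tight_layout()
        p = out_dir / "prediction_maps.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("prediction.asc missing; panel skipped", stacklevel=2)

    lc_path = run_dir / "learning_curve.csv"
    if lc_path.exists():
        lc = pd.read_csv(lc_path)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ok = lc[lc["converged"]]
        ax.scatter(ok["n_train"], ok["error"], s=10, alpha=0.5)
        mean = ok.groupby("n_train")["error"].mean()
        ax.plot(mean.index, mean.values, color="white", lw=3)
        ax.plot(mean.index, mean.values, color="tab:blue", lw=1.5)
        import json

        summ_path = run_dir / "learning_curve_summary.json"
        if summ_path.exists():
            full_error = json.loads(summ_path.read_text())["full_error"]
            ax.axhline(full_error, ls="--", color="k")
        ax.set_xlabel("training quadrats")
        ax.set_ylabel("LOOCV prediction error (RMSE)")
        fig.tight_layout()
        p = out_dir / "learning_curve.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("learning_curve.csv missing; panel skipped", stacklevel=2)

    return written
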