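"""Result visualization: isotherm curves, parity plot, 3-D response surface.

All model values shown in these figures go through :func:`aquasorb.fitting.predict`
on the calibrated result, so the plots are guaranteed to be consistent
with the JSON report.  Output is static PNG/SVG chosen by file extension.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .fitting import FitResult, predict  # noqa: E402
from .models import SorptionDataset  # noqa: E402

__all__ = ["plot_isotherms", "plot_parity", "plot_surface"]

#: Half the DDI a_w resolution — replicates whose a_w values differ by less
#: than this are averaged together for the mean +/- SD display.
AW_GROUP_TOLERANCE = 0.005


def _group_replicates(aw: np.ndarray, xe: np.ndarray, tol: float = AW_GROUP_TOLERANCE):
    """Mean and SD of moisture over replicate points sharing (within tol) an a_w."""
    keys = np.round(aw / tol).astype(int)
    order = np.argsort(keys, kind="stable")
    keys, aw, xe = keys[order], aw[order], xe[order]
    uniq, start = np.unique(keys, return_index=True)
    mean_aw, mean_xe, sd_xe, counts = [], [], [], []
    bounds = np.append(start, len(keys))
    for a, b in zip(bounds[:-1], bounds[1:]):
        mean_aw.append(aw[a:b].mean())
        mean_xe.append(xe[a:b].mean())
        sd_xe.append(xe[a:b].std(ddof=1) if b - a > 1 else np.nan)
        counts.append(b - a)
    return (np.asarray(mean_aw), np.asarray(mean_xe), np.asarray(sd_xe), np.asarray(counts))


def _curve(result: FitResult, temperature: float | None, n: int = 200):
    aw = np.linspace(result.fit_bounds.aw_min, result.fit_bounds.aw_max, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xe, _ = predict(result, aw, temperature, warn=False)
    return aw, xe


def plot_isotherms(dataset: SorptionDataset, result: FitResult, path, dpi: int = 150) -> Path:
    """Per-temperature replicate means (+/- SD error bars) with fitted curves."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 5))
    cmap = plt.get_cmap("viridis")
    temps = np.unique(dataset.temperature)
    for i, temp in enumerate(temps):
        color = cmap(i / max(len(temps) - 1, 1) * 0.8)
        sel = dataset.temperature == temp
        m_aw, m_xe, sd, counts = _group_replicates(
            dataset.water_activity[sel], dataset.moisture[sel]
        )
        yerr = None if np.all(np.isnan(sd)) else np.where(np.isnan(sd), 0.0, sd)
        ax.errorbar(
            m_aw, m_xe, yerr=yerr, fmt="o", ms=3, lw=0.8, alpha=0.6, color=color,
            label=f"data T={temp:g}",
        )
        caw, cxe = _curve(result, temp if result.spec.generalized else None)
        ax.plot(caw, cxe, "-", color=color, label=f"model T={temp:g}")
    ax.set_xlabel("water activity $a_w$ (-)")
    ax.set_ylabel("equilibrium moisture content $X_e$ (% d.b.)")
    ax.set_title(f"{result.spec.family.value} isotherms ({dataset.temperature_unit})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def plot_parity(dataset: SorptionDataset, result: FitResult, path, dpi: int = 150) -> Path:
    """Predicted-vs-observed scatter with the identity line and the fit R2."""
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred, _ = predict(
            result,
            dataset.water_activity,
            dataset.temperature if result.spec.generalized else None,
            warn=False,
        )
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(dataset.moisture, pred, s=8, alpha=0.5)
    lo = min(dataset.moisture.min(), np.min(pred))
    hi = max(dataset.moisture.max(), np.max(pred))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="identity")
    ax.annotate(
        f"$R^2$ = {result.goodness.r_squared:.3f} %",
        xy=(0.05, 0.92), xycoords="axes fraction",
    )
    ax.set_xlabel("experimental $X_e$ (% d.b.)")
    ax.set_ylabel("predicted $X_e$ (% d.b.)")
    ax.set_title("parity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def plot_surface(
    dataset: SorptionDataset, result: FitResult, path, n_grid: int = 40, dpi: int = 150
) -> Path:
    """Fitted X_e surface over the calibration (a_w, T) box with data overlay."""
    if not result.spec.generalized:
        raise ValueError("the response surface requires a temperature-generalized model")
    path = Path(path)
    b = result.fit_bounds
    aw = np.linspace(b.aw_min, b.aw_max, n_grid)
    temp = np.linspace(b.t_min, b.t_max, n_grid)
    AW, TT = np.meshgrid(aw, temp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z, _ = predict(result, AW.ravel(), TT.ravel(), warn=False)
    Z = np.asarray(Z).reshape(AW.shape)
    fig = plt.figure(figsize=(7, 5.5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(AW, TT, Z, cmap="viridis", alpha=0.65, linewidth=0)
    ax.scatter(
        dataset.water_activity, dataset.temperature, dataset.moisture,
        s=4, c="crimson", alpha=0.5, label="experimental",
    )
    ax.set_xlabel("$a_w$ (-)")
    ax.set_ylabel(f"T ({b.temperature_unit})")
    ax.set_zlabel("$X_e$ (% d.b.)")
    ax.set_title(f"{result.spec.family.value} response surface")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
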