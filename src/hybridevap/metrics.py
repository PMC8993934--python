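"""Model-evaluation metrics centred on the Kling-Gupta efficiency (KGE).

KGE combines correlation, variability bias and mean bias::

    KGE = 1 - sqrt((r - 1)**2 + (sigma_sim/sigma_obs - 1)**2
                   + (mu_sim/mu_obs - 1)**2)

It ranges from -inf to 1.0 (perfect). A constant prediction equal to the
observed mean scores 1 - sqrt(2) ~ -0.41 under the convention r := 0 for
zero-variance predictions; values above that threshold beat the
mean-seasonal-cycle benchmark. Standard deviations are population (ddof=0)
throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KGEResult",
    "kge",
    "rmse",
    "correlation",
    "summarize_by_class",
    "KGE_MEAN_BENCHMARK",
]

#: KGE of the constant mean-of-observations predictor (r := 0 convention).
KGE_MEAN_BENCHMARK = 1.0 - np.sqrt(2.0)


@dataclass(frozen=True)
class KGEResult:
    """KGE with its components: correlation r, variability ratio alpha
    (sigma_sim/sigma_obs) and bias ratio beta (mu_sim/mu_obs)."""

    kge: float
    r: float
    alpha: float
    beta: float


def _paired(sim, obs) -> tuple[np.ndarray, np.ndarray]:
    sim = np.asarray(sim, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if sim.shape != obs.shape:
        raise ValueError("sim and obs must have the same length")
    if sim.size < 2:
        raise ValueError("need at least two paired points")
    if not (np.all(np.isfinite(sim)) and np.all(np.isfinite(obs))):
        raise ValueError("series must be finite")
    return sim, obs


def kge(sim, obs) -> KGEResult:
    """Kling-Gupta efficiency of ``sim`` against ``obs``.

    A zero-variance (constant) simulation takes r := 0, which makes the
    mean benchmark reproducible: sim == mean(obs) gives KGE = 1 - sqrt(2).

    Raises
    ------
    ValueError
        If the observations have zero mean or zero variance (the bias and
        variability ratios are then undefined).
    """
    sim, obs = _paired(sim, obs)
    mu_obs = obs.mean()
    sd_obs = obs.std()
    if mu_obs == 0:
        raise ValueError("observed mean is zero; bias ratio undefined")
    if sd_obs == 0:
        raise ValueError("observed variance is zero; variability ratio undefined")
    mu_sim = sim.mean()
    sd_sim = sim.std()
    if sd_sim == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(sim, obs)[0, 1])
    alpha = float(sd_sim / sd_obs)
    beta = float(mu_sim / mu_obs)
    value = 1.0 - float(np.sqrt((r - 1.0) ** 2 + (alpha - 1.0) ** 2 + (beta - 1.0) ** 2))
    return KGEResult(kge=value, r=r, alpha=alpha, beta=beta)


def rmse(sim, obs) -> float:
    """Root mean square error."""
    sim, obs = _paired(sim, obs)
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def correlation(sim, obs) -> float:
    """Pearson linear correlation (0 for a constant series, matching the
    KGE convention)."""
    sim, obs = _paired(sim, obs)
    if sim.std() == 0 or obs.std() == 0:
        return 0.0
    return float(np.corrcoef(sim, obs)[0, 1])


def summarize_by_class(
    per_site: pd.DataFrame,
    metric: str = "kge",
    class_col: str = "veg_class",
    benchmark: float = KGE_MEAN_BENCHMARK,
) -> pd.DataFrame:
    """Per-class median, interquartile range and fraction of sites beating
    the mean benchmark, mirroring distribution-style model intercomparison.

    Parameters
    ----------
    per_site : DataFrame
        One row per site with at least ``metric`` and ``class_col`` columns.
    """
    import warnings

    rows = []
    for cls, grp in per_site.groupby(class_col):
        vals = grp[metric].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"class {cls!r} has no sites; omitted", stacklevel=2)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                class_col: cls,
                "n_sites": vals.size,
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": q3 - q1,
                "frac_above_benchmark": float(np.mean(vals > benchmark)),
            }
        )
    return pd.DataFrame(rows)


def violin_plot(per_site: pd.DataFrame, metric: str = "kge", class_col: str = "veg_class",
                out_path: str | None = None):
    """Optional violin plot of per-site metric distributions by class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted(per_site[class_col].unique())
    data = [per_site.loc[per_site[class_col] == c, metric].dropna() for c in classes]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.violinplot(data, showmedians=True)
    ax.axhline(KGE_MEAN_BENCHMARK, color="red", lw=1, label="mean benchmark (1 - sqrt(2))")
    ax.set_xticks(range(1, len(classes) + 1), classes)
    ax.set_ylabel(metric)
    ax.legend(frameon=False)
    if out_path:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
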