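"""Post-fit contrasts and predictions for the segmented MTP model.

All slope-effect cells, region-difference projections and trajectory
curves are linear combinations of fitted coefficients; every public
operation here routes through :func:`contrast` so there is a single source
of truth for the weight algebra.  On the overall-mean part the fitted
coefficients act on the log of the marginal mean, so contrasts are
log cost ratios; ``exp(contrast)`` is a multiplicative cost ratio for the
whole population, zeros included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DIAGNOSIS_TIME, MAX_TIME, STRUCTURAL_COLUMNS
from .inference import FitResult, wald_ci


class EffectsError(ValueError):
    """Raised for unknown coefficient names or invalid grids."""


@dataclass
class ContrastResult:
    """A linear combination w'theta of fitted coefficients."""

    weights: dict
    estimate: float
    se: float | None
    ci: tuple[float, float] | None
    scale_note: str = "log"

    def __repr__(self) -> str:  # compact, table-friendly
        if self.se is None:
            return f"ContrastResult({self.estimate:.4f}, se=n/a)"
        return (f"ContrastResult({self.estimate:.4f}, se={self.se:.4f}, "
                f"ci=({self.ci[0]:.4f}, {self.ci[1]:.4f}))")


def contrast(fit: FitResult, weights: Mapping[str, float],
             level: float = 0.95) -> ContrastResult:
    """Delta-method inference for w'theta on the natural scale.

    ``weights`` maps parameter names (e.g. ``"mean:region:after_time"``)
    to weights.  The standard error is sqrt(w' V w) when the fit carries a
    covariance; results loaded from printed coefficients give the point
    estimate only.
    """
    unknown = [k for k in weights if k not in fit.names]
    if unknown:
        raise EffectsError(
            f"unknown parameter names {unknown}; valid names: {fit.names}")
    w = np.zeros(len(fit.names))
    for k, v in weights.items():
        w[fit.names.index(k)] = v
    est = float(w @ fit.estimates)
    if fit.vcov is None:
        return ContrastResult(dict(weights), est, None, None)
    se = float(np.sqrt(max(w @ fit.vcov @ w, 0.0)))
    ci = wald_ci(est, se, level) if se > 0 else (est, est)
    return ContrastResult(dict(weights), est, se, ci)


# ---------------------------------------------------------------------------
# slope-effect grid


def _require_standard(fit: FitResult) -> None:
    missing = [c for c in STRUCTURAL_COLUMNS if c not in fit.columns]
    if missing:
        raise EffectsError(
            f"fit does not use the standard segmented design; missing {missing}")


def slope_contrast_weights(component: str = "mean") -> dict:
    """Coefficient weights for the 3x3 monthly log-mean slope grid.

    Rows: vulnerable / nonvulnerable / difference (vulnerable minus
    nonvulnerable); columns: before / after / after minus before.  In the
    identifiable segmented layout the nonvulnerable pre-diagnosis slope is
    the ``time`` coefficient; vulnerable regions add the ``region:time``
    trend difference; post-diagnosis both regions add the
    ``diagnosis:after_time`` slope change and vulnerable regions
    additionally the ``region:after_time`` term.  The region
    difference-in-differences of pre/post slopes is therefore the
    ``region:after_time`` coefficient alone, while the post-diagnosis
    region slope gap — the rate at which the regional cost gap accrues
    after diagnosis — is ``region:time`` + ``region:after_time``.
    """
    pre = f"{component}:time"
    post = f"{component}:diagnosis:after_time"
    rtrend = f"{component}:region:time"
    rafter = f"{component}:region:after_time"
    return {
        ("vulnerable", "before"): {pre: 1.0, rtrend: 1.0},
        ("vulnerable", "after"): {pre: 1.0, post: 1.0, rtrend: 1.0, rafter: 1.0},
        ("vulnerable", "after-before"): {post: 1.0, rafter: 1.0},
        ("nonvulnerable", "before"): {pre: 1.0},
        ("nonvulnerable", "after"): {pre: 1.0, post: 1.0},
        ("nonvulnerable", "after-before"): {post: 1.0},
        ("difference", "before"): {rtrend: 1.0},
        ("difference", "after"): {rtrend: 1.0, rafter: 1.0},
        ("difference", "after-before"): {rafter: 1.0},
    }


def named_slope_contrasts(fit: FitResult, component: str = "mean",
                          level: float = 0.95) -> pd.DataFrame:
    """The 3x3 grid of monthly slope effects as a tidy table.

    Every cell is a :func:`contrast` call with the weights from
    :func:`slope_contrast_weights` (units: change in log mean cost per
    month).
    """
    _require_standard(fit)
    rows = []
    for (region, period), w in slope_contrast_weights(component).items():
        c = contrast(fit, w, level=level)
        rows.append({
            "region": region, "period": period, "estimate": c.estimate,
            "se": c.se if c.se is not None else np.nan,
            "lower": c.ci[0] if c.ci else np.nan,
            "upper": c.ci[1] if c.ci else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# region difference over time


def predict_region_difference(fit: FitResult, years: float,
                              variant: str = "linear",
                              with_ci: bool = False):
    """Accrued vulnerable-vs-nonvulnerable gap in overall mean cost, in %.

    Computed as ``100 * (b7 + b8) * years`` where ``b7 + b8`` is the
    post-diagnosis region slope gap on the log-mean scale
    (:func:`slope_contrast_weights` cell ``("difference", "after")``).

    .. warning::
       The slope coefficients are per MONTH of follow-up, yet the
       reference reporting convention multiplies by elapsed YEARS without
       the factor 12; this function reproduces that convention.  The
       ``variant="exp"`` form ``100 * (exp((b7+b8)*years) - 1)`` is the
       exact percent ratio under the same convention.
    """
    if years < 0:
        raise EffectsError("years must be non-negative")
    c = contrast(fit, slope_contrast_weights("mean")[("difference", "after")])
    if variant == "linear":
        est = 100.0 * c.estimate * years
    elif variant == "exp":
        est = 100.0 * (np.exp(c.estimate * years) - 1.0)
    else:
        raise EffectsError("variant must be 'linear' or 'exp'")
    if not with_ci:
        return float(est)
    if c.se is None:
        return float(est), None, None
    if variant == "linear":
        se = 100.0 * c.se * years
    else:
        se = 100.0 * np.exp(c.estimate * years) * c.se * years  # delta method
    lo, hi = wald_ci(float(est), float(se))
    return float(est), lo, hi


def region_difference_table(fit: FitResult, years: Sequence[float] = (1, 2, 3, 4, 5),
                            variant: str = "linear") -> pd.DataFrame:
    """Projection table of the region gap (%) at a grid of years."""
    rows = []
    for yr in years:
        est, lo, hi = predict_region_difference(fit, yr, variant=variant, with_ci=True)
        rows.append({"years": yr, "difference_pct": round(est, 2),
                     "lower": np.nan if lo is None else round(lo, 2),
                     "upper": np.nan if hi is None else round(hi, 2)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectories


def _structural_row(time: float, region: float) -> dict:
    diag = 1.0 if time >= DIAGNOSIS_TIME else 0.0
    after = max(0.0, time - DIAGNOSIS_TIME)
    return {
        "intercept": 1.0,
        "diagnosis": diag,
        "region": region,
        "time": float(time),
        "diagnosis:region": diag * region,
        "diagnosis:after_time": diag * after,
        "region:time": region * float(time),
        "region:after_time": region * after,
    }


def predict_trajectory(fit: FitResult, profile: Mapping[str, float],
                       times: Sequence[float] | None = None,
                       component: str = "mean",
                       level: float = 0.95) -> pd.DataFrame:
    """Model-implied log mean cost over the diagnosis window.

    ``profile`` fixes the region (1 = vulnerable, or the strings
    ``"vulnerable"``/``"nonvulnerable"``) and any adjustment covariates in
    the fitted design.  Returns a piecewise-linear curve in ``time`` with
    a possible level shift at the diagnosis month, plus delta-method
    pointwise confidence bands when a covariance is available.
    """
    _require_standard(fit)
    if times is None:
        times = np.arange(MAX_TIME + 1)
    times = np.asarray(times, dtype=float)
    if times.min() < 0 or times.max() > MAX_TIME:
        raise EffectsError(f"time grid must lie within [0, {MAX_TIME}]")

    region = profile.get("region", 0.0)
    if isinstance(region, str):
        region = 1.0 if region == "vulnerable" else 0.0

    rows = []
    for t in times:
        vals = _structural_row(t, float(region))
        for col in fit.columns:
            if col not in vals:
                if col not in profile:
                    raise EffectsError(f"profile must set covariate {col!r}")
                vals[col] = float(profile[col])
        weights = {f"{component}:{col}": vals[col] for col in fit.columns
                   if vals[col] != 0.0}
        c = contrast(fit, weights, level=level)
        rows.append({"time": t, "estimate": c.estimate,
                     "se": c.se if c.se is not None else np.nan,
                     "lower": c.ci[0] if c.ci else np.nan,
                     "upper": c.ci[1] if c.ci else np.nan})
    return pd.DataFrame(rows)


def plot_trajectory(curves: Mapping[str, pd.DataFrame], path=None, ax=None):
    """Plot log-mean cost trajectories (one labelled curve per profile)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for label, df in curves.items():
        ax.plot(df["time"], df["estimate"], label=label)
        if df["lower"].notna().any():
            ax.fill_between(df["time"], df["lower"], df["upper"], alpha=0.2)
    ax.axvline(DIAGNOSIS_TIME, color="grey", ls=":", lw=1)
    ax.set_xlabel("month (diagnosis at 24)")
    ax.set_ylabel("log mean expenditure")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
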