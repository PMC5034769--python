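"""Size-resolved scaling-exponent estimation.

Records are split into size classes on log10 total mass (equal-frequency by
default), per-class medians of log organ masses are taken, local slopes are
estimated over each adjacent class triplet with a central derivative kernel
(the three estimates touching a class are averaged), the per-class slopes
are smoothed by a Loess curve, and a stratified record-level bootstrap
yields the pointwise median curve and its 95% band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dataio import DataSet
from .errors import ConfigError, DegenerateInputError

__all__ = [
    "SizeBinning",
    "SlopeCurve",
    "make_bins",
    "triplet_slopes",
    "smooth_slopes",
    "bootstrap_slope_curve",
    "polynomial_derivative_slope",
]


@dataclass
class SizeBinning:
    """Assignment of records to ordered size classes with per-class stats."""

    n_bins: int
    edges: np.ndarray               # log10 total-mass boundaries, len n_bins + 1
    assignment: np.ndarray          # record index -> bin index
    counts: np.ndarray
    med_log_leaf: np.ndarray
    med_log_stem: np.ndarray
    med_log_root: np.ndarray
    med_log_total: np.ndarray
    mean_lmf: np.ndarray
    mean_smf: np.ndarray
    mean_rmf: np.ndarray
    mean_log_total: np.ndarray
    members: list                   # bin index -> record-index array

    def med_log(self, organ: str) -> np.ndarray:
        return getattr(self, f"med_log_{organ}")


def make_bins(ds: DataSet, n_bins: int = 50, scheme: str = "quantile") -> SizeBinning:
    """Split records into ``n_bins`` size classes on log10 total mass.

    ``scheme='quantile'`` (default) makes equal-frequency classes (counts
    balanced to +/-1, ties at boundaries broken by stable input order);
    ``scheme='width'`` uses equal log-width classes and then merges empty
    ones into their left neighbour.
    """
    n = len(ds)
    if n < n_bins:
        raise DegenerateInputError(
            f"{n} records cannot fill {n_bins} bins; lower n_bins"
        )
    log_total = ds.log10_mass("total")
    log_leaf = ds.log10_mass("leaf")
    log_stem = ds.log10_mass("stem")
    log_root = ds.log10_mass("root")

    if scheme == "quantile":
        order = np.argsort(log_total, kind="stable")
        groups = np.array_split(order, n_bins)
    elif scheme == "width":
        edges = np.linspace(log_total.min(), log_total.max(), n_bins + 1)
        idx = np.clip(np.searchsorted(edges, log_total, side="right") - 1, 0, n_bins - 1)
        groups = [np.flatnonzero(idx == b) for b in range(n_bins)]
        groups = [g for g in groups if len(g)]  # drop empties
    else:
        raise ConfigError(f"unknown binning scheme {scheme!r}")

    assignment = np.empty(n, dtype=int)
    for b, g in enumerate(groups):
        assignment[g] = b
    k = len(groups)
    total = ds.organ_mass("total")
    lmf = ds.organ_mass("leaf") / total
    smf = ds.organ_mass("stem") / total
    rmf = ds.organ_mass("root") / total

    def agg(fun, values):
        return np.array([fun(values[g]) for g in groups])

    edges = np.empty(k + 1)
    edges[0] = log_total.min()
    edges[-1] = log_total.max()
    for b in range(1, k):
        edges[b] = 0.5 * (log_total[groups[b - 1]].max() + log_total[groups[b]].min())

    return SizeBinning(
        n_bins=k,
        edges=edges,
        assignment=assignment,
        counts=np.array([len(g) for g in groups]),
        med_log_leaf=agg(np.median, log_leaf),
        med_log_stem=agg(np.median, log_stem),
        med_log_root=agg(np.median, log_root),
        med_log_total=agg(np.median, log_total),
        mean_lmf=agg(np.mean, lmf),
        mean_smf=agg(np.mean, smf),
        mean_rmf=agg(np.mean, rmf),
        mean_log_total=agg(np.mean, log_total),
        members=[np.asarray(g) for g in groups],
    )


def _triplet_slope_matrix(ymed: np.ndarray, xmed: np.ndarray) -> np.ndarray:
    """Averaged central-kernel triplet slopes along the last axis.

    For each interior class i the slope (y[i+1]-y[i-1])/(x[i+1]-x[i-1]) is
    assigned to classes i-1, i, i+1; each class averages the (up to three)
    estimates it receives.  Triplets with a zero x-difference yield NaN and
    are excluded from the average.
    """
    ymed = np.asarray(ymed, dtype=float)
    xmed = np.asarray(xmed, dtype=float)
    nb = ymed.shape[-1]
    if nb < 3:
        raise DegenerateInputError("need at least 3 bins for triplet slopes")
    dy = ymed[..., 2:] - ymed[..., :-2]
    dx = xmed[..., 2:] - xmed[..., :-2]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(dx != 0, dy / np.where(dx == 0, 1.0, dx), np.nan)
    stack = np.full(ymed.shape[:-1] + (3, nb), np.nan)
    stack[..., 0, :-2] = s
    stack[..., 1, 1:-1] = s
    stack[..., 2, 2:] = s
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(stack, axis=-2)


def triplet_slopes(binning: SizeBinning, y_organ: str, x_organ: str) -> np.ndarray:
    """Per-class averaged central-kernel slopes of y-organ vs x-organ medians."""
    ymed = binning.med_log(y_organ)
    xmed = binning.med_log(x_organ)
    dx = xmed[2:] - xmed[:-2]
    if np.any(dx == 0):
        warnings.warn("zero x-difference in some triplet(s); skipped", stacklevel=2)
    return _triplet_slope_matrix(ymed, xmed)


def smooth_slopes(slopes, grid, span: float = 0.75, xvals=None) -> np.ndarray:
    """Loess (tricube weights, local degree 1) through (grid, slopes)."""
    if not 0 < span <= 1:
        raise ConfigError("span must be in (0, 1]")
    slopes = np.asarray(slopes, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 5:
        raise DegenerateInputError("need at least 5 points to smooth")
    out = lowess(slopes, grid, frac=span, it=0,
                 xvals=np.asarray(xvals if xvals is not None else grid, dtype=float))
    return np.asarray(out, dtype=float)


@dataclass
class SlopeCurve:
    """Loess-smoothed local-exponent curve with a bootstrap 95% band."""

    grid: np.ndarray
    slope: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_boot: int
    n_redrawn: int = 0


def bootstrap_slope_curve(
    ds: DataSet,
    y_organ: str,
    x_organ: str,
    n_bins: int = 50,
    n_boot: int = 20000,
    span: float = 0.75,
    seed: int | None = None,
    scheme: str = "quantile",
) -> SlopeCurve:
    """Bootstrap the Loess slope curve; pointwise median and 2.5/97.5 band.

    Each repetition resamples records with replacement *within* their size
    class (so every class stays populated), recomputes class medians,
    triplet slopes and the Loess smooth evaluated on the original class
    grid.  Per-class member values are sorted before resampling, making the
    curve invariant to record order.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap band will be unreliable", stacklevel=2)
    binning = make_bins(ds, n_bins=n_bins, scheme=scheme)
    grid = binning.med_log_total
    log_y = ds.log10_mass(y_organ)
    log_x = ds.log10_mass(x_organ)
    log_t = ds.log10_mass("total")

    rng = np.random.default_rng(seed)
    k = binning.n_bins
    ymed = np.empty((n_boot, k))
    xmed = np.empty((n_boot, k))
    tmed = np.empty((n_boot, k))
    for b, members in enumerate(binning.members):
        # sort member values so resampling ignores input record order
        key = np.lexsort((log_y[members], log_x[members], log_t[members]))
        m = members[key]
        idx = rng.integers(0, len(m), size=(n_boot, len(m)))
        ymed[:, b] = np.median(log_y[m][idx], axis=1)
        xmed[:, b] = np.median(log_x[m][idx], axis=1)
        tmed[:, b] = np.median(log_t[m][idx], axis=1)

    tri = _triplet_slope_matrix(ymed, xmed)
    n_redrawn = 0
    bad = np.flatnonzero(np.any(~np.isfinite(tri), axis=1))
    for rep in bad:
        for _ in range(100):  # redraw the repetition until all slopes finite
            n_redrawn += 1
            for b, members in enumerate(binning.members):
                key = np.lexsort((log_y[members], log_x[members], log_t[members]))
                m = members[key]
                idx = rng.integers(0, len(m), size=len(m))
                ymed[rep, b] = np.median(log_y[m][idx])
                xmed[rep, b] = np.median(log_x[m][idx])
                tmed[rep, b] = np.median(log_t[m][idx])
            tri[rep] = _triplet_slope_matrix(ymed[rep], xmed[rep])
            if np.all(np.isfinite(tri[rep])):
                break
        else:
            raise DegenerateInputError("could not obtain finite slopes by resampling")

    curves = np.empty((n_boot, k))
    for rep in range(n_boot):
        curves[rep] = lowess(tri[rep], tmed[rep], frac=span, it=0, xvals=grid)
    return SlopeCurve(
        grid=grid,
        slope=np.median(curves, axis=0),
        lo=np.percentile(curves, 2.5, axis=0),
        hi=np.percentile(curves, 97.5, axis=0),
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


def polynomial_derivative_slope(fit, grid) -> np.ndarray:
    """Analytic derivative b1 + 2*b2*x + 3*b3*x^2 of a PolyFit on ``grid``.

    ``grid`` is in log10 x-organ mass; map to a total-mass grid via the
    class medians of a :class:`SizeBinning` if needed.
    """
    x = np.asarray(grid, dtype=float)
    out = np.full_like(x, float(fit.coefs[0]))
    if fit.degree >= 2:
        out = out + 2.0 * fit.coefs[1] * x
    if fit.degree >= 3:
        out = out + 3.0 * fit.coefs[2] * x ** 2
    return out
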