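"""Biomass fractions (LMF/SMF/RMF) and their size trends.

The trend curve for a fraction is a Loess fit through the per-size-class
mean fraction versus the class mean log10 total mass; how much of the
record-level variation the curve explains is reported both against records
(via monotone interpolation of the class-level curve, clamped at the ends)
and against the class means themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import DataSet
from .dynamic_slopes import SizeBinning, smooth_slopes

__all__ = ["FractionSet", "FractionTrend", "compute_fractions", "fraction_trend"]

_FRACTIONS = ("lmf", "smf", "rmf")


@dataclass
class FractionSet:
    record_ids: np.ndarray
    lmf: np.ndarray
    smf: np.ndarray
    rmf: np.ndarray

    def values(self, which: str) -> np.ndarray:
        if which not in _FRACTIONS:
            raise ValueError(f"fraction must be one of {_FRACTIONS}")
        return getattr(self, which)


def compute_fractions(ds: DataSet) -> FractionSet:
    """Per-record organ mass divided by total plant mass; sums to 1 exactly."""
    total = ds.organ_mass("total")
    return FractionSet(
        record_ids=np.array([r.record_id for r in ds.records], dtype=object),
        lmf=ds.organ_mass("leaf") / total,
        smf=ds.organ_mass("stem") / total,
        rmf=ds.organ_mass("root") / total,
    )


@dataclass
class FractionTrend:
    which: str
    grid: np.ndarray          # class mean log10 total mass
    curve: np.ndarray         # Loess of class mean fraction
    r2_records: float         # 1 - SSres/SStot over all records
    r2_bins: float            # same computed on the class means
    n_extrapolated: int       # records outside the class-mean grid (clamped)


def fraction_trend(
    ds: DataSet, which: str, binning: SizeBinning, span: float = 0.75
) -> FractionTrend:
    """Loess size trend of one biomass fraction plus explained variance.

    Record-level predictions come from linear interpolation of the
    class-level curve at each record's log10 total mass; positions beyond
    the outermost class means are clamped to the end values and counted.
    A constant fraction gives r2 = 0 by convention (no variation to explain).
    """
    fr = compute_fractions(ds).values(which)
    grid = binning.mean_log_total
    mean_frac = getattr(binning, f"mean_{which}")
    curve = smooth_slopes(mean_frac, grid, span=span)

    log_t = ds.log10_mass("total")
    pred = np.interp(log_t, grid, curve)  # np.interp clamps outside the grid
    n_extrap = int(((log_t < grid[0]) | (log_t > grid[-1])).sum())

    def r2(obs, est):
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        # variation at float-rounding level counts as "no variation"
        if ss_tot <= 1e-12 * float((obs ** 2).sum()):
            return 0.0
        return float(1.0 - ((obs - est) ** 2).sum() / ss_tot)

    return FractionTrend(
        which=which,
        grid=grid,
        curve=curve,
        r2_records=r2(fr, pred),
        r2_bins=r2(mean_frac, curve),
        n_extrapolated=n_extrap,
    )
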