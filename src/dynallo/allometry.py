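"""Log-log allometric fits: standardized major axis and OLS polynomials.

All fits operate on paired vectors of log10 organ mass.  The SMA (model 2)
slope is ``sign(r) * sd(y) / sd(x)`` with the classical F-based confidence
interval; polynomial (model 1) fits are compared by BIC
(``n*ln(RSS/n) + k*ln(n)``, a fixed internal convention — only differences
are ever interpreted) and by incremental F-tests in a forward stepwise
scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = [
    "AllometricPair",
    "SMAFit",
    "PolyFit",
    "ResidualDiagnostics",
    "fit_sma",
    "fit_polynomial",
    "select_model",
    "residual_diagnostics",
]

_ORGANS = ("leaf", "stem", "root")


@dataclass
class AllometricPair:
    """Paired log10 masses for a y-organ vs x-organ regression."""

    x: np.ndarray
    y: np.ndarray
    x_organ: str = "stem"
    y_organ: str = "leaf"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and of equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 points")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in pair")

    @classmethod
    def from_dataset(cls, ds, y_organ: str, x_organ: str) -> "AllometricPair":
        if y_organ not in _ORGANS or x_organ not in _ORGANS:
            raise ValueError(f"organs must be one of {_ORGANS}")
        return cls(x=ds.log10_mass(x_organ), y=ds.log10_mass(y_organ),
                   x_organ=x_organ, y_organ=y_organ)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class SMAFit:
    a_log: float
    b: float
    ci_b: tuple
    r2: float
    n: int

    def predict(self, x):
        return self.a_log + self.b * np.asarray(x, dtype=float)


@dataclass
class PolyFit:
    degree: int
    a_log: float
    coefs: np.ndarray          # (b1, ..., b_degree)
    bic: float
    delta_bic_vs_linear: float
    r2: float
    n: int
    term_pvalues: np.ndarray   # incremental F-test p-value per added term
    rss: float

    @property
    def b1(self):
        return self.coefs[0]

    @property
    def b2(self):
        return self.coefs[1] if self.degree >= 2 else None

    @property
    def b3(self):
        return self.coefs[2] if self.degree >= 3 else None

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, self.a_log)
        for j, c in enumerate(self.coefs, start=1):
            out = out + c * x ** j
        return out


def fit_sma(pair: AllometricPair, alpha: float = 0.05) -> SMAFit:
    """Standardized major axis fit with F-based 1-alpha slope CI."""
    x, y, n = pair.x, pair.y, pair.n
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero variance in x or y")
    r = np.corrcoef(x, y)[0, 1]
    if r == 0:
        raise DegenerateInputError("correlation is exactly zero; SMA sign undefined")
    b = np.sign(r) * sy / sx
    a_log = y.mean() - b * x.mean()
    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r * r) / (n - 2)
    lo = b * (np.sqrt(B + 1) - np.sqrt(B))
    hi = b * (np.sqrt(B + 1) + np.sqrt(B))
    if b < 0:
        lo, hi = hi, lo
    return SMAFit(a_log=float(a_log), b=float(b), ci_b=(float(lo), float(hi)),
                  r2=float(r * r), n=n)


def _ols(x: np.ndarray, y: np.ndarray, degree: int):
    X = np.vander(x, degree + 1, increasing=True)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < degree + 1:
        raise DegenerateInputError("collinear design (not enough distinct x values)")
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_polynomial(pair: AllometricPair, max_degree: int = 3) -> list:
    """OLS polynomial fits of degree 1..max_degree with BIC and term p-values."""
    if not 1 <= max_degree <= 3:
        raise ValueError("max_degree must be in 1..3")
    x, y, n = pair.x, pair.y, pair.n
    if n <= max_degree + 1:
        raise ValueError("need n > max_degree + 1")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rss_prev = ss_tot  # intercept-only model
    fits, bic_linear = [], None
    for degree in range(1, max_degree + 1):
        beta, rss = _ols(x, y, degree)
        k = degree + 1
        bic = n * np.log(rss / n) + k * np.log(n)
        if degree == 1:
            bic_linear = bic
        # incremental F-test of the newly added term
        df_resid = n - k
        if rss <= 0:
            pval = 0.0
        else:
            F = (rss_prev - rss) / (rss / df_resid)
            pval = float(stats.f.sf(F, 1, df_resid))
        prev_p = fits[-1].term_pvalues if fits else np.empty(0)
        fits.append(
            PolyFit(
                degree=degree,
                a_log=float(beta[0]),
                coefs=beta[1:].copy(),
                bic=float(bic),
                delta_bic_vs_linear=float(bic - bic_linear),
                r2=float(1 - rss / ss_tot) if ss_tot > 0 else 1.0,
                n=n,
                term_pvalues=np.append(prev_p, pval),
                rss=rss,
            )
        )
        rss_prev = rss
    return fits


def select_model(fits: Sequence[PolyFit], alpha: float = 0.05, strict: bool = False) -> PolyFit:
    """Forward stepwise selection from linear using both p-value and BIC.

    A higher degree is accepted only if its added term is significant at
    ``alpha`` and its BIC is below every lower-degree BIC.  When the two
    criteria disagree at some step and ``strict`` is set, selection falls
    all the way back to the linear fit with a conflict warning; otherwise
    the step is simply rejected.
    """
    if not fits:
        raise ValueError("empty fit list")
    fits = sorted(fits, key=lambda f: f.degree)
    chosen = fits[0]
    for cand in fits[1:]:
        significant = bool(cand.term_pvalues[-1] < alpha)
        bic_better = cand.bic < min(f.bic for f in fits if f.degree < cand.degree)
        if significant and bic_better:
            chosen = cand
        else:
            if strict and significant != bic_better:
                warnings.warn(
                    f"degree {cand.degree}: p-value and BIC criteria disagree "
                    f"(p={cand.term_pvalues[-1]:.3g}); falling back to linear",
                    stacklevel=2,
                )
                chosen = fits[0]
            break
    return chosen


@dataclass
class ResidualDiagnostics:
    residuals: np.ndarray
    x: np.ndarray
    runs_z: float
    runs_p: float
    curvature_r: float   # correlation of residuals with x^2
    curvature_p: float


def residual_diagnostics(pair: AllometricPair, fit) -> ResidualDiagnostics:
    """Residuals vs x with a runs test and an x^2-correlation curvature check."""
    order = np.argsort(pair.x, kind="stable")
    x = pair.x[order]
    resid = (pair.y - fit.predict(pair.x))[order]
    runs_z, runs_p = _runs_test(resid)
    if np.allclose(resid, 0):
        cr, cp = 0.0, 1.0
    else:
        cr, cp = stats.pearsonr(resid, x ** 2)
    return ResidualDiagnostics(residuals=resid, x=x, runs_z=runs_z, runs_p=runs_p,
                               curvature_r=float(cr), curvature_p=float(cp))


def _runs_test(values: np.ndarray):
    """Wald-Wolfowitz runs test on the signs of ``values`` (zeros dropped)."""
    signs = np.sign(values)
    signs = signs[signs != 0]
    if len(signs) < 2:
        return 0.0, 1.0
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    if n_pos == 0 or n_neg == 0:
        return 0.0, 1.0
    runs = 1 + int((signs[1:] != signs[:-1]).sum())
    n = n_pos + n_neg
    mean = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n * n * (n - 1.0))
    if var <= 0:
        return 0.0, 1.0
    z = (runs - mean) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))
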