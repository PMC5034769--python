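"""Two self-contained demonstrations.

1. r2 inflation: even with root mass fraction drawn uniformly over almost
   its whole possible range, the squared correlation between log shoot and
   log root mass stays very high once total size spans several orders of
   magnitude — the r2 of a log-log allometric fit mostly measures size
   range, not proportionality.  A closed-form prediction from the variance
   decomposition of log shoot/root serves as the analytic oracle.

2. A minimal teleonomic growth model: carbon gain proportional to leaf mass
   (discounted by a hydraulic height penalty) is divided among organs by
   allocation weights; rewarding height growth tilts allocation toward the
   stem, producing a stem-vs-root exponent above 1 and a leaf-vs-stem
   exponent below 1, while without reward or penalty growth is isometric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .synthetic_data import generate_rmf_uniform

__all__ = [
    "R2DemoResult",
    "r2_inflation",
    "r2_range_sweep",
    "predicted_r2",
    "GrowthParams",
    "GrowthTrajectory",
    "simulate_growth",
]


@dataclass
class R2DemoResult:
    orders_of_magnitude: float
    rmf_range: tuple
    n: int
    seed: int
    r2: float
    r2_predicted: float


def predicted_r2(orders: float, rmf_range=(0.01, 0.99)) -> float:
    """Closed-form r2 of log shoot vs log root under the uniform-RMF model.

    With M log-uniform over ``orders`` decades (variance V = orders^2/12)
    independent of R ~ U(lo, hi):

        log10 shoot = log10 M + log10(1-R),   log10 root = log10 M + log10 R

    so r2 = (V + c)^2 / ((V + v_s)(V + v_r)) where v_s, v_r and c are the
    variances and covariance of log10(1-R) and log10(R), integrated
    numerically over the uniform density.
    """
    lo, hi = rmf_range
    if not 0 < lo <= hi < 1:
        raise ValueError("rmf_range must satisfy 0 < lo <= hi < 1")
    V = orders ** 2 / 12.0
    if lo == hi:
        return 1.0
    width = hi - lo

    def mom(f):
        val, _ = integrate.quad(f, lo, hi, limit=200)
        return val / width

    f = np.log10
    g = lambda r: np.log10(1.0 - r)
    Ef, Eg = mom(f), mom(g)
    v_r = mom(lambda r: f(r) ** 2) - Ef ** 2
    v_s = mom(lambda r: g(r) ** 2) - Eg ** 2
    c = mom(lambda r: f(r) * g(r)) - Ef * Eg
    return float((V + c) ** 2 / ((V + v_s) * (V + v_r)))


def r2_inflation(
    orders: float = 10.0,
    rmf_range=(0.01, 0.99),
    n: int = 11000,
    seed: int = 0,
) -> R2DemoResult:
    """Monte-Carlo r2 of log10 shoot vs log10 root plus the analytic value."""
    if orders <= 0:
        raise ValueError("orders must be > 0")
    if n < 10:
        raise ValueError("n must be >= 10")
    lo, hi = rmf_range
    table = generate_rmf_uniform(n, log10_mass_range=(0.0, orders), seed=seed)
    if lo != 0.01 or hi != 0.99:
        # re-map the uniform draw onto the requested fraction range
        rmf = lo + (table["rmf"].to_numpy() - 0.01) * (hi - lo) / 0.98
        total = table["total_mass"].to_numpy()
        root = rmf * total
        shoot = total - root
    else:
        root = table["root_mass"].to_numpy()
        shoot = table["shoot_mass"].to_numpy()
    r = stats.pearsonr(np.log10(shoot), np.log10(root)).statistic
    return R2DemoResult(
        orders_of_magnitude=float(orders),
        rmf_range=(float(lo), float(hi)),
        n=n,
        seed=seed,
        r2=float(r * r),
        r2_predicted=predicted_r2(orders, rmf_range),
    )


def r2_range_sweep(orders_list, rmf_range=(0.01, 0.99), n: int = 11000, seed: int = 0):
    """One :class:`R2DemoResult` per size range, plus a monotonicity report.

    Returns ``(results, monotone)`` where ``monotone`` says whether the
    predicted r2 is non-decreasing along the sorted ranges.
    """
    if not len(list(orders_list)):
        raise ValueError("orders_list must be non-empty")
    results = [r2_inflation(o, rmf_range, n, seed) for o in orders_list]
    preds = [r.r2_predicted for r in sorted(results, key=lambda r: r.orders_of_magnitude)]
    monotone = all(b >= a - 1e-12 for a, b in zip(preds, preds[1:]))
    return results, monotone


# ---------------------------------------------------------------------------
# Minimal teleonomic growth model


@dataclass
class GrowthParams:
    assimilation: float = 1.0        # carbon gain per unit leaf mass per time
    base_leaf: float = 1.0 / 3.0     # baseline allocation weights
    base_stem: float = 1.0 / 3.0
    base_root: float = 1.0 / 3.0
    height_reward: float = 0.0       # w: stem weight multiplier ~ (1 + w*H)
    hydraulic_penalty: float = 0.0   # h: gain discounted by 1 / (1 + h*H)
    height_coef: float = 1.0         # H = height_coef * stem^height_exp
    height_exp: float = 0.5
    leaf0: float = 1.0
    stem0: float = 1.0
    root0: float = 1.0

    def __post_init__(self):
        if min(self.leaf0, self.stem0, self.root0) <= 0:
            raise ValueError("initial masses must be > 0")
        if self.height_reward < 0 or self.hydraulic_penalty < 0:
            raise ValueError("height_reward and hydraulic_penalty must be >= 0")


@dataclass
class GrowthTrajectory:
    time: np.ndarray
    leaf: np.ndarray
    stem: np.ndarray
    root: np.ndarray
    fractions: np.ndarray       # (n_steps, 3) allocation fractions used per step
    gain: np.ndarray            # G per step

    def log10(self, organ: str) -> np.ndarray:
        return np.log10(getattr(self, organ))

    def realized_exponent(self, y_organ: str, x_organ: str) -> float:
        """OLS slope of log10 y-organ on log10 x-organ over the trajectory."""
        x, y = self.log10(x_organ), self.log10(y_organ)
        return float(np.polyfit(x, y, 1)[0])

    def local_exponents(self, y_organ: str, x_organ: str) -> np.ndarray:
        """Per-step finite-difference exponents d log y / d log x."""
        x, y = self.log10(x_organ), self.log10(y_organ)
        return np.diff(y) / np.diff(x)

    def rgr_ratio_exponents(self, y_organ: str, x_organ: str) -> np.ndarray:
        """Analytic per-step exponents: ratio of relative growth rates."""
        organs = {"leaf": 0, "stem": 1, "root": 2}
        ym = getattr(self, y_organ)[:-1]
        xm = getattr(self, x_organ)[:-1]
        fy = self.fractions[:, organs[y_organ]]
        fx = self.fractions[:, organs[x_organ]]
        return (fy * self.gain / ym) / (fx * self.gain / xm)


def simulate_growth(params: GrowthParams, n_steps: int = 2000, dt: float = 0.01) -> GrowthTrajectory:
    """Explicit-Euler integration of the toy allocation model.

    Per step: height ``H = c * S**gamma``; gain ``G = A*L / (1 + h*H)``;
    allocation weights ``(base_leaf, base_stem*(1 + w*H), base_root)``
    normalized to fractions summing to one; each organ receives its
    fraction of ``G*dt``.
    """
    L, S, R = params.leaf0, params.stem0, params.root0
    leaf = np.empty(n_steps + 1)
    stem = np.empty(n_steps + 1)
    root = np.empty(n_steps + 1)
    fractions = np.empty((n_steps, 3))
    gain = np.empty(n_steps)
    leaf[0], stem[0], root[0] = L, S, R
    for i in range(n_steps):
        H = params.height_coef * S ** params.height_exp
        G = params.assimilation * L / (1.0 + params.hydraulic_penalty * H)
        weights = np.array(
            [params.base_leaf, params.base_stem * (1.0 + params.height_reward * H), params.base_root]
        )
        f = weights / weights.sum()
        dL, dS, dR = f * G * dt
        L, S, R = L + dL, S + dS, R + dR
        if not np.all(np.isfinite([L, S, R])):
            raise FloatingPointError(f"non-finite state at step {i}")
        leaf[i + 1], stem[i + 1], root[i + 1] = L, S, R
        fractions[i] = f
        gain[i] = G
    return GrowthTrajectory(
        time=np.arange(n_steps + 1) * dt,
        leaf=leaf,
        stem=stem,
        root=root,
        fractions=fractions,
        gain=gain,
    )
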