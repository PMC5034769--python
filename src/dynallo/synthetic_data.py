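"""Generators for datasets with the statistical structure the analysis assumes.

Every generator draws all randomness from one explicit seed, assigns
synthetic species contiguously along the size axis (each species spans a
narrow size window, emulating per-species harvest series) and returns a
regular :class:`~dynallo.dataio.DataSet`, so the full pipeline can run on
data with known ground truth.

Noise model
-----------
Noise is additive Gaussian on log10 organ mass (multiplicative lognormal on
mass).  For the power-law regimes the configured ``noise_sd`` is placed on
the y-organ (leaf) and a matching ``noise_sd / b`` on the x-organ (stem), so
that the errors-in-variables ratio equals the generative slope and the
standardized-major-axis estimator is consistent for it; with noise on one
axis only, no slope-recovery criterion could be met by any estimator of the
sd-ratio form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator, interp1d
from scipy.special import expit, logit
from scipy.stats import norm

from .dataio import BiomassRecord, DataSet
from .errors import ConfigError

__all__ = [
    "SynthConfig",
    "DynamicTruth",
    "generate_fixed",
    "generate_dynamic",
    "generate_fraction_trajectory",
    "generate_rmf_uniform",
]


@dataclass
class SynthConfig:
    """Shared knobs for all synthetic regimes."""

    n_records: int = 1000
    log10_mass_range: tuple = (-3.0, 7.0)
    noise_sd: float = 0.15
    n_species: int = 50
    n_families: int = 10
    group_offsets: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.log10_mass_range
        if not lo < hi and self.n_records > 1:
            raise ConfigError("log10_mass_range must satisfy lo < hi")
        if self.n_records < 1:
            raise ConfigError("n_records must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def _species_labels(order_values: np.ndarray, cfg: SynthConfig):
    """Assign species contiguously by size and families contiguously by species."""
    n = len(order_values)
    n_species = min(cfg.n_species, n)
    species = np.empty(n, dtype=object)
    family = np.empty(n, dtype=object)
    rank = np.argsort(np.argsort(order_values, kind="stable"), kind="stable")
    block = rank * n_species // n  # species index per record
    per_family = -(-n_species // cfg.n_families)  # ceil
    for i in range(n):
        s = int(block[i])
        species[i] = f"sp{s:04d}"
        family[i] = f"fam{s // per_family:03d}"
    return species, family


def _to_dataset(log_leaf, log_stem, log_root, cfg: SynthConfig, labels=None, provenance=""):
    species, family = _species_labels(
        np.log10(10.0 ** log_leaf + 10.0 ** log_stem + 10.0 ** log_root), cfg
    )
    records = []
    for i in range(len(log_leaf)):
        records.append(
            BiomassRecord(
                record_id=f"syn{i:06d}",
                species=species[i],
                family=family[i],
                growth_form="woody",
                group_labels=labels[i] if labels is not None else frozenset(),
                leaf_mass=10.0 ** log_leaf[i],
                stem_mass=10.0 ** log_stem[i],
                root_mass=10.0 ** log_root[i],
                source_id="synthetic",
            )
        )
    return DataSet(records, provenance=provenance)


def generate_fixed(
    cfg: SynthConfig,
    b_leaf_stem: float = 0.75,
    b_stem_root: float = 1.0,
    a_leaf_stem: float = 1.3,
    a_stem_root: float = 1.0,
) -> DataSet:
    """Fixed-exponent power-law regime.

    Latent log10 stem mass is drawn log-uniformly over ``log10_mass_range``;
    leaf follows ``log10(a_ls) + b_ls * s``, root ``(s - log10(a_sr)) / b_sr``,
    with lognormal noise split between axes as described in the module
    docstring.
    """
    if b_leaf_stem <= 0 or b_stem_root <= 0:
        raise ConfigError("exponents must be > 0")
    lo, hi = cfg.log10_mass_range
    rng = np.random.default_rng(cfg.seed)
    s_star = rng.uniform(lo, hi, cfg.n_records)
    eps_y = rng.normal(0.0, cfg.noise_sd, cfg.n_records)
    eps_r = rng.normal(0.0, cfg.noise_sd, cfg.n_records)
    eps_x = rng.normal(0.0, cfg.noise_sd / b_leaf_stem, cfg.n_records)
    log_leaf = np.log10(a_leaf_stem) + b_leaf_stem * s_star + eps_y
    log_stem = s_star + eps_x
    log_root = (s_star - np.log10(a_stem_root)) / b_stem_root + eps_r
    return _to_dataset(log_leaf, log_stem, log_root, cfg, provenance="synthetic fixed regime")


@dataclass
class DynamicTruth:
    """Ground-truth exponent curve returned alongside a dynamic dataset."""

    b_of_log_stem: Callable
    log_total_grid: np.ndarray
    b_on_grid: np.ndarray
    _interp: Callable

    def b_at_log_total(self, log_total):
        return self._interp(log_total)


def generate_dynamic(
    cfg: SynthConfig,
    control_points: Sequence[tuple],
    a_leaf_stem: float = 1.3,
    b_stem_root: float = 1.0,
    a_stem_root: float = 1.0,
):
    """Smoothly size-varying exponent regime.

    ``control_points`` give ``(log10 stem mass, b)`` pairs; the exponent
    function is their monotone piecewise-cubic (PCHIP) interpolation and the
    leaf curve is its exact antiderivative, so the local derivative
    d log10(leaf) / d log10(stem) equals b everywhere.  Returns
    ``(DataSet, DynamicTruth)``; the truth object maps log10 total mass to
    the generative exponent for later comparison with estimates.
    """
    cp = sorted((float(x), float(b)) for x, b in control_points)
    cp_x = np.array([p[0] for p in cp])
    cp_b = np.array([p[1] for p in cp])
    if np.any(cp_b <= 0):
        raise ConfigError("exponent function must be > 0 everywhere")
    b_fun = PchipInterpolator(cp_x, cp_b, extrapolate=True)
    B = b_fun.antiderivative()
    lo, hi = cfg.log10_mass_range
    if not np.all(np.isfinite([B(lo), B(hi), B(0.0)])):
        raise ConfigError("non-finite integral of exponent function over range")

    rng = np.random.default_rng(cfg.seed)
    s_star = rng.uniform(lo, hi, cfg.n_records)
    eps_y = rng.normal(0.0, cfg.noise_sd, cfg.n_records)
    eps_r = rng.normal(0.0, cfg.noise_sd, cfg.n_records)
    b_mid = float(b_fun(0.5 * (lo + hi)))
    eps_x = rng.normal(0.0, cfg.noise_sd / b_mid, cfg.n_records)

    log_leaf = np.log10(a_leaf_stem) + (B(s_star) - B(0.0)) + eps_y
    log_stem = s_star + eps_x
    log_root = (s_star - np.log10(a_stem_root)) / b_stem_root + eps_r
    ds = _to_dataset(log_leaf, log_stem, log_root, cfg, provenance="synthetic dynamic regime")

    # Noiseless mapping from log10 total mass to the generative exponent.
    u = np.linspace(lo, hi, 2001)
    ll = np.log10(a_leaf_stem) + (B(u) - B(0.0))
    lr = (u - np.log10(a_stem_root)) / b_stem_root
    log_total = np.log10(10.0 ** ll + 10.0 ** u + 10.0 ** lr)
    interp = interp1d(log_total, b_fun(u), bounds_error=False,
                      fill_value=(b_fun(u[0]), b_fun(u[-1])))
    truth = DynamicTruth(b_of_log_stem=b_fun, log_total_grid=log_total,
                         b_on_grid=b_fun(u), _interp=interp)
    return ds, truth


def generate_fraction_trajectory(
    cfg: SynthConfig,
    lmf_points: Sequence[tuple],
    smf_points: Sequence[tuple],
    frac_noise_sd: float = 0.3,
    within_species_sd: float = 0.05,
) -> DataSet:
    """Size-dependent target fraction curves with logit-normal fraction noise.

    ``lmf_points`` / ``smf_points`` are ``(log10 total mass, fraction)``
    control points interpolated by PCHIP; RMF is the complement.  Per-record
    fractions are the targets perturbed on the logit scale and renormalized
    to sum to one; organ masses are fraction x total with the configured
    lognormal mass noise on top.

    Logit noise has two components, mirroring harvest series of coherent
    species: a species-level effect with sd ``frac_noise_sd`` (drawn once
    per species) and a record-level effect with sd ``within_species_sd``.

    A group offset of ``d`` percentile points moves the median record of the
    group to the ``(50 + d)``-th percentile of the base within-size
    distribution, i.e. a logit shift of ``s * Phi^-1((50+d)/100)`` with
    ``s`` the total logit sd.
    """
    lmf_fun = PchipInterpolator(*_cp_arrays(lmf_points), extrapolate=True)
    smf_fun = PchipInterpolator(*_cp_arrays(smf_points), extrapolate=True)
    lo, hi = cfg.log10_mass_range
    grid = np.linspace(lo, hi, 501)
    l_t, s_t = lmf_fun(grid), smf_fun(grid)
    if np.any(l_t <= 0) or np.any(l_t >= 1) or np.any(s_t <= 0) or np.any(s_t >= 1):
        raise ConfigError("target fraction curves must stay within (0,1) on the range")
    if np.any(l_t + s_t >= 1):
        raise ConfigError("LMF + SMF must stay < 1 so RMF > 0 on the range")

    rng = np.random.default_rng(cfg.seed)
    t = rng.uniform(lo, hi, cfg.n_records)
    lmf, smf = lmf_fun(t), smf_fun(t)
    rmf = 1.0 - lmf - smf

    species, family = _species_labels(t, cfg)
    sp_index = np.array([int(s[2:]) for s in species])
    n_species = min(cfg.n_species, cfg.n_records)
    sp_effect = rng.normal(0.0, frac_noise_sd, (n_species, 3))

    rec = rng.normal(0.0, within_species_sd, (cfg.n_records, 3))
    z_l = logit(lmf) + sp_effect[sp_index, 0] + rec[:, 0]
    z_s = logit(smf) + sp_effect[sp_index, 1] + rec[:, 1]
    z_r = logit(rmf) + sp_effect[sp_index, 2] + rec[:, 2]
    raw = np.column_stack([expit(z_l), expit(z_s), expit(z_r)])
    fractions = raw / raw.sum(axis=1, keepdims=True)

    # Group LMF offsets are applied to the renormalized fractions (the
    # renormalization would otherwise attenuate a pre-normalization shift),
    # calibrated against the realized logit spread so that an offset of d
    # percentile points lands the group's median record near the (50+d)-th
    # within-size percentile.
    group_keys = sorted(cfg.group_offsets)
    labels = None
    if group_keys:
        labels = [
            frozenset({group_keys[sp_index[i] % len(group_keys)]})
            for i in range(cfg.n_records)
        ]
        z0 = logit(fractions[:, 0])
        sd_emp = float(np.std(z0 - logit(lmf), ddof=1)) if cfg.n_records > 1 else 0.0
        offsets = np.array(
            [float(cfg.group_offsets[next(iter(lab))]) for lab in labels]
        )
        delta = sd_emp * norm.ppf(np.clip((50.0 + offsets) / 100.0, 1e-6, 1 - 1e-6))
        lmf_new = expit(z0 + delta)
        scale = (1.0 - lmf_new) / (1.0 - fractions[:, 0])
        fractions = np.column_stack(
            [lmf_new, fractions[:, 1] * scale, fractions[:, 2] * scale]
        )

    total = 10.0 ** t
    eps = rng.normal(0.0, cfg.noise_sd, (cfg.n_records, 3))
    log_masses = np.log10(fractions * total[:, None]) + eps
    records = []
    for i in range(cfg.n_records):
        records.append(
            BiomassRecord(
                record_id=f"syn{i:06d}",
                species=species[i],
                family=family[i],
                growth_form="woody",
                group_labels=labels[i] if labels is not None else frozenset(),
                leaf_mass=10.0 ** log_masses[i, 0],
                stem_mass=10.0 ** log_masses[i, 1],
                root_mass=10.0 ** log_masses[i, 2],
                source_id="synthetic",
            )
        )
    return DataSet(records, provenance="synthetic fraction trajectory regime")


def _cp_arrays(points):
    pts = sorted((float(x), float(y)) for x, y in points)
    return np.array([p[0] for p in pts]), np.array([p[1] for p in pts])


def generate_rmf_uniform(n: int, log10_mass_range=(-3.0, 7.0), seed: int = 0):
    """Bounded-random-fraction regime for the r2-inflation demonstration.

    Total mass log-uniform over the range, RMF ~ Uniform(0.01, 0.99);
    root = RMF * total and shoot = total - root (so shoot + root == total
    exactly).  Returns a pandas DataFrame with columns
    ``total_mass, shoot_mass, root_mass, rmf``.
    """
    import pandas as pd

    if n < 3:
        raise ConfigError("n must be >= 3")
    lo, hi = log10_mass_range
    rng = np.random.default_rng(seed)
    total = 10.0 ** rng.uniform(lo, hi, n)
    rmf = rng.uniform(0.01, 0.99, n)
    root = rmf * total
    shoot = total - root
    # re-derive total as the sum so shoot + root == total holds bit-exactly
    return pd.DataFrame(
        {"total_mass": shoot + root, "shoot_mass": shoot, "root_mass": root, "rmf": rmf}
    )
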