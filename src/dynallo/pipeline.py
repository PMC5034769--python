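"""End-to-end orchestration: data -> fits -> slope curves -> fractions -> percentiles.

A :class:`RunConfig` names either an input file or a synthetic regime, plus
the analysis knobs.  :func:`run_all` executes every stage in a fixed order,
writes per-stage CSV/JSON artifacts into the output directory and returns a
single machine-readable summary.  Per-stage random generators are derived
from the one run seed by hashing the stage name, so adding a stage never
perturbs the draws of earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import AllometricPair, fit_polynomial, fit_sma, select_model
from .clasmometry import compute_fractions, fraction_trend
from .dataio import DataSet, Dialect, filter_records, read_dataset
from .dynamic_slopes import bootstrap_slope_curve, make_bins
from .errors import ConfigError
from .percentiles import (
    family_summaries,
    percentile_ranks,
    species_summaries,
    variance_partition,
)
from . import synthetic_data

log = logging.getLogger("dynallo")

PAIRS = (("leaf", "stem"), ("leaf", "root"), ("stem", "root"))


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed: run seed combined with a stage-name hash."""
    h = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([int(base_seed), h]).generate_state(1)[0])


@dataclass
class RunConfig:
    input_path: str | None = None
    synth: dict | None = None       # {'regime': ..., regime kwargs...}
    dialect: Dialect = field(default_factory=Dialect)
    filters: list = field(default_factory=list)
    n_bins: int = 50
    span: float = 0.75
    n_boot: int = 1000
    seed: int = 0
    outdir: str = "dynallo_out"
    min_records_per_species: int = 4
    min_species_per_family: int = 4

    def __post_init__(self):
        if (self.input_path is None) == (self.synth is None):
            raise ConfigError("exactly one of input_path / synth must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "dialect" in data:
            data["dialect"] = Dialect(**data["dialect"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**data)


def _load(cfg: RunConfig) -> DataSet:
    if cfg.input_path is not None:
        return read_dataset(cfg.input_path, cfg.dialect)
    synth = dict(cfg.synth)
    regime = synth.pop("regime")
    scfg_keys = {f.name for f in dataclasses.fields(synthetic_data.SynthConfig)}
    scfg = synthetic_data.SynthConfig(
        **{k: v for k, v in synth.items() if k in scfg_keys},
    )
    if "seed" not in synth:
        scfg.seed = stage_seed(cfg.seed, "simulate")
    extra = {k: v for k, v in synth.items() if k not in scfg_keys}
    if regime == "fixed":
        return synthetic_data.generate_fixed(scfg, **extra)
    if regime == "dynamic":
        ds, _truth = synthetic_data.generate_dynamic(scfg, **extra)
        return ds
    if regime == "fraction_trajectory":
        return synthetic_data.generate_fraction_trajectory(scfg, **extra)
    raise ConfigError(f"unknown synthetic regime {regime!r}")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_all(cfg: RunConfig) -> dict:
    """Run the complete analysis; write artifacts; return the summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": {
            "input_path": cfg.input_path,
            "synth": _jsonable(cfg.synth),
            "n_bins": cfg.n_bins,
            "span": cfg.span,
            "n_boot": cfg.n_boot,
            "seed": cfg.seed,
        },
        "version": __version__,
    }
    stage = "load"
    try:
        ds = _load(cfg)
        if cfg.filters:
            result = filter_records(ds, [tuple(a) for a in cfg.filters])
            summary["filter_removed"] = result.removed
            ds = result.dataset
        summary["n_records"] = len(ds)
        log.info("loaded %d records", len(ds))

        stage = "allometry"
        allo = {}
        for y_organ, x_organ in PAIRS:
            pair = AllometricPair.from_dataset(ds, y_organ, x_organ)
            sma = fit_sma(pair)
            fits = fit_polynomial(pair, max_degree=3)
            best = select_model(fits)
            key = f"{y_organ}_vs_{x_organ}"
            allo[key] = {
                "sma": {"a_log": sma.a_log, "b": sma.b, "ci_b": list(sma.ci_b),
                        "r2": sma.r2, "n": sma.n, "operation": "fit_sma"},
                "poly": [
                    {
                        "degree": f.degree, "a_log": f.a_log,
                        "coefs": _jsonable(f.coefs), "bic": f.bic,
                        "delta_bic_vs_linear": f.delta_bic_vs_linear,
                        "r2": f.r2,
                        "term_pvalues": _jsonable(f.term_pvalues),
                        "operation": "fit_polynomial",
                    }
                    for f in fits
                ],
                "selected_degree": best.degree,
            }
            (outdir / f"sma_{key}.json").write_text(
                json.dumps(_jsonable(allo[key]["sma"]), indent=2, sort_keys=True)
            )
        summary["allometry"] = allo

        stage = "slopes"
        binning = make_bins(ds, n_bins=cfg.n_bins)
        slope_summary = {}
        for y_organ, x_organ in PAIRS:
            curve = bootstrap_slope_curve(
                ds, y_organ, x_organ, n_bins=cfg.n_bins, n_boot=cfg.n_boot,
                span=cfg.span, seed=stage_seed(cfg.seed, f"slopes:{y_organ}:{x_organ}"),
            )
            key = f"{y_organ}_vs_{x_organ}"
            pd.DataFrame(
                {"log10_total_mass": curve.grid, "slope": curve.slope,
                 "lo": curve.lo, "hi": curve.hi}
            ).to_csv(outdir / f"slopes_{key}.csv", index=False)
            slope_summary[key] = {
                "slope_first": float(curve.slope[0]),
                "slope_last": float(curve.slope[-1]),
                "n_boot": curve.n_boot,
                "operation": "bootstrap_slope_curve",
            }
        summary["slopes"] = slope_summary

        stage = "fractions"
        fr = compute_fractions(ds)
        pd.DataFrame(
            {"record_id": fr.record_ids, "lmf": fr.lmf, "smf": fr.smf, "rmf": fr.rmf}
        ).to_csv(outdir / "fractions.csv", index=False)
        trends = {}
        for which in ("lmf", "smf", "rmf"):
            trend = fraction_trend(ds, which, binning, span=cfg.span)
            pd.DataFrame(
                {"log10_total_mass": trend.grid, which: trend.curve}
            ).to_csv(outdir / f"trend_{which}.csv", index=False)
            trends[which] = {"r2_records": trend.r2_records, "r2_bins": trend.r2_bins,
                             "operation": "fraction_trend"}
        summary["fraction_trends"] = trends

        stage = "percentiles"
        pt = percentile_ranks(ds, binning)
        pd.DataFrame(
            {"record_id": pt.record_ids, "bin": pt.bin_index,
             "p_lmf": pt.p_lmf, "p_smf": pt.p_smf, "p_rmf": pt.p_rmf}
        ).to_csv(outdir / "percentiles_records.csv", index=False)
        per_mode = {}
        for mode, min_rec in (("min4", cfg.min_records_per_species), ("min1", 1)):
            sp = species_summaries(pt, min_records=min_rec)
            fams = family_summaries(sp, mode=mode, min_species=cfg.min_species_per_family)
            pd.DataFrame(
                [
                    {"family": f.family, "n_species": f.n_species,
                     "median_p_lmf": f.median_p["lmf"], "p_value_lmf": f.p_value["lmf"]}
                    for f in fams
                ]
            ).to_csv(outdir / f"families_{mode}.csv", index=False)
            per_mode[mode] = {
                f.family: {"median_p_lmf": f.median_p["lmf"], "n_species": f.n_species}
                for f in fams
            }
        summary["families"] = per_mode
        try:
            vp = variance_partition(pt, "lmf")
            summary["variance_partition_plmf"] = {
                "species": vp.species_prop + vp.family_prop,
                "family": vp.family_prop,
                "residual": vp.residual_prop,
                "operation": "variance_partition",
            }
        except Exception as exc:  # single-species sets etc.
            summary["variance_partition_plmf"] = {"error": str(exc)}
    except Exception:
        log.exception("stage %r failed; partial outputs kept in %s", stage, outdir)
        raise

    text = json.dumps(_jsonable(summary), indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(text)
    return summary
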