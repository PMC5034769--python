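"""Size-corrected percentile ranks of biomass fractions and group statistics.

Within each size class the fraction values are ranked (midranks for ties)
and converted to percentiles via ``(rank - 0.5) / n * 100``, which makes the
within-class mean exactly 50 and avoids 0/100 extremes.  Species medians,
family medians (two species-filter modes), Welch/ANOVA group contrasts and
a sequential sums-of-squares variance partition are built on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clasmometry import compute_fractions
from .dataio import DataSet
from .dynamic_slopes import SizeBinning
from .errors import DegenerateInputError

__all__ = [
    "PercentileTable",
    "SpeciesSummary",
    "FamilySummary",
    "GroupContrast",
    "VariancePartition",
    "percentile_ranks",
    "species_summaries",
    "family_summaries",
    "variance_partition",
    "variance_partition_values",
    "group_contrast",
    "group_anova",
    "significance_stars",
]

_FRACTIONS = ("lmf", "smf", "rmf")


@dataclass
class PercentileTable:
    record_ids: np.ndarray
    species: np.ndarray
    families: np.ndarray
    group_labels: list            # per record frozenset
    bin_index: np.ndarray
    p_lmf: np.ndarray
    p_smf: np.ndarray
    p_rmf: np.ndarray
    singleton_bins: np.ndarray    # bin indices that contained a single record

    def values(self, which: str) -> np.ndarray:
        if which not in _FRACTIONS:
            raise ValueError(f"fraction must be one of {_FRACTIONS}")
        return getattr(self, f"p_{which}")


def percentile_ranks(ds: DataSet, binning: SizeBinning) -> PercentileTable:
    """Within-class percentile rank of each record's LMF, SMF and RMF."""
    fr = compute_fractions(ds)
    n = len(ds)
    out = {w: np.empty(n) for w in _FRACTIONS}
    for members in binning.members:
        nb = len(members)
        for w in _FRACTIONS:
            ranks = stats.rankdata(fr.values(w)[members], method="average")
            out[w][members] = (ranks - 0.5) / nb * 100.0
    return PercentileTable(
        record_ids=fr.record_ids,
        species=ds.species,
        families=ds.families,
        group_labels=[r.group_labels for r in ds.records],
        bin_index=binning.assignment.copy(),
        p_lmf=out["lmf"],
        p_smf=out["smf"],
        p_rmf=out["rmf"],
        singleton_bins=np.flatnonzero(binning.counts == 1),
    )


@dataclass
class SpeciesSummary:
    species: str
    family: str
    n_records: int
    group_labels: frozenset
    median_p: dict      # fraction -> median percentile
    t_statistic: dict   # fraction -> t vs 50 (NaN if undefined)
    p_value: dict       # fraction -> two-sided p (NaN if undefined)


def _t_vs_50(values: np.ndarray):
    if len(values) < 2 or np.std(values, ddof=1) == 0:
        return float("nan"), float("nan")
    t, p = stats.ttest_1samp(values, 50.0)
    return float(t), float(p)


def species_summaries(pt: PercentileTable, min_records: int = 4) -> list:
    """Per-species medians of the pooled percentiles with a t-test vs 50.

    Species with fewer than ``min_records`` records are excluded
    (``min_records=1`` gives the quantity-of-species mode).
    """
    order = {}
    for i, sp in enumerate(pt.species):
        order.setdefault(sp, []).append(i)
    summaries = []
    for sp, idx in order.items():
        if len(idx) < min_records:
            continue
        idx = np.asarray(idx)
        med, tstat, pval = {}, {}, {}
        for w in _FRACTIONS:
            vals = pt.values(w)[idx]
            med[w] = float(np.median(vals))
            tstat[w], pval[w] = _t_vs_50(vals)
        labels = frozenset().union(*(pt.group_labels[i] for i in idx))
        summaries.append(
            SpeciesSummary(
                species=sp,
                family=str(pt.families[idx[0]]),
                n_records=len(idx),
                group_labels=labels,
                median_p=med,
                t_statistic=tstat,
                p_value=pval,
            )
        )
    return summaries


@dataclass
class FamilySummary:
    family: str
    n_species: int
    mode: str                  # 'min4' or 'min1'
    median_p: dict             # fraction -> median over species medians
    t_statistic: dict
    p_value: dict


def family_summaries(summaries: list, mode: str = "min4", min_species: int = 4) -> list:
    """Family medians over species medians (species weighted equally).

    ``summaries`` should come from :func:`species_summaries` with
    ``min_records=4`` for mode ``'min4'`` and ``min_records=1`` for
    ``'min1'``.  Families with fewer than ``min_species`` qualifying
    species are excluded.
    """
    if mode not in ("min4", "min1"):
        raise ValueError("mode must be 'min4' or 'min1'")
    by_family = {}
    for s in summaries:
        by_family.setdefault(s.family, []).append(s)
    out = []
    for fam in sorted(by_family):
        group = by_family[fam]
        if len(group) < min_species:
            continue
        med, tstat, pval = {}, {}, {}
        for w in _FRACTIONS:
            vals = np.array([s.median_p[w] for s in group])
            med[w] = float(np.median(vals))
            tstat[w], pval[w] = _t_vs_50(vals)
        out.append(
            FamilySummary(
                family=fam,
                n_species=len(group),
                mode=mode,
                median_p=med,
                t_statistic=tstat,
                p_value=pval,
            )
        )
    return out


@dataclass
class VariancePartition:
    family_prop: float
    species_prop: float
    residual_prop: float


def variance_partition_values(values, species, families) -> VariancePartition:
    """Sequential (hierarchical) SS partition: family, then species in family."""
    values = np.asarray(values, dtype=float)
    species = np.asarray(species, dtype=object)
    families = np.asarray(families, dtype=object)
    if len(set(species)) < 2:
        raise DegenerateInputError("variance partition needs at least 2 species")
    grand = values.mean()
    ss_tot = float(((values - grand) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateInputError("no variation in values")
    fam_mean = {f: values[families == f].mean() for f in set(families)}
    ss_fam = sum(
        (families == f).sum() * (fam_mean[f] - grand) ** 2 for f in fam_mean
    )
    ss_sp = 0.0
    for sp in set(species):
        mask = species == sp
        ss_sp += mask.sum() * (values[mask].mean() - fam_mean[families[mask][0]]) ** 2
    return VariancePartition(
        family_prop=float(ss_fam / ss_tot),
        species_prop=float(ss_sp / ss_tot),
        residual_prop=float(1.0 - (ss_fam + ss_sp) / ss_tot),
    )


def variance_partition(pt: PercentileTable, which: str = "lmf") -> VariancePartition:
    """Partition of per-record percentile variance into family/species/residual."""
    return variance_partition_values(pt.values(which), pt.species, pt.families)


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "+"))


def significance_stars(p: float) -> str:
    """ns / + / * / ** / *** at (0.10, 0.05, 0.01, 0.001), half-open intervals."""
    if not np.isfinite(p):
        return "na"
    for threshold, stars in _STAR_LEVELS:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class GroupContrast:
    groups: tuple
    n_species: tuple
    statistic: float
    p_value: float
    stars: str
    test: str               # 'welch-t' or 'anova'
    medians: dict = field(default_factory=dict)


def _group_values(summaries, label, which):
    vals = [s.median_p[which] for s in summaries if label in s.group_labels]
    if len(vals) < 2:
        raise DegenerateInputError(f"group {label!r} has fewer than 2 species")
    return np.array(vals)


def group_contrast(summaries: list, group_a: str, group_b: str, which: str = "lmf") -> GroupContrast:
    """Welch's t-test on species-median percentiles between two labelled groups."""
    a = _group_values(summaries, group_a, which)
    b = _group_values(summaries, group_b, which)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupContrast(
        groups=(group_a, group_b),
        n_species=(len(a), len(b)),
        statistic=float(t),
        p_value=float(p),
        stars=significance_stars(float(p)),
        test="welch-t",
        medians={group_a: float(np.median(a)), group_b: float(np.median(b))},
    )


def group_anova(summaries: list, groups: list, which: str = "lmf") -> GroupContrast:
    """One-way ANOVA on species-median percentiles across > 2 labelled groups."""
    if len(groups) < 3:
        raise ValueError("use group_contrast for 2 groups")
    samples = [_group_values(summaries, g, which) for g in groups]
    f, p = stats.f_oneway(*samples)
    return GroupContrast(
        groups=tuple(groups),
        n_species=tuple(len(s) for s in samples),
        statistic=float(f),
        p_value=float(p),
        stars=significance_stars(float(p)),
        test="anova",
        medians={g: float(np.median(s)) for g, s in zip(groups, samples)},
    )
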