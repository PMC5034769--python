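import numpy as np
import pytest
from scipy import stats

from dynallo.dataio import DataSet
from dynallo.dynamic_slopes import make_bins
from dynallo.errors import DegenerateInputError
from dynallo.percentiles import (
    SpeciesSummary,
    family_summaries,
    group_anova,
    group_contrast,
    percentile_ranks,
    significance_stars,
    species_summaries,
    variance_partition_values,
)
from dynallo.synthetic_data import SynthConfig, generate_fraction_trajectory

from conftest import make_record

LMF_PTS = [(-3.0, 0.5), (7.0, 0.3)]
SMF_PTS = [(-3.0, 0.2), (7.0, 0.4)]


def dataset_with_lmf(lmf_values, species=None, total=100.0):
    """One-bin-sized dataset with prescribed LMF values (SMF fixed at 0.3)."""
    recs = []
    for i, lmf in enumerate(lmf_values):
        sp = species[i] if species is not None else f"s{i}"
        recs.append(
            make_record(
                i, lmf * total, 0.3 * total, (0.7 - lmf) * total, species=sp
            )
        )
    return DataSet(recs)


class TestPercentileRanks:
    def test_five_distinct_values(self):
        ds = dataset_with_lmf([0.1, 0.2, 0.3, 0.4, 0.5])
        pt = percentile_ranks(ds, make_bins(ds, 1))
        np.testing.assert_allclose(sorted(pt.p_lmf), [10, 30, 50, 70, 90])
        assert pt.p_lmf[2] == 50

    def test_ties_get_midrank(self):
        ds = dataset_with_lmf([0.1, 0.2, 0.2, 0.4])
        pt = percentile_ranks(ds, make_bins(ds, 1))
        # tied values occupy ranks 2,3 -> midrank 2.5 -> (2.5-0.5)/4*100 = 50
        assert pt.p_lmf[1] == pytest.approx(50.0)
        assert pt.p_lmf[2] == pytest.approx(50.0)

    def test_bin_mean_is_exactly_50(self):
        cfg = SynthConfig(n_records=1000, seed=3, noise_sd=0.1)
        ds = generate_fraction_trajectory(cfg, LMF_PTS, SMF_PTS)
        binning = make_bins(ds, 20)
        pt = percentile_ranks(ds, binning)
        for b in range(binning.n_bins):
            mask = pt.bin_index == b
            for vals in (pt.p_lmf, pt.p_smf, pt.p_rmf):
                assert np.mean(vals[mask]) == pytest.approx(50.0, abs=1e-9)

    def test_monotone_transform_invariance(self):
        ds = dataset_with_lmf([0.1, 0.25, 0.33, 0.4, 0.6])
        pt1 = percentile_ranks(ds, make_bins(ds, 1))
        # cubing LMF values preserves order, so percentiles are unchanged
        ds2 = dataset_with_lmf([v ** 3 for v in [0.1, 0.25, 0.33, 0.4, 0.6]])
        pt2 = percentile_ranks(ds2, make_bins(ds2, 1))
        np.testing.assert_allclose(pt1.p_lmf, pt2.p_lmf)

    def test_singleton_bin_gets_50_and_flag(self):
        ds = dataset_with_lmf([0.2])
        pt = percentile_ranks(ds, make_bins(ds, 1))
        assert pt.p_lmf[0] == 50.0
        assert 0 in pt.singleton_bins

    def test_pooled_distribution_uniform(self):
        cfg = SynthConfig(
            n_records=10000, seed=9, noise_sd=0.0, n_species=10000
        )  # one record per species -> no clustering
        ds = generate_fraction_trajectory(
            cfg, LMF_PTS, SMF_PTS, frac_noise_sd=0.3, within_species_sd=0.0
        )
        pt = percentile_ranks(ds, make_bins(ds, 50))
        d = stats.kstest(pt.p_lmf / 100.0, "uniform").statistic
        assert d < 0.02


class TestSpeciesSummaries:
    def _table(self, percentiles, species):
        ds = dataset_with_lmf(np.linspace(0.1, 0.6, len(percentiles)))
        pt = percentile_ranks(ds, make_bins(ds, 1))
        pt.p_lmf = np.asarray(percentiles, dtype=float)
        pt.p_smf = pt.p_lmf.copy()
        pt.p_rmf = pt.p_lmf.copy()
        pt.species = np.asarray(species, dtype=object)
        return pt

    def test_constant_percentiles_na_test(self):
        pt = self._table([50, 50, 50, 50], ["A"] * 4)
        (s,) = species_summaries(pt, min_records=4)
        assert s.median_p["lmf"] == 50
        assert np.isnan(s.p_value["lmf"])

    def test_shifted_species_significant(self):
        pt = self._table([80, 85, 90, 95], ["A"] * 4)
        (s,) = species_summaries(pt, min_records=4)
        assert s.median_p["lmf"] == pytest.approx(87.5)
        # hand check: mean 87.5, sd 6.455, t = 37.5/3.227 = 11.6
        assert s.t_statistic["lmf"] == pytest.approx(11.6189, abs=1e-3)
        assert s.p_value["lmf"] < 0.05

    def test_min_records_filter(self):
        pt = self._table([60, 70, 80, 90, 10, 20], ["A"] * 4 + ["B"] * 2)
        assert {s.species for s in species_summaries(pt, 4)} == {"A"}
        assert {s.species for s in species_summaries(pt, 1)} == {"A", "B"}

    def test_species_t_test_power_for_shifted_species(self):
        # A species shifted +15 percentile points against a broad background
        # population occupies a coherent band (records ~ N(65, 7) in
        # percentile space, as harvest series of one species do).  The
        # per-species t-test then detects it with power > 0.8 at 6 records.
        detected = 0
        reps = 500
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            vals = np.clip(rng.normal(65.0, 7.0, 6), 0.5, 99.5)
            t, p = stats.ttest_1samp(vals, 50.0)
            detected += (p < 0.05) and (np.median(vals) > 50)
        assert detected / reps > 0.8


class TestFamilySummaries:
    def _species(self, family, medians):
        return [
            SpeciesSummary(
                species=f"{family}-{i}",
                family=family,
                n_records=4,
                group_labels=frozenset(),
                median_p={"lmf": m, "smf": m, "rmf": m},
                t_statistic={"lmf": 0.0, "smf": 0.0, "rmf": 0.0},
                p_value={"lmf": 1.0, "smf": 1.0, "rmf": 1.0},
            )
            for i, m in enumerate(medians)
        ]

    def test_symmetric_family_not_significant(self):
        fams = family_summaries(self._species("F", [40, 45, 55, 60]))
        assert fams[0].median_p["lmf"] == 50
        assert fams[0].p_value["lmf"] == pytest.approx(1.0)

    def test_min_species_filter(self):
        summaries = self._species("big", [40, 45, 55, 60]) + self._species("small", [70, 80])
        fams = family_summaries(summaries, mode="min4", min_species=4)
        assert [f.family for f in fams] == ["big"]

    def test_shifted_family_detected(self):
        fams = family_summaries(self._species("F", [62, 68, 70, 75, 80]))
        assert fams[0].median_p["lmf"] == 70
        assert fams[0].p_value["lmf"] < 0.01


class TestVariancePartition:
    def test_identical_species_near_zero(self, rng):
        values = rng.normal(50, 10, 2000)
        species = np.repeat([f"s{i}" for i in range(100)], 20)
        families = np.repeat([f"f{i}" for i in range(10)], 200)
        vp = variance_partition_values(values, species, families)
        assert vp.family_prop + vp.species_prop < 0.10
        assert vp.residual_prop > 0.90

    def test_known_variance_components_recovered(self, rng):
        sigma_s, sigma_e = 8.0, 6.0
        n_species, per = 200, 25
        offsets = rng.normal(0, sigma_s, n_species)
        values = np.repeat(offsets, per) + rng.normal(0, sigma_e, n_species * per)
        species = np.repeat([f"s{i}" for i in range(n_species)], per)
        families = np.repeat("onefam", n_species * per)
        vp = variance_partition_values(values, species, families)
        expected = sigma_s ** 2 / (sigma_s ** 2 + sigma_e ** 2)
        assert vp.species_prop == pytest.approx(expected, abs=0.05)

    def test_proportions_sum_to_one(self, rng):
        values = rng.normal(0, 1, 300)
        species = np.repeat([f"s{i}" for i in range(30)], 10)
        families = np.repeat([f"f{i}" for i in range(6)], 50)
        vp = variance_partition_values(values, species, families)
        assert vp.family_prop + vp.species_prop + vp.residual_prop == pytest.approx(1.0)

    def test_single_species_error(self):
        with pytest.raises(DegenerateInputError):
            variance_partition_values([1.0, 2.0], ["a", "a"], ["f", "f"])


class TestGroupContrast:
    def _summaries(self, rng, n_a=20, n_b=20, shift=0.0):
        out = []
        for i in range(n_a):
            m = float(rng.normal(50 + shift, 10))
            out.append(
                SpeciesSummary(f"a{i}", "fa", 4, frozenset({"evergreen"}),
                               {"lmf": m, "smf": m, "rmf": m}, {}, {})
            )
        for i in range(n_b):
            m = float(rng.normal(50, 10))
            out.append(
                SpeciesSummary(f"b{i}", "fb", 4, frozenset({"deciduous"}),
                               {"lmf": m, "smf": m, "rmf": m}, {}, {})
            )
        return out

    def test_null_mostly_ns(self):
        ns = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            c = group_contrast(self._summaries(rng), "evergreen", "deciduous")
            ns += c.stars == "ns"
        assert ns / reps >= 0.80  # expect ~90% at alpha = 0.10

    def test_shifted_group_strongly_significant(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            c = group_contrast(self._summaries(rng, shift=15.0), "evergreen", "deciduous")
            hits += c.stars == "***"
        assert hits / reps > 0.5

    def test_direction_on_synthetic_offsets(self):
        cfg = SynthConfig(
            n_records=3000, seed=31, noise_sd=0.0, n_species=300,
            group_offsets={"evergreen": 15.0, "deciduous": 0.0},
        )
        ds = generate_fraction_trajectory(
            cfg, LMF_PTS, SMF_PTS, frac_noise_sd=0.3, within_species_sd=0.05
        )
        pt = percentile_ranks(ds, make_bins(ds, 20))
        sp = species_summaries(pt, min_records=4)
        c = group_contrast(sp, "evergreen", "deciduous")
        assert c.medians["evergreen"] > c.medians["deciduous"]
        assert c.p_value < 0.05

    def test_anova_needs_three_groups(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            group_anova(self._summaries(rng), ["evergreen", "deciduous"])

    def test_empty_group_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DegenerateInputError):
            group_contrast(self._summaries(rng), "evergreen", "palm")


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, "ns"), (0.10, "ns"), (0.07, "+"), (0.05, "+"), (0.03, "*"),
         (0.01, "*"), (0.005, "**"), (0.001, "**"), (0.0005, "***"),
         (float("nan"), "na")],
    )
    def test_half_open_bins(self, p, expected):
        assert significance_stars(p) == expected
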