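"""One-sided KS machinery, its calibration, and burden correlations."""

import numpy as np
import pytest
from scipy import stats

from neofit.seq_io import EpitopeRecord
from neofit.viral_compare import (
    burden_til_correlation,
    ecdf,
    ks_one_sided,
    subsampled_ks,
)


class TestKsOneSided:
    def test_identical_samples(self):
        x = np.arange(1.0, 101.0)
        res = ks_one_sided(x, x, method="asymp")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_complete_separation_in_hypothesized_direction(self):
        neo = np.arange(1.0, 101.0)
        res = ks_one_sided(neo, neo + 1000.0, method="asymp")
        assert res.statistic == 1.0
        assert res.pvalue < 1e-10

    def test_reversed_direction_floors_at_zero(self):
        neo = np.arange(1.0, 101.0)
        res = ks_one_sided(neo + 1000.0, neo, method="asymp")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_agrees_with_scipy_one_sided(self):
        """Statistic matches scipy exactly; the p-value uses the plain
        exponential tail bound, so it agrees with scipy's corrected
        asymptotic p only to leading order."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.lognormal(6.0, 1.0, 200)
            b = rng.lognormal(6.5, 1.2, 150)
            ours = ks_one_sided(a, b, method="asymp")
            ref = stats.ks_2samp(a, b, alternative="greater", method="asymp")
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.pvalue == pytest.approx(ref.pvalue, rel=0.3, abs=1e-3)
            assert ours.pvalue >= ref.pvalue  # scipy's correction only shrinks p

    def test_invariant_under_common_monotone_transform(self):
        rng = np.random.default_rng(9)
        a = rng.lognormal(6.0, 1.0, 300)
        b = rng.lognormal(6.4, 1.0, 250)
        d1 = ks_one_sided(a, b).statistic
        d2 = ks_one_sided(np.log(a), np.log(b)).statistic
        assert d1 == pytest.approx(d2, abs=1e-15)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_one_sided([], [1.0])

    def test_permutation_p_close_to_asymptotic(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(0.5, 1.0, 40)
        p_perm = ks_one_sided(a, b, method="permutation", n_permutations=2000).pvalue
        p_asym = ks_one_sided(a, b, method="asymp").pvalue
        assert p_perm == pytest.approx(p_asym, abs=0.05)


class TestSubsampledKs:
    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        neo = rng.lognormal(6.0, 1.5, 3000)
        viral = rng.lognormal(7.0, 1.5, 3000)
        a = subsampled_ks(neo, viral, m=200, reps=50, seed=4)
        b = subsampled_ks(neo, viral, m=200, reps=50, seed=4)
        assert np.array_equal(a.statistics, b.statistics)
        assert a.rejection_fraction == b.rejection_fraction

    def test_null_calibration_quick(self):
        # populations much larger than the subsample, so the fixed
        # population-level ECDF gap is negligible against subsample noise
        rng = np.random.default_rng(2)
        res = subsampled_ks(
            rng.lognormal(6.0, 1.5, 20_000),
            rng.lognormal(6.0, 1.5, 20_000),
            m=200,
            reps=100,
            seed=3,
        )
        assert res.rejection_fraction <= 0.12

    def test_power_under_planted_shift(self):
        rng = np.random.default_rng(3)
        neo = rng.lognormal(5.0, 1.5, 5000)
        viral = rng.lognormal(6.5, 1.5, 5000)
        res = subsampled_ks(neo, viral, m=500, reps=50, seed=5)
        assert res.rejection_fraction == 1.0

    def test_small_population_samples_with_replacement(self):
        rng = np.random.default_rng(4)
        neo = rng.lognormal(6.0, 1.0, 50)
        viral = rng.lognormal(6.0, 1.0, 50)
        with pytest.warns(UserWarning, match="replacement"):
            res = subsampled_ks(neo, viral, m=200, reps=10, seed=6)
        assert res.replicates == 10

    def test_rejection_monotone_in_shift(self):
        rng = np.random.default_rng(7)
        base = rng.lognormal(6.0, 1.0, 4000)
        fracs = []
        for shift in (0.0, 0.4, 1.0):
            neo = base * np.exp(-shift)
            fracs.append(
                subsampled_ks(neo, base, m=300, reps=60, seed=8).rejection_fraction
            )
        assert fracs == sorted(fracs)


class TestEcdf:
    def test_nondecreasing_and_terminates_at_one(self):
        c = ecdf([3.0, 1.0, 2.0, 2.0])
        assert np.all(np.diff(c.fractions) >= 0)
        assert c.fractions[-1] == 1.0
        assert np.all(np.diff(c.values) >= 0)


class TestBurdenCorrelation:
    def _patients(self, til):
        import pandas as pd

        return pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(len(til))], "til_burden": til}
        )

    def _records(self, counts, ic50=100.0, viral=False):
        records = []
        for i, k in enumerate(counts):
            for _ in range(k):
                records.append(
                    EpitopeRecord(
                        f"p{i}",
                        "KLLEIFTEL",
                        None if viral else "KLLEIFSEL",
                        "HLA-A*02:01",
                        ic50,
                        None if viral else 500.0,
                    )
                )
        return records

    def test_perfect_rank_agreement(self):
        counts = [1, 2, 3, 4, 5, 6, 7, 8]
        patients = self._patients([10.0 * c for c in counts])
        out = burden_til_correlation(patients, self._records(counts), [])
        assert out["neo"][0] == pytest.approx(1.0)

    def test_weak_binders_do_not_count(self):
        counts = [1, 2, 3, 4, 5]
        patients = self._patients([1.0, 2.0, 3.0, 4.0, 5.0])
        weak = self._records(counts, ic50=5000.0)
        out = burden_til_correlation(patients, weak, [])
        assert np.isnan(out["neo"][0])  # all burdens zero -> undefined

    def test_planted_correlation_recovered_at_cohort_scale(self):
        """rho0 = 0.25 between neo burden and TIL recovered within +-0.15
        at n = 88; a null viral burden stays within the sampling envelope."""
        rng = np.random.default_rng(11)
        n = 88
        r = 2 * np.sin(np.pi * 0.25 / 6)
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
        til = np.exp(z[:, 0])
        neo_counts = np.maximum(0, np.round(8 + 4 * z[:, 1])).astype(int)
        viral_counts = rng.poisson(8, size=n)
        patients = self._patients(til)
        out = burden_til_correlation(
            patients,
            self._records(neo_counts),
            self._records(viral_counts, viral=True),
        )
        assert out["neo"][0] == pytest.approx(0.25, abs=0.15)
        assert abs(out["viral"][0]) < 0.2

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            burden_til_correlation(self._patients([1.0, 2.0]), [], [])
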