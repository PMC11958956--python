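"""Unit and property tests for the two biological-age clocks."""

import numpy as np
import pandas as pd
import pytest

import bioaging_mixtures as bm
from bioaging_mixtures import synthdata
from bioaging_mixtures.clocks import PHENOAGE_BIOMARKERS


# -- independent transcription of the phenotypic-age equations --------------
# (used as an oracle against the packaged constants file)

def phenoage_oracle(v, age):
    xb = (-19.907 - 0.0336 * v["albumin"] + 0.0095 * v["creatinine"]
          + 0.1953 * v["glucose"] + 0.0954 * v["ln_crp"]
          - 0.0120 * v["lymphocyte_pct"] + 0.0268 * v["mcv"]
          + 0.3306 * v["rdw"] + 0.0019 * v["alp"] + 0.0554 * v["wbc"]
          + 0.0804 * age)
    mortality = 1.0 - np.exp(-1.51714 * np.exp(xb) / 0.0076927)
    pheno = 141.50 + np.log(-0.00553 * np.log(1.0 - mortality)) / 0.09165
    return xb, mortality, pheno


def _random_biomarkers(rng, n):
    return {
        "albumin": rng.uniform(35, 52, n),
        "creatinine": rng.uniform(40, 120, n),
        "glucose": rng.uniform(3.5, 9.0, n),
        "ln_crp": rng.uniform(-3.0, 2.0, n),
        "lymphocyte_pct": rng.uniform(15, 55, n),
        "mcv": rng.uniform(75, 100, n),
        "rdw": rng.uniform(11, 16, n),
        "alp": rng.uniform(30, 130, n),
        "wbc": rng.uniform(3, 12, n),
    }


class TestPhenoAge:
    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(1)
        v = _random_biomarkers(rng, 500)
        age = rng.uniform(20, 80, 500)
        xb, mort, pheno = bm.phenoage(v, age)
        oxb, omort, opheno = phenoage_oracle(v, age)
        np.testing.assert_allclose(xb, oxb, atol=1e-10)
        np.testing.assert_allclose(mort, omort, atol=1e-10)
        np.testing.assert_allclose(pheno, opheno, atol=1e-10)

    def test_age_partial_difference(self):
        rng = np.random.default_rng(2)
        v = {k: val[:1] for k, val in _random_biomarkers(rng, 1).items()}
        xb50, *_ = bm.phenoage(v, np.array([50.0]))
        xb51, *_ = bm.phenoage(v, np.array([51.0]))
        assert abs((xb51 - xb50)[0] - 0.0804) < 1e-10

    def test_monotone_in_xb(self):
        # raising any positively-weighted biomarker raises phenotypic age
        rng = np.random.default_rng(3)
        v = _random_biomarkers(rng, 50)
        _, _, p0 = bm.phenoage(v, np.full(50, 50.0))
        for eps in (1e-3, 0.1, 1.0):
            v2 = dict(v)
            v2["rdw"] = v["rdw"] + eps
            _, _, p1 = bm.phenoage(v2, np.full(50, 50.0))
            assert np.all(p1 > p0)

    def test_batch_and_row_order_invariance(self, small_cohort):
        table, _ = small_cohort
        full = bm.phenoage_table(table, warn_implausible=False)
        perm = np.random.default_rng(4).permutation(len(table))
        shuffled = bm.phenoage_table(table.iloc[perm], warn_implausible=False)
        np.testing.assert_array_equal(
            full["phenotypic_age"].to_numpy()[perm],
            shuffled["phenotypic_age"].to_numpy(),
        )
        one = bm.phenoage_table(table.iloc[[7]], warn_implausible=False)
        assert one["phenotypic_age"].iloc[0] == full["phenotypic_age"].iloc[7]

    def test_rejects_missing_biomarker_and_nonfinite(self):
        rng = np.random.default_rng(5)
        v = _random_biomarkers(rng, 3)
        bad = dict(v)
        del bad["rdw"]
        with pytest.raises(ValueError, match="missing"):
            bm.phenoage(bad, np.full(3, 50.0))
        v["mcv"][1] = np.nan
        with pytest.raises(ValueError, match="mcv"):
            bm.phenoage(v, np.full(3, 50.0))

    def test_crp_floor_applies(self):
        table = pd.DataFrame({
            "ph_albumin": [45.0], "ph_creatinine": [70.0], "ph_glucose": [5.0],
            "ph_crp": [0.0], "ph_lymphpct": [30.0], "ph_mcv": [88.0],
            "ph_rdw": [13.0], "ph_alp": [60.0], "ph_wbc": [7.0], "age": [50.0],
        })
        with pytest.warns(UserWarning, match="floored"):
            out = bm.phenoage_table(table, warn_implausible=False)
        assert np.isfinite(out["phenotypic_age"]).all()

    def test_all_finite_on_default_cohort(self, small_cohort):
        table, _ = small_cohort
        assert np.isfinite(table["phenotypic_age"]).all()
        assert np.isfinite(table["kdm_biological_age"]).all()


class TestKDM:
    def test_exact_linear_single_biomarker(self):
        age = np.linspace(20, 80, 200)
        x = 2.0 + 0.5 * age + 1e-9 * np.sin(age)
        tr = bm.fit_kdm(x[:, None], age, names=["b"])
        assert abs(tr.k[0] - 0.5) < 1e-6
        assert abs(tr.q[0] - 2.0) < 1e-6
        assert tr.r2[0] > 1 - 1e-9

    def test_rchar_is_slope_weighted_average(self, small_cohort):
        # independent transcription of the characteristic-correlation formula
        table, _ = small_cohort
        tr = bm.fit_kdm(table[list(synthdata.KDM_BIOMARKERS)], table["age"],
                        names=list(synthdata.KDM_BIOMARKERS))
        w = tr.k / tr.s
        r = np.sign(tr.k) * np.sqrt(tr.r2)
        assert abs(tr.r_char - (w * r).sum() / w.sum()) < 1e-12

    def test_hand_built_two_biomarker_formula(self):
        # k=(1,2), q=(0,0), s=(1,1), s_BA^2=25, CA=50, x=(60,90):
        # BA = (60*1 + 90*2 + 50/25) / (1 + 4 + 1/25)  [spreadsheet oracle]
        tr = bm.KDMTraining(
            biomarkers=["a", "b"], k=np.array([1.0, 2.0]),
            q=np.array([0.0, 0.0]), s=np.array([1.0, 1.0]),
            r2=np.array([0.5, 0.5]), r_char=0.7, s_ba2=25.0,
            ca_min=20.0, ca_max=80.0,
        )
        ba = bm.kdm_biological_age(np.array([[60.0, 90.0]]), 50.0, tr)
        expected = (60 * 1 / 1 + 90 * 2 / 1 + 50 / 25) / (1 + 4 + 1 / 25)
        assert abs(ba[0] - expected) < 1e-12

    def test_noiseless_identity_and_large_sba2_limit(self):
        tr = bm.KDMTraining(
            biomarkers=["a", "b"], k=np.array([0.5, -0.2]),
            q=np.array([10.0, 40.0]), s=np.array([1.0, 2.0]),
            r2=np.array([0.8, 0.6]), r_char=0.7, s_ba2=30.0,
            ca_min=20.0, ca_max=80.0,
        )
        ca = np.array([35.0, 50.0, 72.0])
        x = tr.q[None, :] + tr.k[None, :] * ca[:, None]
        np.testing.assert_allclose(bm.kdm_biological_age(x, ca, tr), ca,
                                   atol=1e-10)
        # s_BA^2 -> inf: shrinkage toward CA vanishes, BA -> BA_E
        x2 = x + np.array([1.0, -0.5])
        tr_wide = bm.KDMTraining(
            biomarkers=tr.biomarkers, k=tr.k, q=tr.q, s=tr.s, r2=tr.r2,
            r_char=tr.r_char, s_ba2=1e12, ca_min=20.0, ca_max=80.0,
        )
        np.testing.assert_allclose(
            bm.kdm_biological_age(x2, ca, tr_wide), bm.kdm_ba_e(x2, tr),
            rtol=1e-6)

    def test_parameter_recovery_on_synthetic_cohort(self):
        config = bm.SimConfig(n_participants=5000, seed=11)
        table, truth = bm.generate_cohort(config)
        age = table["age"].to_numpy()
        tr = bm.fit_kdm(table[list(synthdata.KDM_BIOMARKERS)], age,
                        names=list(synthdata.KDM_BIOMARKERS))
        sxx = np.sum((age - age.mean()) ** 2)
        for j, name in enumerate(synthdata.KDM_BIOMARKERS):
            se_k = tr.s[j] / np.sqrt(sxx)
            se_q = tr.s[j] * np.sqrt(1 / len(age) + age.mean() ** 2 / sxx)
            assert abs(tr.k[j] - truth.biomarker_slopes[name]) < 3 * se_k, name
            assert abs(tr.q[j] - truth.biomarker_intercepts[name]) < 3 * se_q, name

    def test_noise_shrink_limit(self):
        # mean |BA - CA| decreases monotonically as biomarker noise shrinks
        errs = []
        for sd_scale in (1.0, 0.5, 0.1, 0.01):
            specs = {
                name: synthdata.BiomarkerSpec(s.slope, s.intercept,
                                              max(s.sd * sd_scale, 1e-6))
                for name, s in synthdata._default_biomarkers().items()
            }
            config = bm.SimConfig(n_participants=600, seed=13,
                                  biomarker_specs=specs)
            table, _ = bm.generate_cohort(config)
            tr = bm.fit_kdm(table[list(synthdata.KDM_BIOMARKERS)],
                            table["age"], names=list(synthdata.KDM_BIOMARKERS))
            ba = bm.kdm_biological_age(table[list(synthdata.KDM_BIOMARKERS)],
                                       table["age"], tr)
            errs.append(np.mean(np.abs(ba - table["age"])))
        assert errs == sorted(errs, reverse=True)
        # residual floor is set by the k/s ratios of the panel (~0.17 y here)
        assert errs[-1] < 0.25

    def test_bootstrap_rchar_stability(self):
        config = bm.SimConfig(n_participants=5000, seed=17)
        table, _ = bm.generate_cohort(config)
        panel = table[list(synthdata.KDM_BIOMARKERS)]
        tr = bm.fit_kdm(panel, table["age"], names=list(synthdata.KDM_BIOMARKERS))
        rng = np.random.default_rng(18)
        idx = rng.integers(0, len(table), len(table))
        tr_b = bm.fit_kdm(panel.iloc[idx], table["age"].to_numpy()[idx],
                          names=list(synthdata.KDM_BIOMARKERS))
        assert abs(tr.r_char - tr_b.r_char) < 0.05

    def test_error_conditions(self):
        age = np.linspace(20, 80, 100)
        rng = np.random.default_rng(19)
        noisy = 3.0 + 0.1 * age + rng.normal(0, 0.5, 100)
        with pytest.raises(ValueError, match="zero age slope"):
            bm.fit_kdm(np.column_stack([np.full(100, 5.0), noisy]), age,
                       names=["flat", "ok"])
        with pytest.raises(ValueError, match="constant"):
            bm.fit_kdm(noisy[:, None], np.full(100, 50.0))
        tr = bm.fit_kdm((2 + 0.5 * age + rng.normal(0, 1, 100))[:, None], age)
        with pytest.raises(ValueError, match="missing"):
            bm.kdm_biological_age(np.array([[np.nan]]), 50.0, tr)

    def test_training_roundtrip(self, small_cohort):
        table, _ = small_cohort
        tr = bm.fit_kdm(table[list(synthdata.KDM_BIOMARKERS)], table["age"],
                        names=list(synthdata.KDM_BIOMARKERS))
        back = bm.KDMTraining.from_text(tr.to_text())
        np.testing.assert_array_equal(tr.k, back.k)
        np.testing.assert_array_equal(tr.s, back.s)
        assert tr.r_char == back.r_char and tr.s_ba2 == back.s_ba2
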