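"""Standardization, PGS construction and Steiger filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import chronomr as cm
from chronomr.prep import (
    PGSWeights,
    point_biserial_outcome_correlations,
    pooled_age_stratum,
)


def toy_cohort(ages, sexes, exposure):
    return pd.DataFrame(
        {
            "id": np.arange(len(ages)),
            "age_at_assessment": ages,
            "sex": sexes,
            "exposure_raw": exposure,
        }
    )


class TestZTransform:
    def test_every_stratum_standardized(self, rng):
        n = 5000
        coh = toy_cohort(
            rng.integers(35, 75, n), rng.integers(0, 2, n), rng.normal(27, 5, n)
        )
        out = cm.ztransform_by_stratum(coh)
        key = [pooled_age_stratum(out["age_at_assessment"].to_numpy()), out["sex"]]
        for _, sub in out.groupby(key):
            assert abs(sub["exposure_z"].mean()) < 1e-10
            assert abs(sub["exposure_z"].std(ddof=1) - 1) < 1e-10

    def test_tail_pooling_rule(self):
        ages = np.array([30, 35, 40, 41, 69, 70, 75, 80])
        assert pooled_age_stratum(ages).tolist() == [40, 40, 40, 41, 69, 70, 70, 70]

    def test_all_old_ages_form_single_stratum(self, rng):
        coh = toy_cohort(np.full(100, 75), np.zeros(100), rng.normal(size=100))
        out = cm.ztransform_by_stratum(coh)
        assert abs(out["exposure_z"].mean()) < 1e-12
        assert abs(out["exposure_z"].std(ddof=1) - 1) < 1e-12

    def test_two_individual_stratum_hand_value(self):
        coh = toy_cohort([50, 50], [0, 0], [1.0, 3.0])
        out = cm.ztransform_by_stratum(coh)
        # (1, 3) standardized with the n-1 convention: +/- 1/sqrt(2)*sqrt(2)
        assert np.allclose(out["exposure_z"], [-0.7071067811865475, 0.7071067811865475])

    def test_singleton_stratum_rejected(self):
        coh = toy_cohort([50, 50, 60], [0, 0, 0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            cm.ztransform_by_stratum(coh)

    def test_idempotent(self, rng):
        coh = toy_cohort(
            rng.integers(35, 75, 2000), rng.integers(0, 2, 2000), rng.normal(size=2000)
        )
        once = cm.ztransform_by_stratum(coh)
        twice = cm.ztransform_by_stratum(once, exposure="exposure_z", out="exposure_z2")
        assert np.allclose(once["exposure_z"], twice["exposure_z2"], atol=1e-12)


class TestPGS:
    def weights(self, rows):
        return pd.DataFrame(
            rows, columns=["snp_id", "effect_allele", "weight", "source_split"]
        )

    def test_single_snp_unit_weight_is_identity(self, rng):
        geno = pd.DataFrame({"rs1": rng.integers(0, 3, 50).astype(float)})
        w = self.weights([("rs1", "A", 1.0, "A")])
        assert np.allclose(cm.compute_pgs(geno, w), geno["rs1"])

    def test_unit_weights_give_unweighted_sum(self, rng):
        geno = pd.DataFrame(
            {f"rs{j}": rng.integers(0, 3, 40).astype(float) for j in (1, 2, 3)}
        )
        w = self.weights([(f"rs{j}", "A", 1.0, "A") for j in (1, 2, 3)])
        assert np.allclose(cm.compute_pgs(geno, w), geno.sum(axis=1))

    def test_weighted_arithmetic(self):
        geno = pd.DataFrame({"rs1": [2.0], "rs2": [1.0]})
        w = self.weights([("rs1", "A", 0.5, "A"), ("rs2", "C", -0.2, "A")])
        assert cm.compute_pgs(geno, w)[0] == pytest.approx(0.8)

    def test_missing_dosage_imputed_to_twice_allele_freq(self):
        geno = pd.DataFrame({"rs1": [0.0, 1.0, 2.0, np.nan]})
        w = self.weights([("rs1", "A", 1.0, "A")])
        score = cm.compute_pgs(geno, w)
        assert score[3] == pytest.approx(1.0)  # af = 0.25 -> 2*af*... = mean

    def test_absent_snp_rejected(self):
        with pytest.raises(KeyError):
            cm.compute_pgs(pd.DataFrame({"rs1": [1.0]}), self.weights([("rs9", "A", 1.0, "A")]))

    def test_out_of_range_dosage_rejected(self):
        with pytest.raises(ValueError):
            cm.compute_pgs(pd.DataFrame({"rs1": [3.0]}), self.weights([("rs1", "A", 1.0, "A")]))

    def test_duplicate_snp_in_split_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PGSWeights(self.weights([("rs1", "A", 1.0, "A"), ("rs1", "A", 0.5, "A")]))


class TestCrossFit:
    def make_splits(self, rng, n=400):
        def split(ids):
            return pd.DataFrame(
                {
                    "id": ids,
                    "rs1": rng.integers(0, 3, n).astype(float),
                    "rs2": rng.integers(0, 3, n).astype(float),
                }
            )

        wtab = pd.DataFrame(
            [
                ("rs1", "A", 0.4, "A"),
                ("rs2", "C", -0.1, "A"),
                ("rs1", "A", 0.35, "B"),
                ("rs2", "C", -0.2, "B"),
            ],
            columns=["snp_id", "effect_allele", "weight", "source_split"],
        )
        return split(np.arange(n)), split(np.arange(n, 2 * n)), PGSWeights(wtab)

    def test_no_individual_scored_with_own_split_weights(self, rng):
        a, b, w = self.make_splits(rng)
        merged = cm.crossfit_pgs(a, b, w)
        assert (merged.loc[merged["split"] == "A", "pgs_weights_from"] == "B").all()
        assert (merged.loc[merged["split"] == "B", "pgs_weights_from"] == "A").all()

    def test_within_split_standardization_gives_overall_zero_mean(self, rng):
        a, b, w = self.make_splits(rng)
        merged = cm.crossfit_pgs(a, b, w)
        for _, sub in merged.groupby("split"):
            assert abs(sub["pgs"].mean()) < 1e-10
            assert abs(sub["pgs"].std(ddof=1) - 1) < 1e-10
        assert abs(merged["pgs"].mean()) < 1e-10

    def test_overlapping_ids_rejected(self, rng):
        a, b, w = self.make_splits(rng)
        b_bad = b.copy()
        b_bad.loc[0, "id"] = a["id"].iloc[0]
        with pytest.raises(ValueError, match="share"):
            cm.crossfit_pgs(a, b_bad, w)


def steiger_oracle(rho_gx, rho_gy, n, rho_xy):
    """Step-by-step transcription of the overlapping-correlation z test."""
    Zgx = np.arctanh(rho_gx)
    Zgy = np.arctanh(rho_gy)
    rho2bar = (rho_gx**2 + rho_gy**2) / 2
    f = 0.5 * (1 - rho_xy) / (1 - rho2bar)
    h = (1 - f * rho2bar) / (1 - rho2bar)
    return (Zgx - Zgy) * np.sqrt((n - 3) / (2 * h * (1 - rho_xy)))


class TestSteiger:
    def test_equal_correlations_give_null(self):
        z, p = cm.steiger_test(0.1, 0.1, 1000, 0.2)
        assert z == pytest.approx(0.0, abs=1e-14)
        assert p == pytest.approx(0.5)

    def test_matches_formula_transcription_oracle(self):
        z, p = cm.steiger_test(0.1, 0.02, 10_000, 0.2)
        z_o = steiger_oracle(0.1, 0.02, 10_000, 0.2)
        assert z == pytest.approx(z_o, abs=1e-12)
        assert p == pytest.approx(stats.norm.sf(z_o), rel=1e-12)

    @given(
        rho_gx=st.floats(-0.6, 0.6),
        rho_gy=st.floats(-0.6, 0.6),
        rho_xy=st.floats(-0.5, 0.9),
    )
    @settings(deadline=None, max_examples=150)
    def test_antisymmetric_under_exchange(self, rho_gx, rho_gy, rho_xy):
        z1, _ = cm.steiger_test(rho_gx, rho_gy, 500, rho_xy)
        z2, _ = cm.steiger_test(rho_gy, rho_gx, 500, rho_xy)
        assert z1 == pytest.approx(-z2, abs=1e-10)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            cm.steiger_test(1.0, 0.2, 100, 0.1)
        with pytest.raises(ValueError):
            cm.steiger_test(0.5, 0.2, 3, 0.1)


class TestSteigerFilter:
    def test_all_strong_snps_kept(self):
        snps = pd.DataFrame(
            {"snp_id": ["a", "b"], "rho_gx": [0.3, 0.25], "rho_gy": [0.01, 0.0]}
        )
        out = cm.steiger_filter(snps, n=50_000, rho_xy=0.1)
        assert out["keep"].all()

    def test_bh_hand_computation(self):
        # p = (0.01, 0.02, 0.04, 0.9) -> q = (0.04, 0.04, 0.0533..., 0.9)
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.04, 0.9])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, [0.04, 0.04, 0.16 / 3, 0.9])
        assert (q <= 0.05).tolist() == [True, True, False, False]

    def test_q_values_monotone_and_geq_p(self, rng):
        k = 40
        snps = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(k)],
                "rho_gx": rng.uniform(0.0, 0.3, k),
                "rho_gy": rng.uniform(0.0, 0.3, k),
            }
        )
        out = cm.steiger_filter(snps, n=5_000, rho_xy=0.1)
        srt = out.sort_values("p_one_sided")
        assert np.all(np.diff(srt["q_fdr"]) >= -1e-12)
        assert np.all(out["q_fdr"] >= out["p_one_sided"] - 1e-12)

    def test_rho_xy_estimated_as_median_ratio(self):
        snps = pd.DataFrame(
            {
                "snp_id": list("abc"),
                "rho_gx": [0.2, 0.1, 0.4],
                "rho_gy": [0.02, 0.05, 0.04],
            }
        )
        out = cm.steiger_filter(snps, n=1000)
        want = float(np.median([0.1, 0.5, 0.1]))
        assert out.attrs["rho_xy"] == pytest.approx(want)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cm.steiger_filter(pd.DataFrame(columns=["snp_id", "rho_gx", "rho_gy"]), n=100)


class TestOutcomeCorrelations:
    def test_point_biserial_convention(self, rng):
        n = 4000
        g = rng.integers(0, 3, n).astype(float)
        x = 0.2 * g + rng.normal(size=n)
        event_age = np.where(rng.random(n) < 0.2, 60.0, np.nan)
        coh = pd.DataFrame(
            {
                "snp": g,
                "exposure_z": x,
                "event_age": event_age,
            }
        )
        out = point_biserial_outcome_correlations(coh, ["snp"])
        y = np.isfinite(event_age).astype(float)
        assert out.loc[0, "rho_gy"] == pytest.approx(np.corrcoef(g, y)[0, 1], abs=1e-12)
        assert out.loc[0, "rho_gx"] == pytest.approx(np.corrcoef(g, x)[0, 1], abs=1e-12)
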