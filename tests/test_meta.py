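import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from myometa.meta import (
    dl_tau2, forest_data, heterogeneity_stats, logfc_to_fold, meta_all_genes,
    reml_fit, reml_loglik,
)
from myometa.filters import SubgroupFilter
from myometa.simulate import SimulationConfig, StudySpec, simulate_effect_table
from myometa.types import EffectTable, StudyAnnotation, STATUS_OK, STATUS_TOO_FEW

from oracles import reml_grid


class TestDLTau2:
    def test_moment_formula_hand_examples(self):
        assert dl_tau2([0, 1], [0.5, 0.5]) == pytest.approx(0.0)
        assert dl_tau2([0, 2], [0.5, 0.5]) == pytest.approx(1.5)

    def test_identical_effects_have_no_heterogeneity(self):
        assert dl_tau2([0.7, 0.7, 0.7], [0.1, 0.2, 0.3]) == 0.0

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            dl_tau2([1.0], [0.1])


class TestHeterogeneity:
    def test_q_and_i2_hand_example(self):
        q, i2 = heterogeneity_stats([0, 2], [0.5, 0.5])
        assert q == pytest.approx(4.0)
        assert i2 == pytest.approx(75.0)

    def test_homogeneous_effects(self):
        q, i2 = heterogeneity_stats([0.3, 0.3], [1, 1])
        assert q == pytest.approx(0.0)
        assert i2 == 0.0

    def test_small_q_truncates_i2_to_zero(self):
        q, i2 = heterogeneity_stats([0, 0.1], [1, 1])
        assert q == pytest.approx(0.005)
        assert i2 == 0.0


class TestREMLFit:
    def test_zero_heterogeneity_limit_is_inverse_variance_mean(self):
        fit = reml_fit([0.5, 0.5, 0.5], [0.1, 0.1, 0.1])
        assert fit.tau2 == 0.0
        assert fit.mu == pytest.approx(0.5)
        assert fit.se == pytest.approx(np.sqrt(0.1 / 3))

    def test_matches_dense_grid_oracle_on_fixture(self):
        y, v = [0.2, 0.8, 1.4], [0.04, 0.04, 0.04]
        fit = reml_fit(y, v)
        tau2_grid, mu_grid = reml_grid(y, v)
        assert fit.tau2 == pytest.approx(tau2_grid, abs=1e-4)
        assert fit.mu == pytest.approx(mu_grid, abs=1e-6)

    def test_requires_two_studies_and_finite_input(self):
        with pytest.raises(ValueError):
            reml_fit([1.0], [0.1])
        with pytest.raises(ValueError):
            reml_fit([1.0, np.inf], [0.1, 0.1])
        with pytest.raises(ValueError):
            reml_fit([1.0, 2.0], [0.1, 0.0])

    def test_scale_equivariance(self, rng):
        y = rng.normal(0, 1, 6)
        v = rng.uniform(0.05, 0.3, 6)
        base = reml_fit(y, v)
        c = 3.7
        scaled = reml_fit(c * y, c ** 2 * v)
        assert scaled.mu == pytest.approx(c * base.mu, rel=1e-5)
        assert scaled.tau2 == pytest.approx(c ** 2 * base.tau2,
                                            rel=1e-4, abs=1e-8)

    def test_agrees_with_metafor_reference(self):
        """Independent cross-check against the R meta-analysis package."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the cross-check oracle")
        y = [0.2, 0.8, 1.4, 0.1, 0.6]
        v = [0.04, 0.09, 0.05, 0.1, 0.02]
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({','.join(map(str, y))}), "
            f"vi=c({','.join(map(str, v))}), method='REML');"
            "cat(r$tau2, r$b, r$se)"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        tau2_r, mu_r, se_r = map(float, out.stdout.split())
        fit = reml_fit(y, v)
        assert fit.tau2 == pytest.approx(tau2_r, abs=1e-4)
        assert fit.mu == pytest.approx(mu_r, abs=1e-5)
        assert fit.se == pytest.approx(se_r, abs=1e-5)


class TestLogfcToFold:
    @pytest.mark.parametrize("mu,fold,pct", [
        (1.0, 2.0, 100.0),
        (0.0, 1.0, 0.0),
        (-0.41504, 0.75, -25.0),
    ])
    def test_reporting_conversion(self, mu, fold, pct):
        f, p = logfc_to_fold(mu)
        assert f == pytest.approx(fold, abs=1e-4)
        assert p == pytest.approx(pct, abs=1e-2)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            logfc_to_fold(np.nan)


def _effect_table(rows, annotations):
    frame = pd.DataFrame(rows)
    for col in ("t", "df", "p", "fdr", "ci_low", "ci_high"):
        if col not in frame:
            frame[col] = np.nan
    if "n" not in frame:
        frame["n"] = 8.0
    return EffectTable(frame=frame, studies=annotations)


class TestMetaAllGenes:
    def test_too_few_studies_reported_na(self):
        anns = [StudyAnnotation(f"s{i}", "acute_aerobic", n_subjects=8)
                for i in (1, 2)]
        table = _effect_table(
            [{"gene": "g1", "study_id": f"s{i}", "logfc": 0.5, "var": 0.1}
             for i in (1, 2)], anns)
        res = meta_all_genes(table, "acute_aerobic", min_k=3)
        row = res.iloc[0]
        assert row["status"] == STATUS_TOO_FEW
        assert row["k"] == 2
        assert np.isnan(row["mu"]) and np.isnan(row["p"])

    def test_single_gene_composition_of_verified_parts(self):
        y, v = [0.2, 0.8, 1.4], [0.04, 0.04, 0.04]
        anns = [StudyAnnotation(f"s{i}", "inactivity", n_subjects=10)
                for i in (1, 2, 3)]
        rows = [{"gene": "g1", "study_id": f"s{i + 1}", "logfc": yy, "var": vv}
                for i, (yy, vv) in enumerate(zip(y, v))]
        res = meta_all_genes(_effect_table(rows, anns), "inactivity")
        row = res.iloc[0]
        fit = reml_fit(y, v)
        q, i2 = heterogeneity_stats(y, v)
        assert row["mu"] == pytest.approx(fit.mu)
        assert row["tau2"] == pytest.approx(fit.tau2)
        assert row["Q"] == pytest.approx(q)
        assert row["I2"] == pytest.approx(i2)
        z = fit.mu / fit.se
        from scipy import stats
        assert row["p"] == pytest.approx(2 * stats.norm.sf(abs(z)))
        assert row["ci_low"] == pytest.approx(fit.mu - stats.norm.ppf(0.975) * fit.se)
        assert row["status"] == STATUS_OK

    def test_missing_observations_reduce_k(self):
        anns = [StudyAnnotation(f"s{i}", "acute_aerobic", n_subjects=8)
                for i in (1, 2, 3, 4)]
        rows = [{"gene": "g1", "study_id": f"s{i}", "logfc": 0.4, "var": 0.05}
                for i in (1, 2, 3)]
        rows.append({"gene": "g1", "study_id": "s4", "logfc": np.nan,
                     "var": np.nan})
        res = meta_all_genes(_effect_table(rows, anns), "acute_aerobic")
        assert res.iloc[0]["k"] == 3

    def test_unmatched_filter_raises(self):
        anns = [StudyAnnotation("s1", "acute_aerobic", n_subjects=8)]
        table = _effect_table(
            [{"gene": "g1", "study_id": "s1", "logfc": 0.1, "var": 0.1}], anns)
        with pytest.raises(ValueError, match="no studies match"):
            meta_all_genes(table, "acute_aerobic",
                           filters=SubgroupFilter(health_status={"MTI"}))


class TestForestData:
    def _table(self):
        anns = [StudyAnnotation(f"s{i}", "acute_aerobic", n_subjects=8)
                for i in (1, 2, 3)]
        rows = []
        for i in (1, 2, 3):
            rows.append({"gene": "NR4A3", "study_id": f"s{i}",
                         "logfc": 0.5 + 0.1 * i, "var": 0.04,
                         "ci_low": 0.1, "ci_high": 1.2, "fdr": 0.01})
            if i != 2:  # g2 absent from one platform
                rows.append({"gene": "G2", "study_id": f"s{i}",
                             "logfc": 0.2, "var": 0.05,
                             "ci_low": -0.2, "ci_high": 0.6, "fdr": 0.5})
        return _effect_table(rows, anns)

    def test_rows_follow_stable_study_order_plus_meta(self):
        record = forest_data("NR4A3", "acute_aerobic", self._table())
        assert [r["study_id"] for r in record["studies"]] == ["s1", "s2", "s3"]
        assert not any(r["missing"] for r in record["studies"])
        assert record["meta"]["status"] == STATUS_OK
        assert record["meta"]["k"] == 3

    def test_absent_study_flagged_missing(self):
        record = forest_data("G2", "acute_aerobic", self._table())
        flags = {r["study_id"]: r["missing"] for r in record["studies"]}
        assert flags == {"s1": False, "s2": True, "s3": False}
        assert record["meta"]["status"] == STATUS_TOO_FEW

    def test_unknown_gene_and_empty_filter_errors(self):
        table = self._table()
        with pytest.raises(KeyError):
            forest_data("NOPE", "acute_aerobic", table)
        with pytest.raises(ValueError):
            forest_data("NR4A3", "acute_aerobic", table,
                        filters=SubgroupFilter(exclude_studies={"s1", "s2", "s3"}))


def test_reml_oracle_equivalence_on_random_instances(rng):
    """Optimizer agrees with the independent dense-grid oracle across a
    spread of study counts and variance scales."""
    for _ in range(50):
        k = int(rng.integers(3, 13))
        y = rng.normal(0, 1, k)
        v = rng.uniform(0.01, 0.5, k)
        fit = reml_fit(y, v)
        tau2_g, mu_g = reml_grid(y, v)
        assert abs(fit.tau2 - tau2_g) <= 1e-4
        assert abs(fit.mu - mu_g) <= 1e-6


def test_meta_on_simulated_null_collection_is_calibrated():
    spec = StudySpec(protocol="acute_aerobic", n_subjects=10, noise_sd=0.8)
    config = SimulationConfig(n_genes=500, studies=(spec,) * 8,
                              pi_responsive=0.0, effect_mean=0.0,
                              effect_sd=0.0, tau=0.0, seed=20200124)
    table, _ = simulate_effect_table(config)
    res = meta_all_genes(table, "acute_aerobic")
    ok = res[res["status"] == STATUS_OK]
    frac = (ok["p"] < 0.05).mean()
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(ok))
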