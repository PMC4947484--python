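import numpy as np
import pandas as pd
import pytest

from deltag import simulate as simu, tag_model as tm
from deltag.cohort_io import SnpGenotypeMatrix
from deltag.errors import DataError
from deltag.popgen_stats import GenotypeCounts, hwe_lrt

from conftest import genotype_series


def _matrix(dosages: dict[str, list[float]], samples: list[str]) -> SnpGenotypeMatrix:
    df = pd.DataFrame(dosages, index=pd.Index(samples, name="sample_id"), dtype=float)
    variants = pd.DataFrame(
        {
            "chrom": "chr12",
            "pos": np.arange(1, len(df.columns) + 1) * 100,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(df.columns, name="snp_id"),
    )
    return SnpGenotypeMatrix(dosages=df, variants=variants)


FAST = tm.ForestParams(n_trees=100, seed=7)


class TestTrainForest:
    def test_perfectly_predictive_feature(self):
        samples = [f"S{i}" for i in range(30)]
        labels = genotype_series({s: i % 3 for i, s in enumerate(samples)})
        feats = _matrix({"good": [i % 3 for i in range(30)]}, samples)
        fit = tm.train_forest(feats, labels, FAST)
        assert fit.ranking.entries[0][1] > 0
        acc = (fit.classifier.predict(feats.dosages.to_numpy()) == labels.to_numpy()).mean()
        assert acc == 1.0

    def test_planted_tags_top_three(self, sim_cohort_2000):
        cohort = sim_cohort_2000.cohort
        fit = tm.train_forest(
            cohort.snp_matrix, cohort.deletion_calls, tm.ForestParams(n_trees=300, seed=1)
        )
        assert set(fit.ranking.top(3)) == {"tag_1", "tag_2", "tag_3"}

    def test_noise_feature_importance_near_zero(self, sim_cohort_2000):
        cohort = sim_cohort_2000.cohort
        fit = tm.train_forest(
            cohort.snp_matrix, cohort.deletion_calls, tm.ForestParams(n_trees=300, seed=1)
        )
        noise_imp = [v for s, v in fit.ranking.entries if s.startswith("noise")]
        assert max(np.abs(noise_imp)) < 0.01

    def test_determinism(self):
        cfg = simu.SimulationConfig(n_samples=400, n_noise_snps=10, seed=3)
        cohort = simu.simulate_genotypes(cfg).cohort
        fit1 = tm.train_forest(cohort.snp_matrix, cohort.deletion_calls, FAST)
        fit2 = tm.train_forest(cohort.snp_matrix, cohort.deletion_calls, FAST)
        assert fit1.ranking.entries == fit2.ranking.entries

    def test_single_class_labels_error(self):
        samples = [f"S{i}" for i in range(10)]
        labels = genotype_series({s: 0 for s in samples})
        feats = _matrix({"x": list(range(10))}, samples)
        with pytest.raises(DataError):
            tm.train_forest(feats, labels, FAST)

    def test_zero_candidates_error(self):
        samples = ["S1", "S2"]
        labels = genotype_series({"S1": 0, "S2": 1})
        feats = _matrix({}, samples)
        with pytest.raises(DataError):
            tm.train_forest(feats, labels, FAST)

    def test_missing_features_median_imputed(self):
        samples = [f"S{i}" for i in range(20)]
        vals = [float(i % 3) for i in range(20)]
        vals[5] = np.nan
        labels = genotype_series({s: i % 3 for i, s in enumerate(samples)})
        feats = _matrix({"x": vals}, samples)
        fit = tm.train_forest(feats, labels, FAST)  # does not raise
        assert fit.medians["x"] == 1.0

    def test_noise_only_forest_near_majority_class(self):
        cfg = simu.SimulationConfig(n_samples=1000, n_noise_snps=30, seed=6)
        cohort = simu.simulate_genotypes(cfg).cohort
        noise = [s for s in cohort.snp_matrix.snp_ids if s.startswith("noise")]
        feats = cohort.snp_matrix.restrict(noise)
        fit = tm.train_forest(
            feats, cohort.deletion_calls, tm.ForestParams(n_trees=200, seed=2), oob_score=True
        )
        majority = cohort.deletion_calls.value_counts(normalize=True).max()
        assert abs(fit.classifier.oob_score_ - majority) < 0.05


@pytest.fixture(scope="module")
def report(sim_cohort_2000):
    cohort = sim_cohort_2000.cohort
    feats = cohort.snp_matrix.restrict(["tag_1", "tag_2", "tag_3"])
    fit = tm.train_forest(feats, cohort.deletion_calls, FAST)
    return tm.evaluate_topk_models(
        feats, cohort.deletion_calls, fit.ranking, k_max=3, params=FAST
    )


@pytest.fixture(scope="module")
def model(sim_cohort_2000):
    cohort = sim_cohort_2000.cohort
    feats = cohort.snp_matrix.restrict(["tag_1", "tag_2", "tag_3"])
    fit = tm.train_forest(feats, cohort.deletion_calls, FAST)
    rep = tm.evaluate_topk_models(feats, cohort.deletion_calls, fit.ranking, 3, FAST)
    return tm.select_best_model(rep, variants=cohort.snp_matrix.variants)


class TestModelSelection:

    def test_one_row_per_k(self, report):
        assert list(report.table["k"]) == [1, 2, 3]
        assert (report.table["n_correct"] <= report.table["n_total"]).all()
        acc = report.table["n_correct"] / report.table["n_total"]
        assert np.allclose(acc, report.table["accuracy"])

    def test_accuracy_non_decreasing_with_k(self, report):
        acc = report.table["accuracy"].to_numpy()
        assert (np.diff(acc) >= -0.01).all()

    def test_select_best_prefers_fewest_misclassifications(self, report):
        model = tm.select_best_model(report)
        t = report.table
        best_mis = (t["n_total"] - t["n_correct"]).min()
        chosen = t[t["k"] == len(model.snp_ids)].iloc[0]
        assert chosen["n_total"] - chosen["n_correct"] == best_mis

    def test_tie_breaking_rules(self):
        """Equal misclassifications -> higher kappa wins; full tie -> smaller k."""
        def row(k, correct, kappa):
            return {
                "k": k, "snp_ids": "x", "n_correct": correct, "n_total": 300,
                "accuracy": correct / 300, "kappa_unweighted": kappa,
                "kappa_unweighted_ci_low": 0, "kappa_unweighted_ci_high": 1,
                "kappa_weighted": kappa, "kappa_weighted_ci_low": 0,
                "kappa_weighted_ci_high": 1,
            }

        fits = {k: tm.ForestFit(None, [], pd.Series(dtype=float), None, None) for k in (1, 2, 3)}
        rep = tm.ModelSelectionReport(
            table=pd.DataFrame([row(1, 289, 0.90), row(2, 292, 0.91), row(3, 292, 0.93)]),
            fits=fits,
        )
        assert len(tm.select_best_model(rep).snp_ids) == 0  # picked fits[3]
        assert rep.table.iloc[2]["k"] == 3
        # fewest misclassifications beats smaller k
        rep2 = tm.ModelSelectionReport(
            table=pd.DataFrame([row(1, 289, 0.90), row(3, 292, 0.91)]), fits=fits
        )
        mis = rep2.table["n_total"] - rep2.table["n_correct"]
        assert mis.idxmin() == 1
        # equal everything -> smaller k
        rep3 = tm.ModelSelectionReport(
            table=pd.DataFrame([row(2, 290, 0.90), row(1, 290, 0.90)]), fits=fits
        )
        chosen = rep3.table.iloc[
            np.lexsort((rep3.table["k"], -rep3.table["kappa_unweighted"],
                        rep3.table["n_total"] - rep3.table["n_correct"]))[0]
        ]
        assert chosen["k"] == 1

    def test_single_row_report(self, sim_cohort_2000):
        cohort = sim_cohort_2000.cohort
        feats = cohort.snp_matrix.restrict(["tag_1"])
        fit = tm.train_forest(feats, cohort.deletion_calls, FAST)
        rep = tm.evaluate_topk_models(feats, cohort.deletion_calls, fit.ranking, 1, FAST)
        model = tm.select_best_model(rep)
        assert model.snp_ids == ["tag_1"]

    def test_perfect_snp_gives_kappa_one(self):
        samples = [f"S{i}" for i in range(60)]
        labels = genotype_series({s: i % 3 for i, s in enumerate(samples)})
        feats = _matrix({"exact": [i % 3 for i in range(60)]}, samples)
        fit = tm.train_forest(feats, labels, FAST)
        rep = tm.evaluate_topk_models(feats, labels, fit.ranking, 1, FAST)
        assert rep.table.iloc[0]["accuracy"] == 1.0
        assert rep.table.iloc[0]["kappa_unweighted"] == pytest.approx(1.0)


class TestImputation:
    def test_missing_model_snp_data_excludes_sample(self, model):
        cfg = simu.SimulationConfig(n_samples=300, n_noise_snps=0, snp_missing_rate=0.05, seed=12)
        sim = simu.simulate_genotypes(cfg)
        calls, excluded = tm.impute_genotypes(model, sim.cohort.snp_matrix)
        assert len(calls) + len(excluded) == 300
        assert len(excluded) > 0
        incomplete = sim.cohort.snp_matrix.dosages[model.snp_ids].isna().any(axis=1)
        assert set(excluded) == set(incomplete.index[incomplete])

    def test_test_cohort_concordance(self, model):
        sim = simu.simulate_genotypes(simu.SimulationConfig(n_samples=1000, seed=99))
        calls, excluded = tm.impute_genotypes(model, sim.cohort.snp_matrix)
        truth = sim.true_del_dosage.loc[calls.index]
        assert (calls == truth).mean() >= 0.90

    def test_training_reimputation_matches_report(self, model, sim_cohort_2000):
        cohort = sim_cohort_2000.cohort
        calls, _ = tm.impute_genotypes(model, cohort.snp_matrix)
        acc = (calls == cohort.deletion_calls.loc[calls.index]).mean()
        k = len(model.snp_ids)
        reported = model.report.table.set_index("k").loc[k, "accuracy"]
        assert acc == pytest.approx(reported)

    def test_absent_model_snp_errors(self, model):
        cfg = simu.SimulationConfig(
            n_samples=50,
            n_noise_snps=0,
            tags=(simu.TagSnpSpec("other", 0.3, 0.5),),
            seed=1,
        )
        sim = simu.simulate_genotypes(cfg)
        with pytest.raises(DataError, match="tag_"):
            tm.impute_genotypes(model, sim.cohort.snp_matrix)

    def test_chrom_pos_fallback_matching(self, model, sim_cohort_2000):
        matrix = sim_cohort_2000.cohort.snp_matrix
        renamed = SnpGenotypeMatrix(
            dosages=matrix.dosages.rename(columns=lambda c: "x_" + c),
            variants=matrix.variants.rename(index=lambda c: "x_" + c),
        )
        calls, _ = tm.impute_genotypes(model, renamed)
        assert len(calls) == 2000

    def test_save_load_round_trip(self, model, tmp_path, sim_cohort_2000):
        path = tmp_path / "model.joblib"
        tm.save_model(model, str(path))
        loaded = tm.load_model(str(path))
        assert loaded.snp_ids == model.snp_ids
        matrix = sim_cohort_2000.cohort.snp_matrix
        a, _ = tm.impute_genotypes(model, matrix)
        b, _ = tm.impute_genotypes(loaded, matrix)
        assert a.equals(b)

    def test_imputation_preserves_hwe_across_seeds(self, model):
        """Imputation must not distort Hardy-Weinberg proportions.

        Truth genotypes are drawn by random union of gametes, so any one
        realization can itself fluctuate away from HWE; the property to
        preserve is conditional: whenever the drawn truth is comfortably in
        HWE (p > 0.05), the imputed calls must also pass (p > 0.01).
        """

        def _counts(series):
            c = series.value_counts()
            return GenotypeCounts(
                int(c.get(0.0, 0)), int(c.get(1.0, 0)), int(c.get(2.0, 0))
            )

        checked = 0
        for seed in range(200, 210):
            sim = simu.simulate_genotypes(
                simu.SimulationConfig(n_samples=2000, n_noise_snps=0, seed=seed)
            )
            calls, _ = tm.impute_genotypes(model, sim.cohort.snp_matrix)
            if hwe_lrt(_counts(sim.true_del_dosage)).p > 0.05:
                assert hwe_lrt(_counts(calls)).p > 0.01
                checked += 1
        assert checked >= 5  # most draws do satisfy the premise
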