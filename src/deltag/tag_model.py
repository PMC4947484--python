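"""Tag-SNP classifier: forest training, importance, model reduction, imputation.

Pipeline: the candidate SNPs from the LD scan are fed to a random-forest
classifier of the three-state deletion genotype; variable importance ranks
the candidates; the model is retrained on the top 1..k_max SNPs and the
row with the fewest misclassifications (ties: higher unweighted kappa,
then fewer SNPs) becomes the final tag-SNP classifier, which can then be
applied to impute deletion genotypes in cohorts lacking experimental calls.

Importance is permutation importance computed on the out-of-bag samples of
each tree (mean decrease in OOB accuracy when one feature is permuted),
the convention of the ranger-style forests this mirrors; Gini impurity
importance is available as an alternative.  Missing candidate dosages are
median-imputed per SNP at training time; at imputation time samples with
any missing model-SNP dosage are excluded and listed instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import agreement
from .cohort_io import SnpGenotypeMatrix
from .errors import DataError

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestParams:
    """Random-forest hyperparameters (ranger-style defaults)."""

    n_trees: int = 500
    features_per_split: int | None = None  # None -> floor(sqrt(#features))
    min_node_size: int = 1
    importance: str = "permutation"  # or "impurity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.importance not in ("permutation", "impurity"):
            raise ValueError("importance must be 'permutation' or 'impurity'")


@dataclass(frozen=True)
class ImportanceRanking:
    """SNPs ordered by decreasing variable importance."""

    entries: tuple[tuple[str, float], ...]
    basis: str  # "oob" (permutation) or "resubstitution" (impurity)

    @property
    def snp_ids(self) -> list[str]:
        return [s for s, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return self.snp_ids[:k]


@dataclass
class ForestFit:
    classifier: RandomForestClassifier
    snp_ids: list[str]
    medians: pd.Series
    ranking: ImportanceRanking
    params: ForestParams


@dataclass
class ModelSelectionReport:
    """Per-k accuracy and kappa table for the top-k nested models."""

    table: pd.DataFrame
    fits: dict[int, ForestFit] = field(default_factory=dict)
    evaluation: str = "resubstitution"


@dataclass
class TagSnpModel:
    """Final minimal tag-SNP classifier plus its selection report."""

    snp_ids: list[str]
    classifier: RandomForestClassifier
    medians: pd.Series
    params: ForestParams
    report: ModelSelectionReport | None = None
    variants: pd.DataFrame | None = None


def _prepare_training(
    features: SnpGenotypeMatrix, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray, list[str], pd.Series, list[str]]:
    y_all = labels.reindex(features.samples)
    keep = y_all.notna()
    if keep.sum() == 0:
        raise DataError("no samples with a non-missing deletion call")
    sample_ids = [s for s, k in zip(features.samples, keep) if k]
    X = features.dosages.loc[sample_ids]
    y = y_all[keep].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    if features.n_snps == 0:
        raise DataError("no candidate SNPs to train on")
    medians = X.median()
    n_missing = int(X.isna().to_numpy().sum())
    if n_missing:
        logger.info("train_forest: median-imputed %d missing dosages", n_missing)
        X = X.fillna(medians)
    return X.to_numpy(dtype=float), y, list(X.columns), medians, sample_ids


def _oob_permutation_importance(
    clf: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Mean over trees of the OOB accuracy drop when one feature is permuted."""
    n, p = X.shape
    rng = np.random.default_rng(seed)
    imp = np.zeros(p)
    n_trees_used = 0
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    y_idx = np.searchsorted(clf.classes_, y)
    buf = np.empty((p * n, p), dtype=np.float32)  # reused across trees
    for tree, sampled in zip(clf.estimators_, clf.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        m = int(oob.sum())
        if m < 2:
            continue
        Xo, yo = X32[oob], y_idx[oob]
        # low-level tree predict: (rows, 1, n_classes) leaf class counts
        base_pred = tree.tree_.predict(Xo).reshape(m, -1).argmax(axis=1)
        base = np.mean(base_pred == yo)
        # one stacked prediction per tree: block j has feature j permuted
        stacked = buf[: p * m]
        stacked.reshape(p, m, p)[:] = Xo[None, :, :]
        for j in range(p):
            stacked[j * m : (j + 1) * m, j] = Xo[rng.permutation(m), j]
        pred = tree.tree_.predict(stacked).reshape(p * m, -1).argmax(axis=1)
        hits = (pred == np.tile(yo, p)).reshape(p, m)
        imp += base - hits.mean(axis=1)
        n_trees_used += 1
    if n_trees_used == 0:
        raise DataError("no tree had enough out-of-bag samples for importance")
    return imp / n_trees_used


def train_forest(
    features: SnpGenotypeMatrix,
    labels: pd.Series,
    params: ForestParams | None = None,
    oob_score: bool = False,
) -> ForestFit:
    """Grow a random forest of deletion genotype on candidate SNP dosages
    and rank the SNPs by variable importance.

    Fully reproducible from ``params.seed``.  Samples with a missing label
    are excluded; missing feature dosages are median-imputed per SNP.
    """
    params = params or ForestParams()
    X, y, snp_ids, medians, _ = _prepare_training(features, labels)
    mtry = params.features_per_split or max(1, int(np.sqrt(len(snp_ids))))
    if not 1 <= mtry <= len(snp_ids):
        raise ValueError("features_per_split out of range")
    clf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=mtry,
        min_samples_leaf=params.min_node_size,
        criterion="gini",
        bootstrap=True,
        oob_score=oob_score,
        random_state=params.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    if params.importance == "permutation":
        scores = _oob_permutation_importance(clf, X, y, params.seed)
        basis = "oob"
    else:
        scores = clf.feature_importances_
        basis = "resubstitution"
    order = np.lexsort((np.arange(len(snp_ids)), -scores))
    ranking = ImportanceRanking(
        entries=tuple((snp_ids[i], float(scores[i])) for i in order), basis=basis
    )
    return ForestFit(
        classifier=clf, snp_ids=snp_ids, medians=medians, ranking=ranking, params=params
    )


def evaluate_topk_models(
    features: SnpGenotypeMatrix,
    labels: pd.Series,
    ranking: ImportanceRanking,
    k_max: int = 4,
    params: ForestParams | None = None,
    evaluation: str = "resubstitution",
) -> ModelSelectionReport:
    """Retrain on the top 1..k_max SNPs; record accuracy and kappas per k.

    ``evaluation`` is ``resubstitution`` (predictions on the training
    samples) or ``oob`` (out-of-bag majority vote), both scored against the
    experimental genotypes.
    """
    if evaluation not in ("resubstitution", "oob"):
        raise ValueError("evaluation must be 'resubstitution' or 'oob'")
    params = params or ForestParams()
    if k_max > len(ranking.snp_ids):
        raise ValueError(
            f"k_max={k_max} exceeds the {len(ranking.snp_ids)} ranked SNPs"
        )
    rows = []
    fits: dict[int, ForestFit] = {}
    for k in range(1, k_max + 1):
        top = ranking.top(k)
        sub = features.restrict(top)
        fit = train_forest(sub, labels, params=params, oob_score=(evaluation == "oob"))
        X, y, _, _, sample_ids = _prepare_training(sub, labels)
        if evaluation == "oob":
            proba = fit.classifier.oob_decision_function_
            votes = np.where(
                np.isnan(proba).any(axis=1), np.nan, np.argmax(proba, axis=1)
            )
            pred_classes = np.where(
                np.isnan(votes), np.nan, fit.classifier.classes_[np.nan_to_num(votes).astype(int)]
            )
        else:
            pred_classes = fit.classifier.predict(X).astype(float)
        truth = pd.Series(y.astype(float), index=sample_ids)
        pred = pd.Series(pred_classes, index=sample_ids)
        cm = agreement.cross_tabulate(truth, pred)
        acc, _ = agreement.overall_accuracy(cm)
        ku = agreement.cohen_kappa(cm, "none")
        kw = agreement.cohen_kappa(cm, "quadratic")
        rows.append(
            {
                "k": k,
                "snp_ids": "+".join(top),
                "n_correct": int(np.trace(cm.counts)),
                "n_total": cm.n,
                "accuracy": acc,
                "kappa_unweighted": ku.kappa,
                "kappa_unweighted_ci_low": ku.ci95[0],
                "kappa_unweighted_ci_high": ku.ci95[1],
                "kappa_weighted": kw.kappa,
                "kappa_weighted_ci_low": kw.ci95[0],
                "kappa_weighted_ci_high": kw.ci95[1],
            }
        )
        fits[k] = fit
    return ModelSelectionReport(
        table=pd.DataFrame(rows), fits=fits, evaluation=evaluation
    )


def select_best_model(
    report: ModelSelectionReport, variants: pd.DataFrame | None = None
) -> TagSnpModel:
    """Pick the row with the fewest misclassifications; break ties by
    higher unweighted kappa, then by fewer SNPs."""
    t = report.table
    if len(t) == 0:
        raise DataError("empty model-selection report")
    mis = t["n_total"] - t["n_correct"]
    order = np.lexsort((t["k"], -t["kappa_unweighted"], mis))
    best = t.iloc[order[0]]
    k = int(best["k"])
    fit = report.fits[k]
    logger.info(
        "selected %d-SNP model (%s): %d/%d correct, kappa %.3f",
        k, best["snp_ids"], best["n_correct"], best["n_total"], best["kappa_unweighted"],
    )
    sub_variants = None
    if variants is not None:
        sub_variants = variants.loc[[s for s in fit.snp_ids if s in variants.index]]
    return TagSnpModel(
        snp_ids=fit.snp_ids,
        classifier=fit.classifier,
        medians=fit.medians,
        params=fit.params,
        report=report,
        variants=sub_variants,
    )


def _resolve_model_snps(model: TagSnpModel, matrix: SnpGenotypeMatrix) -> list[str]:
    """Match model SNPs to matrix columns by id, falling back to chrom:pos."""
    by_pos = {
        (str(r["chrom"]), int(r["pos"])): sid for sid, r in matrix.variants.iterrows()
    }
    resolved = []
    for sid in model.snp_ids:
        if sid in matrix.dosages.columns:
            resolved.append(sid)
            continue
        if model.variants is not None and sid in model.variants.index:
            key = (
                str(model.variants.loc[sid, "chrom"]),
                int(model.variants.loc[sid, "pos"]),
            )
            if key in by_pos:
                resolved.append(by_pos[key])
                continue
        raise DataError(f"model SNP {sid} absent from the genotype matrix")
    return resolved


def impute_genotypes(
    model: TagSnpModel, snp_matrix: SnpGenotypeMatrix
) -> tuple[pd.Series, list[str]]:
    """Impute deletion genotypes by ensemble majority vote.

    Samples with any missing model-SNP dosage are excluded and returned in
    the exclusion list, so imputed calls plus exclusions reconcile exactly
    to the input sample count.
    """
    cols = _resolve_model_snps(model, snp_matrix)
    X = snp_matrix.dosages[cols]
    complete = X.notna().all(axis=1)
    excluded = list(X.index[~complete])
    Xc = X.loc[complete].to_numpy(dtype=float)
    if len(Xc) == 0:
        return pd.Series(dtype=float, name="dosage"), excluded
    pred = model.classifier.predict(Xc).astype(float)
    calls = pd.Series(
        pred, index=pd.Index(X.index[complete], name="sample_id"), name="dosage"
    )
    logger.info(
        "impute_genotypes: %d imputed, %d excluded for missing model-SNP data",
        len(calls), len(excluded),
    )
    return calls, excluded


def save_model(model: TagSnpModel, path: str) -> None:
    """Serialize the model (format-versioned) to a single file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "snp_ids": model.snp_ids,
        "classifier": model.classifier,
        "medians": model.medians,
        "params": model.params,
        "variants": model.variants,
        "report_table": None if model.report is None else model.report.table,
    }
    joblib.dump(payload, path)


def load_model(path: str) -> TagSnpModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise DataError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    report = None
    if payload.get("report_table") is not None:
        report = ModelSelectionReport(table=payload["report_table"], fits={})
    return TagSnpModel(
        snp_ids=payload["snp_ids"],
        classifier=payload["classifier"],
        medians=payload["medians"],
        params=payload["params"],
        report=report,
        variants=payload.get("variants"),
    )


def write_selection_report(report: ModelSelectionReport, path: str) -> None:
    t = report.table.copy()
    t["accuracy_pct"] = (100 * t["accuracy"]).map(lambda v: f"{v:.1f}")
    t.to_csv(path, sep="\t", index=False, float_format="%.4f")
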