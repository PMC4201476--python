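"""Cross-validated benchmarking of the threshold index model.

Implements case/control-stratified k-fold splitting (cases and controls
are each permuted and cut into k near-equal blocks, then block j of each
class forms fold j), classification error metrics, ROC/AUC, a linear
logistic baseline, and the head-to-head comparison loop.

Error-rate conventions: Type I error is the proportion of controls
predicted to be cases; Type II error the proportion of cases predicted to
be controls; a subject is predicted "case" when the fitted probability is
at or above the classification threshold (default 0.5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score, roc_curve

from .estimation import FitResult, fit_mle
from .model import FitConfig, GenotypeMatrix, case_probability

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "ConfusionMetrics",
    "LinearLogisticFit",
    "CVReport",
    "stratified_kfold",
    "confusion_metrics",
    "roc_auc",
    "fit_linear_logistic",
    "run_cv_comparison",
]


@dataclass
class FoldAssignment:
    """Per-subject fold labels in {1..k}, stratified by phenotype class."""

    fold_index: np.ndarray
    k: int
    seed: int

    def test_mask(self, j: int) -> np.ndarray:
        return self.fold_index == j


def _block_sizes(m: int, k: int) -> list[int]:
    # near-equal blocks; any remainder goes to the last blocks
    base, rem = divmod(m, k)
    return [base] * (k - rem) + [base + 1] * rem


def stratified_kfold(data: GenotypeMatrix, k: int, seed: int) -> FoldAssignment:
    """Randomly split cases and controls each into k near-equal groups.

    Group j of the cases and group j of the controls together form fold j,
    so every fold mirrors the overall case/control ratio.  Deterministic
    given the seed.
    """
    data._require_phenotype()
    if k < 2:
        raise ValueError("k must be at least 2")
    y = data.phenotype
    rng = np.random.default_rng(seed)
    fold = np.zeros(data.n, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"phenotype class {cls} has {idx.size} members, fewer than k={k}"
            )
        perm = rng.permutation(idx)
        start = 0
        for j, size in enumerate(_block_sizes(idx.size, k), start=1):
            fold[perm[start : start + size]] = j
            start += size
    return FoldAssignment(fold, k, seed)


@dataclass
class ConfusionMetrics:
    """Classification rates as proportions in [0, 1]; NaN when undefined."""

    type_i: float
    type_ii: float
    accuracy: float


def confusion_metrics(
    y_true: np.ndarray, p_hat: np.ndarray, threshold: float = 0.5
) -> ConfusionMetrics:
    """Type I / Type II error and accuracy at a probability cut-off.

    Predicts case when p_hat >= threshold.  Type I (false positive rate)
    is undefined (NaN) without controls, Type II without cases.
    """
    y = np.asarray(y_true)
    p = np.asarray(p_hat, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y_true and p_hat must have equal length")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    pred = p >= threshold
    n_controls = int((y == 0).sum())
    n_cases = int((y == 1).sum())
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    type_i = fp / n_controls if n_controls else float("nan")
    type_ii = fn / n_cases if n_cases else float("nan")
    accuracy = (y.size - fp - fn) / y.size
    return ConfusionMetrics(type_i, type_ii, accuracy)


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all score thresholds and the trapezoidal AUC.

    Ties follow the rank / Mann-Whitney convention (tied case-control pairs
    count one half).  Requires both classes present.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(y, s))


@dataclass
class LinearLogisticFit:
    """Linear-logit baseline: intercept + one coefficient per SNP."""

    params: np.ndarray            # (intercept, slopes for kept columns)
    fitted_probs: np.ndarray
    converged: bool
    kept_columns: np.ndarray      # indices of non-constant SNP columns

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept_columns]
        eta = self.params[0] + X @ self.params[1:]
        return np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)


def fit_linear_logistic(data: GenotypeMatrix) -> LinearLogisticFit:
    """Maximum-likelihood linear logistic regression on the raw SNP codes.

    Constant genotype columns are dropped with a warning (they are not
    estimable alongside the intercept).  Under complete separation the IRLS
    iteration cannot converge; the result is then flagged and probabilities
    are clipped away from {0, 1}.
    """
    data._require_phenotype()
    X = np.asarray(data.genotypes, dtype=float)
    keep = np.flatnonzero(X.std(axis=0) > 0)
    if keep.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - keep.size} constant genotype column(s) "
            "from the linear-logistic baseline"
        )
    design = sm.add_constant(X[:, keep], has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(data.phenotype, design, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
            params = np.asarray(res.params)
            converged = bool(res.converged)
        except Exception:  # perfect separation or singular design
            logger.warning("GLM failed to converge; falling back to ridge-stabilized fit")
            res = sm.GLM(
                data.phenotype, design, family=sm.families.Binomial()
            ).fit_regularized(alpha=1e-6, L1_wt=0.0)
            params = np.asarray(res.params)
            converged = False
    eta = design @ params
    probs = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return LinearLogisticFit(params, probs, converged, keep)


@dataclass
class CVReport:
    """Per-fold and averaged comparison metrics for the two classifiers.

    ``metrics`` maps method -> metric -> length-k array of per-fold values
    (error rates and accuracy as proportions); ``averages`` holds the
    across-fold means (NaN-skipping only if a fold failed, in which case the
    failure is recorded in ``failed_folds``).
    """

    metrics: dict
    averages: dict
    k: int
    seed: int
    classification_threshold: float
    roc_points: dict = field(default_factory=dict)
    failed_folds: dict = field(default_factory=dict)
    fit_results: list[FitResult] = field(default_factory=list)

    METRICS = ("type_i", "type_ii", "accuracy", "auc")

    def to_frame(self) -> pd.DataFrame:
        """Long layout: method × metric rows, fold columns plus the average.

        Rates are shown in percent; AUC on its natural [0, 1] scale.
        """
        rows = []
        for method, md in self.metrics.items():
            for metric in self.METRICS:
                vals = np.asarray(md[metric], dtype=float)
                scale = 100.0 if metric != "auc" else 1.0
                row = {"method": method, "metric": metric}
                for j in range(self.k):
                    row[f"fold{j + 1}"] = vals[j] * scale
                row["average"] = self.averages[method][metric] * scale
                rows.append(row)
        return pd.DataFrame(rows)


def run_cv_comparison(
    data: GenotypeMatrix,
    k: int = 3,
    seed: int = 0,
    fit_config: FitConfig | None = None,
    classification_threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold comparison of the threshold index model vs linear logit.

    Each fold in turn is the test set; both models are fitted on the
    remaining folds and scored on it.  A fold where a model fit raises is
    reported as missing (NaN metrics) and listed in ``failed_folds``, never
    silently dropped.
    """
    if fit_config is None:
        fit_config = FitConfig()
    folds = stratified_kfold(data, k, seed)
    metrics = {
        m: {met: np.full(k, np.nan) for met in CVReport.METRICS}
        for m in ("tilor", "glm")
    }
    roc_points: dict = {}
    failed: dict = {}
    fit_results: list[FitResult] = []

    for j in range(1, k + 1):
        test = folds.test_mask(j)
        train = ~test
        train_data = GenotypeMatrix(
            data.genotypes[train],
            data.phenotype[train],
            list(data.snp_ids),
            [s for s, t in zip(data.subject_ids, train) if t],
        )
        X_test = data.genotypes[test]
        y_test = data.phenotype[test]
        scores = {}
        try:
            fr = fit_mle(train_data, fit_config)
            fit_results.append(fr)
            scores["tilor"] = case_probability(fr.theta_hat, X_test)
        except Exception as exc:  # keep the fold's entry, mark it failed
            logger.warning("TILoR fit failed on fold %d: %s", j, exc)
            failed[("tilor", j)] = str(exc)
        try:
            glm = fit_linear_logistic(train_data)
            scores["glm"] = glm.predict(X_test)
        except Exception as exc:
            logger.warning("GLM fit failed on fold %d: %s", j, exc)
            failed[("glm", j)] = str(exc)

        for method, p_hat in scores.items():
            cm = confusion_metrics(y_test, p_hat, classification_threshold)
            points, auc = roc_auc(y_test, p_hat)
            metrics[method]["type_i"][j - 1] = cm.type_i
            metrics[method]["type_ii"][j - 1] = cm.type_ii
            metrics[method]["accuracy"][j - 1] = cm.accuracy
            metrics[method]["auc"][j - 1] = auc
            roc_points[(method, j)] = points

    averages = {
        m: {met: float(np.mean(vals)) for met, vals in md.items()}
        for m, md in metrics.items()
    }
    return CVReport(
        metrics=metrics,
        averages=averages,
        k=k,
        seed=seed,
        classification_threshold=classification_threshold,
        roc_points=roc_points,
        failed_folds=failed,
        fit_results=fit_results,
    )
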