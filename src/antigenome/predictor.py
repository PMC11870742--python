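"""L1-penalized logistic biomarker models with nested cross-validation.

The penalized objective is ``-(1/n) * log-likelihood + lambda * ||beta||_1``
with an unpenalized intercept.  Nested CV selects lambda on inner folds by
mean validation AUC, reports training (re-substitution), validation
(inner-fold), and test (outer held-out) AUCs, and refits a final model on
all data at the median selected lambda.  Attribution uses variance-based
effect shares and closed-form linear Shapley values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

ZERO_COEF_TOL = 1e-8


@dataclass
class ModelConfig:
    outer_folds: int = 4
    inner_folds: int = 5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    q_threshold: float = 0.05
    prevalence_threshold: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must both be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")


@dataclass
class LassoPath:
    lambdas: np.ndarray  # strictly decreasing
    coefficients: np.ndarray  # (n_lambda, p)
    intercepts: np.ndarray
    feature_names: list[str]

    @property
    def l1_norms(self) -> np.ndarray:
        return np.abs(self.coefficients).sum(axis=1)

    @property
    def n_nonzero(self) -> np.ndarray:
        return (np.abs(self.coefficients) > ZERO_COEF_TOL).sum(axis=1)


@dataclass
class ModelReport:
    coefficients: pd.Series
    intercept: float
    retained: list[str]
    excluded: list[str]
    lambda_stars: list[float]
    final_lambda: float
    auc_train: float
    auc_validation: float
    auc_test: float
    path: LassoPath
    effects: pd.DataFrame | None = None
    shap_values: pd.DataFrame | None = None
    feature_means: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "intercept": self.intercept,
            "retained": self.retained,
            "excluded": self.excluded,
            "lambda_stars": self.lambda_stars,
            "final_lambda": self.final_lambda,
            "auc": {
                "train": self.auc_train,
                "validation": self.auc_validation,
                "test": self.auc_test,
            },
            "path": {
                "lambdas": self.path.lambdas.tolist(),
                "l1_norms": self.path.l1_norms.tolist(),
                "n_nonzero": self.path.n_nonzero.tolist(),
            },
            "effects": None if self.effects is None else self.effects.to_dict(),
        }


# --------------------------------------------------------------------------
# design matrix


def build_design_matrix(
    log2cpm: pd.DataFrame,
    differential_result: pd.DataFrame,
    labels: pd.Series,
    q_threshold: float = 0.05,
    prevalence_threshold: float = 0.30,
) -> tuple[pd.DataFrame, pd.Series]:
    """Qualifying antigens as predictors, binary labels as response.

    Features are antigens with ``q < q_threshold`` and case prevalence
    above ``prevalence_threshold``; values are log2(CPM+1) for the samples
    in ``labels``.  Constant features are dropped with a warning.
    Standardization is left to the CV loop so fold statistics stay
    train-only.
    """
    if not set(labels.unique()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    qualifying = differential_result.index[
        (differential_result["q"] < q_threshold)
        & (differential_result["case_prevalence"] > prevalence_threshold)
    ]
    if len(qualifying) == 0:
        raise ValueError(
            f"no antigens satisfy q < {q_threshold} and prevalence > "
            f"{prevalence_threshold}"
        )
    X = log2cpm.loc[qualifying, labels.index].T
    constant = X.columns[X.std(axis=0, ddof=0) == 0]
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant predictor(s): "
            f"{list(constant[:5])}",
            stacklevel=2,
        )
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("all qualifying predictors are constant")
    return X, labels.astype(int)


class FoldScaler:
    """Column standardization with train-fold statistics only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FoldScaler":
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_


# --------------------------------------------------------------------------
# penalized fits


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero.

    At the all-zero solution the score is ``X^T (y - mean(y)) / n``; the
    largest absolute component is the entry penalty of the first feature.
    """
    n = len(y)
    residual = y - y.mean()
    return float(np.abs(X.T @ residual).max() / n)


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambda: int = 100, min_ratio: float = 1e-3
) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def fit_lasso(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-7
) -> tuple[np.ndarray, float]:
    """One penalized (or, at lambda=0, unpenalized) logistic fit."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=tol)
    else:
        # large intercept_scaling keeps the liblinear intercept effectively
        # unpenalized; fixed random_state keeps coordinate descent deterministic
        model = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (len(y) * lam),
            solver="liblinear",
            intercept_scaling=100.0,
            random_state=0,
            max_iter=20000,
            tol=tol,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(f"logistic fit failed to converge at lambda={lam}: {exc}")
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    config: ModelConfig | None = None,
) -> LassoPath:
    """Solution path over a decreasing lambda grid (X must be standardized)."""
    config = config or ModelConfig()
    if lambdas is None:
        lambdas = default_lambda_grid(X, y, config.n_lambda, config.lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    coefs = np.zeros((len(lambdas), X.shape[1]))
    intercepts = np.zeros(len(lambdas))
    for i, lam in enumerate(lambdas):
        coefs[i], intercepts[i] = fit_lasso(X, y, lam)
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return LassoPath(lambdas=lambdas, coefficients=coefs, intercepts=intercepts, feature_names=names)


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic: P(case > control) + P(tie)/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# nested cross-validation


def _inner_select(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, inner_folds: int, rng_seed: int
) -> tuple[float, float]:
    """Pick lambda* by mean inner-fold validation AUC; return (lambda*, AUC)."""
    splitter = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=rng_seed)
    aucs = np.zeros(len(lambdas))
    counts = np.zeros(len(lambdas))
    for train_idx, val_idx in splitter.split(X, y):
        if len(np.unique(y[val_idx])) < 2:
            continue
        scaler = FoldScaler().fit(X[train_idx])
        X_train = scaler.transform(X[train_idx])
        X_val = scaler.transform(X[val_idx])
        for i, lam in enumerate(lambdas):
            coef, intercept = fit_lasso(X_train, y[train_idx], lam)
            scores = X_val @ coef + intercept
            aucs[i] += roc_auc(scores, y[val_idx])
            counts[i] += 1
    if counts.max() == 0:
        raise ValueError("no inner validation fold contained both classes")
    mean_auc = aucs / np.maximum(counts, 1)
    best = int(np.argmax(mean_auc))  # ties resolve to the strongest penalty
    return float(lambdas[best]), float(mean_auc[best])


def nested_cv(X: pd.DataFrame, y: pd.Series, config: ModelConfig | None = None) -> ModelReport:
    """Nested cross-validation and a final refit on all data.

    Outer folds are stratified; every outer-training portion runs an inner
    CV over the shared lambda grid.  Reported AUCs: ``train`` averages
    re-substitution on outer-training fits, ``validation`` averages the
    inner-fold AUC at the selected lambda, ``test`` averages the outer
    held-out AUC.  The final model uses the median selected lambda and
    all data.
    """
    config = config or ModelConfig()
    X_values = X.to_numpy(dtype=float)
    y_values = y.to_numpy(dtype=int)
    if len(np.unique(y_values)) < 2:
        raise ValueError("both classes must be present")

    full_scaler = FoldScaler().fit(X_values)
    lambdas = default_lambda_grid(
        full_scaler.transform(X_values), y_values, config.n_lambda, config.lambda_min_ratio
    )

    outer = StratifiedKFold(
        n_splits=config.outer_folds, shuffle=True, random_state=config.seed
    )
    lambda_stars: list[float] = []
    train_aucs: list[float] = []
    val_aucs: list[float] = []
    test_aucs: list[float] = []
    for fold, (train_idx, test_idx) in enumerate(outer.split(X_values, y_values)):
        y_train, y_test = y_values[train_idx], y_values[test_idx]
        if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
            raise ValueError(
                f"outer fold {fold} lacks a class; reduce outer_folds or rebalance"
            )
        lam_star, inner_auc = _inner_select(
            X_values[train_idx], y_train, lambdas, config.inner_folds,
            (config.seed * 1000 + fold) % (2**32),
        )
        lambda_stars.append(lam_star)
        val_aucs.append(inner_auc)
        scaler = FoldScaler().fit(X_values[train_idx])
        coef, intercept = fit_lasso(scaler.transform(X_values[train_idx]), y_train, lam_star)
        train_scores = scaler.transform(X_values[train_idx]) @ coef + intercept
        test_scores = scaler.transform(X_values[test_idx]) @ coef + intercept
        train_aucs.append(roc_auc(train_scores, y_train))
        test_aucs.append(roc_auc(test_scores, y_test))

    final_lambda = float(np.median(lambda_stars))
    X_std = full_scaler.transform(X_values)
    final_coef, final_intercept = fit_lasso(X_std, y_values, final_lambda)
    path = fit_lasso_path(X_std, y_values, lambdas, list(X.columns), config)

    coefficients = pd.Series(final_coef, index=X.columns)
    retained = [c for c in X.columns if abs(coefficients[c]) > ZERO_COEF_TOL]
    excluded = [c for c in X.columns if c not in retained]
    coefficients[excluded] = 0.0

    effects = None
    shap = None
    if retained:
        effects = effect_decomposition(coefficients, pd.DataFrame(X_std, columns=X.columns))
        shap = shap_linear(
            coefficients, pd.DataFrame(X_std, columns=X.columns, index=X.index)
        )
    return ModelReport(
        coefficients=coefficients,
        intercept=final_intercept,
        retained=retained,
        excluded=excluded,
        lambda_stars=lambda_stars,
        final_lambda=final_lambda,
        auc_train=float(np.mean(train_aucs)),
        auc_validation=float(np.mean(val_aucs)),
        auc_test=float(np.mean(test_aucs)),
        path=path,
        effects=effects,
        shap_values=shap,
        feature_means=pd.Series(full_scaler.mean_, index=X.columns),
    )


# --------------------------------------------------------------------------
# attribution


def effect_decomposition(coefficients: pd.Series, X: pd.DataFrame) -> pd.DataFrame:
    """Variance-based main/total effect shares of the linear predictor.

    ``share_j = Var(beta_j x_j) / sum_k Var(beta_k x_k)`` over retained
    predictors.  For a main-effects-only linear model the main and total
    shares coincide; both columns are reported for interface parity.
    """
    retained = coefficients.index[np.abs(coefficients) > ZERO_COEF_TOL]
    if len(retained) == 0:
        raise ValueError("effect decomposition needs at least one retained predictor")
    variances = np.array(
        [
            coefficients[name] ** 2 * X[name].to_numpy().var()
            for name in retained
        ]
    )
    total = variances.sum()
    if total <= 0:
        raise ValueError("retained predictors have zero variance")
    shares = variances / total
    return pd.DataFrame(
        {"main_effect": shares, "total_effect": shares}, index=retained
    ).sort_values("total_effect", ascending=False)


def shap_linear(coefficients: pd.Series, X: pd.DataFrame) -> pd.DataFrame:
    """Exact Shapley values for a linear model under feature independence.

    ``phi_ij = beta_j (x_ij - mean_j)`` on the linear-predictor scale;
    each row sums to the sample's deviation from the cohort-mean linear
    predictor (local accuracy).
    """
    means = X.mean(axis=0)
    centered = X - means
    phi = centered * coefficients
    return pd.DataFrame(phi, index=X.index, columns=X.columns)


def predict_probability(report: ModelReport, X_std: pd.DataFrame) -> pd.Series:
    """Class-1 probabilities from the final model on standardized features."""
    eta = X_std.to_numpy() @ report.coefficients.to_numpy() + report.intercept
    return pd.Series(expit(eta), index=X_std.index)
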