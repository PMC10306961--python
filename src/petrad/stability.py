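"""Repeated-split LASSO stability-selection protocol.

The pipeline, run as a pure function of (data, config, master seed):

1. drop features with missing values or zero variance, then keep only those
   whose Pearson correlation with TNR is significant (two-sided p < alpha,
   no multiplicity correction) — by default computed once on the full
   dataset, before any splitting (a per-split mode is available);
2. for each of ``n_tests`` repetitions: draw a random 70/30 train/test
   split, center/scale predictors on the training split only, regress
   log10(TNR) with an L1 penalty chosen by seeded 5-fold cross-validation,
   potentiate the test predictions back to the TNR scale, and record MAE,
   RMSE, Spearman rho and the selected predictors with their absolute
   standardized coefficients;
3. aggregate medians/quartiles of the metrics and per-predictor occurrence
   counts, model shares and mean significance across all tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

__all__ = [
    "ModelConfig",
    "TestResult",
    "AggregateReport",
    "correlation_filter",
    "standardize",
    "transform_target",
    "potentiate",
    "split",
    "fit_lasso",
    "evaluate_test",
    "run_stability",
    "aggregate",
    "results_to_frame",
]

_ZERO_VAR_TOL = 1e-12


@dataclass
class ModelConfig:
    """Configuration of the stability protocol (defaults mirror the protocol)."""

    n_tests: int = 300
    train_fraction: float = 0.7
    filter_alpha: float = 0.05
    lambda_rule: str = "cv_min"  # "cv_min" or "fixed:<alpha>"
    n_cv_folds: int = 5
    filter_scope: str = "full"  # "full" (filter once, pre-split) or "per_split"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if self.filter_scope not in ("full", "per_split"):
            raise ValueError(f"unknown filter_scope {self.filter_scope!r}")


@dataclass
class TestResult:
    test_index: int
    mae: float
    rmse: float
    spearman_rho: float  # NaN when predictions are constant
    spearman_p: float
    selected: list[tuple[str, float]]  # (feature id, |coefficient|)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


@dataclass
class AggregateReport:
    metrics: dict[str, dict[str, float]]  # metric -> {median, q25, q75}
    predictors: pd.DataFrame  # feature, n_models, share_pct, mean_significance
    n_selected_summary: dict[str, float]  # median, q25, q75, min, max
    n_tests: int


def transform_target(tnr: np.ndarray) -> np.ndarray:
    """Decimal logarithm of TNR values (all must be positive)."""
    tnr = np.asarray(tnr, dtype=np.float64)
    if np.any(tnr <= 0):
        raise ValueError("TNR values must be positive for log10 transform")
    return np.log10(tnr)


def potentiate(pred: np.ndarray) -> np.ndarray:
    """Back-transform log10-scale predictions to the TNR scale (10**x)."""
    return np.power(10.0, np.asarray(pred, dtype=np.float64))


def correlation_filter(
    features: pd.DataFrame, tnr: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Pearson pre-filter: keep features significantly correlated with TNR.

    Features with any missing value or (numerically) zero variance are
    dropped before testing. Two-sided p-values come from the t transform
    with n-2 degrees of freedom; no multiple-testing correction is applied.

    Returns the kept feature ids and a per-feature table of (r, p) for every
    feature that reached the test.
    """
    y = np.asarray(tnr, dtype=np.float64)
    n = len(y)
    if n < 3 or len(features) != n:
        raise ValueError("need >= 3 cases with matching feature rows")
    complete = features.columns[features.notna().all(axis=0)]
    x = features[complete].to_numpy(dtype=np.float64)
    sd = x.std(axis=0, ddof=1)
    varying = sd > _ZERO_VAR_TOL
    cols = list(complete[varying])
    x = x[:, varying]

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    r = (xc * yc[:, None]).sum(axis=0) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    table = pd.DataFrame({"r": r, "p": p}, index=cols)
    kept = [c for c, pv in zip(cols, p) if pv < alpha]
    return kept, table


def standardize(
    train: pd.DataFrame, test: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Center/scale columns on the training split; apply the same to test.

    Uses the sample (ddof=1) standard deviation. Training columns with zero
    variance are dropped from both splits (logged via the returned params).
    """
    center = train.mean(axis=0)
    scale = train.std(axis=0, ddof=1)
    keep = scale > _ZERO_VAR_TOL
    cols = train.columns[keep]
    params = pd.DataFrame({"center": center[cols], "scale": scale[cols]})
    tr = (train[cols] - center[cols]) / scale[cols]
    te = None if test is None else (test[cols] - center[cols]) / scale[cols]
    return tr, te, params


def split(
    n_cases: int, train_fraction: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test index sets; train size = round(fraction*n)."""
    if n_cases < 2:
        raise ValueError("need at least 2 cases to split")
    n_train = int(round(train_fraction * n_cases))
    if n_train < 1 or n_train >= n_cases:
        raise ValueError(
            f"degenerate split: {n_train} train of {n_cases} cases"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n_cases)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def fit_lasso(
    train_x: pd.DataFrame,
    train_logy: np.ndarray,
    lambda_rule: str = "cv_min",
    seed: int = 0,
    n_cv_folds: int = 5,
) -> tuple[float, pd.Series]:
    """L1-penalized least squares on standardized features.

    ``lambda_rule`` is either ``"cv_min"`` (penalty at the minimum of a
    seeded k-fold cross-validation curve on the training split) or
    ``"fixed:<value>"``. An empty feature set yields the intercept-only
    model (intercept = mean of the training target).
    """
    y = np.asarray(train_logy, dtype=np.float64)
    if train_x.shape[1] == 0:
        return float(y.mean()), pd.Series(dtype=np.float64)
    x = train_x.to_numpy(dtype=np.float64)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if lambda_rule == "cv_min":
            folds = min(n_cv_folds, len(y))
            cv = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
            model = LassoCV(cv=cv, alphas=100, max_iter=10000)
            model.fit(x, y)
        elif lambda_rule.startswith("fixed:"):
            alpha = float(lambda_rule.split(":", 1)[1])
            model = Lasso(alpha=alpha, max_iter=10000)
            model.fit(x, y)
        else:
            raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    coefs = pd.Series(model.coef_, index=train_x.columns)
    return float(model.intercept_), coefs


def evaluate_test(
    intercept: float,
    coefs: pd.Series,
    test_x: pd.DataFrame,
    test_tnr: np.ndarray,
    test_index: int = 0,
) -> TestResult:
    """Metrics of one fitted model on its test split, on the TNR scale.

    Predictions are potentiated before computing MAE and RMSE. When the
    predictions are constant, Spearman rho/p are recorded as NaN.
    """
    y_true = np.asarray(test_tnr, dtype=np.float64)
    if len(y_true) == 0:
        raise ValueError("empty test split")
    if coefs.empty:
        pred_log = np.full(len(y_true), intercept)
    else:
        pred_log = test_x[coefs.index].to_numpy(dtype=np.float64) @ coefs.to_numpy() + intercept
    y_pred = potentiate(pred_log)
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.ptp(y_pred) == 0 or np.ptp(y_true) == 0:
        rho, pval = float("nan"), float("nan")
    else:
        rho, pval = stats.spearmanr(y_true, y_pred)
        rho, pval = float(rho), float(pval)
    selected = [(str(f), float(abs(c))) for f, c in coefs.items() if c != 0.0]
    return TestResult(
        test_index=test_index, mae=mae, rmse=rmse,
        spearman_rho=rho, spearman_p=pval, selected=selected,
    )


def run_stability(
    features: pd.DataFrame,
    tnr: np.ndarray,
    config: ModelConfig | None = None,
) -> list[TestResult]:
    """Run the full repeated-split protocol; returns one result per test.

    Deterministic in (features, tnr, config.master_seed): per-test seeds are
    spawned from the master seed. Per-test failures are recorded as all-NaN
    results rather than aborting the batch.
    """
    config = config or ModelConfig()
    y = np.asarray(tnr, dtype=np.float64)
    n = len(y)
    logy = transform_target(y)

    if config.filter_scope == "full":
        kept, _ = correlation_filter(features, y, config.filter_alpha)
        pool = features[kept]
    else:
        pool = features.loc[:, features.notna().all(axis=0)]

    seed_seq = np.random.SeedSequence(config.master_seed)
    children = seed_seq.spawn(config.n_tests)
    results: list[TestResult] = []
    for t, child in enumerate(children):
        rng = np.random.default_rng(child)
        lasso_seed = int(child.generate_state(1)[0])
        try:
            tr_idx, te_idx = split(n, config.train_fraction, rng)
            sub = pool
            if config.filter_scope == "per_split":
                kept, _ = correlation_filter(
                    pool.iloc[tr_idx], y[tr_idx], config.filter_alpha
                )
                sub = pool[kept]
            tr_x, te_x, _ = standardize(sub.iloc[tr_idx], sub.iloc[te_idx])
            intercept, coefs = fit_lasso(
                tr_x, logy[tr_idx], config.lambda_rule, lasso_seed, config.n_cv_folds
            )
            results.append(evaluate_test(intercept, coefs, te_x, y[te_idx], t))
        except ValueError:
            results.append(TestResult(
                test_index=t, mae=float("nan"), rmse=float("nan"),
                spearman_rho=float("nan"), spearman_p=float("nan"), selected=[],
            ))
    return results


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Per-test results as a flat table (selected predictors ;-joined)."""
    return pd.DataFrame({
        "test_index": [r.test_index for r in results],
        "mae": [r.mae for r in results],
        "rmse": [r.rmse for r in results],
        "spearman_rho": [r.spearman_rho for r in results],
        "spearman_p": [r.spearman_p for r in results],
        "n_selected": [r.n_selected for r in results],
        "selected": [";".join(f for f, _ in r.selected) for r in results],
    })


def _summary(values: np.ndarray) -> dict[str, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {"median": float("nan"), "q25": float("nan"), "q75": float("nan")}
    return {
        "median": float(np.median(v)),
        "q25": float(np.percentile(v, 25)),
        "q75": float(np.percentile(v, 75)),
    }


def aggregate(results: list[TestResult]) -> AggregateReport:
    """Cross-test aggregation: metric quartiles and predictor occurrence table."""
    if not results:
        raise ValueError("no results to aggregate")
    n_tests = len(results)
    metrics = {
        "mae": _summary(np.array([r.mae for r in results])),
        "rmse": _summary(np.array([r.rmse for r in results])),
        "spearman_rho": _summary(np.array([r.spearman_rho for r in results])),
        "spearman_p": _summary(np.array([r.spearman_p for r in results])),
    }
    occurrence: dict[str, int] = {}
    weight_sum: dict[str, float] = {}
    for r in results:
        for feat, w in r.selected:
            occurrence[feat] = occurrence.get(feat, 0) + 1
            weight_sum[feat] = weight_sum.get(feat, 0.0) + w
    rows = [
        {
            "feature": f,
            "n_models": c,
            "share_pct": 100.0 * c / n_tests,
            "mean_significance": weight_sum[f] / c,
        }
        for f, c in occurrence.items()
    ]
    predictors = pd.DataFrame(
        rows, columns=["feature", "n_models", "share_pct", "mean_significance"]
    )
    if len(predictors):
        predictors = predictors.sort_values(
            ["n_models", "feature"], ascending=[False, True]
        ).reset_index(drop=True)
    n_sel = np.array([r.n_selected for r in results], dtype=np.float64)
    n_selected_summary = {
        **_summary(n_sel),
        "min": float(n_sel.min()),
        "max": float(n_sel.max()),
    }
    return AggregateReport(
        metrics=metrics,
        predictors=predictors,
        n_selected_summary=n_selected_summary,
        n_tests=n_tests,
    )
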