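"""Factor screening, multi-correlation, preprocessing and the RF/LM models.

The modeling table has one row per dynalog file: the response
``deviation_mm`` (file-mean absolute MLC positional deviation) and eleven
inputs — five fluence features (correlation, energy, entropy, homogeneity,
dice) and six bank-matched wear parameters (ME, BL, MSC, PWM, LO, CO).
Contrast and LG are screened alongside but excluded from the model, being
the factors that fail the Spearman screen.

Screening uses Spearman rank correlation (average ranks, two-sided p) with
p < 0.05 as the effectiveness criterion; the deviations are not normally
distributed, so rank correlation is the appropriate screen. The
multi-correlation coefficient R is the Pearson correlation between the
response and its best linear combination of the factors, i.e. sqrt(R^2) of
the OLS fit, with the overall F-test p-value.

Model fitting follows a 0.7:0.3 train/test split. Preprocessing is fit on
training rows only: z-score by the training mean/sd, then min-max to [0, 1]
by the z-scored training extrema (test rows may fall outside [0, 1]; they
are not clipped). A 5-fold cross-validation inside the training set — with
the scaler re-fit inside each fold, so no leakage — reports per-fold MSE
(mean squared prediction error) and variance explained; the random forest
(200 trees, 6 predictors tried per split) is compared against an ordinary
linear model on the held-out test rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, train_test_split

from .errors import ConfigurationError, ValidationError

#: The eleven model inputs (5 fluence + 6 wear).
MODEL_INPUTS = (
    "correlation",
    "energy",
    "entropy",
    "homogeneity",
    "dice",
    "ME",
    "BL",
    "MSC",
    "PWM",
    "LO",
    "CO",
)
#: Screened factors: the model inputs plus the two that fail the screen.
SCREENING_FACTORS = MODEL_INPUTS + ("contrast", "LG")

RESPONSE = "deviation_mm"


# ---------------------------------------------------------------------------
# screening and multi-correlation


def spearman_screen(
    table: pd.DataFrame,
    factors=SCREENING_FACTORS,
    response: str = RESPONSE,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-factor Spearman r and two-sided p against the response.

    Returns a DataFrame indexed by factor with columns ``spearman_r``,
    ``p_value`` and ``effective`` (p < alpha; optionally after
    Benjamini-Hochberg when ``fdr``). A constant factor yields NaN r and is
    never effective.
    """
    factors = [f for f in factors if f in table.columns]
    if len(table) < 3:
        raise ValidationError("screening requires at least 3 rows")
    sub = table[list(factors) + [response]]
    if sub.isna().any().any():
        raise ValidationError("missing values in screened factors or response")
    y = sub[response].to_numpy()
    rows = []
    for name in factors:
        x = sub[name].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((name, np.nan, np.nan))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = stats.spearmanr(x, y)
        rows.append((name, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["factor", "spearman_r", "p_value"]).set_index("factor")
    pvals = out["p_value"].to_numpy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = ~np.isnan(pvals)
        adj = np.full_like(pvals, np.nan)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        pvals = adj
    out["effective"] = np.where(np.isnan(pvals), False, pvals < alpha)
    return out


@dataclass(frozen=True)
class MultiCorrelationResult:
    R: float
    r_squared: float
    coefficients: np.ndarray  # beta_0 (intercept) first
    p_value: float
    n: int
    k: int


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            bad.append(str(names[j]))
    return bad


def multi_correlation(X, y) -> MultiCorrelationResult:
    """Multiple correlation coefficient of y with the factor matrix X.

    Fits y-hat = b0 + sum b_j x_j by OLS; R is the Pearson correlation
    between y and y-hat (equivalently sqrt of the OLS R^2), with the overall
    F-test p-value.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.asarray(X).shape[1]))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValidationError(f"need more rows ({n}) than factors + 1 ({k + 1})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError(
            "factor matrix is rank deficient; collinear columns: "
            + ", ".join(_collinear_columns(X, names))
        )
    res = sm.OLS(y, design).fit()
    return MultiCorrelationResult(
        R=float(np.sqrt(max(res.rsquared, 0.0))),
        r_squared=float(res.rsquared),
        coefficients=np.asarray(res.params),
        p_value=float(res.f_pvalue),
        n=n,
        k=k,
    )


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class Scaler:
    """Z-score by training mean/sd, then min-max by the z-scored training
    extrema. Fit exclusively on training rows; transformed training columns
    span exactly [0, 1], test values may fall outside (no clipping)."""

    columns_: list[str] = field(default_factory=list)
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None
    zmin_: np.ndarray | None = None
    zmax_: np.ndarray | None = None

    def fit(self, train: pd.DataFrame) -> "Scaler":
        self.columns_ = list(train.columns)
        arr = train.to_numpy(dtype=float)
        self.mean_ = arr.mean(axis=0)
        self.sd_ = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.ones(arr.shape[1])
        zero = np.nonzero(self.sd_ == 0)[0]
        if zero.size:
            raise ValidationError(
                "zero-variance training column(s): "
                + ", ".join(self.columns_[j] for j in zero)
            )
        z = (arr - self.mean_) / self.sd_
        self.zmin_ = z.min(axis=0)
        self.zmax_ = z.max(axis=0)
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise ValidationError("scaler not fitted")
        if list(data.columns) != self.columns_:
            raise ValidationError("column mismatch between fit and transform")
        z = (data.to_numpy(dtype=float) - self.mean_) / self.sd_
        span = np.where(self.zmax_ > self.zmin_, self.zmax_ - self.zmin_, 1.0)
        return pd.DataFrame((z - self.zmin_) / span, columns=self.columns_, index=data.index)

    def inverse_transform_column(self, values: np.ndarray, column: str) -> np.ndarray:
        j = self.columns_.index(column)
        span = self.zmax_[j] - self.zmin_[j] if self.zmax_[j] > self.zmin_[j] else 1.0
        return (np.asarray(values) * span + self.zmin_[j]) * self.sd_[j] + self.mean_[j]

    def params(self) -> dict[str, np.ndarray]:
        return {
            "mean": np.array(self.mean_),
            "sd": np.array(self.sd_),
            "zmin": np.array(self.zmin_),
            "zmax": np.array(self.zmax_),
        }


def preprocess(train: pd.DataFrame, apply_to: pd.DataFrame) -> tuple[pd.DataFrame, Scaler]:
    """Fit the scaler on ``train`` and apply it to ``apply_to``."""
    scaler = Scaler().fit(train)
    return scaler.transform(apply_to), scaler


# ---------------------------------------------------------------------------
# models and evaluation


def mse(y, y_pred) -> float:
    """Mean squared prediction error (1/m) sum (y_i - yhat_i)^2."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValidationError("y and y_pred must have equal length")
    return float(np.mean((y - y_pred) ** 2))


def variance_explained_pct(y, y_pred) -> float:
    """100 * (1 - MSE / Var(y)) on the given set."""
    y = np.asarray(y, dtype=float)
    var = float(np.var(y))
    if var == 0:
        return 100.0 if mse(y, y_pred) == 0 else float("-inf")
    return 100.0 * (1.0 - mse(y, y_pred) / var)


def fit_rf(
    X,
    y,
    n_trees: int = 200,
    mtry: int = 6,
    seed: int = 0,
    min_samples_leaf: int = 5,
    oob: bool = True,
) -> RandomForestRegressor:
    """Bagged regression trees: ``n_trees`` trees, ``mtry`` predictors tried
    per split, variance-reduction splitting; deterministic given ``seed``."""
    X = np.asarray(X, dtype=float)
    if mtry > X.shape[1]:
        raise ConfigurationError(f"mtry={mtry} exceeds the {X.shape[1]} available inputs")
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
        oob_score=oob,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-sample OOB coverage warnings
        model.fit(X, np.asarray(y, dtype=float))
    return model


def fit_lm(X, y) -> LinearRegression:
    """Ordinary least squares on the same inputs."""
    X = np.asarray(X, dtype=float)
    design = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("rank-deficient input matrix for the linear model")
    return LinearRegression().fit(X, np.asarray(y, dtype=float))


def importances_pct(model: RandomForestRegressor, names) -> dict[str, float]:
    """Impurity-based importances normalized to sum to 100%."""
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        imp = np.ones_like(imp)
        total = imp.sum()
    return {str(n): float(v) for n, v in zip(names, 100.0 * imp / total)}


def kfold_indices(n: int, n_folds: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled K-fold partition of range(n); validation-fold sizes differ by
    at most one (e.g. n=521 -> 105,104,104,104,104)."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in kf.split(np.arange(n))]


@dataclass
class CvResult:
    fold_mse_scaled: list[float]
    fold_mse_raw: list[float]
    fold_variance_explained_pct: list[float]
    fold_val_indices: list[np.ndarray]
    fold_scaler_params: list[dict]

    @property
    def mse_scaled(self) -> float:
        return float(np.mean(self.fold_mse_scaled))

    @property
    def mse_raw(self) -> float:
        return float(np.mean(self.fold_mse_raw))

    @property
    def variance_explained_pct(self) -> float:
        return float(np.mean(self.fold_variance_explained_pct))


def cross_validate(
    train_table: pd.DataFrame,
    inputs=MODEL_INPUTS,
    response: str = RESPONSE,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = 200,
    mtry: int = 6,
) -> CvResult:
    """K-fold CV of the random forest inside the training set. The scaler is
    re-fit on each fold's training rows, so fold validation data never leaks
    into preprocessing."""
    cols = list(inputs) + [response]
    folds = kfold_indices(len(train_table), n_folds, seed)
    res = CvResult([], [], [], [], [])
    for tr, va in folds:
        fold_train = train_table.iloc[tr][cols]
        fold_val = train_table.iloc[va][cols]
        scaler = Scaler().fit(fold_train)
        strain = scaler.transform(fold_train)
        sval = scaler.transform(fold_val)
        model = fit_rf(strain[list(inputs)], strain[response], n_trees, mtry, seed, oob=False)
        pred = model.predict(sval[list(inputs)].to_numpy())
        res.fold_mse_scaled.append(mse(sval[response], pred))
        res.fold_variance_explained_pct.append(variance_explained_pct(sval[response], pred))
        pred_raw = scaler.inverse_transform_column(pred, response)
        res.fold_mse_raw.append(mse(fold_val[response], pred_raw))
        res.fold_val_indices.append(va)
        res.fold_scaler_params.append(scaler.params())
    return res


@dataclass
class ModelEvaluation:
    """Held-out and cross-validated performance of the RF model and its
    linear baseline, on both the preprocessed ([0,1]) and raw (mm^2) scales."""

    n_train: int
    n_test: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    cv: CvResult
    rf_test_mse_scaled: float
    rf_test_mse_raw: float
    rf_test_variance_explained_pct: float
    lm_test_mse_scaled: float
    lm_test_mse_raw: float
    rf_oob_variance_explained_pct: float
    importances: dict[str, float]
    rf_model: RandomForestRegressor
    lm_model: LinearRegression
    scaler: Scaler


def train_and_evaluate(
    table: pd.DataFrame,
    inputs=MODEL_INPUTS,
    response: str = RESPONSE,
    seed: int = 0,
    test_fraction: float = 0.3,
    n_folds: int = 5,
    n_trees: int = 200,
    mtry: int = 6,
) -> ModelEvaluation:
    """Full experiment: seeded 0.7:0.3 split, leakage-free 5-fold CV on the
    training rows, final RF and LM fits, held-out evaluation per the MSE
    definition, and normalized importances."""
    inputs = list(inputs)
    cols = inputs + [response]
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(idx, test_size=test_fraction, random_state=seed)
    train_tbl = table.iloc[train_idx][cols].reset_index(drop=True)
    test_tbl = table.iloc[test_idx][cols].reset_index(drop=True)

    cv = cross_validate(train_tbl, inputs, response, n_folds, seed, n_trees, mtry)

    scaler = Scaler().fit(train_tbl)
    strain = scaler.transform(train_tbl)
    stest = scaler.transform(test_tbl)
    rf = fit_rf(strain[inputs], strain[response], n_trees, mtry, seed, oob=True)
    lm = fit_lm(strain[inputs], strain[response])

    rf_pred = rf.predict(stest[inputs].to_numpy())
    lm_pred = lm.predict(stest[inputs].to_numpy())
    rf_pred_raw = scaler.inverse_transform_column(rf_pred, response)
    lm_pred_raw = scaler.inverse_transform_column(lm_pred, response)

    return ModelEvaluation(
        n_train=len(train_tbl),
        n_test=len(test_tbl),
        train_indices=train_idx,
        test_indices=test_idx,
        cv=cv,
        rf_test_mse_scaled=mse(stest[response], rf_pred),
        rf_test_mse_raw=mse(test_tbl[response], rf_pred_raw),
        rf_test_variance_explained_pct=variance_explained_pct(stest[response], rf_pred),
        lm_test_mse_scaled=mse(stest[response], lm_pred),
        lm_test_mse_raw=mse(test_tbl[response], lm_pred_raw),
        rf_oob_variance_explained_pct=100.0 * float(rf.oob_score_),
        importances=importances_pct(rf, inputs),
        rf_model=rf,
        lm_model=lm,
        scaler=scaler,
    )
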