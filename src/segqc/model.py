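"""LASSO regression of the quality score on radiomics features.

The estimator solves ``(1/2n) ||y - Xb||^2 + lambda ||b||_1`` on predictors
standardized to zero mean / unit SD over the training data (responses are
left on the 0-100 score scale). The penalty weight lambda is chosen by
k-fold cross-validation at the patient level — all segmentations of one
patient share a fold — as the smallest CV mean squared error among lambdas
whose out-of-fold Bland-Altman mean difference is within a configurable
tolerance; ties go to the larger (sparser) lambda. Predictions are clamped
to [0, 100].

The modelling surface follows the statsmodels idiom: build a
:class:`QualityRegression` from arrays or a DataFrame, call ``fit()`` and
work with the returned :class:`QualityRegressionResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from .radiomics import FEATURE_NAMES, FeatureVector

__all__ = [
    "QCModel",
    "LambdaSearchResult",
    "QualityRegression",
    "QualityRegressionResults",
    "train",
    "select_lambda",
    "predict",
    "selected_features",
]


def _as_matrix(features, feature_names=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), tuple(features.columns)
    if len(features) and isinstance(features[0], FeatureVector):
        return (
            np.vstack([f.as_array() for f in features]),
            FEATURE_NAMES,
        )
    arr = np.asarray(features, dtype=float)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(arr.shape[1])
    )
    return arr, names


@dataclass(frozen=True)
class QCModel:
    """A trained quality-score regressor: standardization + linear weights."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    coef: np.ndarray
    intercept: float
    lam: float
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coef))

    def predict_array(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        sds = np.where(self.sds > 0, self.sds, 1.0)
        xs = (x - self.means) / sds
        raw = xs @ self.coef + self.intercept
        return np.clip(raw, 0.0, 100.0)

    def to_json(self, path: str) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "lambda": self.lam,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "QCModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(d["feature_names"]),
            np.array(d["means"]),
            np.array(d["sds"]),
            np.array(d["coef"]),
            float(d["intercept"]),
            float(d["lambda"]),
            d.get("provenance", {}),
        )


@dataclass(frozen=True)
class LambdaSearchResult:
    """Cross-validation trace of the lambda search."""

    grid: np.ndarray
    cv_mse: np.ndarray
    bias: np.ndarray
    bias_slope: np.ndarray
    chosen_lambda: float
    fold_assignment: dict
    fallback: bool = False


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    safe = np.where(sds > 0, sds, 1.0)
    return (x - means) / safe, means, sds


def _default_grid(xs: np.ndarray, y: np.ndarray, n_points: int = 100) -> np.ndarray:
    n = len(y)
    lam_max = np.abs(xs.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-8)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - 4, n_points)


def _patient_folds(patient_ids, k: int, seed: int) -> dict:
    """Seeded patient-level fold assignment (patient id -> fold index)."""
    unique = sorted(set(patient_ids), key=str)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            assignment[unique[idx]] = fold
    return assignment


def train(features, rqs, lam: float, feature_names=None, provenance=None) -> QCModel:
    """Fit the LASSO at a fixed lambda.

    Zero-SD (constant) predictors are excluded from the fit and reported
    with coefficient 0.
    """
    x, names = _as_matrix(features, feature_names)
    y = np.asarray(rqs, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"{len(x)} feature rows but {len(y)} responses")
    if len(y) < 10:
        raise ValueError("training needs at least 10 cases")
    if np.any((y < 0) | (y > 100)):
        raise ValueError("reference scores must lie in [0, 100]")
    xs, means, sds = _standardize(x)
    keep = sds > 0
    coef = np.zeros(x.shape[1])
    if y.std() == 0 or not keep.any():
        intercept = float(y.mean())
    else:
        est = Lasso(alpha=lam, fit_intercept=True, max_iter=50000, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(xs[:, keep], y)
        coef[keep] = est.coef_
        intercept = float(est.intercept_)
    prov = dict(provenance or {})
    prov.update({"n": len(y), "lambda": float(lam)})
    return QCModel(names, means, sds, coef, intercept, float(lam), prov)


def select_lambda(
    features,
    rqs,
    k: int = 5,
    grid=None,
    seed: int = 0,
    patient_ids=None,
    bias_tolerance: float = 1.0,
    feature_names=None,
) -> LambdaSearchResult:
    """Choose lambda by patient-level k-fold CV with a Bland-Altman filter.

    Out-of-fold predictions (clamped to the score scale) give, per lambda,
    the CV mean squared error and the Bland-Altman diagnostics: the mean
    difference (bias) and the slope of the difference against the pair
    mean. The chosen lambda minimizes CV-MSE among lambdas with
    ``|bias| <= bias_tolerance``; if none qualify it falls back to the
    unconstrained argmin with a warning.
    """
    x, names = _as_matrix(features, feature_names)
    y = np.asarray(rqs, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k-fold CV needs k >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} cases")
    if patient_ids is None:
        patient_ids = [f"case{i}" for i in range(n)]
    if grid is None:
        xs_all, _, _ = _standardize(x)
        grid = _default_grid(xs_all, y)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0:
        raise ValueError("empty lambda grid")

    assignment = _patient_folds(patient_ids, k, seed)
    fold_of = np.array([assignment[p] for p in patient_ids])
    oof = np.full((len(grid), n), np.nan)
    for fold in range(k):
        test = fold_of == fold
        if not test.any() or test.all():
            continue
        xtr, ytr = x[~test], y[~test]
        xs, means, sds = _standardize(xtr)
        keep = sds > 0
        safe = np.where(keep, sds, 1.0)
        xte = (x[test] - means) / safe
        _, coefs, _ = lasso_path(
            xs[:, keep], ytr - ytr.mean(), alphas=grid, max_iter=50000, tol=1e-8
        )
        # lasso_path returns coefs for alphas sorted descending (our order)
        preds = xte[:, keep] @ coefs + ytr.mean()
        oof[:, test] = np.clip(preds.T, 0.0, 100.0)

    diff = oof - y[None, :]
    cv_mse = np.nanmean(diff**2, axis=1)
    bias = np.nanmean(diff, axis=1)
    bias_slope = np.array(
        [
            np.polyfit((o + y) / 2.0, o - y, 1)[0] if np.nanstd((o + y) / 2) > 0 else 0.0
            for o in oof
        ]
    )
    ok = np.abs(bias) <= bias_tolerance
    fallback = not ok.any()
    if fallback:
        warnings.warn(
            "no lambda met the Bland-Altman bias tolerance "
            f"({bias_tolerance}); falling back to the CV-MSE minimizer",
            stacklevel=2,
        )
        candidates = np.arange(len(grid))
    else:
        candidates = np.flatnonzero(ok)
    # grid is descending, so argmin's first-minimum rule breaks CV-MSE ties
    # toward the larger (sparser) lambda
    best = candidates[np.argmin(cv_mse[candidates])]
    return LambdaSearchResult(
        grid, cv_mse, bias, bias_slope, float(grid[best]), assignment, fallback
    )


def predict(model: QCModel, features) -> np.ndarray | float:
    """Apply a trained model; eQS values are clamped to [0, 100].

    Accepts a single :class:`FeatureVector`, a DataFrame or an array. Named
    inputs must carry exactly the model's features.
    """
    single = False
    if isinstance(features, FeatureVector):
        _check_names(model, FEATURE_NAMES)
        x = features.as_array()[None, :]
        single = True
    elif isinstance(features, pd.DataFrame):
        _check_names(model, tuple(features.columns))
        x = features.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {x.shape[1]}"
            )
    out = model.predict_array(x)
    return float(out[0]) if single else out


def _check_names(model: QCModel, names: tuple[str, ...]) -> None:
    if tuple(names) == tuple(model.feature_names):
        return
    missing = sorted(set(model.feature_names) - set(names))
    extra = sorted(set(names) - set(model.feature_names))
    raise ValueError(
        f"feature mismatch: missing {missing[:5]}{'...' if len(missing) > 5 else ''}, "
        f"extra {extra[:5]}{'...' if len(extra) > 5 else ''}"
    )


def selected_features(model: QCModel) -> pd.DataFrame:
    """Nonzero-coefficient counts and percentages by class and by region.

    Feature names of the form ``region_class_Feature`` are grouped both
    ways; other names are grouped under class ``other``.
    """
    rows = []
    for name, c in zip(model.feature_names, model.coef):
        parts = name.split("_", 2)
        region, cls = (parts[0], parts[1]) if len(parts) == 3 else ("?", "other")
        rows.append({"feature": name, "region": region, "class": cls, "selected": c != 0, "coef": c})
    df = pd.DataFrame(rows)
    by_class = df.groupby("class", sort=False)["selected"].agg(["sum", "count"])
    by_region = df.groupby("region", sort=False)["selected"].agg(["sum", "count"])
    out = pd.concat([by_class, by_region], keys=["class", "region"])
    out.columns = ["n_selected", "n_total"]
    out["pct_selected"] = 100.0 * out["n_selected"] / out["n_total"]
    out["n_selected"] = out["n_selected"].astype(int)
    return out


class QualityRegression:
    """Quality-score regression model built from a feature table.

    Parameters
    ----------
    features : DataFrame, array or list of FeatureVector
        Predictor table, one row per segmentation.
    rqs : array-like
        Reference quality scores in [0, 100].
    patient_ids : array-like, optional
        Grouping labels for patient-level cross-validation folds.
    """

    def __init__(self, features, rqs, patient_ids=None, feature_names=None):
        self.exog, self.exog_names = _as_matrix(features, feature_names)
        self.endog = np.asarray(rqs, dtype=float)
        if len(self.exog) != len(self.endog):
            raise ValueError("features and responses differ in length")
        self.patient_ids = (
            list(patient_ids)
            if patient_ids is not None
            else [f"case{i}" for i in range(len(self.endog))]
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, response: str = "rqs", patient_col: str | None = "patient_id"
    ) -> "QualityRegression":
        drop = [response] + ([patient_col] if patient_col and patient_col in df else [])
        features = df.drop(columns=drop)
        pids = df[patient_col] if patient_col and patient_col in df else None
        return cls(features, df[response], patient_ids=pids)

    def fit(
        self,
        lam: float | None = None,
        cv: int = 5,
        grid=None,
        seed: int = 0,
        bias_tolerance: float = 1.0,
    ) -> "QualityRegressionResults":
        """Fit the LASSO, selecting lambda by CV when not given."""
        search = None
        if lam is None:
            search = select_lambda(
                self.exog,
                self.endog,
                k=cv,
                grid=grid,
                seed=seed,
                patient_ids=self.patient_ids,
                bias_tolerance=bias_tolerance,
                feature_names=self.exog_names,
            )
            lam = search.chosen_lambda
        model = train(
            self.exog,
            self.endog,
            lam,
            feature_names=self.exog_names,
            provenance={"seed": seed, "folds": cv},
        )
        return QualityRegressionResults(self, model, search)


class QualityRegressionResults:
    """Fitted LASSO results: coefficients, lambda search trace, summaries."""

    def __init__(self, model_spec, qc_model: QCModel, search: LambdaSearchResult | None):
        self.model = model_spec
        self.qc_model = qc_model
        self.search = search

    @property
    def params(self) -> pd.Series:
        s = pd.Series(self.qc_model.coef, index=list(self.qc_model.feature_names))
        s["(intercept)"] = self.qc_model.intercept
        return s

    @property
    def lambda_(self) -> float:
        return self.qc_model.lam

    @property
    def n_selected(self) -> int:
        return self.qc_model.n_selected

    def predict(self, features=None):
        if features is None:
            features = self.model.exog
        return predict(self.qc_model, features)

    def selected_features(self) -> pd.DataFrame:
        return selected_features(self.qc_model)

    def summary(self) -> str:
        m = self.qc_model
        lines = [
            "Quality-score LASSO regression",
            "=" * 46,
            f"n cases:            {len(self.model.endog)}",
            f"n features:         {len(m.feature_names)}",
            f"lambda:             {m.lam:.6g}",
            f"selected features:  {m.n_selected} / {len(m.feature_names)}",
            f"intercept:          {m.intercept:.3f}",
        ]
        if self.search is not None:
            i = int(np.argmin(np.abs(self.search.grid - m.lam)))
            lines += [
                f"CV MSE at lambda:   {self.search.cv_mse[i]:.3f}",
                f"CV bias at lambda:  {self.search.bias[i]:+.3f}",
            ]
        lines.append("-" * 46)
        sel = self.selected_features().loc["class"]
        for cls, row in sel.iterrows():
            lines.append(
                f"{cls:>12}: {int(row.n_selected):3d} / {int(row.n_total):3d} "
                f"({row.pct_selected:5.1f}%)"
            )
        return "\n".join(lines)
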