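"""Four regression learners behind one contract, with repeated-split CV.

The trait-environment relationship is fitted with two statistical models
— a polynomial Gaussian GLM and a penalized-spline GAM — and two machine
learning models — random forest (RF) and boosted regression trees (BRT).
All four are validated identically: ``n_repetitions`` independent random
80/20 train/test splits, held-out predictions pooled over repetitions,
and predictive skill summarized as the cross-validated pseudo-R² — the
squared Pearson correlation between pooled held-out predictions and
observations (0 by convention when either vector is constant).

Defaults (all configurable through :class:`LearnerSpec`):

* glm — degree-2 polynomial per predictor on standardized inputs
  (permits unimodal responses), ordinary least squares;
* gam — cubic B-spline smooth per predictor (df 6), fixed modest
  penalty, via statsmodels ``GLMGam``;
* rf  — 300 trees, mtry = p/3;
* brt — learning rate 0.01, depth 3, up to 500 trees with early
  stopping on an internal 15% validation fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

LEARNER_KINDS = ("glm", "gam", "rf", "brt")

DEFAULT_PARAMS: dict[str, dict] = {
    "glm": {"degree": 2},
    "gam": {"df": 6, "spline_degree": 3, "alpha": 10.0},
    "rf": {"n_trees": 300, "max_features": 1.0 / 3.0, "min_samples_leaf": 5},
    "brt": {"learning_rate": 0.01, "max_depth": 3, "max_trees": 500,
            "n_iter_no_change": 30, "validation_fraction": 0.15},
}


def pseudo_r2(predicted, observed) -> float:
    """Squared Pearson correlation between predictions and observations.

    Returns 0.0 when either vector is constant (no linear association
    can be estimated); rejects length mismatches and n < 3.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"length mismatch: predicted {predicted.shape} vs observed {observed.shape}"
        )
    if predicted.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return 0.0
    r = np.corrcoef(predicted, observed)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class LearnerSpec:
    """One learner: kind, hyperparameters, seed (fully serializable)."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        merged = dict(DEFAULT_PARAMS[self.kind], **self.params)
        object.__setattr__(self, "params", merged)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params), "seed": self.seed}


class ConvergenceFailure(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model wrappers

class _PolyGLM:
    """Per-predictor polynomial least squares on standardized inputs."""

    def __init__(self, degree: int):
        self.degree = degree

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PolyGLM":
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        design = self._design(X)
        self._coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        if not np.all(np.isfinite(self._coef)):
            raise ConvergenceFailure("glm coefficients not finite")
        return self

    def _design(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self._mu) / self._sd
        cols = [np.ones(len(Z))]
        for d in range(1, self.degree + 1):
            cols.append(Z**d)
        return np.column_stack([c if c.ndim > 1 else c[:, None] for c in cols])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._design(X) @ self._coef


class _SplineGAM:
    """Gaussian GAM with one B-spline smooth per predictor (statsmodels).

    Inputs are z-scored before the basis is built so that one curvature
    penalty weight is meaningful across predictors of very different
    physical scales.  The basis is only defined over the training range;
    beyond it the smooth is extended as a constant (inputs are clipped
    at predict time), the usual conservative treatment of spline
    extrapolation.
    """

    def __init__(self, df: int, spline_degree: int, alpha: float):
        self.df = df
        self.spline_degree = spline_degree
        self.alpha = alpha

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SplineGAM":
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Z = (X - self._mu) / self._sd
        self._lo = Z.min(axis=0)
        self._hi = Z.max(axis=0)
        self._const = float(y[0]) if np.ptp(y) == 0 else None
        if self._const is not None:  # degenerate response: the smooth is flat
            return self
        from statsmodels.gam.api import BSplines, GLMGam

        k = X.shape[1]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._smoother = BSplines(
                    Z, df=[self.df] * k, degree=[self.spline_degree] * k,
                    include_intercept=False,
                )
                model = GLMGam(
                    y, np.ones((len(y), 1)), smoother=self._smoother,
                    alpha=[self.alpha] * k,
                )
                self._res = model.fit()
        except Exception as exc:  # singular design, degenerate predictor, ...
            raise ConvergenceFailure(f"gam fit failed: {exc}") from exc
        if not np.all(np.isfinite(self._res.params)):
            raise ConvergenceFailure("gam coefficients not finite")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._const is not None:
            return np.full(len(X), self._const)
        Z = np.clip((X - self._mu) / self._sd, self._lo, self._hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(
                self._res.predict(np.ones((len(X), 1)), exog_smooth=Z)
            )


def _build_model(spec: LearnerSpec):
    p = spec.params
    if spec.kind == "glm":
        return _PolyGLM(degree=p["degree"])
    if spec.kind == "gam":
        return _SplineGAM(df=p["df"], spline_degree=p["spline_degree"],
                          alpha=p["alpha"])
    if spec.kind == "rf":
        return RandomForestRegressor(
            n_estimators=p["n_trees"], max_features=p["max_features"],
            min_samples_leaf=p["min_samples_leaf"],
            random_state=spec.seed, n_jobs=1,
        )
    return GradientBoostingRegressor(
        n_estimators=p["max_trees"], learning_rate=p["learning_rate"],
        max_depth=p["max_depth"], n_iter_no_change=p["n_iter_no_change"],
        validation_fraction=p["validation_fraction"], random_state=spec.seed,
    )


class FittedLearner:
    """A trained model bound to its predictor names and training ranges."""

    def __init__(self, spec: LearnerSpec, model, predictor_names: list[str],
                 train_ranges: dict[str, tuple[float, float]]):
        self.spec = spec
        self._model = model
        self.predictor_names = list(predictor_names)
        self.train_ranges = train_ranges

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [p for p in self.predictor_names if p not in features.columns]
            if missing:
                raise ValueError(f"missing predictor columns: {missing}")
            X = features[self.predictor_names].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
        return np.asarray(self._model.predict(X), dtype=float)


def fit_learner(spec: LearnerSpec, features: pd.DataFrame,
                targets: np.ndarray | pd.Series) -> FittedLearner:
    """Train one learner; deterministic given ``spec.seed``.

    Raises :class:`ConvergenceFailure` when the underlying fit breaks
    down; ``cross_validate`` converts that into a flagged result.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if len(X) < 20:
        raise ValueError(f"need at least 20 rows to fit, got {len(X)}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("features/targets contain missing values")
    names = (list(features.columns) if isinstance(features, pd.DataFrame)
             else [f"x{i}" for i in range(X.shape[1])])
    model = _build_model(spec)
    model.fit(X, y)
    ranges = {n: (float(X[:, j].min()), float(X[:, j].max()))
              for j, n in enumerate(names)}
    return FittedLearner(spec, model, names, ranges)


# ---------------------------------------------------------------------------
# repeated split-sample cross-validation

@dataclass
class FitResult:
    """One learner's CV record plus the final full-data refit.

    ``predictions`` has one row per held-out observation per repetition
    (columns: row, repetition, predicted, observed); ``inner_scores``
    holds one training-side pseudo-R² per repetition, estimated on an
    inner 80/20 split of that repetition's training part (used for
    leakage-free ensemble weighting at evaluation time).
    """

    spec: LearnerSpec
    model: FittedLearner | None
    predictions: pd.DataFrame
    pseudo_r2: float
    train_ranges: dict[str, tuple[float, float]]
    inner_scores: list[float]
    splits: list[tuple[np.ndarray, np.ndarray]]
    flagged: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "pseudo_r2": self.pseudo_r2,
            "flagged": self.flagged,
            "message": self.message,
            "inner_scores": list(self.inner_scores),
            "train_ranges": {k: list(v) for k, v in self.train_ranges.items()},
        }


def split_indices(n: int, n_repetitions: int, train_fraction: float,
                  seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """The shared random 80/20 split sequence (depends only on n and seed),
    so that all learners see identical train/test partitions."""
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    splits = []
    for _ in range(n_repetitions):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def cross_validate(
    spec: LearnerSpec,
    features: pd.DataFrame,
    targets: np.ndarray | pd.Series,
    n_repetitions: int = 10,
    train_fraction: float = 0.8,
    seed: int = 0,
    inner_scores: bool = True,
    refit_final: bool = True,
) -> FitResult:
    """Repeated random split-sample cross-validation of one learner.

    Held-out predictions are pooled across repetitions and scored with
    :func:`pseudo_r2`; the final model is refit on all rows.  Any
    :class:`ConvergenceFailure` yields a flagged result with
    pseudo-R² 0 instead of aborting.
    """
    y = np.asarray(targets, dtype=float)
    n = len(y)
    if n < 25:
        raise ValueError(f"need at least 25 rows for cross-validation, got {n}")
    splits = split_indices(n, n_repetitions, train_fraction, seed)
    if len(splits[0][0]) < 20:
        raise ValueError("training part of each split must have >= 20 rows")

    feats = features.reset_index(drop=True)
    rows, reps, preds, obs = [], [], [], []
    inner: list[float] = []
    inner_rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    try:
        for rep, (tr, te) in enumerate(splits):
            fit = fit_learner(spec, feats.iloc[tr], y[tr])
            p = fit.predict(feats.iloc[te])
            rows.extend(te)
            reps.extend([rep] * len(te))
            preds.extend(p)
            obs.extend(y[te])
            if inner_scores:
                m = len(tr)
                iperm = inner_rng.permutation(m)
                n_itr = int(round(train_fraction * m))
                itr, ite = tr[iperm[:n_itr]], tr[iperm[n_itr:]]
                ifit = fit_learner(spec, feats.iloc[itr], y[itr])
                inner.append(pseudo_r2(ifit.predict(feats.iloc[ite]), y[ite]))
        final = fit_learner(spec, feats, y) if refit_final else None
    except ConvergenceFailure as exc:
        warnings.warn(f"{spec.kind} flagged: {exc}", stacklevel=2)
        return FitResult(
            spec=spec, model=None,
            predictions=pd.DataFrame(columns=["row", "repetition", "predicted",
                                              "observed"]),
            pseudo_r2=0.0, train_ranges={}, inner_scores=[],
            splits=splits, flagged=True, message=str(exc),
        )

    table = pd.DataFrame({
        "row": np.asarray(rows, dtype=int),
        "repetition": np.asarray(reps, dtype=int),
        "predicted": np.asarray(preds, dtype=float),
        "observed": np.asarray(obs, dtype=float),
    })
    score = pseudo_r2(table["predicted"], table["observed"])
    if final is not None:
        ranges = final.train_ranges
    else:
        arr = feats.to_numpy(dtype=float)
        ranges = {c: (float(arr[:, j].min()), float(arr[:, j].max()))
                  for j, c in enumerate(feats.columns)}
    return FitResult(
        spec=spec, model=final, predictions=table, pseudo_r2=score,
        train_ranges=ranges, inner_scores=inner, splits=splits,
    )
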