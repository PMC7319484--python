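"""Performance-weighted ensemble of the four learners.

The ensemble averages learner predictions weighted by each learner's
cross-validated pseudo-R² (flagged learners enter with weight 0).  On
top of plain prediction it provides:

* ensemble accuracy — held-out predictions of the four learners
  composed per cross-validation repetition with weights estimated from
  an inner split of that repetition's training part (no test-set
  leakage), then scored against the observations;
* permutation variable importance — 1 minus the Spearman rank
  correlation between predictions on the original table and predictions
  with one predictor column permuted, averaged over seeded permutations;
* partial responses — partial-dependence style curves per predictor
  with a weighted coefficient-of-variation band and extrapolation flags;
* model-disagreement maps — per-cell ensemble prediction and the
  performance-weighted coefficient of variation (CV) of the individual
  model predictions around it.

The weighted CV at a point is ``sqrt(sum_m w_m (y_m - y_ens)^2 / sum_m
w_m) / |y_ens|`` — zero exactly when all positively weighted models
agree, undefined (NaN) where the ensemble prediction is ~0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import PredictorStack
from .learners import LEARNER_KINDS, FitResult, pseudo_r2


class NoSkilledLearnerError(RuntimeError):
    """All learner scores are zero: no basis for ensemble weighting."""


def ensemble_weights(pseudo_r2_by_learner: dict[str, float]) -> dict[str, float]:
    """Normalize cross-validated pseudo-R² scores into ensemble weights."""
    scores = {}
    for kind, s in pseudo_r2_by_learner.items():
        if not np.isfinite(s):
            s = 0.0
        scores[kind] = max(0.0, float(s))
    total = sum(scores.values())
    if total <= 0:
        raise NoSkilledLearnerError(
            "all learners have zero cross-validated pseudo-R2"
        )
    return {k: v / total for k, v in scores.items()}


@dataclass
class EnsembleModel:
    """Four fitted learners plus their normalized performance weights."""

    trait: str
    fits: dict[str, FitResult]
    weights: dict[str, float]
    predictors: list[str]

    @property
    def train_ranges(self) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for fr in self.fits.values():
            for p, (lo, hi) in fr.train_ranges.items():
                if p in out:
                    out[p] = (min(out[p][0], lo), max(out[p][1], hi))
                else:
                    out[p] = (lo, hi)
        return out

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "weights": dict(self.weights),
            "predictors": list(self.predictors),
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
        }


def build_ensemble(trait: str, fits: dict[str, FitResult]) -> EnsembleModel:
    scores = {k: (0.0 if f.flagged else f.pseudo_r2) for k, f in fits.items()}
    weights = ensemble_weights(scores)
    predictors = next(
        (f.model.predictor_names for f in fits.values() if f.model is not None),
        None,
    )
    if predictors is None:  # CV-only fits (refit_final=False)
        predictors = next(
            list(f.train_ranges) for f in fits.values() if f.train_ranges
        )
    return EnsembleModel(trait=trait, fits=fits, weights=weights,
                         predictors=predictors)


def ensemble_predict(model: EnsembleModel, features: pd.DataFrame) -> np.ndarray:
    """Weighted average of the individual learners' predictions."""
    missing = [p for p in model.predictors if p not in features.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    out = np.zeros(len(features))
    for kind, w in model.weights.items():
        if w > 0:
            out += w * model.fits[kind].model.predict(features)
    return out


def member_predictions(model: EnsembleModel, features: pd.DataFrame) -> pd.DataFrame:
    """Per-learner predictions (columns = positively weighted learners)."""
    return pd.DataFrame({
        kind: model.fits[kind].model.predict(features)
        for kind, w in model.weights.items() if w > 0
    })


def ensemble_cv(predictions: np.ndarray, weights: np.ndarray,
                epsilon: float = 1e-9) -> float:
    """Performance-weighted coefficient of variation at one point.

    NaN where the ensemble prediction magnitude is below ``epsilon``;
    0 by convention with a single positively weighted learner.
    """
    p = np.asarray(predictions, dtype=float)
    w = np.asarray(weights, dtype=float)
    pos = w > 0
    if pos.sum() == 0:
        raise ValueError("need at least one positive weight")
    p, w = p[pos], w[pos]
    ens = float(np.sum(w * p) / np.sum(w))
    if len(p) == 1:
        return 0.0
    if abs(ens) < epsilon:
        return float("nan")
    sd = np.sqrt(np.sum(w * (p - ens) ** 2) / np.sum(w))
    return float(sd / abs(ens))


def _cv_vector(member: pd.DataFrame, weights: dict[str, float],
               epsilon: float = 1e-9) -> np.ndarray:
    """Vectorized weighted CV across learners for many points."""
    w = np.array([weights[k] for k in member.columns])
    P = member.to_numpy(dtype=float)
    wsum = w.sum()
    ens = P @ w / wsum
    if P.shape[1] == 1:
        return np.zeros(len(P))
    sd = np.sqrt(((P - ens[:, None]) ** 2 @ w) / wsum)
    out = np.where(np.abs(ens) < epsilon, np.nan, sd / np.abs(ens))
    return out


def ensemble_accuracy(model: EnsembleModel) -> float:
    """Cross-validated accuracy of the ensemble itself.

    For every repetition, the learners' held-out predictions are
    composed with weights estimated from that repetition's inner
    training-side scores; the pooled composed predictions are then
    scored against the observations with :func:`pseudo_r2`.
    """
    active = {k: f for k, f in model.fits.items() if not f.flagged}
    if not active:
        raise NoSkilledLearnerError("every learner is flagged")
    # all learners must have seen identical splits
    tables = {}
    ref = None
    for kind, f in active.items():
        t = f.predictions.sort_values(["repetition", "row"]).reset_index(drop=True)
        key = t[["repetition", "row"]].to_numpy()
        if ref is None:
            ref = key
        elif key.shape != ref.shape or (key != ref).any():
            raise ValueError("learners' held-out predictions are misaligned")
        tables[kind] = t
    first = next(iter(tables.values()))
    reps = first["repetition"].to_numpy()
    observed = first["observed"].to_numpy()

    composed = np.zeros(len(first))
    for rep in np.unique(reps):
        inner = {k: (f.inner_scores[rep] if f.inner_scores else 0.0)
                 for k, f in active.items()}
        try:
            w = ensemble_weights(inner)
        except NoSkilledLearnerError:
            w = {k: 1.0 / len(active) for k in active}
        m = reps == rep
        for kind, t in tables.items():
            composed[m] += w[kind] * t.loc[m, "predicted"].to_numpy()
    return pseudo_r2(composed, observed)


# ---------------------------------------------------------------------------
# permutation importance

def permutation_importance(
    fit: FitResult,
    features: pd.DataFrame,
    n_permutations: int = 10,
    seed: int = 0,
    permutation_func=None,
) -> pd.Series:
    """Relative importance of each predictor for one fitted learner.

    importance = 1 - Spearman rho between predictions on the original
    table and predictions with the focal column permuted, averaged over
    ``n_permutations`` seeded permutations.  A negative rho is kept
    (importance may exceed 1).  ``permutation_func(rng, n)`` can override
    the permutation for testing.
    """
    if fit.model is None:
        raise ValueError("cannot compute importance of a flagged learner")
    if len(features) < 10:
        raise ValueError("need at least 10 rows")
    rng = np.random.default_rng(seed)
    base = fit.model.predict(features)
    if np.std(base) == 0:
        warnings.warn("constant predictions; importances reported as 0",
                      stacklevel=2)
        return pd.Series(0.0, index=fit.model.predictor_names)

    out = {}
    for name in fit.model.predictor_names:
        vals = []
        for _ in range(n_permutations):
            idx = (permutation_func(rng, len(features)) if permutation_func
                   else rng.permutation(len(features)))
            perm = features.copy()
            perm[name] = features[name].to_numpy()[idx]
            pred = fit.model.predict(perm)
            if np.array_equal(pred, base):
                vals.append(0.0)  # model provably ignores this predictor
                continue
            if np.std(pred) == 0:
                warnings.warn(f"constant permuted predictions for {name}",
                              stacklevel=2)
                vals.append(0.0)
                continue
            rho = stats.spearmanr(base, pred).statistic
            vals.append(1.0 - rho)
        out[name] = float(np.mean(vals))
    return pd.Series(out)


def ensemble_importance(
    importances: dict[str, pd.Series],
    weights: dict[str, float],
) -> pd.DataFrame:
    """Combine per-learner importances into the ensemble importance table.

    Per predictor: each learner's importance, their weighted mean, and
    the weighted coefficient of variation across learners (same
    weighting rule as the prediction CV).
    """
    active = {k: w for k, w in weights.items() if w > 0}
    missing = [k for k in active if k not in importances]
    if missing:
        raise ValueError(f"missing importances for weighted learners: {missing}")
    table = pd.DataFrame({k: importances[k] for k in active})
    w = np.array([active[k] for k in table.columns])
    w = w / w.sum()
    vals = table.to_numpy(dtype=float)
    mean = vals @ w
    sd = np.sqrt(((vals - mean[:, None]) ** 2) @ w)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(np.abs(mean) > 1e-12, sd / np.abs(mean), 0.0)
    table["ensemble"] = mean
    table["cv"] = cv
    return table


# ---------------------------------------------------------------------------
# partial responses and maps

@dataclass
class PartialResponse:
    trait: str
    predictor: str
    table: pd.DataFrame  # focal_value, response, cv, extrapolated (+ per-learner)


def partial_response(
    model: EnsembleModel,
    features: pd.DataFrame,
    focal: str,
    grid_size: int = 50,
    margin: float = 0.0,
) -> PartialResponse:
    """Ensemble partial-dependence curve for one predictor.

    At each focal value on an even grid spanning the observed range
    (optionally extended by ``margin`` as a fraction of the range), each
    learner's prediction is averaged over all training rows with the
    focal column replaced; the ensemble curve is the weighted mean
    across learners and the band the weighted CV.  Points outside the
    training range of the focal predictor are flagged as extrapolated.
    """
    if focal not in model.predictors:
        raise ValueError(f"predictor {focal!r} not in model")
    x = features[focal].to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    span = hi - lo
    grid = np.linspace(lo - margin * span, hi + margin * span, grid_size)
    t_lo, t_hi = model.train_ranges[focal]

    curves = {}
    for kind, w in model.weights.items():
        if w <= 0:
            continue
        fit = model.fits[kind].model
        resp = np.empty(grid_size)
        for i, v in enumerate(grid):
            mod_feats = features.copy()
            mod_feats[focal] = v
            resp[i] = fit.predict(mod_feats).mean()
        curves[kind] = resp
    member = pd.DataFrame(curves)
    w = np.array([model.weights[k] for k in member.columns])
    response = member.to_numpy() @ (w / w.sum())
    cv = _cv_vector(member, model.weights)
    table = pd.DataFrame({
        "focal_value": grid,
        "response": response,
        "cv": cv,
        "extrapolated": (grid < t_lo) | (grid > t_hi),
    })
    for kind in member.columns:
        table[f"response_{kind}"] = member[kind]
    return PartialResponse(trait=model.trait, predictor=focal, table=table)


def predict_maps(
    model: EnsembleModel,
    stack: PredictorStack,
    predictors: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble prediction and weighted-CV rasters over a predictor stack.

    Cells outside the mask or with any missing predictor value are NaN
    in both outputs.
    """
    predictors = predictors or model.predictors
    for p in predictors:
        if p not in stack.layers:
            raise ValueError(f"predictor {p!r} absent from stack")
    frame = stack.to_frame()
    complete = frame[predictors].notna().all(axis=1)
    frame = frame[complete]
    member = member_predictions(model, frame[predictors])
    w = np.array([model.weights[k] for k in member.columns])
    pred = member.to_numpy() @ (w / w.sum())
    cv = _cv_vector(member, model.weights)

    shape = (stack.grid.n_rows, stack.grid.n_cols)
    pred_map = np.full(shape, np.nan)
    cv_map = np.full(shape, np.nan)
    r = frame["row"].to_numpy(dtype=int)
    c = frame["col"].to_numpy(dtype=int)
    pred_map[r, c] = pred
    cv_map[r, c] = cv
    return pred_map, cv_map
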