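"""Prediction reliability: MESS applicability domain, trait-combination
realism, and preservation of among-trait correlations.

MESS (multivariate environmental similarity surface) scores each target
point against the reference (training) environmental table.  For one
predictor with reference values ``x_1..x_n`` and target value ``p``,
with ``f`` the percentage of reference values strictly below ``p``::

    S = (p - min) / (max - min) * 100      if f = 0
      = 2 f                                if 0 < f <= 50
      = 2 (100 - f)                        if 50 < f < 100
      = (max - p) / (max - min) * 100      if f = 100

The point similarity is the minimum over predictors; it is negative iff
at least one predictor lies outside the reference min-max range, and the
minimizing predictor identifies what limits the prediction there.

Trait-combination realism asks whether each predicted community-mean
4-trait vector falls inside a one-class support-vector boundary fitted
to observation-level trait combinations (log10, z-scored).  Note the
deliberate scale mismatch: community-mean predictions are tested against
an individual-level boundary, so a cell flagged outside means only that
the combination was never observed in the input data — it should be
interpreted with caution, not read as impossible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .synthetic import TRAITS


# ---------------------------------------------------------------------------
# MESS

@dataclass
class MESSResult:
    """Per target point: similarity and the most dissimilar predictor."""

    table: pd.DataFrame          # similarity, limiting_predictor
    per_predictor: pd.DataFrame  # S_j per predictor column
    skipped_predictors: list[str] = field(default_factory=list)

    @property
    def similarity(self) -> np.ndarray:
        return self.table["similarity"].to_numpy()


def mess(reference: pd.DataFrame, target: pd.DataFrame,
         on_constant: str = "skip") -> MESSResult:
    """Multivariate environmental similarity of target points to a
    reference table (same predictor columns).

    A reference predictor with no spread cannot be scored; by default it
    is skipped with a warning (``on_constant='error'`` raises instead).
    """
    cols = [c for c in reference.columns if c in target.columns]
    if not cols:
        raise ValueError("reference and target share no predictor columns")
    usable, skipped = [], []
    for c in cols:
        v = reference[c].to_numpy(dtype=float)
        if np.unique(v).size < 2:
            if on_constant == "error":
                raise ValueError(f"reference predictor {c!r} is constant")
            skipped.append(c)
        else:
            usable.append(c)
    if skipped:
        warnings.warn(f"constant reference predictors skipped: {skipped}",
                      stacklevel=2)
    if not usable:
        raise ValueError("no reference predictor has at least 2 distinct values")

    n_t = len(target)
    S = np.empty((n_t, len(usable)))
    for j, c in enumerate(usable):
        ref = np.sort(reference[c].to_numpy(dtype=float))
        p = target[c].to_numpy(dtype=float)
        n = len(ref)
        lo, hi = ref[0], ref[-1]
        f = np.searchsorted(ref, p, side="left") / n * 100.0
        s = np.where(f <= 50.0, 2.0 * f, 2.0 * (100.0 - f))
        s = np.where(f == 0.0, (p - lo) / (hi - lo) * 100.0, s)
        s = np.where(f == 100.0, (hi - p) / (hi - lo) * 100.0, s)
        S[:, j] = s

    idx = np.argmin(S, axis=1)  # ties -> first in column order
    table = pd.DataFrame({
        "similarity": S[np.arange(n_t), idx],
        "limiting_predictor": [usable[i] for i in idx],
    })
    return MESSResult(table=table,
                      per_predictor=pd.DataFrame(S, columns=usable),
                      skipped_predictors=skipped)


# ---------------------------------------------------------------------------
# trait hypervolume realism

@dataclass
class TraitHypervolume:
    """One-class SVM boundary in log10 z-scored 4-trait space."""

    traits: list[str]
    log_mean: np.ndarray
    log_sd: np.ndarray
    svm: OneClassSVM
    nu: float
    gamma: float
    training_inclusion: float

    def _transform(self, table: pd.DataFrame) -> np.ndarray:
        vals = table[self.traits].to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValueError("trait values must be positive for log transform")
        return (np.log10(vals) - self.log_mean) / self.log_sd

    def contains(self, table: pd.DataFrame) -> np.ndarray:
        """Deterministic inside/outside decision per row."""
        return self.svm.predict(self._transform(table)) > 0


def trait_combinations(observations: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long observation table to one 4-trait row per individual
    record (study x site x species), keeping only complete rows."""
    wide = observations.pivot_table(
        index=["study_id", "site_id", "species"],
        columns="trait", values="value", aggfunc="mean",
    ).reset_index()
    wide = wide.dropna(subset=[t for t in TRAITS if t in wide.columns])
    return wide


def fit_trait_hypervolume(
    records: pd.DataFrame,
    looseness: float = 0.05,
    gamma: float | None = None,
    traits: list[str] | None = None,
) -> TraitHypervolume:
    """Fit the trait-space boundary on observation-level records.

    ``looseness`` is the one-class nu parameter: the fraction of
    training points allowed to fall outside the boundary (default 5%).
    The RBF kernel width defaults to the median heuristic
    ``gamma = 1 / (2 median(d)^2)`` over pairwise distances in the
    transformed space (deterministic strided subsample above 500 rows).
    """
    traits = traits or [t for t in TRAITS if t in records.columns]
    complete = records.dropna(subset=traits)
    if len(complete) < 50:
        raise ValueError(
            f"need at least 50 complete {len(traits)}-trait records, "
            f"got {len(complete)}"
        )
    vals = complete[traits].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("trait values must be positive for log transform")
    logs = np.log10(vals)
    mu = logs.mean(axis=0)
    sd = logs.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (logs - mu) / sd

    if gamma is None:
        sub = Z if len(Z) <= 500 else Z[:: len(Z) // 500 + 1]
        d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1))
        med = np.median(d[np.triu_indices(len(sub), k=1)])
        gamma = 1.0 / (2.0 * med**2) if med > 0 else 1.0

    svm = OneClassSVM(kernel="rbf", nu=looseness, gamma=gamma).fit(Z)
    inclusion = float((svm.predict(Z) > 0).mean())
    return TraitHypervolume(
        traits=list(traits), log_mean=mu, log_sd=sd, svm=svm,
        nu=looseness, gamma=float(gamma), training_inclusion=inclusion,
    )


REALISM_CAVEAT = (
    "A trait combination outside the boundary did not occur in the input "
    "data; that does not imply it cannot exist. Interpret with caution."
)


@dataclass
class RealismReport:
    fraction_inside: float | None
    n_tested: int
    n_skipped: int
    outside: pd.DataFrame
    caveat: str = REALISM_CAVEAT

    def to_dict(self) -> dict:
        return {
            "fraction_inside": self.fraction_inside,
            "n_tested": self.n_tested,
            "n_skipped": self.n_skipped,
            "n_outside": len(self.outside),
            "caveat": self.caveat,
        }


def combination_realism(hv: TraitHypervolume,
                        predicted: pd.DataFrame) -> RealismReport:
    """Fraction of predicted per-cell trait vectors inside the boundary.

    Rows missing any trait are skipped and counted separately; an empty
    prediction set yields an explicit empty report (fraction None).
    """
    if predicted.empty:
        return RealismReport(fraction_inside=None, n_tested=0, n_skipped=0,
                             outside=predicted.copy())
    complete = predicted.dropna(subset=hv.traits)
    n_skipped = len(predicted) - len(complete)
    if complete.empty:
        return RealismReport(fraction_inside=None, n_tested=0,
                             n_skipped=n_skipped, outside=complete.copy())
    inside = hv.contains(complete)
    return RealismReport(
        fraction_inside=float(inside.mean()),
        n_tested=len(complete),
        n_skipped=n_skipped,
        outside=complete[~inside],
    )


# ---------------------------------------------------------------------------
# trait-correlation preservation

def correlation_preservation(observed: pd.DataFrame,
                             predicted: pd.DataFrame,
                             traits: list[str] | None = None) -> float:
    """Correlation between the off-diagonal entries of the observed and
    predicted trait correlation matrices (pairwise-complete Pearson).

    With four traits this compares the 6 upper-triangle correlations.
    Pairs with fewer than 3 complete observations are dropped with a
    warning; NaN is returned when fewer than 3 usable pairs remain.
    """
    traits = traits or [t for t in TRAITS
                        if t in observed.columns and t in predicted.columns]
    if len(traits) < 3:
        raise ValueError("need at least 3 shared traits")
    c_obs = observed[traits].corr(min_periods=3)
    c_pred = predicted[traits].corr(min_periods=3)
    iu = np.triu_indices(len(traits), k=1)
    a = c_obs.to_numpy()[iu]
    b = c_pred.to_numpy()[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < len(a):
        warnings.warn(
            f"{int((~ok).sum())} trait pair(s) dropped for lack of complete "
            "observations", stacklevel=2,
        )
    a, b = a[ok], b[ok]
    if len(a) < 3:
        warnings.warn("fewer than 3 usable trait pairs; score undefined",
                      stacklevel=2)
        return float("nan")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
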