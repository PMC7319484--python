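"""Observation selection, cleaning, community means and grid linkage.

Observation tables follow the column contract of
:data:`traitscape.synthetic.OBSERVATION_COLUMNS`.  Six selection
criteria are applied in a fixed order; each removed observation is
attributed to the first criterion it definitively fails, and rows whose
relevant metadata flag is missing/unknown (while failing no definite
check) are removed as "uncheckable":

1. georeferenced (valid lon/lat present);
2. direct measurement (no species-level averages);
3. sampled in natural vegetation;
4. study sampled all or the most abundant species of the community;
5. study targeted adults or all life stages;
6. measured from 1980 onwards.

Community means are species-first: within a community (study x site),
values are first averaged within species, then species means are
averaged without abundance weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import PREDICTORS, GridSpec, PredictorStack
from .synthetic import TRAITS

#: coarse physical plausibility bounds per trait (same units as the data)
DEFAULT_TRAIT_BOUNDS: dict[str, tuple[float, float]] = {
    "sla": (0.1, 200.0),       # mm2/mg
    "lnc": (1.0, 100.0),       # mg/g
    "height": (0.01, 150.0),   # m
    "wood_density": (0.05, 1.5),  # mg/mm3
}

CRITERIA = ("c1_georeferenced", "c2_direct_measurement", "c3_natural_vegetation",
            "c4_sampling_strategy", "c5_life_stage", "c6_year")


@dataclass
class FilterReport:
    """Accounting of the six-criterion selection."""

    n_input: int
    removed: dict[str, int]
    uncheckable: int
    retained_per_trait: dict[str, int]

    @property
    def n_retained(self) -> int:
        return sum(self.retained_per_trait.values())

    def check_conservation(self) -> bool:
        return self.n_input == self.n_retained + sum(self.removed.values()) + self.uncheckable

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "uncheckable": self.uncheckable,
            "retained_per_trait": dict(self.retained_per_trait),
        }


def _bool_flag(series: pd.Series) -> pd.Series:
    """Normalize a boolean-ish metadata column; NaN/'unknown' -> <NA>."""
    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return pd.NA
        s = str(v).strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        return pd.NA
    return series.map(conv)


def apply_selection_criteria(
    observations: pd.DataFrame,
    criteria_config: dict | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the six selection criteria; return retained rows and a report."""
    cfg = {"min_year": 1980}
    cfg.update(criteria_config or {})
    obs = observations.reset_index(drop=True)
    n = len(obs)

    lon = pd.to_numeric(obs.get("lon"), errors="coerce")
    lat = pd.to_numeric(obs.get("lat"), errors="coerce")
    year = pd.to_numeric(obs.get("year"), errors="coerce")
    direct = _bool_flag(obs.get("is_direct_measurement", pd.Series(True, index=obs.index)))
    natural = _bool_flag(obs.get("natural_vegetation", pd.Series(pd.NA, index=obs.index)))
    strategy = obs.get("sampling_strategy", pd.Series(pd.NA, index=obs.index)).astype("string").str.lower()
    stage = obs.get("life_stage", pd.Series(pd.NA, index=obs.index)).astype("string").str.lower()

    # definite failures per criterion; a missing/unknown flag is never a
    # definite failure (it makes the row uncheckable instead)
    fails = {
        "c1_georeferenced": (lon.isna() | lat.isna() | (lon < -180) | (lon >= 180)
                             | (lat < -90) | (lat > 90)).astype(bool),
        "c2_direct_measurement": direct.eq(False).fillna(False).astype(bool),
        "c3_natural_vegetation": natural.eq(False).fillna(False).astype(bool),
        "c4_sampling_strategy": strategy.eq("partial").fillna(False).astype(bool),
        "c5_life_stage": stage.eq("juvenile_only").fillna(False).astype(bool),
        "c6_year": (year < cfg["min_year"]).fillna(False).astype(bool),
    }

    unknown_strategy = ~strategy.isin(["all_or_dominant", "partial"])
    unknown_stage = ~stage.isin(["adult_or_all", "juvenile_only"])
    unknown = (
        direct.isna() | natural.isna() | unknown_strategy | unknown_stage | year.isna()
    ).astype(bool)

    reason = pd.Series("", index=obs.index, dtype=object)
    for crit in CRITERIA:
        hit = fails[crit] & reason.eq("")
        reason[hit] = crit
    reason[(reason == "") & unknown] = "uncheckable"

    kept = obs[reason == ""].copy()
    removed_counts = {c: int((reason == c).sum()) for c in CRITERIA}
    report = FilterReport(
        n_input=n,
        removed=removed_counts,
        uncheckable=int((reason == "uncheckable").sum()),
        retained_per_trait={
            t: int((kept["trait"] == t).sum()) for t in sorted(kept["trait"].unique())
        } if "trait" in kept.columns else {},
    )
    if len(kept) == 0:
        warnings.warn("no observations passed the selection criteria", stacklevel=2)
    return kept, report


@dataclass
class OutlierConfig:
    trait_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_BOUNDS))
    k_sd: float = 4.0            # log-scale SD multiple within species
    min_species_records: int = 10


def clean_observations(
    observations: pd.DataFrame,
    outlier_config: OutlierConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop duplicates, invalid coordinates, and outliers.

    Outliers are removed in two passes: values outside coarse global
    plausibility bounds per trait, then values farther than ``k_sd``
    log-scale standard deviations from their species mean (only for
    species x trait groups with at least ``min_species_records`` records).
    Returns (clean table, removal log with a ``reason`` column).
    """
    cfg = outlier_config or OutlierConfig()
    obs = observations.reset_index(drop=True)
    removed = []

    dup_cols = [c for c in ("study_id", "site_id", "species", "trait", "value", "year")
                if c in obs.columns]
    dup = obs.duplicated(subset=dup_cols, keep="first")
    removed.append(obs[dup].assign(reason="duplicate"))
    obs = obs[~dup]

    lon = pd.to_numeric(obs["lon"], errors="coerce")
    lat = pd.to_numeric(obs["lat"], errors="coerce")
    bad_coord = lon.isna() | lat.isna() | (lon < -180) | (lon >= 180) | (lat < -90) | (lat > 90)
    removed.append(obs[bad_coord].assign(reason="invalid_coordinates"))
    obs = obs[~bad_coord]

    value = pd.to_numeric(obs["value"], errors="coerce")
    out_of_bounds = value.isna() | (value <= 0)
    for trait, (lo, hi) in cfg.trait_bounds.items():
        m = obs["trait"].eq(trait)
        out_of_bounds |= m & ((value < lo) | (value > hi))
    removed.append(obs[out_of_bounds].assign(reason="global_bounds"))
    obs = obs[~out_of_bounds]

    logv = np.log(obs["value"].astype(float))
    grp = logv.groupby([obs["species"], obs["trait"]])
    mean = grp.transform("mean")
    sd = grp.transform("std")        # ddof=1
    count = grp.transform("count")
    with np.errstate(invalid="ignore"):
        outlier = (
            (count >= cfg.min_species_records)
            & (sd > 0)
            & ((logv - mean).abs() > cfg.k_sd * sd)
        )
    outlier = outlier.fillna(False)
    removed.append(obs[outlier].assign(reason="species_log_sd"))
    obs = obs[~outlier]

    log = pd.concat(removed, ignore_index=True) if removed else pd.DataFrame()
    return obs.reset_index(drop=True), log


def community_mean(observations: pd.DataFrame) -> pd.DataFrame:
    """Unweighted community means per (study, site, trait).

    Values are first averaged within species, then species means are
    averaged — so a heavily re-measured species does not dominate, and
    abundances (if present) are deliberately ignored.
    """
    required = {"study_id", "site_id", "species", "trait", "value"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations lack required columns: {sorted(missing)}")
    sp = (
        observations.groupby(["study_id", "site_id", "trait", "species"], sort=True)
        .agg(value=("value", "mean"), n_obs=("value", "size"),
             lon=("lon", "first"), lat=("lat", "first"))
        .reset_index()
    )
    cm = (
        sp.groupby(["study_id", "site_id", "trait"], sort=True)
        .agg(value=("value", "mean"), n_species=("species", "nunique"),
             n_observations=("n_obs", "sum"),
             lon=("lon", "first"), lat=("lat", "first"))
        .reset_index()
    )
    return cm[["study_id", "site_id", "lon", "lat", "trait",
               "value", "n_species", "n_observations"]]


def grid_aggregate(
    community_means: pd.DataFrame,
    grid_spec: GridSpec | None = None,
) -> pd.DataFrame:
    """Average community means to grid cells (half-open cell convention)."""
    grid = grid_spec or GridSpec()
    cm = community_means.copy()
    col, row = grid.cell_of(cm["lon"].to_numpy(), cm["lat"].to_numpy())
    cm["col"], cm["row"] = col, row
    agg = (
        cm.groupby(["col", "row", "trait"], sort=True)
        .agg(value=("value", "mean"), n_communities=("value", "size"))
        .reset_index()
    )
    lon, lat = grid.cell_center(agg["col"].to_numpy(), agg["row"].to_numpy())
    agg.insert(2, "lon", lon)
    agg.insert(3, "lat", lat)
    return agg


def link_env(
    records: pd.DataFrame,
    stack: PredictorStack,
    grid_spec: GridSpec | None = None,
) -> tuple[pd.DataFrame, int]:
    """Attach predictor values to grid records; drop incomplete rows.

    Returns (feature table, number of records excluded for missing
    predictor values).  ``grid_spec`` (when given) must match the
    stack's grid — there is no implicit resampling.
    """
    if grid_spec is not None and grid_spec != stack.grid:
        raise ValueError(
            "record grid and predictor stack grid differ; supply resampled layers"
        )
    env = stack.values_at(records["col"].to_numpy(), records["row"].to_numpy())
    env.index = records.index
    features = pd.concat([records.reset_index(drop=True),
                          env.reset_index(drop=True)], axis=1)
    complete = env.notna().all(axis=1).to_numpy()
    n_excluded = int((~complete).sum())
    return features[complete].reset_index(drop=True), n_excluded


DEFAULT_PROTECTED_GROUPS: dict[str, set[str]] = {
    "climate": {"tmin", "humind", "precdryq", "precseas"},
    "soil": {"cec", "ph"},
}

_VIF_CAP = 1e12  # stands in for infinity under perfect collinearity


class UnresolvableCollinearityError(RuntimeError):
    """Raised when collinear predictors cannot be dropped without emptying
    a protected group."""


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) of its least-squares fit on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return float("nan")
    r2 = 1.0 - (resid**2).sum() / tss
    if r2 >= 1.0 - 1.0 / _VIF_CAP:
        return _VIF_CAP
    return 1.0 / (1.0 - r2)


def vif_select(
    features: pd.DataFrame,
    threshold: float = 4.0,
    protected_groups: dict[str, set[str]] | None = None,
    predictors: list[str] | None = None,
) -> tuple[list[str], list[dict]]:
    """Iteratively drop the highest-VIF predictor until all VIFs < threshold.

    The last remaining member of a protected group (by default: climate
    and soil, so both environmental factor families stay represented) is
    never dropped.  Returns the selected predictors and a per-round
    trace of all VIFs and the predictor dropped.
    """
    groups = protected_groups if protected_groups is not None else DEFAULT_PROTECTED_GROUPS
    current = list(predictors) if predictors is not None else [
        p for p in PREDICTORS if p in features.columns]
    if not current:
        current = [c for c in features.columns
                   if pd.api.types.is_numeric_dtype(features[c])]
    if len(current) < 3:
        raise ValueError("need at least 3 candidate predictors")
    if len(features) < 10:
        raise ValueError("need at least 10 rows to estimate VIFs")

    trace: list[dict] = []
    while True:
        X = features[current].to_numpy(dtype=float)
        vifs = {p: _vif_one(X, j) for j, p in enumerate(current)}
        max_vif = max(vifs.values())
        if not (max_vif >= threshold):
            trace.append({"vifs": dict(vifs), "dropped": None})
            break

        def droppable(p: str) -> bool:
            for members in groups.values():
                if p in members and sum(q in members for q in current) <= 1:
                    return False
            return True

        candidates = [p for p in current if droppable(p) and vifs[p] >= threshold]
        if not candidates:
            raise UnresolvableCollinearityError(
                f"max VIF {max_vif:.2f} >= {threshold} but every offending "
                f"predictor is the last member of a protected group: {vifs}"
            )
        drop = max(candidates, key=lambda p: vifs[p])
        trace.append({"vifs": dict(vifs), "dropped": drop})
        current.remove(drop)
        if len(current) < 2:
            break
    return current, trace
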