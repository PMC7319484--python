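"""End-to-end orchestration: simulate -> filter -> aggregate -> fit ->
ensemble -> map -> assess, plus the data-quality sensitivity experiment.

A run is driven by a :class:`RunConfig` (YAML-serializable) and a single
master seed from which every stage seed is derived deterministically.
Each run writes a manifest (config + stage seeds + sha256 of every
output file); re-running with the same config reproduces every hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import learners as lrn
from . import reliability as rel
from . import synthetic as syn
from . import traitdata as td
from .grids import GridSpec, PredictorStack

logger = logging.getLogger("traitscape")

STAGE_NAMES = ("simulate", "filter", "clean", "aggregate", "link", "vif",
               "fit", "predict", "assess", "quality")


def derive_seeds(master_seed: int) -> dict[str, int]:
    """One deterministic sub-seed (< 2^31) per pipeline stage."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGE_NAMES))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(STAGE_NAMES, children)}


@dataclass
class WorldConfig:
    """Synthetic-world parameters (the study conditions of a run)."""

    n_cols: int = 30
    n_rows: int = 30
    cell_size: float = 0.5
    origin_lon: float = -180.0
    origin_lat: float = -90.0
    spatial_correlation_length: float = 2.0
    n_species: int = 400
    n_sites: int = 400
    species_per_site: int = 15
    noise_sd: float = 0.1
    itv_fraction: float = 0.5
    plasticity_scale: float = 1.0
    total_signal_sd: float = 0.5
    trait_correlation: float = 0.0   # off-diagonal of the 4x4 base-trait target

    def grid_spec(self) -> GridSpec:
        return GridSpec(origin_lon=self.origin_lon, origin_lat=self.origin_lat,
                        cell_size=self.cell_size, n_cols=self.n_cols,
                        n_rows=self.n_rows)

    def correlation_target(self) -> np.ndarray:
        k = len(syn.TRAITS)
        m = np.full((k, k), self.trait_correlation)
        np.fill_diagonal(m, 1.0)
        return m


@dataclass
class RunConfig:
    """Full run configuration; serializable to/from YAML."""

    out_dir: str = "run"
    seed: int = 0
    world: WorldConfig = field(default_factory=WorldConfig)
    traits: list[str] = field(default_factory=lambda: list(syn.TRAITS))
    n_repetitions: int = 10
    train_fraction: float = 0.8
    vif_threshold: float = 4.0
    n_permutations: int = 10
    partial_grid_size: int = 50
    hypervolume_looseness: float = 0.05
    learner_params: dict = field(default_factory=dict)
    variants: list[str] = field(
        default_factory=lambda: list(syn.DEGRADATION_VARIANTS))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "world" in d and isinstance(d["world"], dict):
            d["world"] = WorldConfig(**d["world"])
        return cls(**d)

    def to_yaml(self, path, include_out_dir: bool = True) -> None:
        d = self.to_dict()
        if not include_out_dir:
            # a run's config file describes its content, not its location
            d.pop("out_dir", None)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return v
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _setup_logging(out: Path) -> None:
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler)
               and Path(getattr(h, "baseFilename", "")) == out / "run.log"
               for h in logger.handlers):
        fh = logging.FileHandler(out / "run.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s [%(stage)s] %(message)s"))
        logger.addHandler(fh)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


def simulate_world(config: RunConfig):
    """Generate the synthetic world for a run (stack, pool, observations,
    truth) from the config's derived stage seeds."""
    seeds = derive_seeds(config.seed)
    world = config.world
    stack = syn.generate_env_grid(
        world.grid_spec(),
        spatial_correlation_length=world.spatial_correlation_length,
        seed=seeds["simulate"],
    )
    pool = syn.generate_species_pool(
        world.n_species,
        trait_correlation_target=world.correlation_target(),
        plasticity_scale=world.plasticity_scale,
        seed=seeds["simulate"] + 1,
    )
    observations, truth = syn.assemble_communities(
        stack, pool, syn.default_response_specs(),
        n_sites=world.n_sites, species_per_site=world.species_per_site,
        noise_sd=world.noise_sd, seed=seeds["simulate"] + 2,
        itv_fraction=world.itv_fraction, total_signal_sd=world.total_signal_sd,
    )
    return stack, pool, observations, truth


@dataclass
class RunResult:
    config: RunConfig
    out_dir: Path
    filter_report: td.FilterReport
    features: pd.DataFrame
    selected_predictors: list[str]
    ensembles: dict[str, ens.EnsembleModel]
    ensemble_accuracy: dict[str, float]
    mess_result: rel.MESSResult
    realism: rel.RealismReport
    correlation_preservation: float
    manifest: dict


def _fit_trait(config: RunConfig, features: pd.DataFrame, trait: str,
               selected: list[str], seeds: dict[str, int]
               ) -> tuple[dict[str, lrn.FitResult], pd.DataFrame, pd.Series]:
    sub = features[features["trait"] == trait].reset_index(drop=True)
    X = sub[selected]
    y = sub["value"]
    fits = {}
    for i, kind in enumerate(lrn.LEARNER_KINDS):
        spec = lrn.LearnerSpec(kind, params=config.learner_params.get(kind, {}),
                               seed=seeds["fit"] + i)
        fits[kind] = lrn.cross_validate(
            spec, X, y, n_repetitions=config.n_repetitions,
            train_fraction=config.train_fraction, seed=seeds["fit"],
        )
    return fits, X, y


def run_full_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write all tables, maps, reports and the
    manifest into ``config.out_dir``.  A stage failure halts the run with
    a stage-named error; outputs of earlier stages are preserved."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    seeds = derive_seeds(config.seed)
    config.to_yaml(out / "config.yaml", include_out_dir=False)
    outputs: list[Path] = [out / "config.yaml"]

    stage = "simulate"
    try:
        stack, pool, observations, truth = simulate_world(config)
        observations.to_csv(out / "observations.csv", index=False)
        stack.write_csv(out / "predictors.csv")
        _write_json(out / "truth.json", truth.to_json_dict())
        outputs += [out / "observations.csv", out / "predictors.csv",
                    out / "predictors.gridspec.json", out / "truth.json"]
        _log(stage, f"{len(observations)} observations at "
                    f"{observations['site_id'].nunique()} sites")

        stage = "filter"
        kept, report = td.apply_selection_criteria(observations)
        _write_json(out / "filter_report.json", report.to_dict())
        outputs.append(out / "filter_report.json")
        _log(stage, f"retained {report.n_retained}/{report.n_input}")

        stage = "clean"
        clean, removal_log = td.clean_observations(kept)
        _log(stage, f"removed {len(removal_log)} rows in cleaning")

        stage = "aggregate"
        cm = td.community_mean(clean)
        cm.to_csv(out / "community_means.csv", index=False)
        records = td.grid_aggregate(cm, stack.grid)
        records.to_csv(out / "grid_records.csv", index=False)
        outputs += [out / "community_means.csv", out / "grid_records.csv"]
        _log(stage, f"{len(cm)} community means -> {len(records)} cell records")

        stage = "link"
        features, n_excluded = td.link_env(records, stack)
        features.to_csv(out / "features.csv", index=False)
        outputs.append(out / "features.csv")
        _log(stage, f"{len(features)} usable records, {n_excluded} excluded")

        stage = "vif"
        selected, trace = td.vif_select(
            features.drop_duplicates(subset=["col", "row"]),
            threshold=config.vif_threshold,
        )
        _write_json(out / "vif_trace.json", {"selected": selected, "trace": trace})
        outputs.append(out / "vif_trace.json")
        _log(stage, f"selected predictors: {selected}")

        stage = "fit"
        ensembles: dict[str, ens.EnsembleModel] = {}
        accuracy: dict[str, float] = {}
        fit_summaries = {}
        trait_features: dict[str, pd.DataFrame] = {}
        for trait in config.traits:
            if not (features["trait"] == trait).any():
                _log(stage, f"trait {trait!r} absent from data; skipped")
                continue
            fits, X, y = _fit_trait(config, features, trait, selected, seeds)
            model = ens.build_ensemble(trait, fits)
            ensembles[trait] = model
            accuracy[trait] = ens.ensemble_accuracy(model)
            trait_features[trait] = X
            fit_summaries[trait] = {
                "weights": model.weights,
                "pseudo_r2": {k: f.pseudo_r2 for k, f in fits.items()},
                "flagged": {k: f.flagged for k, f in fits.items()},
                "ensemble_accuracy": accuracy[trait],
                "n_cells": int(len(X)),
            }
            _log(stage, f"{trait}: r2={fit_summaries[trait]['pseudo_r2']}, "
                        f"ensemble={accuracy[trait]:.3f}")
        _write_json(out / "fits.json", fit_summaries)
        outputs.append(out / "fits.json")

        stage = "predict"
        pred_wide = {}
        for trait, model in ensembles.items():
            pred_map, cv_map = ens.predict_maps(model, stack, selected)
            frame = stack.to_frame()
            frame["prediction"] = pred_map[frame["row"], frame["col"]]
            frame["cv"] = cv_map[frame["row"], frame["col"]]
            keep = frame[["col", "row", "lon", "lat", "prediction", "cv"]]
            keep.to_csv(out / f"map_{trait}.csv", index=False)
            outputs.append(out / f"map_{trait}.csv")
            pred_wide[trait] = frame.set_index(["col", "row"])["prediction"]

            importances = {
                kind: ens.permutation_importance(
                    model.fits[kind], trait_features[trait],
                    n_permutations=config.n_permutations,
                    seed=seeds["predict"],
                )
                for kind, w in model.weights.items() if w > 0
            }
            imp = ens.ensemble_importance(importances, model.weights)
            imp.to_csv(out / f"importance_{trait}.csv")
            outputs.append(out / f"importance_{trait}.csv")

            curves = []
            for pred_name in selected:
                pr = ens.partial_response(model, trait_features[trait],
                                          pred_name,
                                          grid_size=config.partial_grid_size)
                curves.append(pr.table.assign(predictor=pred_name))
            pd.concat(curves, ignore_index=True).to_csv(
                out / f"partial_{trait}.csv", index=False)
            outputs.append(out / f"partial_{trait}.csv")
        _log(stage, f"maps and responses written for {sorted(ensembles)}")

        stage = "assess"
        reference = features.drop_duplicates(subset=["col", "row"])[selected]
        target = stack.to_frame().dropna(subset=selected)
        mess_res = rel.mess(reference, target[selected])
        mess_table = target[["col", "row", "lon", "lat"]].reset_index(drop=True)
        mess_table = pd.concat([mess_table, mess_res.table], axis=1)
        mess_table.to_csv(out / "mess.csv", index=False)
        outputs.append(out / "mess.csv")

        combos = rel.trait_combinations(clean)
        modelled = [t for t in syn.TRAITS if t in ensembles]
        hv = rel.fit_trait_hypervolume(combos, traits=modelled,
                                       looseness=config.hypervolume_looseness)
        predicted = pd.DataFrame(pred_wide).reset_index()
        realism = rel.combination_realism(hv, predicted)

        observed_cells = (
            features.pivot_table(index=["col", "row"], columns="trait",
                                 values="value").reset_index()
        )
        if len(modelled) >= 3:
            corr_score = rel.correlation_preservation(observed_cells, predicted,
                                                      traits=modelled)
        else:
            corr_score = float("nan")
            _log(stage, "fewer than 3 modelled traits; correlation "
                        "preservation undefined")
        _write_json(out / "reliability.json", {
            "mess_negative_fraction": float((mess_res.similarity < 0).mean()),
            "realism": realism.to_dict(),
            "hypervolume": {"nu": hv.nu, "gamma": hv.gamma,
                            "training_inclusion": hv.training_inclusion},
            "correlation_preservation": corr_score,
        })
        outputs.append(out / "reliability.json")
        _log(stage, f"realism={realism.fraction_inside}, corr={corr_score:.3f}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # out_dir is the run's location, not its content: leaving it out makes
    # manifests of identical-seed runs byte-identical wherever they live
    manifest_config = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    manifest = {
        "config": manifest_config,
        "seeds": seeds,
        "files": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    _write_json(out / "manifest.json", manifest)
    return RunResult(
        config=config, out_dir=out, filter_report=report, features=features,
        selected_predictors=selected, ensembles=ensembles,
        ensemble_accuracy=accuracy, mess_result=mess_res, realism=realism,
        correlation_preservation=corr_score, manifest=manifest,
    )


# ---------------------------------------------------------------------------
# data-quality sensitivity experiment

@dataclass
class QualityExperimentResult:
    """Per trait x variant learner scores and percent changes vs default."""

    scores: pd.DataFrame       # trait, variant, learner, pseudo_r2
    summary: pd.DataFrame      # trait, variant, mean/min/max, pct_change
    overall_pct_change: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "summary": self.summary.to_dict(orient="records"),
            "overall_pct_change": dict(self.overall_pct_change),
        }


def _features_from_observations(observations: pd.DataFrame,
                                stack: PredictorStack) -> pd.DataFrame:
    kept, _ = td.apply_selection_criteria(observations)
    clean, _ = td.clean_observations(kept)
    cm = td.community_mean(clean)
    records = td.grid_aggregate(cm, stack.grid)
    features, _ = td.link_env(records, stack)
    return features


def run_quality_experiment(
    config: RunConfig,
    variants: list[str] | None = None,
    world=None,
) -> QualityExperimentResult:
    """Refit all learners on degraded data and evaluate against the
    default dataset's observed community means.

    Every variant consumes identical CV split seeds and learner seeds,
    so any performance difference is attributable to the data variant
    alone.  Held-out predictions of models fitted on degraded targets
    are scored against the *default* targets of the same grid cells.
    """
    variants = variants or config.variants
    unknown = set(variants) - set(syn.DEGRADATION_VARIANTS)
    if unknown:
        raise ValueError(f"unknown variants: {sorted(unknown)}")
    seeds = derive_seeds(config.seed)
    if world is None:
        stack, pool, observations, truth = simulate_world(config)
    else:
        stack, pool, observations, truth = world

    default_features = _features_from_observations(observations, stack)
    selected, _ = td.vif_select(
        default_features.drop_duplicates(subset=["col", "row"]),
        threshold=config.vif_threshold,
    )

    rows = []
    for variant in variants:
        degraded = syn.degrade_dataset(observations, variant,
                                       seed=seeds["quality"])
        feats = _features_from_observations(degraded, stack)
        for trait in config.traits:
            deg = feats[feats["trait"] == trait][["col", "row", "value"] + selected]
            ref = default_features[default_features["trait"] == trait][
                ["col", "row", "value"]].rename(columns={"value": "observed"})
            merged = deg.merge(ref, on=["col", "row"], how="inner")
            merged = merged.sort_values(["col", "row"]).reset_index(drop=True)
            if len(merged) < 25:
                rows.append({"trait": trait, "variant": variant,
                             "learner": None, "pseudo_r2": np.nan,
                             "status": "insufficient", "n_cells": len(merged)})
                continue
            X = merged[selected]
            y_train = merged["value"].to_numpy()
            y_eval = merged["observed"].to_numpy()
            splits = lrn.split_indices(len(merged), config.n_repetitions,
                                       config.train_fraction, seeds["fit"])
            for i, kind in enumerate(lrn.LEARNER_KINDS):
                spec = lrn.LearnerSpec(
                    kind, params=config.learner_params.get(kind, {}),
                    seed=seeds["fit"] + i)
                preds, obs = [], []
                try:
                    for tr, te in splits:
                        fit = lrn.fit_learner(spec, X.iloc[tr], y_train[tr])
                        preds.extend(fit.predict(X.iloc[te]))
                        obs.extend(y_eval[te])
                    score = lrn.pseudo_r2(np.asarray(preds), np.asarray(obs))
                    status = "ok"
                except lrn.ConvergenceFailure:
                    score, status = 0.0, "flagged"
                rows.append({"trait": trait, "variant": variant,
                             "learner": kind, "pseudo_r2": score,
                             "status": status, "n_cells": len(merged)})

    scores = pd.DataFrame(rows)
    ok = scores[scores["learner"].notna()]
    summary = (
        ok.groupby(["trait", "variant"])["pseudo_r2"]
        .agg(["mean", "min", "max"]).reset_index()
    )
    default_mean = summary[summary["variant"] == "default"].set_index("trait")["mean"]
    summary["pct_change"] = [
        100.0 * (row["mean"] - default_mean[row["trait"]]) / default_mean[row["trait"]]
        if row["trait"] in default_mean.index and default_mean[row["trait"]] != 0
        else np.nan
        for _, row in summary.iterrows()
    ]
    overall = {
        v: float(summary.loc[summary["variant"] == v, "pct_change"].mean())
        for v in variants
    }
    return QualityExperimentResult(scores=scores, summary=summary,
                                   overall_pct_change=overall)
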