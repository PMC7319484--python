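"""Synthetic world generator: environments, species pools, communities.

This module builds a fully known ground truth against which every
downstream stage of the pipeline can be tested: spatially autocorrelated
environmental layers, a species pool with correlated base traits and
environmental niches, community assembly by Gaussian niche filtering, and
observation-level trait values whose community-mean response to each
predictor follows a configurable shape (increase / decrease / flat /
unimodal) at a configurable effect size.

Trait values are generated on the log scale::

    log v(s, i, t) = log base(s, t)
                   + sum_j A_tj * [ sqrt(1-phi) * g_tj(u_sj)      (turnover)
                                  + sqrt(phi)   * g_tj(z_ij) ]    (plastic)
                   + sum_j  b_stj * (z_ij - 0.5)                  (idiosyncratic)
                   + eps,   eps ~ N(0, noise_sd^2)

where ``z_ij`` is the site's predictor value scaled to [0, 1], ``u_sj``
the species' niche optimum on the same scale, ``g_tj`` a zero-mean
unit-variance shape function, ``A_tj = sqrt(effect) * total_signal_sd``
and ``phi`` the intraspecific (plastic) share of the signal.  The
turnover channel survives species-mean substitution ("no_itv"); the
plastic channel does not — which is what makes the data-quality
experiment meaningful.

All operations are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import PREDICTOR_RANGES, PREDICTORS, GridSpec, PredictorStack

TRAITS: tuple[str, ...] = ("sla", "lnc", "height", "wood_density")

TRAIT_UNITS: dict[str, str] = {
    "sla": "mm2/mg",
    "lnc": "mg/g",
    "height": "m",
    "wood_density": "mg/mm3",
}

#: geometric-mean base trait values of the species pool
DEFAULT_BASE_MEANS: dict[str, float] = {
    "sla": 15.0,
    "lnc": 20.0,
    "height": 2.0,
    "wood_density": 0.6,
}

SHAPES = ("increase", "decrease", "flat", "unimodal")

OBSERVATION_COLUMNS = [
    "study_id", "site_id", "lon", "lat", "species", "trait", "value", "unit",
    "year", "is_direct_measurement", "sampling_strategy", "life_stage",
    "natural_vegetation", "abundance",
]

DEGRADATION_VARIANTS = ("default", "no_itv", "random_species", "no_itv_random_species")


# ---------------------------------------------------------------------------
# response specifications

@dataclass(frozen=True)
class ShapeSpec:
    """One trait-predictor response: shape code, effect size, bump geometry.

    ``effect`` is the fraction of the total log-trait signal variance
    attributed to this predictor.  ``optimum``/``width`` only matter for
    unimodal shapes and live on the scaled [0, 1] predictor axis.
    """

    shape: str
    effect: float
    optimum: float = 0.5
    width: float = 0.18

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError(f"effect must be in [0, 1], got {self.effect}")

    def g(self, z: np.ndarray) -> np.ndarray:
        """Shape function, standardized to mean 0 / var 1 under z ~ U(0, 1)."""
        z = np.asarray(z, dtype=float)
        if self.shape == "flat":
            return np.zeros_like(z)
        if self.shape == "increase":
            return (z - 0.5) * np.sqrt(12.0)
        if self.shape == "decrease":
            return -(z - 0.5) * np.sqrt(12.0)
        # unimodal Gaussian bump, standardized numerically
        zz = np.linspace(0.0, 1.0, 2001)
        b = np.exp(-((zz - self.optimum) ** 2) / (2.0 * self.width**2))
        mu = np.trapezoid(b, zz)
        sd = np.sqrt(np.trapezoid((b - mu) ** 2, zz))
        return (np.exp(-((z - self.optimum) ** 2) / (2.0 * self.width**2)) - mu) / sd


@dataclass(frozen=True)
class ResponseSpec:
    """Per-trait map of predictor -> ShapeSpec; effects must sum to <= 1."""

    trait: str
    shapes: dict[str, ShapeSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.shapes) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors in ResponseSpec: {sorted(unknown)}")
        total = sum(s.effect for s in self.shapes.values())
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"effect sizes for trait {self.trait!r} sum to {total:.3f} > 1"
            )

    def effect(self, predictor: str) -> float:
        s = self.shapes.get(predictor)
        return 0.0 if s is None else s.effect


def default_response_specs() -> dict[str, ResponseSpec]:
    """Trait-environment response shapes emulating community-level
    expectations for the four traits (leaf economics responding to cold
    and moisture, height to dry-season water, wood density to
    temperature and humidity)."""
    return {
        "sla": ResponseSpec("sla", {
            "tmin": ShapeSpec("unimodal", 0.30, optimum=0.6, width=0.2),
            "humind": ShapeSpec("increase", 0.30),
            "precseas": ShapeSpec("flat", 0.0),
            "ph": ShapeSpec("increase", 0.10),
        }),
        "lnc": ResponseSpec("lnc", {
            "tmin": ShapeSpec("decrease", 0.30),
            "humind": ShapeSpec("increase", 0.30),
            "precseas": ShapeSpec("flat", 0.0),
            "cec": ShapeSpec("flat", 0.0),
        }),
        "height": ResponseSpec("height", {
            "tmin": ShapeSpec("increase", 0.25),
            "humind": ShapeSpec("increase", 0.15),
            "precdryq": ShapeSpec("increase", 0.35),
        }),
        "wood_density": ResponseSpec("wood_density", {
            "tmin": ShapeSpec("increase", 0.30),
            "humind": ShapeSpec("decrease", 0.30),
            "precseas": ShapeSpec("decrease", 0.15),
        }),
    }


# ---------------------------------------------------------------------------
# environment grids

def generate_env_grid(
    grid_spec: GridSpec,
    spatial_correlation_length: float = 2.0,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
    layer_correlations: dict[tuple[str, str], float] | None = None,
    invalid_fraction: float = 0.0,
) -> PredictorStack:
    """Six spatially autocorrelated predictor layers on a shared grid.

    Each layer is Gaussian-smoothed white noise (kernel sigma equal to
    the correlation length, in degrees) rescaled into its physical
    range.  The six fields are orthogonalized before rescaling, so
    pairwise correlations among layers are ~0 unless explicitly induced
    through ``layer_correlations`` (mapping ``(a, b) -> r``, which mixes
    layer *b* towards layer *a*).
    """
    if grid_spec.n_cols < 2 or grid_spec.n_rows < 2:
        raise ValueError(
            f"grid must be at least 2x2, got n_cols={grid_spec.n_cols}, "
            f"n_rows={grid_spec.n_rows}"
        )
    if spatial_correlation_length <= 0:
        raise ValueError("spatial_correlation_length must be positive")
    ranges = dict(PREDICTOR_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    shape = (grid_spec.n_rows, grid_spec.n_cols)
    sigma_cells = spatial_correlation_length / grid_spec.cell_size

    fields = np.empty((grid_spec.n_cells, len(PREDICTORS)))
    for k in range(len(PREDICTORS)):
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
        fields[:, k] = smooth.ravel()

    # orthogonalize the (centered) fields so layer correlations start at ~0;
    # linear combinations of smooth fields stay smooth
    centered = fields - fields.mean(axis=0)
    q, r = np.linalg.qr(centered)
    # fix sign for reproducibility across BLAS implementations
    q = q * np.sign(np.diag(r))
    std = {name: q[:, k] / q[:, k].std() for k, name in enumerate(PREDICTORS)}

    for (a, b), rho in (layer_correlations or {}).items():
        if not -1.0 < rho < 1.0:
            raise ValueError(f"layer correlation for ({a}, {b}) must be in (-1, 1)")
        std[b] = rho * std[a] + np.sqrt(1.0 - rho**2) * std[b]

    layers = {}
    for name in PREDICTORS:
        lo, hi = ranges[name]
        f = std[name]
        f = (f - f.min()) / (f.max() - f.min())
        layers[name] = (lo + f * (hi - lo)).reshape(shape)

    mask = np.ones(shape, dtype=bool)
    if invalid_fraction > 0:
        n_bad = int(round(invalid_fraction * grid_spec.n_cells))
        bad = rng.choice(grid_spec.n_cells, size=n_bad, replace=False)
        mask.ravel()[bad] = False

    return PredictorStack(grid=grid_spec, layers=layers, mask=mask)


def scale_to_unit(values: np.ndarray, predictor: str,
                  ranges: dict[str, tuple[float, float]] | None = None) -> np.ndarray:
    """Map predictor values onto [0, 1] using the configured physical range."""
    lo, hi = (ranges or PREDICTOR_RANGES)[predictor]
    return (np.asarray(values, dtype=float) - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# species pools

@dataclass
class SpeciesPool:
    """Species pool: base traits, niche optima/breadths, plasticity slopes.

    ``optima`` and ``breadth`` live on the scaled [0, 1] predictor axes;
    ``plasticity`` has shape (n_species, n_traits, n_predictors) in log-trait
    units per unit of scaled predictor.
    """

    species: np.ndarray            # (n,) species ids
    base_traits: pd.DataFrame      # (n, 4), columns TRAITS, positive
    optima: np.ndarray             # (n, 6)
    breadth: np.ndarray            # (n, 6)
    plasticity: np.ndarray         # (n, 4, 6)
    plasticity_scale: float
    seed: int

    @property
    def n_species(self) -> int:
        return len(self.species)


def generate_species_pool(
    n_species: int,
    trait_correlation_target: np.ndarray | None = None,
    plasticity_scale: float = 1.0,
    seed: int = 0,
    base_means: dict[str, float] | None = None,
    base_log_sd: float = 0.3,
    plasticity_slope_sd: float = 0.05,
    breadth_range: tuple[float, float] = (0.25, 0.5),
) -> SpeciesPool:
    """Draw a species pool with lognormal base traits at a target
    among-species log-trait correlation structure."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    k = len(TRAITS)
    if trait_correlation_target is None:
        trait_correlation_target = np.eye(k)
    corr = np.asarray(trait_correlation_target, dtype=float)
    if corr.shape != (k, k) or not np.allclose(corr, corr.T):
        raise ValueError(f"trait correlation target must be symmetric {k}x{k}")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("trait correlation target must have unit diagonal")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("trait correlation target is not positive definite") from exc

    means = dict(DEFAULT_BASE_MEANS, **(base_means or {}))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_species, k)) @ chol.T
    log_base = np.log([means[t] for t in TRAITS]) + base_log_sd * z
    base = pd.DataFrame(np.exp(log_base), columns=list(TRAITS))

    optima = rng.uniform(0.0, 1.0, size=(n_species, len(PREDICTORS)))
    breadth = rng.uniform(*breadth_range, size=(n_species, len(PREDICTORS)))
    plasticity = plasticity_scale * plasticity_slope_sd * rng.standard_normal(
        (n_species, k, len(PREDICTORS))
    )
    species = np.array([f"sp{i:05d}" for i in range(n_species)])
    return SpeciesPool(
        species=species, base_traits=base, optima=optima, breadth=breadth,
        plasticity=plasticity, plasticity_scale=plasticity_scale, seed=seed,
    )


# ---------------------------------------------------------------------------
# community assembly

@dataclass
class SyntheticTruth:
    """Ground-truth record of one assembled world.

    ``site_truth`` holds, per site and trait, the expected (noise-free)
    community mean; ``curves`` the injected single-predictor response
    curves (multiplicative modifier vs scaled predictor) on a reference
    grid.  Regenerating with the recorded seeds reproduces the
    observation table bit-identically.
    """

    specs: dict[str, ResponseSpec]
    site_truth: pd.DataFrame          # site_id, col, row, z_<pred>..., true_<trait>...
    curves: pd.DataFrame              # trait, predictor, z, modifier
    seed: int
    itv_fraction: float
    noise_sd: float

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "itv_fraction": self.itv_fraction,
            "noise_sd": self.noise_sd,
            "specs": {
                t: {p: vars(s) for p, s in spec.shapes.items()}
                for t, spec in self.specs.items()
            },
        }


def assemble_communities(
    stack: PredictorStack,
    pool: SpeciesPool,
    specs: dict[str, ResponseSpec],
    n_sites: int = 400,
    species_per_site: int = 15,
    noise_sd: float = 0.1,
    seed: int = 0,
    itv_fraction: float = 0.5,
    total_signal_sd: float = 0.5,
    sites_per_study: int = 20,
    year_range: tuple[int, int] = (1990, 2015),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Assemble communities by niche filtering and emit trait observations.

    Sites are placed at distinct random valid cells; community membership
    is sampled with probability proportional to each species' Gaussian
    niche weight around its optima; every member yields one observation
    per trait (see module docstring for the value model).  Observations
    carry full study metadata satisfying the six selection criteria.
    """
    if pool.n_species == 0:
        raise ValueError("species pool is empty")
    valid = np.flatnonzero(stack.mask.ravel())
    if valid.size == 0:
        raise ValueError("predictor stack has no valid cells")
    if n_sites > valid.size:
        raise ValueError(
            f"n_sites={n_sites} exceeds the {valid.size} valid cells"
        )
    if species_per_site < 1:
        raise ValueError("species_per_site must be >= 1")
    if not 0.0 <= itv_fraction <= 1.0:
        raise ValueError("itv_fraction must be in [0, 1]")
    for trait in TRAITS:
        if trait not in specs:
            raise ValueError(f"missing ResponseSpec for trait {trait!r}")

    # plasticity_scale == 0 disables every intraspecific channel: all of the
    # injected signal flows through species turnover
    phi = itv_fraction if pool.plasticity_scale > 0 else 0.0

    rng = np.random.default_rng(seed)
    cells = rng.choice(valid, size=n_sites, replace=False)
    rows_idx, cols_idx = np.unravel_index(cells, stack.mask.shape)
    env = stack.values_at(cols_idx, rows_idx)   # (n_sites, 6)
    z = np.column_stack([scale_to_unit(env[p].to_numpy(), p) for p in PREDICTORS])
    z = np.clip(z, 0.0, 1.0)

    # site coordinates jittered inside the cell
    lon0, lat0 = stack.grid.cell_center(cols_idx, rows_idx)
    jitter = rng.uniform(-0.5, 0.5, size=(n_sites, 2)) * stack.grid.cell_size
    lon = lon0 + jitter[:, 0] * 0.98
    lat = lat0 + jitter[:, 1] * 0.98

    # signal amplitudes A_tj and per-species turnover offsets
    amp = np.zeros((len(TRAITS), len(PREDICTORS)))
    gfun: dict[tuple[int, int], ShapeSpec] = {}
    for ti, trait in enumerate(TRAITS):
        for pj, pred in enumerate(PREDICTORS):
            sh = specs[trait].shapes.get(pred)
            if sh is not None and sh.effect > 0 and sh.shape != "flat":
                amp[ti, pj] = np.sqrt(sh.effect) * total_signal_sd
                gfun[(ti, pj)] = sh

    turnover = np.zeros((pool.n_species, len(TRAITS)))
    for (ti, pj), sh in gfun.items():
        turnover[:, ti] += np.sqrt(1.0 - phi) * amp[ti, pj] * sh.g(pool.optima[:, pj])

    log_base = np.log(pool.base_traits.to_numpy())  # (n_species, 4)
    years = rng.integers(year_range[0], year_range[1] + 1, size=n_sites)

    records: dict[str, list] = {c: [] for c in OBSERVATION_COLUMNS}
    n_traits = len(TRAITS)
    site_true = np.zeros((n_sites, n_traits))
    for i in range(n_sites):
        # Gaussian niche weights in scaled predictor space
        d2 = ((z[i][None, :] - pool.optima) / pool.breadth) ** 2
        w = np.exp(-0.5 * d2.sum(axis=1))
        w_sum = w.sum()
        if w_sum <= 0 or np.count_nonzero(w) < species_per_site:
            w = w + 1e-12
        members = rng.choice(
            pool.n_species, size=min(species_per_site, pool.n_species),
            replace=False, p=w / w.sum(),
        )
        s = len(members)

        plastic_site = np.zeros(n_traits)
        for (ti, pj), sh in gfun.items():
            plastic_site[ti] += np.sqrt(phi) * amp[ti, pj] * sh.g(z[i, pj])
        idio = pool.plasticity[members] @ (z[i] - 0.5)      # (s, 4)
        log_det = log_base[members] + turnover[members] + plastic_site + idio
        site_true[i] = np.exp(log_det).mean(axis=0)

        eps = rng.standard_normal((s, n_traits)) * noise_sd
        values = np.exp(log_det + eps)

        # geometric rank abundances by niche weight (available, unused by
        # the default unweighted aggregation)
        order = np.argsort(-w[members], kind="stable")
        ab = np.empty(s)
        ab[order] = 0.5 ** np.arange(s)
        ab /= ab.sum()

        site_id = f"site{i:05d}"
        study_id = f"study{i // sites_per_study:03d}"
        for ti, trait in enumerate(TRAITS):
            records["study_id"].extend([study_id] * s)
            records["site_id"].extend([site_id] * s)
            records["lon"].extend([lon[i]] * s)
            records["lat"].extend([lat[i]] * s)
            records["species"].extend(pool.species[members])
            records["trait"].extend([trait] * s)
            records["value"].extend(values[:, ti])
            records["unit"].extend([TRAIT_UNITS[trait]] * s)
            records["year"].extend([int(years[i])] * s)
            records["is_direct_measurement"].extend([True] * s)
            records["sampling_strategy"].extend(["all_or_dominant"] * s)
            records["life_stage"].extend(["adult_or_all"] * s)
            records["natural_vegetation"].extend([True] * s)
            records["abundance"].extend(ab)

    observations = pd.DataFrame(records)

    site_truth = pd.DataFrame({
        "site_id": [f"site{i:05d}" for i in range(n_sites)],
        "col": cols_idx, "row": rows_idx, "lon": lon, "lat": lat,
    })
    for pj, pred in enumerate(PREDICTORS):
        site_truth[f"z_{pred}"] = z[:, pj]
        site_truth[pred] = env[pred].to_numpy()
    for ti, trait in enumerate(TRAITS):
        site_truth[f"true_{trait}"] = site_true[:, ti]

    zz = np.linspace(0.0, 1.0, 101)
    curve_rows = []
    for ti, trait in enumerate(TRAITS):
        for pj, pred in enumerate(PREDICTORS):
            sh = gfun.get((ti, pj))
            mod = np.exp(amp[ti, pj] * sh.g(zz)) if sh is not None else np.ones_like(zz)
            curve_rows.append(pd.DataFrame({
                "trait": trait, "predictor": pred, "z": zz, "modifier": mod,
            }))
    truth = SyntheticTruth(
        specs=specs,
        site_truth=site_truth,
        curves=pd.concat(curve_rows, ignore_index=True),
        seed=seed,
        itv_fraction=phi,
        noise_sd=noise_sd,
    )
    return observations, truth


# ---------------------------------------------------------------------------
# data-quality degradation

def degrade_dataset(
    observations: pd.DataFrame,
    variant: str = "default",
    seed: int = 0,
) -> pd.DataFrame:
    """Produce a degraded copy of the observation table.

    ``no_itv``
        every value is replaced by the global mean of that species x trait
        over the whole (pre-degradation) dataset — the species-average
        surrogate for local measurements;
    ``random_species``
        within each community only one uniformly chosen species is kept
        (an unrepresentative species sample);
    ``no_itv_random_species``
        both, with species means computed on the full input.
    """
    if variant not in DEGRADATION_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {DEGRADATION_VARIANTS}"
        )
    obs = observations.copy()
    if variant == "default":
        return obs
    for col in ("species", "study_id", "site_id"):
        if col not in obs.columns:
            raise ValueError(f"observations lack required column {col!r}")

    if variant in ("random_species", "no_itv_random_species"):
        rng = np.random.default_rng(seed)
        keep_parts = []
        for (_study, _site), grp in obs.groupby(["study_id", "site_id"], sort=True):
            sp = np.sort(grp["species"].unique())
            chosen = sp[rng.integers(len(sp))]
            keep_parts.append(grp[grp["species"] == chosen])
        out = pd.concat(keep_parts).sort_index()
    else:
        out = obs

    if variant in ("no_itv", "no_itv_random_species"):
        species_means = observations.groupby(["species", "trait"])["value"].mean()
        key = pd.MultiIndex.from_frame(out[["species", "trait"]])
        out = out.assign(value=species_means.loc[key].to_numpy())
    return out
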