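"""Synthetic dominant-marker datasets and environmental surfaces.

Population structure follows the Balding-Nichols model: each locus has an
ancestral dominant-allele frequency q̄ drawn from a configurable law, each
population draws its allele frequency from

    q_p ~ Beta(q̄ (1 - F_p) / F_p, (1 - q̄)(1 - F_p) / F_p)

with a single interpretable drift parameter F_p per population (founder
effects are emulated by large F). Individuals carry two allele copies and a
band is present iff at least one copy is the dominant allele, so presence
probability is 1 - (1 - q_p)^2 — genuine dominance masking.

Environmental surfaces are Gaussian random fields with exponential covariance
C(d) = variance * exp(-d / range), sampled by Cholesky factorisation of the
site covariance. Because diversity under this model has a closed-form
expectation in F (Beta moments), a linear dependence of diversity on one
environmental variable can be injected exactly by inverting that expectation.

Everything is reproducible under a fixed ``numpy`` Generator seed, and every
generated dataset passes marker-matrix validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .env_grid import ENV_VARIABLES, RasterGrid
from .errors import AchievableRangeError
from .marker_data import MarkerMatrix
from .spatial import euclidean_matrix, haversine_matrix

_F_BOUNDS = (0.01, 0.95)


@dataclass
class EnvFieldConfig:
    """Spatially autocorrelated surface parameters (degrees / field units)."""

    range_deg: float = 1.0
    variance: float = 1.0
    grid_shape: tuple[int, int] = (30, 30)       # (rows, cols)
    extent: tuple[float, float, float, float] = (5.0, 15.0, 43.0, 48.0)
    # (lon_min, lon_max, lat_min, lat_max)


@dataclass
class EffectConfig:
    """Injected linear dependence of diversity on one predictor."""

    predictor: str = "pcurv"
    beta: float = 0.0            # change in expected H_S per predictor unit
    sigma: float = 0.0           # extra (non-sampling) residual sd of H_S
    alpha: float | None = None   # baseline H_S; default = achievable midpoint


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_species: int = 1
    populations_per_species: int = 25
    individuals_per_population: int = 10
    n_loci: int = 200
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)
    drift: float = 0.2           # default F when no effect is injected
    env_field: EnvFieldConfig = field(default_factory=EnvFieldConfig)
    effect: EffectConfig | None = None

    def __post_init__(self) -> None:
        for name in ("n_species", "populations_per_species",
                     "individuals_per_population", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.drift < 1.0:
            raise ValueError("drift F must be in (0, 1)")
        if self.effect is not None and self.effect.sigma < 0:
            raise ValueError("effect sigma must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded for every generated dataset."""

    f_values: dict[str, dict[str, float]]          # species -> pop -> F
    site_env: dict[str, dict[str, float]]          # species -> pop -> target env
    beta: float | None
    alpha: float | None
    ancestral_freqs: dict[str, list[float]]        # species -> per-locus q̄

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Gaussian random fields

def _chol_with_jitter(cov: np.ndarray) -> np.ndarray:
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance not positive definite after jitter")


def grf_at_points(
    coords: np.ndarray,
    range_: float,
    variance: float,
    rng: np.random.Generator,
    metric: str = "euclidean",
) -> np.ndarray:
    """Draw one realisation of the exponential-covariance field at points."""
    coords = np.asarray(coords, dtype=float)
    d = haversine_matrix(coords) if metric == "haversine" else euclidean_matrix(coords)
    if range_ <= 0:
        cov = variance * np.eye(len(coords))
    else:
        cov = variance * np.exp(-d / range_)
    return _chol_with_jitter(cov) @ rng.standard_normal(len(coords))


def gen_sites(
    n_sites: int,
    extent: tuple[float, float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform random (lon, lat) sites within the extent."""
    lon_min, lon_max, lat_min, lat_max = extent
    lon = rng.uniform(lon_min, lon_max, n_sites)
    lat = rng.uniform(lat_min, lat_max, n_sites)
    return np.column_stack([lon, lat])


def gen_env_surface(
    field_cfg: EnvFieldConfig,
    rng: np.random.Generator,
    sites: np.ndarray | None = None,
    name: str = "env",
) -> tuple[RasterGrid, np.ndarray | None]:
    """Gaussian random field on a grid, plus its values at optional sites.

    The field is sampled jointly at all cell centers via Cholesky of the cell
    covariance, so site values (taken from the containing cell) share the
    exact spatial structure of the written grid.
    """
    n_rows, n_cols = field_cfg.grid_shape
    lon_min, lon_max, lat_min, lat_max = field_cfg.extent
    csx = (lon_max - lon_min) / n_cols
    csy = (lat_max - lat_min) / n_rows
    cell = min(csx, csy)
    xs = lon_min + (np.arange(n_cols) + 0.5) * cell
    ys = lat_max - (np.arange(n_rows) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    vals = grf_at_points(centers, field_cfg.range_deg, field_cfg.variance, rng)
    grid = RasterGrid(
        name=name,
        x_origin=lon_min,
        y_origin=lat_max - n_rows * cell,
        cell_size=cell,
        nodata=-9999.0,
        values=vals.reshape(n_rows, n_cols),
    )
    site_vals = None
    if sites is not None:
        site_vals = np.array([grid.value_at(lon, lat) for lon, lat in sites])
    return grid, site_vals


#: Per-variable scale factors; curvatures live on a radians/m scale orders of
#: magnitude below the other predictors, which is what makes their
#: back-transformed regression coefficients large.
_ENV_SCALES = {"pcurv": 1e-3, "tcurv": 1e-3, "tpi": 1e-2, "vrm": 1e-2}


def gen_env_table(
    sites: np.ndarray,
    field_cfg: EnvFieldConfig,
    rng: np.random.Generator,
    variables: Sequence[str] = ENV_VARIABLES,
) -> pd.DataFrame:
    """Independent spatially autocorrelated realisations of every predictor."""
    out = {}
    for var in variables:
        scale = _ENV_SCALES.get(var, 1.0)
        out[var] = scale * grf_at_points(
            sites, field_cfg.range_deg, field_cfg.variance, rng
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Balding-Nichols marker generation

def _draw_ancestral(law: tuple, n_loci: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        lo, hi = float(law[1]), float(law[2])
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("uniform ancestral law needs 0 <= lo < hi <= 1")
        return rng.uniform(lo, hi, n_loci)
    if kind == "beta":
        a, b = float(law[1]), float(law[2])
        if a <= 0 or b <= 0:
            raise ValueError("degenerate Beta parameters for the ancestral law")
        return rng.beta(a, b, n_loci)
    raise ValueError(f"unknown ancestral frequency law {kind!r}")


def expected_hs(f: float | np.ndarray, qbar: np.ndarray) -> float | np.ndarray:
    """Closed-form E[H_S] for drift F and per-locus ancestral frequencies q̄.

    Band presence probability is p = 1 - (1 - q)^2 with q ~ Beta under the
    drift model; E[2 p (1 - p)] = 2 (m2 - m4) where mk = E[(1 - q)^k] follows
    from Beta moments. The sample estimator with the n/(n-1) correction is
    unbiased for 2 p (1 - p), so this is also the expectation of the realised
    statistic. Vectorised over ``f``.
    """
    f = np.asarray(f, dtype=float)
    qbar = np.asarray(qbar, dtype=float)
    fcol = f.reshape(-1, 1)
    a = qbar * (1.0 - fcol) / fcol
    b = (1.0 - qbar) * (1.0 - fcol) / fcol
    s = a + b
    m2 = b * (b + 1) / (s * (s + 1))
    m4 = m2 * (b + 2) * (b + 3) / ((s + 2) * (s + 3))
    h = np.mean(2.0 * (m2 - m4), axis=1)
    return float(h[0]) if np.isscalar(f) or f.ndim == 0 else h


def achievable_hs_range(qbar: np.ndarray,
                        f_bounds: tuple[float, float] = _F_BOUNDS) -> tuple[float, float]:
    """(min, max) expected H_S attainable over the allowed drift range."""
    lo = expected_hs(f_bounds[1], qbar)
    hi = expected_hs(f_bounds[0], qbar)
    return float(lo), float(hi)


def calibrate_f_for_hs(
    targets: np.ndarray,
    qbar: np.ndarray,
    f_bounds: tuple[float, float] = _F_BOUNDS,
    grid_size: int = 400,
) -> np.ndarray:
    """Invert the monotone map F -> E[H_S] on a lookup grid."""
    f_grid = np.linspace(f_bounds[0], f_bounds[1], grid_size)
    h_grid = expected_hs(f_grid, qbar)  # decreasing in F
    return np.interp(np.asarray(targets, dtype=float), h_grid[::-1], f_grid[::-1])


def inject_linear_effect(
    env_values: np.ndarray,
    beta: float,
    sigma: float,
    qbar: np.ndarray,
    rng: np.random.Generator,
    alpha: float | None = None,
    f_bounds: tuple[float, float] = _F_BOUNDS,
) -> tuple[np.ndarray, float]:
    """Per-population drift values realising H_S ≈ alpha + beta * env + noise.

    The noiseless targets must stay inside the achievable expected-H_S range;
    otherwise :class:`AchievableRangeError` reports the attainable bound.
    Gaussian noise (sd ``sigma``) is added on the H_S scale and clipped to
    the achievable range.
    """
    env_values = np.asarray(env_values, dtype=float)
    h_lo, h_hi = achievable_hs_range(qbar, f_bounds)
    if alpha is None:
        alpha = 0.5 * (h_lo + h_hi)
    targets = alpha + beta * (env_values - env_values.mean())
    margin = 1e-6
    if targets.min() < h_lo - 1e-12 or targets.max() > h_hi + 1e-12:
        raise AchievableRangeError(
            f"requested effect drives expected H_S to "
            f"[{targets.min():.4f}, {targets.max():.4f}], outside the "
            f"achievable range [{h_lo:.4f}, {h_hi:.4f}]; reduce |beta| or "
            f"recentre alpha"
        )
    noisy = targets + rng.normal(0.0, sigma, size=len(targets)) if sigma > 0 else targets
    noisy = np.clip(noisy, h_lo + margin, h_hi - margin)
    return calibrate_f_for_hs(noisy, qbar, f_bounds), float(alpha)


def gen_marker_dataset(
    config: SyntheticConfig,
    f_values: np.ndarray,
    rng: np.random.Generator,
    qbar: np.ndarray | None = None,
    species: str = "species_1",
    pop_ids: Sequence[str] | None = None,
) -> tuple[MarkerMatrix, dict]:
    """Balding-Nichols marker matrix for one species.

    ``f_values`` holds one drift coefficient per population. Returns the
    matrix plus a truth record (per-population F, per-locus q̄, per-population
    allele frequencies).
    """
    n_pops = len(f_values)
    n_ind = config.individuals_per_population
    n_loci = config.n_loci
    f_values = np.asarray(f_values, dtype=float)
    if ((f_values <= 0) | (f_values >= 1)).any():
        raise ValueError("drift values must lie strictly in (0, 1)")
    if qbar is None:
        qbar = _draw_ancestral(config.ancestral_freq_law, n_loci, rng)
    if pop_ids is None:
        pop_ids = [f"{species}_p{i + 1:03d}" for i in range(n_pops)]
    a = qbar[None, :] * (1.0 - f_values[:, None]) / f_values[:, None]
    b = (1.0 - qbar[None, :]) * (1.0 - f_values[:, None]) / f_values[:, None]
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("degenerate Beta parameters (check q̄ and F)")
    q = rng.beta(a, b)  # (n_pops, n_loci) population allele frequencies
    presence_prob = 1.0 - (1.0 - q) ** 2  # dominance masking
    bands = rng.random((n_pops, n_ind, n_loci)) < presence_prob[:, None, :]
    values = bands.reshape(n_pops * n_ind, n_loci).astype(float)
    individuals = [
        f"{pid}_i{j + 1:02d}" for pid in pop_ids for j in range(n_ind)
    ]
    populations = [pid for pid in pop_ids for _ in range(n_ind)]
    matrix = MarkerMatrix(
        individuals=individuals,
        loci=[f"L{j + 1:04d}" for j in range(n_loci)],
        values=values,
        populations=populations,
        species=species,
    )
    truth = {
        "F": dict(zip(pop_ids, f_values.tolist())),
        "qbar": qbar.tolist(),
        "q": q.tolist(),
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# whole-study bundles

@dataclass
class SimulatedStudy:
    markers: dict[str, MarkerMatrix]
    env_table: pd.DataFrame          # species, population_id, lon, lat, 48 vars
    truth: SyntheticTruth


def simulate_study(config: SyntheticConfig) -> SimulatedStudy:
    """Generate a full multi-species study bundle.

    Each species gets its own sites, environment realisation and marker
    matrix. When an effect is configured, per-population drift is calibrated
    to the target predictor; otherwise all populations share ``config.drift``.
    """
    rng = np.random.default_rng(config.seed)
    markers: dict[str, MarkerMatrix] = {}
    env_rows = []
    f_truth: dict[str, dict[str, float]] = {}
    env_truth: dict[str, dict[str, float]] = {}
    qbar_truth: dict[str, list[float]] = {}
    alpha_used: float | None = None
    for s in range(config.n_species):
        species = f"species_{s + 1}"
        sites = gen_sites(config.populations_per_species,
                          config.env_field.extent, rng)
        env = gen_env_table(sites, config.env_field, rng)
        qbar = _draw_ancestral(config.ancestral_freq_law, config.n_loci, rng)
        pop_ids = [f"{species}_p{i + 1:03d}"
                   for i in range(config.populations_per_species)]
        if config.effect is not None:
            target = env[config.effect.predictor].to_numpy()
            f_vals, alpha_used = inject_linear_effect(
                target, config.effect.beta, config.effect.sigma, qbar, rng,
                alpha=config.effect.alpha,
            )
        else:
            target = env[ENV_VARIABLES[0]].to_numpy()
            f_vals = np.full(config.populations_per_species, config.drift)
        matrix, truth = gen_marker_dataset(
            config, f_vals, rng, qbar=qbar, species=species, pop_ids=pop_ids
        )
        markers[species] = matrix
        f_truth[species] = truth["F"]
        env_truth[species] = dict(zip(pop_ids, target.tolist()))
        qbar_truth[species] = truth["qbar"]
        block = env.copy()
        block.insert(0, "lat", sites[:, 1])
        block.insert(0, "lon", sites[:, 0])
        block.insert(0, "population_id", pop_ids)
        block.insert(0, "species", species)
        env_rows.append(block)
    return SimulatedStudy(
        markers=markers,
        env_table=pd.concat(env_rows, ignore_index=True),
        truth=SyntheticTruth(
            f_values=f_truth,
            site_env=env_truth,
            beta=config.effect.beta if config.effect else None,
            alpha=alpha_used,
            ancestral_freqs=qbar_truth,
        ),
    )
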