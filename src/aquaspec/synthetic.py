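"""Synthetic canopy spectra and cross-variable data with known ground truth.

The generator emulates the statistical structure a canopy water-content
calibration study assumes, so the whole pipeline can be exercised and scored
without field data:

* water contents drawn from a truncated normal (mean 0.525, SD 0.087,
  bounds 0.32-0.753) matching the moments of a ~90-tree orchard campaign;
* a vegetation-shaped reflectance template on the 350-2500 nm grid at 1 nm:
  low visible reflectance with a green peak near 546 nm and red valley near
  667 nm, a sigmoid red edge rising to an NIR plateau, and a declining SWIR
  with local peaks near 1660 and 2220 nm;
* water-absorption troughs at 981, 1196, 1456, 1780 and 1950 nm whose depths
  increase linearly with water content — the signal the transforms are meant
  to recover;
* the two nuisances the log-reciprocal/derivative chain is designed to remove:
  a per-sample multiplicative illumination scale and an additive linear
  baseline drift, plus white measurement noise.

A separate generator draws data directly at the cross-variable level (products
of derivative values, magnitudes ~1e-7..1e-6) with a known sparse linear model
for the response, for regression-recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cross_variables import CrossVariableMatrix, DEFAULT_PAIRS
from .preprocessing import SpectralDataset

__all__ = [
    "SpectralSimConfig",
    "GroundTruth",
    "WATER_TROUGHS",
    "generate_water_contents",
    "template_reflectance",
    "generate_spectrum",
    "generate_dataset",
    "generate_cross_variable_data",
]

#: (centre nm, Gaussian width nm, base absorbance, absorbance increase per unit
#: water content).  Beer-Lambert attenuation: R *= exp(-depth * G(lam)), so the
#: log-reflectance signal is exactly linear in water content.
WATER_TROUGHS: tuple[tuple[float, float, float, float], ...] = (
    (981.0, 25.0, 0.05, 0.45),
    (1196.0, 30.0, 0.08, 0.50),
    (1456.0, 45.0, 0.25, 0.55),
    (1780.0, 50.0, 0.12, 0.35),
    (1950.0, 60.0, 0.55, 0.35),
)


@dataclass
class SpectralSimConfig:
    """Study conditions for the spectra generator.

    Defaults reproduce a 90-sample campaign: water content truncated-normal
    with mean 0.525 and SD 0.087 on [0.32, 0.753]; illumination scales jitter
    +/-5% around 1; baseline drift is a per-sample line a + b*(lam - 350 nm)
    with small offset and slope; measurement noise is white with SD 0.0015
    reflectance units (a realistic field-spectroradiometer level after
    instrument averaging).
    """

    n_samples: int = 90
    wc_mean: float = 0.525
    wc_sd: float = 0.087
    wc_bounds: tuple[float, float] = (0.32, 0.753)
    wc_distribution: str = "truncnorm"  # or "uniform" over wc_bounds
    grid_start: float = 350.0
    grid_stop: float = 2500.0
    grid_step: float = 1.0
    troughs: tuple[tuple[float, float, float, float], ...] = WATER_TROUGHS
    illumination_range: tuple[float, float] = (0.95, 1.05)
    drift_offset_range: tuple[float, float] = (-0.01, 0.01)
    drift_slope_range: tuple[float, float] = (-1.5e-5, 1.5e-5)
    noise_sd: float = 0.0015

    def __post_init__(self) -> None:
        lo, hi = self.wc_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("water-content bounds must satisfy 0 < lo < hi < 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + self.grid_step / 2, self.grid_step)


@dataclass
class GroundTruth:
    """Everything the generator knew: the targets recovery is scored against."""

    water_content: np.ndarray
    illumination: np.ndarray | None = None
    drift_offset: np.ndarray | None = None
    drift_slope: np.ndarray | None = None
    active_variables: tuple[str, ...] = ()
    intercept: float = float("nan")
    coefficients: dict[str, float] = field(default_factory=dict)
    noise_sd: float = float("nan")


def generate_water_contents(cfg: SpectralSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw n water-content fractions from the configured distribution."""
    lo, hi = cfg.wc_bounds
    if cfg.wc_distribution == "uniform":
        return rng.uniform(lo, hi, size=cfg.n_samples)
    if cfg.wc_distribution != "truncnorm":
        raise ValueError(f"unknown water-content distribution {cfg.wc_distribution!r}")
    if cfg.wc_sd == 0:
        return np.full(cfg.n_samples, cfg.wc_mean)
    a, b = (lo - cfg.wc_mean) / cfg.wc_sd, (hi - cfg.wc_mean) / cfg.wc_sd
    dist = stats.truncnorm(a, b, loc=cfg.wc_mean, scale=cfg.wc_sd)
    return dist.ppf(rng.uniform(size=cfg.n_samples))


def _gauss(lam: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - centre) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def template_reflectance(wavelengths: np.ndarray) -> np.ndarray:
    """Water-free vegetation reflectance template (smooth parametric pieces)."""
    lam = np.asarray(wavelengths, dtype=float)
    r = np.full_like(lam, 0.04)
    r += 0.06 * _gauss(lam, 546.0, 20.0)          # green peak; red valley sits at ~667
    r += 0.42 * _sigmoid((lam - 715.0) / 18.0)    # red edge up to the NIR plateau
    r -= 0.18 * _sigmoid((lam - 1520.0) / 150.0)  # broad SWIR decline
    r += 0.06 * _gauss(lam, 1660.0, 60.0)         # SWIR reflection peaks between
    r += 0.05 * _gauss(lam, 2220.0, 80.0)         # the water absorptions
    return r


def _absorption(lam: np.ndarray, w: np.ndarray, troughs) -> np.ndarray:
    """Beer-Lambert water-absorption factor exp(-sum of trough absorbances)."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    absorbance = np.zeros((w.size, lam.size))
    for centre, width, base, sens in troughs:
        depth = np.clip(base + sens * w, 0.0, None)
        absorbance += np.outer(depth, _gauss(lam, centre, width))
    return np.exp(-absorbance)


def generate_spectrum(w: float, cfg: SpectralSimConfig, rng: np.random.Generator) -> np.ndarray:
    """One reflectance spectrum at water content ``w``: template x absorption,
    then illumination scale, baseline drift and white noise; clipped to (0, 1]."""
    if not 0 < w < 1:
        raise ValueError("water content must lie in (0, 1)")
    lam = cfg.wavelengths
    clean = template_reflectance(lam) * _absorption(lam, w, cfg.troughs)[0]
    scale = rng.uniform(*cfg.illumination_range)
    offset = rng.uniform(*cfg.drift_offset_range)
    slope = rng.uniform(*cfg.drift_slope_range)
    noisy = scale * clean + offset + slope * (lam - lam[0]) + rng.normal(0, cfg.noise_sd, lam.size)
    return _clip_reflectance(noisy)


def _clip_reflectance(r: np.ndarray, tol_fraction: float = 0.01) -> np.ndarray:
    eps = 1e-6
    n_bad = int(np.sum((r <= 0) | (r > 1)))
    if n_bad > tol_fraction * r.size:
        warnings.warn(f"{n_bad} reflectance values outside (0, 1] were clipped")
    return np.clip(r, eps, 1.0)


def generate_dataset(
    cfg: SpectralSimConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[SpectralDataset, np.ndarray, GroundTruth]:
    """Full synthetic campaign: spectra table, water contents and ground truth.

    The whole matrix is produced vectorised from a single seeded generator, so
    a given (config, seed) pair always yields the identical dataset.
    """
    cfg = cfg or SpectralSimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = cfg.wavelengths
    w = generate_water_contents(cfg, rng)
    clean = template_reflectance(lam)[None, :] * _absorption(lam, w, cfg.troughs)
    scale = rng.uniform(*cfg.illumination_range, size=cfg.n_samples)
    offset = rng.uniform(*cfg.drift_offset_range, size=cfg.n_samples)
    slope = rng.uniform(*cfg.drift_slope_range, size=cfg.n_samples)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, lam.size))
    r = scale[:, None] * clean + offset[:, None] + slope[:, None] * (lam - lam[0])[None, :] + noise
    ds = SpectralDataset(
        sample_ids=[f"S{i + 1:03d}" for i in range(cfg.n_samples)],
        wavelengths=lam,
        reflectance=_clip_reflectance(r),
    )
    truth = GroundTruth(
        water_content=w, illumination=scale, drift_offset=offset, drift_slope=slope,
        noise_sd=cfg.noise_sd,
    )
    return ds, w, truth


# ---------------------------------------------------------------------------
# Cross-variable-level generator
# ---------------------------------------------------------------------------

#: Per-variable means and dispersions for synthetic cross variables; products
#: of derivative-scale values (~1e-3 each) land at ~1e-7..1e-6.  The dispersions
#: of the three default-active columns are inversely proportional to their
#: coefficient magnitudes so each active term contributes equally to the
#: response — mimicking data in which all three retained variables are
#: decisively significant rather than one hovering at the detection edge.
CROSS_VARIABLE_MEANS: dict[str, float] = {
    "Z1": 4.2e-7, "Z2": 3.4e-7, "Z3": 3.8e-7, "Z4": 3.1e-7, "Z5": 3.6e-7, "Z6": 4.0e-7,
}
CROSS_VARIABLE_SDS: dict[str, float] = {
    "Z1": 1.2e-7, "Z2": 1.66e-7, "Z3": 1.2e-7, "Z4": 1.2e-7, "Z5": 1.45e-7, "Z6": 0.80e-7,
}
CROSS_VARIABLE_CORR = 0.3  # moderate shared-factor correlation between columns

DEFAULT_TRUE_MODEL: dict[str, float] = {
    "Z2": -480610.4213,
    "Z5": -552189.0450,
    "Z6": -1006181.8358,
}
DEFAULT_TRUE_INTERCEPT = 0.4613


def generate_cross_variable_data(
    n: int = 72,
    intercept: float = DEFAULT_TRUE_INTERCEPT,
    coefficients: Mapping[str, float] | None = None,
    noise_sd: float | None = None,
    target_r2: float | None = 0.7,
    corr: float = CROSS_VARIABLE_CORR,
    rng: int | np.random.Generator | None = None,
    names: Sequence[str] = ("Z1", "Z2", "Z3", "Z4", "Z5", "Z6"),
) -> tuple[CrossVariableMatrix, np.ndarray, GroundTruth]:
    """Cross-variable matrix plus a sparse linear response with known truth.

    Columns share a common factor with loading ``sqrt(corr)`` (pairwise
    correlation ``corr``).  The response is ``intercept + sum(b_j * Z_j) + eps``
    over the active ``coefficients`` (default: Z2/Z5/Z6 with coefficients of
    order 1e5-1e6 against a response near 0.46).  Either pass ``noise_sd``
    directly or a ``target_r2``: the noise SD is then set so the population
    signal-to-total variance ratio equals the target.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    names = tuple(names)
    coefficients = dict(coefficients) if coefficients is not None else dict(DEFAULT_TRUE_MODEL)
    unknown = set(coefficients) - set(names)
    if unknown:
        raise ValueError(f"coefficients refer to unknown variables: {sorted(unknown)}")
    if not 0 <= corr < 1:
        raise ValueError("corr must lie in [0, 1)")
    p = len(names)
    common = rng.normal(size=(n, 1))
    unique = rng.normal(size=(n, p))
    z = np.sqrt(corr) * common + np.sqrt(1 - corr) * unique
    means = np.array([CROSS_VARIABLE_MEANS.get(nm, 3.5e-7) for nm in names])
    sds = np.array([CROSS_VARIABLE_SDS.get(nm, 1.2e-7) for nm in names])
    Z = means[None, :] + sds[None, :] * z
    b = np.array([coefficients.get(nm, 0.0) for nm in names])
    signal = Z @ b
    if noise_sd is None:
        if target_r2 is None or not 0 < target_r2 < 1:
            raise ValueError("pass noise_sd or a target_r2 in (0, 1)")
        # population signal variance from the factor-model covariance
        cov = np.outer(sds, sds) * (corr * np.ones((p, p)) + (1 - corr) * np.eye(p))
        sig_var = float(b @ cov @ b)
        noise_sd = float(np.sqrt(sig_var * (1 - target_r2) / target_r2))
    y = intercept + signal + rng.normal(0.0, noise_sd, size=n)
    zmat = CrossVariableMatrix(
        sample_ids=[f"S{i + 1:03d}" for i in range(n)],
        names=names,
        pairs=tuple(DEFAULT_PAIRS[:p]) if p <= len(DEFAULT_PAIRS) else tuple((0.0, 0.0) for _ in names),
        values=Z,
    )
    truth = GroundTruth(
        water_content=y,
        active_variables=tuple(nm for nm in names if coefficients.get(nm, 0.0) != 0.0),
        intercept=intercept,
        coefficients=coefficients,
        noise_sd=float(noise_sd),
    )
    return zmat, y, truth
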