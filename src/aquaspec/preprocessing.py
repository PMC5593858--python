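"""Spectral-table ingestion, water-content computation, noise-band removal and smoothing.

Field spectroradiometer reflectance comes on a 350-2500 nm grid at 1 nm
resolution. Three wavelength windows (around the strong atmospheric water-vapour
absorptions and the detector edge) are too noisy to use and are excised before
any other processing; the surviving grid is kept as a set of contiguous
*segments* so that smoothing and differencing never reach across an excised gap.

Canopy water content is determined gravimetrically: a sample of fresh mass m1 is
oven-dried to constant mass m2, and the water-content fraction is (m1 - m2)/m1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EXCLUDED_BANDS",
    "SMOOTHING_KERNEL",
    "SpectralDataset",
    "BandMask",
    "InvalidMeasurementError",
    "SpectralDomainError",
    "compute_water_content",
    "load_water_table",
    "remove_noise_bands",
    "smooth_series",
    "smooth_dataset",
]

#: Noise windows (nm, closed intervals) excised before any transform.
DEFAULT_EXCLUDED_BANDS: tuple[tuple[float, float], ...] = (
    (1350.0, 1410.0),
    (1820.0, 1940.0),
    (2390.0, 2500.0),
)

#: 7-point weighted moving-average kernel over offsets -3..+3.  The centre
#: point is down-weighted to 0.10 so the weights sum to one exactly.
SMOOTHING_KERNEL: np.ndarray = np.array([0.15, 0.15, 0.15, 0.10, 0.15, 0.15, 0.15])


class InvalidMeasurementError(ValueError):
    """Raised for physically impossible mass measurements."""


class SpectralDomainError(ValueError):
    """Raised when reflectance values leave the domain later transforms need."""


@dataclass
class SpectralDataset:
    """Per-sample reflectance on a strictly increasing wavelength grid.

    Parameters
    ----------
    sample_ids
        Opaque sample labels, one per spectrum.
    wavelengths
        Strictly increasing grid in nm.
    reflectance
        ``(n_samples, n_wavelengths)`` matrix of reflectance fractions in
        ``(0, 1]``; positivity is required because the log-reciprocal transform
        is applied downstream.
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths.ndim != 1 or not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        n, m = self.reflectance.shape
        if m != self.wavelengths.size:
            raise ValueError(
                f"reflectance has {m} columns but grid has {self.wavelengths.size} wavelengths"
            )
        if n != len(self.sample_ids):
            raise ValueError("one sample id required per spectrum")
        if not np.all(np.isfinite(self.reflectance)):
            bad = np.argwhere(~np.isfinite(self.reflectance))[0]
            raise SpectralDomainError(
                f"non-finite reflectance for sample {self.sample_ids[bad[0]]} "
                f"at {self.wavelengths[bad[1]]:g} nm"
            )
        if np.any(self.reflectance <= 0.0):
            bad = np.argwhere(self.reflectance <= 0.0)[0]
            raise SpectralDomainError(
                f"non-positive reflectance for sample {self.sample_ids[bad[0]]} "
                f"at {self.wavelengths[bad[1]]:g} nm (log-reciprocal undefined)"
            )

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{w:g}" for w in self.wavelengths]
        df = pd.DataFrame(self.reflectance, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralDataset":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise ValueError("spectra CSV must start with a sample_id column")
        wavelengths = np.array([float(c) for c in df.columns[1:]])
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            wavelengths=wavelengths,
            reflectance=df.iloc[:, 1:].to_numpy(dtype=float),
        )


@dataclass
class BandMask:
    """Record of excised wavelength windows and the surviving contiguous blocks.

    ``retained_segments`` holds half-open ``(start, stop)`` column ranges into
    the *masked* grid; every downstream per-segment operation (smoothing,
    differencing) iterates over these so no kernel or difference straddles a gap.
    """

    excluded_ranges: tuple[tuple[float, float], ...]
    retained_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ranges = sorted(tuple(map(float, r)) for r in self.excluded_ranges)
        for (a, b) in ranges:
            if b < a:
                raise ValueError(f"excluded range [{a}, {b}] is inverted")
        for (_, b), (c, _) in zip(ranges, ranges[1:]):
            if c <= b:
                raise ValueError("excluded ranges overlap")
        self.excluded_ranges = tuple(ranges)
        self.retained_segments = tuple((int(a), int(b)) for a, b in self.retained_segments)


def compute_water_content(
    fresh_mass: float | np.ndarray,
    dry_mass: float | np.ndarray,
    sample_id: str | Sequence[str] | None = None,
) -> float | np.ndarray:
    """Gravimetric water-content fraction ``(fresh - dry) / fresh``.

    Both masses are in grams; the result is a fraction in ``(0, 1)``.  A dry
    mass equal to or exceeding the fresh mass, or a non-positive mass, is an
    invalid measurement and raises, naming the offending sample when ids are
    supplied.
    """
    fresh = np.asarray(fresh_mass, dtype=float)
    dry = np.asarray(dry_mass, dtype=float)
    bad = ~(np.isfinite(fresh) & np.isfinite(dry) & (dry > 0) & (fresh > dry))
    if np.any(bad):
        idx = int(np.argwhere(np.atleast_1d(bad))[0][0])
        if sample_id is None:
            label = f"index {idx}"
        elif isinstance(sample_id, str):
            label = sample_id
        else:
            label = str(sample_id[idx])
        raise InvalidMeasurementError(
            f"invalid mass measurement for sample {label}: "
            f"need 0 < dry_mass < fresh_mass, got fresh={np.atleast_1d(fresh)[idx] if fresh.ndim else float(fresh)}, "
            f"dry={np.atleast_1d(dry)[idx] if dry.ndim else float(dry)}"
        )
    wc = (fresh - dry) / fresh
    return float(wc) if wc.ndim == 0 else wc


def load_water_table(path: str | Path) -> pd.Series:
    """Read a water table CSV into a fraction-valued Series indexed by sample id.

    Accepts either a ``water_content`` column (fraction) or the mass pair
    ``fresh_mass_g`` / ``dry_mass_g``, from which the fraction is computed.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("water CSV must contain a sample_id column")
    ids = df["sample_id"].astype(str)
    if "water_content" in df.columns:
        wc = df["water_content"].to_numpy(dtype=float)
        if np.any((wc <= 0) | (wc >= 1)):
            raise InvalidMeasurementError("water_content values must be fractions in (0, 1)")
    elif {"fresh_mass_g", "dry_mass_g"} <= set(df.columns):
        wc = compute_water_content(
            df["fresh_mass_g"].to_numpy(dtype=float),
            df["dry_mass_g"].to_numpy(dtype=float),
            sample_id=ids.tolist(),
        )
    else:
        raise ValueError(
            "water CSV needs either a water_content column or fresh_mass_g/dry_mass_g"
        )
    return pd.Series(wc, index=pd.Index(ids, name="sample_id"), name="water_content")


def _contiguous_segments(kept_original_indices: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Runs of consecutive original column indices, as ranges into the kept grid."""
    if kept_original_indices.size == 0:
        return ()
    breaks = np.flatnonzero(np.diff(kept_original_indices) != 1) + 1
    bounds = np.concatenate(([0], breaks, [kept_original_indices.size]))
    return tuple((int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]))


def remove_noise_bands(
    ds: SpectralDataset,
    excluded_ranges: Iterable[tuple[float, float]] = DEFAULT_EXCLUDED_BANDS,
) -> tuple[SpectralDataset, BandMask]:
    """Drop every column whose wavelength falls in a closed excluded interval.

    Returns the reduced dataset together with a :class:`BandMask` whose
    ``retained_segments`` partition the surviving columns into contiguous
    blocks of the original grid.
    """
    ranges = tuple(tuple(map(float, r)) for r in excluded_ranges)
    keep = np.ones(ds.n_wavelengths, dtype=bool)
    for lo, hi in ranges:
        keep &= ~((ds.wavelengths >= lo) & (ds.wavelengths <= hi))
    if not keep.any():
        raise ValueError("band mask removes every wavelength")
    kept_idx = np.flatnonzero(keep)
    masked = SpectralDataset(
        sample_ids=ds.sample_ids,
        wavelengths=ds.wavelengths[kept_idx],
        reflectance=ds.reflectance[:, kept_idx],
    )
    mask = BandMask(excluded_ranges=ranges, retained_segments=_contiguous_segments(kept_idx))
    return masked, mask


def smooth_series(values: np.ndarray, kernel: np.ndarray = SMOOTHING_KERNEL) -> np.ndarray:
    """Weighted moving average of one contiguous series (last axis).

    Interior points use the full 7-point kernel; within three points of either
    end the kernel is truncated to the available window and renormalised to
    unit sum, so output length equals input length and a constant series is
    returned unchanged.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise SpectralDomainError("non-finite value in series passed to smoothing")
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size % 2 != 1:
        raise ValueError("smoothing kernel must have odd length")
    half = kernel.size // 2
    n = v.shape[-1]
    # accumulate weighted neighbour *differences*: out = x + sum(w_k (x_k - x)) / W
    # with W the truncated-window weight sum.  Mathematically the renormalised
    # weighted mean, but a constant series passes through bit-identically.
    num = np.zeros_like(v)
    den = np.full(n, kernel[half])
    for off in (*range(-half, 0), *range(1, half + 1)):
        wgt = kernel[half + off]
        lo, hi = max(0, -off), min(n, n - off)
        num[..., lo:hi] += wgt * (v[..., lo + off : hi + off] - v[..., lo:hi])
        den[lo:hi] += wgt
    return v + num / den


def smooth_dataset(
    ds: SpectralDataset,
    mask: BandMask | None = None,
    kernel: np.ndarray = SMOOTHING_KERNEL,
) -> SpectralDataset:
    """Smooth every spectrum segment-by-segment; never across an excised gap."""
    segments = mask.retained_segments if mask is not None else ((0, ds.n_wavelengths),)
    covered = sum(b - a for a, b in segments)
    if covered != ds.n_wavelengths:
        raise ValueError("mask segments do not partition the dataset grid")
    out = np.empty_like(ds.reflectance)
    for a, b in segments:
        out[:, a:b] = smooth_series(ds.reflectance[:, a:b], kernel=kernel)
    # smoothing a positive series with convex weights stays positive, but
    # guard against pathological kernels supplied via config
    if np.any(out <= 0):
        warnings.warn("smoothing produced non-positive reflectance; clipping to tiny positive")
        out = np.clip(out, np.finfo(float).tiny, None)
    return SpectralDataset(ds.sample_ids, ds.wavelengths, out)
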