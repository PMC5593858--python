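"""Log-reciprocal and first-derivative transforms plus sensitive-wavelength selection.

The absorbance-like transform log10(1/R) turns a multiplicative illumination
factor (a per-sample positive scale on reflectance) into an additive offset;
the subsequent wavelength derivative removes that offset along with any
baseline drift that is constant in the log domain, and sharpens absorption
features.  Per-wavelength Pearson correlation of the transformed values with
water content then locates the wavelengths worth modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import BandMask, SpectralDataset, SpectralDomainError

__all__ = [
    "TransformedSpectra",
    "CorrelationCurve",
    "log_reciprocal",
    "first_derivative",
    "transform_spectra",
    "correlation_scan",
    "select_sensitive_wavelengths",
]


@dataclass
class TransformedSpectra:
    """First derivative of log10(1/R) per sample, in nm^-1.

    Differencing shortens each contiguous segment by one point; the wavelength
    label of a difference is its left endpoint, so "the value at 760 nm" means
    the difference between the 760 and 761 nm log-reciprocal values.
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    values: np.ndarray
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError("column count does not match wavelength count")

    def column(self, wavelength: float) -> np.ndarray:
        """Transformed values at one wavelength (exact grid match required)."""
        idx = np.flatnonzero(self.wavelengths == float(wavelength))
        if idx.size == 0:
            near = self.wavelengths[np.argsort(np.abs(self.wavelengths - wavelength))[:3]]
            raise KeyError(
                f"wavelength {wavelength:g} nm not on the transformed grid; "
                f"nearest available: {', '.join(f'{w:g}' for w in near)}"
            )
        return self.values[:, idx[0]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CorrelationCurve:
    """Signed Pearson correlation of each kept wavelength with water content."""

    wavelengths: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        finite = self.r[np.isfinite(self.r)]
        if finite.size and np.any(np.abs(finite) > 1 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths, "r": self.r}).to_csv(path, index=False)


def log_reciprocal(reflectance: np.ndarray) -> np.ndarray:
    """Elementwise log10(1/R); monotone decreasing in R, zero at R = 1."""
    r = np.asarray(reflectance, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        bad = np.argwhere(~(np.isfinite(r) & (r > 0)))[0]
        raise SpectralDomainError(f"log-reciprocal undefined at array position {tuple(bad)}")
    return -np.log10(r)


def first_derivative(
    values: np.ndarray,
    wavelengths: np.ndarray,
    segments: Sequence[tuple[int, int]] | None = None,
    sample_ids: Sequence[str] | None = None,
    scheme: str = "forward",
) -> TransformedSpectra:
    """Per-segment wavelength derivative of a (transformed) spectral matrix.

    ``forward`` (the default) uses (v[i+1] - v[i]) / (lam[i+1] - lam[i]) and
    drops the last point of each segment; ``central`` uses the symmetric
    difference over two grid steps and drops both endpoints.  Segments too
    short to difference are dropped with a warning.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    lam = np.asarray(wavelengths, dtype=float)
    if segments is None:
        segments = [(0, lam.size)]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(v.shape[0])]
    trim = 1 if scheme == "forward" else 2
    if scheme not in ("forward", "central"):
        raise ValueError(f"unknown derivative scheme {scheme!r}")

    out_vals, out_lams, out_segs = [], [], []
    pos = 0
    for a, b in segments:
        if b - a <= trim:
            warnings.warn(
                f"segment {lam[a]:g}-{lam[b - 1]:g} nm too short to differentiate; dropped"
            )
            continue
        seg_lam = lam[a:b]
        spacing = np.diff(seg_lam)
        if not np.allclose(spacing, spacing[0]):
            raise ValueError(
                f"segment starting at {seg_lam[0]:g} nm has non-constant spacing"
            )
        if scheme == "forward":
            d = np.diff(v[:, a:b], axis=1) / spacing
            d_lam = seg_lam[:-1]
        else:
            d = (v[:, a + 2 : b] - v[:, a : b - 2]) / (seg_lam[2:] - seg_lam[:-2])
            d_lam = seg_lam[1:-1]
        out_vals.append(d)
        out_lams.append(d_lam)
        out_segs.append((pos, pos + d_lam.size))
        pos += d_lam.size
    if not out_vals:
        raise ValueError("no segment long enough to differentiate")
    return TransformedSpectra(
        sample_ids=list(sample_ids),
        wavelengths=np.concatenate(out_lams),
        values=np.concatenate(out_vals, axis=1),
        segments=tuple(out_segs),
    )


def transform_spectra(
    ds: SpectralDataset,
    mask: BandMask | None = None,
    scheme: str = "forward",
) -> TransformedSpectra:
    """Full transform chain: log10(1/R) followed by the per-segment derivative."""
    segments = mask.retained_segments if mask is not None else None
    return first_derivative(
        log_reciprocal(ds.reflectance),
        ds.wavelengths,
        segments=segments,
        sample_ids=ds.sample_ids,
        scheme=scheme,
    )


def correlation_scan(t: TransformedSpectra, water_content: np.ndarray) -> CorrelationCurve:
    """Pearson correlation of every transformed column with water content.

    Columns with zero variance get NaN (undefined; excluded from selection).
    """
    w = np.asarray(water_content, dtype=float)
    if w.size != t.values.shape[0]:
        raise ValueError("water-content length does not match sample count")
    if w.size < 3:
        raise ValueError("correlation scan needs at least 3 samples")
    wc = w - w.mean()
    sw = np.sqrt(np.sum(wc**2))
    if sw == 0:
        raise ValueError("water content is constant; correlation undefined")
    x = t.values - t.values.mean(axis=0)
    sx = np.sqrt(np.sum(x**2, axis=0))
    # columns whose spread is at rounding level relative to their magnitude are
    # effectively constant: correlation undefined
    degenerate = sx <= 1e-10 * np.maximum(np.abs(t.values).max(axis=0), np.finfo(float).tiny)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x.T @ wc) / (sx * sw)
    r[degenerate] = np.nan
    return CorrelationCurve(wavelengths=t.wavelengths, r=np.clip(r, -1.0, 1.0))


def select_sensitive_wavelengths(
    curve: CorrelationCurve,
    k: int = 4,
    min_gap: float = 0.0,
    explicit: Sequence[float] | None = None,
) -> np.ndarray:
    """Pick modelling wavelengths, either an explicit user list or greedily by |r|.

    The explicit path exists because practitioners mix correlation strength
    with physiological criteria (red-edge position, peak/valley flanks) that no
    scan captures; it only verifies that each requested wavelength is on the
    grid.  The greedy fallback takes the k largest |r| subject to a pairwise
    separation of ``min_gap`` nm, breaking |r| ties toward the shorter
    wavelength.
    """
    if explicit is not None:
        chosen = []
        for wl in explicit:
            idx = np.flatnonzero(curve.wavelengths == float(wl))
            if idx.size == 0:
                near = curve.wavelengths[np.argsort(np.abs(curve.wavelengths - wl))[:3]]
                raise KeyError(
                    f"requested wavelength {wl:g} nm not on the kept grid; "
                    f"nearest available: {', '.join(f'{w:g}' for w in near)}"
                )
            chosen.append(float(wl))
        return np.array(chosen)
    if k < 1:
        raise ValueError("k must be at least 1")
    ok = np.isfinite(curve.r)
    order = np.lexsort((curve.wavelengths[ok], -np.abs(curve.r[ok])))
    candidates = curve.wavelengths[ok][order]
    picked: list[float] = []
    for wl in candidates:
        if all(abs(wl - p) >= min_gap for p in picked):
            picked.append(float(wl))
        if len(picked) == k:
            break
    if len(picked) < k:
        raise ValueError(
            f"only {len(picked)} wavelengths satisfy the {min_gap:g} nm separation; needed {k}"
        )
    return np.array(sorted(picked))
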