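"""Calibration/validation partitioning: equidistant (systematic) vs simple random.

Equidistant sampling sorts the samples by water content, forms consecutive
blocks of (ratio + 1) samples, and sends one sample per complete block to the
validation set.  The hold-out set therefore spans the full response range
evenly, avoiding the "polarised" splits that simple random sampling can
produce, where calibration and validation means drift apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SplitResult",
    "equidistant_split",
    "random_split",
    "summarize_split",
    "format_summary",
]


@dataclass
class SplitResult:
    """Disjoint calibration/validation index sets covering all samples."""

    sample_ids: list[str]
    calibration_idx: np.ndarray
    validation_idx: np.ndarray
    method: str
    ratio: int | None = None
    offset: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.calibration_idx = np.asarray(self.calibration_idx, dtype=int)
        self.validation_idx = np.asarray(self.validation_idx, dtype=int)
        n = len(self.sample_ids)
        combined = np.concatenate([self.calibration_idx, self.validation_idx])
        if np.intersect1d(self.calibration_idx, self.validation_idx).size:
            raise ValueError("calibration and validation sets overlap")
        if not np.array_equal(np.sort(combined), np.arange(n)):
            raise ValueError("split does not cover every sample exactly once")

    @property
    def calibration_ids(self) -> list[str]:
        return [self.sample_ids[i] for i in self.calibration_idx]

    @property
    def validation_ids(self) -> list[str]:
        return [self.sample_ids[i] for i in self.validation_idx]

    def to_frame(self) -> pd.DataFrame:
        subset = np.empty(len(self.sample_ids), dtype=object)
        subset[self.calibration_idx] = "calibration"
        subset[self.validation_idx] = "validation"
        return pd.DataFrame({"sample_id": self.sample_ids, "subset": subset})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _ids_or_default(sample_ids: Sequence[str] | None, n: int) -> list[str]:
    if sample_ids is None:
        return [str(i) for i in range(n)]
    if len(sample_ids) != n:
        raise ValueError("sample_ids length does not match data length")
    return [str(s) for s in sample_ids]


def equidistant_split(
    water_content: np.ndarray,
    ratio: int = 4,
    offset: int | str | None = None,
    sample_ids: Sequence[str] | None = None,
    seed: int | None = None,
) -> SplitResult:
    """Systematic, response-ordered split at calibration:validation = ratio:1.

    Samples are sorted ascending by water content (ties broken by original
    order), grouped into consecutive blocks of ``ratio + 1``; the element at
    position ``offset`` (0-based, default the last position) of each complete
    block is held out for validation, and any leftover partial block goes
    wholly to calibration.  ``offset="random"`` draws a single seeded starting
    position, the classic systematic-sampling variant with a random start.
    For n = 90 at ratio 4 this yields exactly 72 calibration / 18 validation.
    """
    w = np.asarray(water_content, dtype=float)
    n = w.size
    if ratio < 1:
        raise ValueError("ratio must be a positive integer")
    if n < ratio + 1:
        raise ValueError(f"need at least ratio+1={ratio + 1} samples, got {n}")
    if offset is None:
        off = ratio
    elif offset == "random":
        off = int(np.random.default_rng(seed).integers(0, ratio + 1))
    else:
        off = int(offset)
        if not 0 <= off <= ratio:
            raise ValueError(f"offset must lie in [0, {ratio}], got {off}")
    order = np.argsort(w, kind="stable")
    block = ratio + 1
    n_blocks = n // block
    val_sorted_positions = np.arange(n_blocks) * block + off
    val_idx = order[val_sorted_positions]
    cal_idx = np.setdiff1d(np.arange(n), val_idx)
    return SplitResult(
        sample_ids=_ids_or_default(sample_ids, n),
        calibration_idx=cal_idx,
        validation_idx=np.sort(val_idx),
        method="equidistant",
        ratio=ratio,
        offset=off,
        seed=seed,
    )


def random_split(
    n_or_ids: int | Sequence[str],
    n_val: int,
    seed: int | None = None,
    sample_ids: Sequence[str] | None = None,
) -> SplitResult:
    """Uniform random hold-out of ``n_val`` samples, reproducible under ``seed``."""
    if isinstance(n_or_ids, int):
        n = n_or_ids
        ids = _ids_or_default(sample_ids, n)
    else:
        ids = [str(s) for s in n_or_ids]
        n = len(ids)
    if not 0 < n_val < n:
        raise ValueError(f"n_val must satisfy 0 < n_val < {n}, got {n_val}")
    if n_val == n - 1:
        warnings.warn("calibration set reduced to a single sample")
    rng = np.random.default_rng(seed)
    val_idx = np.sort(rng.choice(n, size=n_val, replace=False))
    cal_idx = np.setdiff1d(np.arange(n), val_idx)
    return SplitResult(
        sample_ids=ids,
        calibration_idx=cal_idx,
        validation_idx=val_idx,
        method="random",
        seed=seed,
    )


def _subset_stats(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        raise ValueError("statistics undefined for an empty subset")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return {
        "n": int(values.size),
        "max": float(np.max(values)),
        "min": float(np.min(values)),
        "mean": mean,
        "std_dev": sd,
        "cv": sd / mean if mean != 0 else np.nan,
    }


def summarize_split(split: SplitResult, water_content: np.ndarray) -> pd.DataFrame:
    """Per-subset water-content statistics (fraction units; CV as a ratio).

    Rows Total / Calibration / Validation with N, max, min, mean, sample
    standard deviation (n-1 denominator) and CV = SD/mean.  Percent rendering
    is a formatting concern: see :func:`format_summary`.
    """
    w = np.asarray(water_content, dtype=float)
    if w.size != len(split.sample_ids):
        raise ValueError("water-content length does not match split")
    rows = {
        "Total": _subset_stats(w),
        "Calibration": _subset_stats(w[split.calibration_idx]),
        "Validation": _subset_stats(w[split.validation_idx]),
    }
    return pd.DataFrame(rows).T[["n", "max", "min", "mean", "std_dev", "cv"]]


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a summary the way calibration tables print it: max/min/mean and CV
    in percent (1 d.p.), standard deviation left as a fraction (3 d.p.)."""
    out = pd.DataFrame(index=summary.index)
    out["N"] = summary["n"].astype(int)
    out["Max (%)"] = (100 * summary["max"]).round(1)
    out["Min (%)"] = (100 * summary["min"]).round(1)
    out["Mean (%)"] = (100 * summary["mean"]).round(1)
    out["Std Dev"] = summary["std_dev"].round(3)
    out["CV (%)"] = (100 * summary["cv"]).round(1)
    return out
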