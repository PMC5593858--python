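"""Pairwise-product interaction features ("cross variables") at selected wavelengths.

Each cross variable is the elementwise product of the transformed (derivative of
log-reciprocal) values at two sensitive wavelengths, capturing the joint effect
of the pair on water content.  With the default four wavelengths — 760 nm (red
edge), 821 nm (smooth NIR shoulder), 967 nm and 1174 nm (absorption-trough
flanks) — the six unordered pairs give the canonical variables Z1..Z6.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .transforms import TransformedSpectra

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "DEFAULT_PAIRS",
    "CrossVariableMatrix",
    "build_cross_variables",
]

DEFAULT_WAVELENGTHS: tuple[float, ...] = (760.0, 821.0, 967.0, 1174.0)

#: Conventional pair order: Z1=(760,821), Z2=(760,967), Z3=(821,967),
#: Z4=(821,1174), Z5=(967,1174), Z6=(760,1174).
DEFAULT_PAIRS: tuple[tuple[float, float], ...] = (
    (760.0, 821.0),
    (760.0, 967.0),
    (821.0, 967.0),
    (821.0, 1174.0),
    (967.0, 1174.0),
    (760.0, 1174.0),
)


@dataclass
class CrossVariableMatrix:
    """Samples x cross-variables, each column tagged with its wavelength pair (nm^-2)."""

    sample_ids: list[str]
    names: tuple[str, ...]
    pairs: tuple[tuple[float, float], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.sample_ids), len(self.names)):
            raise ValueError("cross-variable matrix shape mismatch")
        if len(self.pairs) != len(self.names):
            raise ValueError("one wavelength pair required per variable")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.names,
                "wavelength_a_nm": [a for a, _ in self.pairs],
                "wavelength_b_nm": [b for _, b in self.pairs],
            }
        )

    def to_csv(self, path: str | Path, manifest_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if manifest_path is not None:
            self.manifest().to_csv(manifest_path, index=False)


def all_pairs(wavelengths: Sequence[float]) -> tuple[tuple[float, float], ...]:
    """All unordered pairs of the given wavelengths.

    For the canonical quartet (760, 821, 967, 1174) the pairs come back in the
    conventional Z1..Z6 order; any other set is paired lexicographically.
    """
    wls = [float(w) for w in wavelengths]
    if tuple(sorted(wls)) == DEFAULT_WAVELENGTHS:
        return DEFAULT_PAIRS
    return tuple((a, b) for i, a in enumerate(sorted(wls)) for b in sorted(wls)[i + 1 :])


def build_cross_variables(
    t: TransformedSpectra,
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
    pairs: Sequence[tuple[float, float]] | None = None,
) -> CrossVariableMatrix:
    """Elementwise products of transformed columns for each wavelength pair.

    ``pairs`` defaults to all unordered pairs of ``wavelengths`` in the
    conventional order; a missing wavelength (e.g. one excised with a noise
    band) raises a lookup error listing the nearest grid wavelengths.
    """
    if pairs is None:
        pairs = all_pairs(wavelengths)
    pairs = tuple((float(a), float(b)) for a, b in pairs)
    cols = {}
    for wl in sorted({w for p in pairs for w in p}):
        cols[wl] = t.column(wl)  # raises KeyError with nearest-wavelength hint
    values = np.column_stack([cols[a] * cols[b] for a, b in pairs])
    names = tuple(f"Z{i + 1}" for i in range(len(pairs)))
    return CrossVariableMatrix(
        sample_ids=list(t.sample_ids), names=names, pairs=pairs, values=values
    )
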