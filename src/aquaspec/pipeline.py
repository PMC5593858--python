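"""End-to-end orchestration: preprocess, transform, build features, split, fit, score.

A single *arm* runs the whole calibration workflow with one partitioning method
(equidistant or random); the two-arm comparison runs both on the same dataset
and tabulates the metric differences.  A multi-replicate mode repeats the
comparison across many seeded synthetic datasets to estimate the distribution
of each metric per method.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics, sampling
from .cross_variables import DEFAULT_WAVELENGTHS, CrossVariableMatrix, build_cross_variables
from .preprocessing import (
    DEFAULT_EXCLUDED_BANDS,
    SpectralDataset,
    load_water_table,
    remove_noise_bands,
    smooth_dataset,
)
from .stepwise import StepwiseModel, stepwise_select
from .synthetic import SpectralSimConfig, generate_dataset
from .transforms import transform_spectra

__all__ = ["RunConfig", "ArmResult", "ComparisonResult", "run_single_arm", "run_comparison",
           "replicate_comparison", "prepare_features"]


@dataclass
class RunConfig:
    """Complete, serialisable description of one pipeline run."""

    spectra_csv: str | None = None
    water_csv: str | None = None
    simulate: SpectralSimConfig | None = None
    seed: int = 0
    excluded_bands: tuple[tuple[float, float], ...] = DEFAULT_EXCLUDED_BANDS
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    split_ratio: int = 4
    equidistant_offset: int | str | None = None
    alpha_in: float = 0.05
    alpha_out: float = 0.05
    r2_form: str = "ratio"
    outdir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.spectra_csv is not None and self.water_csv is not None
        if not has_files and self.simulate is None:
            self.simulate = SpectralSimConfig()
        if has_files and self.simulate is not None:
            raise ValueError("configure either input CSVs or simulation, not both")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class ArmResult:
    method: str
    model: StepwiseModel
    split: sampling.SplitResult
    summary: pd.DataFrame
    calibration: metrics.EvaluationReport
    validation: metrics.EvaluationReport


@dataclass
class ComparisonResult:
    arms: dict[str, ArmResult]
    table: pd.DataFrame


def _load_inputs(cfg: RunConfig) -> tuple[SpectralDataset, np.ndarray]:
    if cfg.simulate is not None:
        ds, w, _ = generate_dataset(cfg.simulate, seed=cfg.seed)
        return ds, w
    ds = SpectralDataset.from_csv(cfg.spectra_csv)
    table = load_water_table(cfg.water_csv)
    try:
        w = table.loc[ds.sample_ids].to_numpy()
    except KeyError as exc:
        raise ValueError(f"water table is missing spectral sample ids: {exc}") from exc
    return ds, w


def prepare_features(
    ds: SpectralDataset,
    cfg: RunConfig,
    outdir: Path | None = None,
) -> CrossVariableMatrix:
    """Noise-band removal, smoothing, transform chain and cross-variable build."""
    masked, mask = remove_noise_bands(ds, cfg.excluded_bands)
    smoothed = smooth_dataset(masked, mask)
    transformed = transform_spectra(smoothed, mask)
    zmat = build_cross_variables(transformed, wavelengths=cfg.wavelengths)
    if outdir is not None:
        smoothed.to_csv(outdir / "spectra_smoothed.csv")
        transformed.to_csv(outdir / "spectra_transformed.csv")
        zmat.to_csv(outdir / "cross_variables.csv", outdir / "cross_variables_manifest.csv")
    return zmat


def _split(cfg: RunConfig, method: str, w: np.ndarray, ids: Sequence[str]) -> sampling.SplitResult:
    n = len(ids)
    if method == "equidistant":
        return sampling.equidistant_split(
            w, ratio=cfg.split_ratio, offset=cfg.equidistant_offset,
            sample_ids=ids, seed=cfg.seed,
        )
    if method == "random":
        return sampling.random_split(list(ids), n_val=n // (cfg.split_ratio + 1), seed=cfg.seed)
    raise ValueError(f"unknown split method {method!r}")


def run_single_arm(
    cfg: RunConfig,
    method: str,
    _prepared: tuple[CrossVariableMatrix, np.ndarray] | None = None,
) -> ArmResult:
    """One full calibration run: the model is fit on the calibration subset only
    and both subsets are scored."""
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "config.yaml")
    if _prepared is None:
        ds, w = _load_inputs(cfg)
        if outdir is not None:
            ds.to_csv(outdir / "spectra_raw.csv")
            pd.DataFrame({"sample_id": ds.sample_ids, "water_content": w}).to_csv(
                outdir / "water.csv", index=False
            )
        zmat = prepare_features(ds, cfg, outdir)
    else:
        zmat, w = _prepared
    split = _split(cfg, method, w, zmat.sample_ids)
    summary = sampling.summarize_split(split, w)

    cal, val = split.calibration_idx, split.validation_idx
    Zcal = CrossVariableMatrix(
        sample_ids=[zmat.sample_ids[i] for i in cal],
        names=zmat.names, pairs=zmat.pairs, values=zmat.values[cal],
    )
    model = stepwise_select(Zcal, w[cal], alpha_in=cfg.alpha_in, alpha_out=cfg.alpha_out)
    cal_report = metrics.evaluate(w[cal], model.predict(zmat.values[cal][:, _sel(zmat, model)]),
                                  subset="calibration", r2_form=cfg.r2_form)
    val_report = metrics.evaluate(w[val], model.predict(zmat.values[val][:, _sel(zmat, model)]),
                                  subset="validation", r2_form=cfg.r2_form)
    result = ArmResult(method, model, split, summary, cal_report, val_report)
    if outdir is not None:
        split.to_csv(outdir / f"split_{method}.csv")
        sampling.format_summary(summary).to_csv(outdir / f"summary_{method}.csv")
        (outdir / f"model_{method}.txt").write_text(model.report() + "\n")
        pd.DataFrame([cal_report.to_dict(), val_report.to_dict()]).to_csv(
            outdir / f"evaluation_{method}.csv", index=False
        )
    return result


def _sel(zmat: CrossVariableMatrix, model: StepwiseModel) -> list[int]:
    return [zmat.names.index(nm) for nm in model.variable_names]


def run_comparison(cfg: RunConfig) -> ComparisonResult:
    """Both arms on the same dataset plus a side-by-side validation metric table."""
    ds, w = _load_inputs(cfg)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "config.yaml")
        ds.to_csv(outdir / "spectra_raw.csv")
    zmat = prepare_features(ds, cfg, outdir)
    arms = {
        method: run_single_arm(cfg, method, _prepared=(zmat, w))
        for method in ("equidistant", "random")
    }
    table = metrics.comparison_table(
        {method: arm.validation for method, arm in arms.items()}
    )
    if outdir is not None:
        table.to_csv(outdir / "comparison.csv")
    return ComparisonResult(arms=arms, table=table)


def replicate_comparison(
    cfg: RunConfig,
    n_replicates: int = 200,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Repeat the two-arm comparison over seeded synthetic datasets.

    Returns one row per (replicate, method) with the validation metrics and the
    calibration/validation water-content mean gap — the balance quantity
    systematic splitting is meant to shrink.  Requires a simulation config.
    """
    if cfg.simulate is None:
        raise ValueError("multi-replicate mode needs a simulation config")
    rows = []
    for rep in range(n_replicates):
        rep_cfg = RunConfig(**{**asdict_shallow(cfg), "seed": base_seed + rep, "outdir": None})
        result = run_comparison(rep_cfg)
        for method, arm in result.arms.items():
            gap = abs(arm.summary.loc["Calibration", "mean"] - arm.summary.loc["Validation", "mean"])
            rows.append(
                {
                    "replicate": rep,
                    "method": method,
                    "mean_gap": gap,
                    "val_r2": arm.validation.r2,
                    "val_rmse": arm.validation.rmse,
                    "val_re": arm.validation.re,
                    "cal_r2": arm.calibration.r2,
                }
            )
    return pd.DataFrame(rows)


def asdict_shallow(cfg: RunConfig) -> dict:
    """Field dict of a RunConfig without recursing into the simulation config."""
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}
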