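"""Config-driven orchestration: simulate → preprocess → screen → select → evaluate.

A :class:`PipelineConfig` (a flat YAML document) fully determines a run: the
input files or synthetic-generator block, every stage's parameters, and one
master seed from which all stage seeds are derived.  ``run_pipeline`` writes
per-order derivative spectra, correlation profiles and summaries, selection
reports, the metrics table, and a manifest sufficient to reproduce the run
byte-for-byte.  A failed stage leaves a ``FAILED`` marker next to whatever
partial outputs exist.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import read_spectra, read_traits, write_spectra, write_traits
from .learners import LEARNERS
from .model import LeafChlorophyllModel
from .preprocess import DEFAULT_ORDERS
from .selection import SelectionConfig
from .synth import SpectrumModelParams, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

_FLOAT_FMT = "%.10g"


class PipelineError(ValueError):
    """User-facing configuration or input error."""


@dataclass
class PipelineConfig:
    """Flat, human-readable description of a full pipeline run."""

    # inputs: either file paths or a synthetic block
    spectra_csv: str | None = None
    traits_csv: str | None = None
    synthetic_n: int | None = 293
    synthetic_noise_sd: float = 0.005
    # preprocessing
    trim_low: int = 400
    trim_high: int = 2400
    sg_window: int = 9
    sg_polyorder: int = 2
    orders: list = field(default_factory=lambda: list(DEFAULT_ORDERS))
    # screening
    alpha: float = 0.01
    # selection
    selection_low: int = 400
    selection_high: int = 900
    omega: int = 100
    edf_runs: int = 50
    bms_draws: int = 1000
    replications: int = 50
    ga_population: int = 30
    ga_generations: int = 100
    n_calibration: int | None = None
    # evaluation
    split_sizes: list | None = None
    learners: list = field(default_factory=lambda: list(LEARNERS))
    # run
    seed: int = 0
    out_dir: str = "leafspec_run"

    def __post_init__(self) -> None:
        has_files = self.spectra_csv is not None and self.traits_csv is not None
        if not has_files and self.synthetic_n is None:
            raise PipelineError(
                "config must give spectra_csv+traits_csv or a synthetic_n block"
            )
        for name in self.learners:
            if name not in LEARNERS:
                raise PipelineError(
                    f"unknown learner {name!r}; valid: {', '.join(LEARNERS)}"
                )
        if not self.trim_low < self.trim_high:
            raise PipelineError("trim_low must be below trim_high")

    # -- (de)serialisation ---------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {', '.join(sorted(unknown))}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise PipelineError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            omega=self.omega,
            edf_runs=self.edf_runs,
            bms_draws=self.bms_draws,
            replications=self.replications,
            ga_population=self.ga_population,
            ga_generations=self.ga_generations,
            n_calibration=self.n_calibration,
        )


def _load_inputs(cfg: PipelineConfig, seed: int):
    if cfg.spectra_csv is not None:
        spectra = read_spectra(cfg.spectra_csv)
        traits = read_traits(cfg.traits_csv)
        if traits.sample_ids != spectra.sample_ids:
            raise PipelineError("spectra and trait files disagree on sample ids")
        return spectra, traits
    params = SpectrumModelParams(noise_sd=cfg.synthetic_noise_sd)
    return generate_dataset(cfg.synthetic_n, params=params, seed=seed)


def run_pipeline(cfg: PipelineConfig, verbose: bool = False) -> Path:
    """Execute all stages and write the report bundle; returns the run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        rng = np.random.default_rng(cfg.seed)
        data_seed = int(rng.integers(2**31))
        fit_seed = int(rng.integers(2**31))

        spectra, traits = _load_inputs(cfg, data_seed)
        write_spectra(spectra, out / "spectra.csv")
        write_traits(traits, out / "traits.csv")

        model = LeafChlorophyllModel(
            spectra,
            traits,
            trim=(cfg.trim_low, cfg.trim_high),
            sg_window=cfg.sg_window,
            sg_polyorder=cfg.sg_polyorder,
            orders=cfg.orders,
            selection_range=(cfg.selection_low, cfg.selection_high),
            selection=cfg.selection_config(),
            split_sizes=None if cfg.split_sizes is None else tuple(cfg.split_sizes),
            learners=cfg.learners,
            alpha=cfg.alpha,
        )
        res = model.fit(seed=fit_seed)

        fod_dir = out / "fod"
        fod_dir.mkdir(exist_ok=True)
        for fod in res.fod_results:
            tag = f"{fod.order:g}".replace(".", "p")
            df = fod.spectra.to_dataframe()
            df.to_csv(fod_dir / f"order_{tag}.csv", index=False,
                      float_format=_FLOAT_FMT)
            np.savetxt(
                fod_dir / f"order_{tag}_valid_bands.txt",
                fod.spectra.wavelengths[fod.valid_mask],
                fmt="%d",
            )

        corr_dir = out / "correlation"
        corr_dir.mkdir(exist_ok=True)
        for order, prof in res.correlations.items():
            tag = f"{order:g}".replace(".", "p")
            prof.to_frame().to_csv(
                corr_dir / f"order_{tag}_profile.csv", index=False,
                float_format=_FLOAT_FMT,
            )
        with open(corr_dir / "summary.json", "w") as fh:
            json.dump(
                [p.summary_dict() for p in res.correlations.values()], fh, indent=2
            )

        sel_dir = out / "selection"
        sel_dir.mkdir(exist_ok=True)
        for order, sel in res.selections.items():
            tag = f"{order:g}".replace(".", "p")
            with open(sel_dir / f"order_{tag}.json", "w") as fh:
                json.dump(sel.summary_dict(), fh, indent=2)
            sel.replicates.drop(columns=["subset"]).to_csv(
                sel_dir / f"order_{tag}_replicates.csv", index=False,
                float_format=_FLOAT_FMT,
            )

        if res.evaluation is not None:
            res.evaluation.long().to_csv(
                out / "metrics.csv", index=False, float_format=_FLOAT_FMT
            )
            best = res.evaluation.best("validation", "r2")
            res.evaluation.scatter_frame(
                best["order"], best["algorithm"], "validation"
            ).to_csv(out / "scatter_best_validation.csv", index=False,
                     float_format=_FLOAT_FMT)

        with open(out / "summary.txt", "w") as fh:
            fh.write(res.summary() + "\n")

        manifest = {
            "leafspec_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config": asdict(cfg),
            "derived_seeds": {"data": data_seed, "fit": fit_seed,
                              **res.stage_seeds},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        if verbose:
            print(res.summary())
        return out
    except Exception:
        failed_marker.write_text("pipeline stage failed; partial outputs retained\n")
        raise
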