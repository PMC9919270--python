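"""Statsmodels-style facade over the whole calibration pipeline.

:class:`LeafChlorophyllModel` binds a :class:`~leafspec.containers.SpectraSet`
and its paired chlorophyll values to the full processing chain — edge trim,
Savitzky–Golay smoothing, the fractional-derivative sweep, per-order Pearson
screening, VCPA-GA wavelength selection, and the five-learner evaluation
grid.  ``fit(seed)`` runs the chain deterministically and returns a
:class:`LeafChlorophyllResults` that carries every intermediate product and
renders a human-readable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import SpectraSet, TraitVector, read_spectra, read_traits
from .correlation import CorrelationProfile, critical_r, pearson_profile, summarize_profile
from .learners import LEARNERS, EvaluationReport, SplitSpec, evaluate_grid, make_split
from .preprocess import DEFAULT_ORDERS, FODResult, fod_sweep, savgol_smooth, trim_edges
from .selection import SelectionConfig, SelectionResult, vcpa_ga_select

__all__ = ["LeafChlorophyllModel", "LeafChlorophyllResults"]


class LeafChlorophyllModel:
    """Leaf chlorophyll calibration from hyperspectral reflectance.

    Parameters
    ----------
    spectra, traits
        Paired samples; trait order must match spectra rows.
    trim : (low, high) nm
        Noisy edge bands outside this closed interval are dropped (default
        400–2400 nm).
    sg_window, sg_polyorder
        Savitzky–Golay smoothing parameters (default 9-band window, degree 2).
    orders
        Fractional-derivative sweep (default 0…2 by 0.2).
    selection_range : (low, high) nm
        Wavelength window handed to VCPA-GA (default 400–900 nm, the
        visible/near-infrared region where chlorophyll is informative).
    selection
        :class:`SelectionConfig`; defaults to the full-scale study settings.
    split_sizes
        Train/test/validation sizes (default 187/59/47 scaled to n).
    learners, learner_params
        Which regression learners to evaluate and optional per-learner
        hyperparameter overrides.
    alpha
        Significance level of the per-band correlation screen.
    """

    def __init__(
        self,
        spectra: SpectraSet,
        traits: TraitVector | np.ndarray,
        *,
        trim: tuple[int, int] = (400, 2400),
        sg_window: int = 9,
        sg_polyorder: int = 2,
        orders: Sequence[float] = DEFAULT_ORDERS,
        selection_range: tuple[int, int] = (400, 900),
        selection: SelectionConfig | None = None,
        split_sizes: tuple[int, int, int] | None = None,
        learners: Sequence[str] = LEARNERS,
        learner_params: dict | None = None,
        alpha: float = 0.01,
    ) -> None:
        if isinstance(traits, TraitVector):
            if len(traits) != spectra.n_samples:
                raise ValueError("traits and spectra disagree on sample count")
            self.traits = traits
        else:
            y = np.asarray(traits, dtype=float).ravel()
            if y.size != spectra.n_samples:
                raise ValueError("traits and spectra disagree on sample count")
            self.traits = TraitVector(sample_ids=list(spectra.sample_ids), lcc=y)
        self.spectra = spectra
        self.trim = trim
        self.sg_window = sg_window
        self.sg_polyorder = sg_polyorder
        self.orders = tuple(round(float(v), 10) for v in orders)
        self.selection_range = selection_range
        self.selection_config = selection or SelectionConfig()
        self.split_sizes = split_sizes
        self.learners = tuple(learners)
        self.learner_params = learner_params
        self.alpha = alpha

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_dataframe(cls, spectra_df: pd.DataFrame, trait_df: pd.DataFrame, **kw):
        spectra = SpectraSet.from_dataframe(spectra_df)
        traits = TraitVector(
            sample_ids=trait_df["sample_id"].astype(str).tolist(),
            lcc=trait_df["lcc_ug_cm2"].to_numpy(dtype=float),
            spad=trait_df["spad"].to_numpy(dtype=float)
            if "spad" in trait_df.columns
            else None,
        )
        return cls(spectra, traits, **kw)

    @classmethod
    def from_files(cls, spectra_csv, trait_csv, **kw):
        return cls(read_spectra(spectra_csv), read_traits(trait_csv), **kw)

    # -- fitting --------------------------------------------------------
    def fit(self, seed: int = 0, stages: Sequence[str] = ("screen", "select", "evaluate")) -> "LeafChlorophyllResults":
        """Run the calibration chain; ``stages`` can restrict how far it goes."""
        rng = np.random.default_rng(seed)
        stage_seeds = {
            name: int(rng.integers(2**31))
            for name in ("split", "selection", "evaluation")
        }
        y = self.traits.lcc

        trimmed = trim_edges(self.spectra, *self.trim)
        smoothed = savgol_smooth(trimmed, self.sg_window, self.sg_polyorder)
        fods = fod_sweep(smoothed, self.orders)

        correlations: dict[float, CorrelationProfile] = {}
        if "screen" in stages:
            r_crit = critical_r(self.spectra.n_samples, self.alpha)
            for fod in fods:
                r = pearson_profile(fod, y)
                correlations[fod.order] = summarize_profile(
                    r, r_crit, fod.spectra.wavelengths, order=fod.order
                )

        selections: dict[float, SelectionResult] = {}
        if "select" in stages:
            lo, hi = self.selection_range
            for fod in fods:
                keep = (
                    (fod.spectra.wavelengths >= lo)
                    & (fod.spectra.wavelengths <= hi)
                    & fod.valid_mask
                )
                wl = fod.spectra.wavelengths[keep]
                selections[fod.order] = vcpa_ga_select(
                    fod.spectra.reflectance[:, keep],
                    y,
                    self.selection_config,
                    seed=stage_seeds["selection"],
                    wavelengths=wl,
                    order=fod.order,
                )

        evaluation = None
        split = make_split(self.spectra.n_samples, self.split_sizes, stage_seeds["split"])
        if "evaluate" in stages and selections:
            evaluation = evaluate_grid(
                fods,
                selections,
                y,
                split,
                learners=self.learners,
                hyper=self.learner_params,
                seed=stage_seeds["evaluation"],
            )

        return LeafChlorophyllResults(
            model=self,
            seed=seed,
            stage_seeds=stage_seeds,
            preprocessed=smoothed,
            fod_results=fods,
            correlations=correlations,
            selections=selections,
            split=split,
            evaluation=evaluation,
        )


@dataclass
class LeafChlorophyllResults:
    """Everything the fitted calibration produced, with reporting helpers."""

    model: LeafChlorophyllModel
    seed: int
    stage_seeds: dict
    preprocessed: SpectraSet
    fod_results: list[FODResult]
    correlations: dict[float, CorrelationProfile]
    selections: dict[float, SelectionResult]
    split: SplitSpec
    evaluation: EvaluationReport | None

    # -- tables ---------------------------------------------------------
    def correlation_table(self) -> pd.DataFrame:
        """Per-order screening summary: Tb/Pb/Nb counts and max |r|."""
        return pd.DataFrame(
            [p.summary_dict() for p in self.correlations.values()]
        )

    def selection_table(self) -> pd.DataFrame:
        """Per-order Nvar/Nlvs/RMSEC/RMSECV/RMSEP."""
        rows = []
        for sel in self.selections.values():
            d = sel.summary_dict()
            d.pop("wavelengths_nm")
            rows.append(d)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the fitted calibration."""
        lines = [
            "Leaf chlorophyll calibration",
            "=" * 60,
            f"samples: {self.model.spectra.n_samples}   "
            f"bands after trim: {self.preprocessed.n_bands} "
            f"({self.preprocessed.wavelengths[0]}-{self.preprocessed.wavelengths[-1]} nm)",
            f"orders: {', '.join(f'{v:g}' for v in self.model.orders)}   seed: {self.seed}",
        ]
        if self.correlations:
            tab = self.correlation_table()
            lines += ["", "Correlation screen (alpha=%g):" % self.model.alpha,
                      tab.to_string(index=False, float_format=lambda v: f"{v:.4f}")]
        if self.selections:
            tab = self.selection_table()
            lines += ["", "VCPA-GA selection:",
                      tab.to_string(index=False, float_format=lambda v: f"{v:.3f}")]
        if self.evaluation is not None:
            best = self.evaluation.best("validation", "r2")
            lines += [
                "",
                f"Best validation model: order {best['order']:g} / {best['algorithm']}"
                f"  R2={best['validation_r2']:.3f}  MAE={best['validation_mae']:.2f}"
                f"  RMSE={best['validation_rmse']:.2f}  RPIQ={best['validation_rpiq']:.2f}",
            ]
        return "\n".join(lines)

    # -- plots ----------------------------------------------------------
    def plot_correlation(self, orders: Sequence[float] | None = None, ax=None):
        """Correlation-vs-wavelength curves for the chosen orders."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        for order in orders or self.correlations:
            prof = self.correlations[order]
            ax.plot(prof.wavelengths, prof.r, lw=0.8, label=f"v={order:g}")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("Pearson r vs LCC")
        ax.legend(fontsize=7, ncol=4)
        return ax

    def plot_predictions(self, order: float, learner: str, split: str = "validation", ax=None):
        """Measured-vs-estimated scatter with the 1:1 line."""
        import matplotlib.pyplot as plt

        if self.evaluation is None:
            raise ValueError("evaluation stage was not run")
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        df = self.evaluation.scatter_frame(order, learner, split)
        ax.scatter(df["measured"], df["estimated"], s=12, alpha=0.7)
        lims = [df.min().min(), df.max().max()]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("measured LCC (μg·cm⁻²)")
        ax.set_ylabel("estimated LCC (μg·cm⁻²)")
        ax.set_title(f"order {order:g} / {learner} ({split})")
        return ax
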