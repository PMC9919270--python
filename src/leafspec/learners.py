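"""Multi-learner calibration and the R²/MAE/RMSE/RPIQ evaluation harness.

Five regression learners common in leaf-trait spectroscopy are trained on
the selected bands of each derivative order: ridge regression (RR), random
forest (RF), gradient-boosted trees (XGBoost), support vector regression
with a radial-basis kernel (SVR), and Gaussian process regression (GPR).
Samples are split once into train / test / validation parts (187/59/47 for
the default 293-sample campaign) and each fitted learner is scored on all
three with

    R²   = 1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ)²
    MAE  = (1/n) Σ |yᵢ−ŷᵢ|
    RMSE = sqrt( Σ(yᵢ−ŷᵢ)² / n )
    RPIQ = (Q3 − Q1) / RMSE

where Q1/Q3 are the quartiles of the observed values of the evaluated split
(linear-interpolation estimator).  RPIQ is scale-robust and is reported for
the validation split, mirroring the usual calibration-table layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.linear_model import Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .preprocess import FODResult
from .selection import SelectionResult

__all__ = [
    "LEARNERS",
    "SplitSpec",
    "Metrics",
    "EvaluationReport",
    "make_split",
    "train_learner",
    "metrics",
    "evaluate_grid",
]

LEARNERS = ("RR", "RF", "XGBoost", "SVR", "GPR")

#: fixed library-typical hyperparameters, echoed in run manifests
DEFAULT_HYPER: dict[str, dict] = {
    "RR": {"alpha": 1.0},
    "RF": {"n_estimators": 500},
    "XGBoost": {"max_depth": 6, "learning_rate": 0.1, "n_estimators": 200},
    "SVR": {"C": 10.0, "gamma": "scale"},
    "GPR": {},
}


@dataclass
class SplitSpec:
    """A disjoint, exhaustive train/test/validation assignment."""

    sizes: tuple[int, int, int]
    seed: int
    assignment: np.ndarray  # 0=train, 1=test, 2=validation

    @property
    def train_index(self) -> np.ndarray:
        return np.flatnonzero(self.assignment == 0)

    @property
    def test_index(self) -> np.ndarray:
        return np.flatnonzero(self.assignment == 1)

    @property
    def validation_index(self) -> np.ndarray:
        return np.flatnonzero(self.assignment == 2)

    def index(self, split: str) -> np.ndarray:
        return {"train": self.train_index, "test": self.test_index,
                "validation": self.validation_index}[split]


def make_split(
    n: int, sizes: tuple[int, int, int] | None = None, seed: int = 0
) -> SplitSpec:
    """Uniform random three-way split; default sizes 187/59/47 scaled to n."""
    if sizes is None:
        if n == 293:
            sizes = (187, 59, 47)
        else:
            tr = int(round(n * 187 / 293))
            te = int(round(n * 59 / 293))
            sizes = (tr, te, n - tr - te)
    if sum(sizes) != n:
        raise ValueError(f"split sizes {sizes} do not sum to n={n}")
    if min(sizes) < 2:
        raise ValueError("every split needs at least 2 samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    assignment[perm[: sizes[0]]] = 0
    assignment[perm[sizes[0] : sizes[0] + sizes[1]]] = 1
    assignment[perm[sizes[0] + sizes[1] :]] = 2
    return SplitSpec(sizes=tuple(sizes), seed=seed, assignment=assignment)


def _build_estimator(name: str, hyper: dict | None, seed: int):
    params = dict(DEFAULT_HYPER.get(name, {}))
    if hyper:
        params.update(hyper)
    if name == "RR":
        return Ridge(**params)
    if name == "RF":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if name == "XGBoost":
        return XGBRegressor(
            random_state=seed, n_jobs=1, verbosity=0, tree_method="hist", **params
        )
    if name == "SVR":
        return SVR(kernel="rbf", **params)
    if name == "GPR":
        kernel = params.pop("kernel", None) or RBF(
            length_scale=1.0, length_scale_bounds=(1e-3, 1e5)
        ) + WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-12, 1e5))
        return GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=seed, **params
        )
    raise ValueError(f"unknown learner {name!r}; valid names: {', '.join(LEARNERS)}")


def train_learner(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    hyper: dict | None = None,
    seed: int = 0,
):
    """Fit one named learner on (centred) training data.

    Inputs are mean-centred with training means only, applied inside the
    returned pipeline at prediction time — no leakage of evaluation rows.
    """
    est = _build_estimator(name, hyper, seed)
    model = Pipeline(
        [("center", StandardScaler(with_mean=True, with_std=False)), ("model", est)]
    )
    with warnings.catch_warnings():
        # GPR's marginal-likelihood optimiser is chatty near kernel bounds
        warnings.simplefilter("ignore")
        model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=float))
    return model


class Metrics(NamedTuple):
    r2: float
    mae: float
    rmse: float
    rpiq: float


def metrics(
    y: np.ndarray, y_hat: np.ndarray, quartile_source: np.ndarray | None = None
) -> Metrics:
    """R², MAE, RMSE and RPIQ of predictions against observations.

    Quartiles for RPIQ come from ``quartile_source`` (default: the observed
    ``y`` itself).  Degenerate cases yield NaN sentinels: R² when the
    observations are constant, RPIQ when RMSE is zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("y and y_hat must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    resid = y - y_hat
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(sse / y.size))
    mae = float(np.mean(np.abs(resid)))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    src = y if quartile_source is None else np.asarray(quartile_source, dtype=float)
    q1, q3 = np.percentile(src, [25, 75])
    rpiq = (q3 - q1) / rmse if rmse > 0 else float("nan")
    return Metrics(r2=r2, mae=mae, rmse=rmse, rpiq=float(rpiq))


@dataclass
class EvaluationReport:
    """Per-(order × learner) metrics on all three splits.

    ``table`` holds one row per order/learner combination with columns
    ``{split}_{metric}`` plus ``validation_rpiq``; ``long()`` reshapes it to
    the tidy (order, algorithm, split, r2, mae, rmse, rpiq) layout for CSV
    export; ``predictions`` keeps the raw measured/estimated pairs for
    scatter plots.
    """

    table: pd.DataFrame
    predictions: dict  # (order, learner, split) -> (y, y_hat)
    split: SplitSpec

    def long(self) -> pd.DataFrame:
        rows = []
        for _, row in self.table.iterrows():
            for split in ("train", "test", "validation"):
                rows.append(
                    {
                        "order": row["order"],
                        "algorithm": row["algorithm"],
                        "split": split,
                        "r2": row[f"{split}_r2"],
                        "mae": row[f"{split}_mae"],
                        "rmse": row[f"{split}_rmse"],
                        "rpiq": row[f"{split}_rpiq"],
                    }
                )
        return pd.DataFrame(rows)

    def best(self, split: str = "validation", metric: str = "r2") -> pd.Series:
        col = f"{split}_{metric}"
        asc = metric in ("mae", "rmse")
        return self.table.sort_values(col, ascending=asc).iloc[0]

    def scatter_frame(self, order: float, learner: str, split: str = "validation"):
        y, y_hat = self.predictions[(order, learner, split)]
        return pd.DataFrame({"measured": y, "estimated": y_hat})


def evaluate_grid(
    fod_results: Sequence[FODResult],
    selections: dict[float, SelectionResult | np.ndarray],
    y: np.ndarray,
    split: SplitSpec,
    learners: Sequence[str] = LEARNERS,
    hyper: dict[str, dict] | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Train every learner on every order's selected bands and score it.

    ``selections`` maps each derivative order to either a
    :class:`SelectionResult` or a plain array of selected wavelengths (nm).
    Orders without a selection are skipped with a warning.  A full default
    sweep yields 11 orders × 5 learners = 55 report rows.
    """
    y = np.asarray(y, dtype=float)
    rows = []
    predictions: dict = {}
    for fod in fod_results:
        order = round(float(fod.order), 10)
        if order not in selections:
            warnings.warn(f"no selection for order {order}; skipped", stacklevel=2)
            continue
        sel = selections[order]
        wl_sel = sel.wavelengths if isinstance(sel, SelectionResult) else np.asarray(sel)
        band_pos = np.searchsorted(fod.spectra.wavelengths, wl_sel)
        X = fod.spectra.reflectance[:, band_pos]
        for name in learners:
            model = train_learner(
                name,
                X[split.train_index],
                y[split.train_index],
                (hyper or {}).get(name),
                seed=seed,
            )
            row = {"order": order, "algorithm": name, "nvar": int(wl_sel.size)}
            for split_name in ("train", "test", "validation"):
                idx = split.index(split_name)
                y_hat = np.asarray(model.predict(X[idx]), dtype=float).ravel()
                m = metrics(y[idx], y_hat)
                row.update(
                    {
                        f"{split_name}_r2": m.r2,
                        f"{split_name}_mae": m.mae,
                        f"{split_name}_rmse": m.rmse,
                        f"{split_name}_rpiq": m.rpiq,
                    }
                )
                predictions[(order, name, split_name)] = (y[idx], y_hat)
            rows.append(row)
    return EvaluationReport(
        table=pd.DataFrame(rows), predictions=predictions, split=split
    )
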