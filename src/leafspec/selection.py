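"""VCPA-GA hybrid wavelength selection.

Variable combination population analysis (VCPA) shrinks a large band space
by repeating three moves along an exponentially decreasing schedule of
retained-variable counts:

1. **BMS** — binary matrix sampling draws K random band subsets (independent
   Bernoulli inclusions) over the surviving bands;
2. each subset is scored by the cross-validated error (RMSECV) of a PLS
   model restricted to it;
3. **MPA** — model population analysis computes, over the top fraction of
   subsets ranked by RMSECV, the appearance frequency of every band, and the
   schedule's next retained-count of highest-frequency bands survives.

Plain VCPA ends with an exhaustive best-subset search over the last ≤14
survivors, which tends to select very few bands.  The hybrid strategy
instead stops the shrinkage at ω variables (default 100) and hands them to a
genetic algorithm — binary band-inclusion chromosomes, tournament selection,
single-point crossover, bit-flip mutation, one elite — whose fitness is
again the PLS RMSECV.  The GA is effective in the compressed ω-space where
it would struggle on the raw 501-band space.

Selection operates strictly on a calibration subset; an independent test set
is held out up front and touched exactly once, to compute the final RMSEP.
The whole procedure is replicated R times (default 50) and the replication
with the lowest calibration RMSECV defines the reported subset, with
per-band selection frequencies retained for inspection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._pls import cv_score, cv_score_T, make_folds, pls_cv

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "bms_sample",
    "edf_schedule",
    "mpa_frequencies",
    "vcpa_shrink",
    "ga_optimize",
    "exhaustive_best_subset",
    "vcpa_ga_select",
    "vcpa_select",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables of the VCPA-GA strategy.

    Defaults follow the originating VCPA formulation (L=50 EDF runs, K=1000
    BMS draws at inclusion probability 0.5, top 10% of submodels in MPA) and
    standard GA practice; ω, the CV setup, the replication count and the
    193/100 calibration/test split follow the emulated study design.
    """

    omega: int = 100
    edf_runs: int = 50  # L
    bms_draws: int = 1000  # K
    bms_prob: float = 0.5
    mpa_top_fraction: float = 0.10
    max_latent: int = 10
    cv_folds: int = 5
    replications: int = 50
    ga_population: int = 30
    ga_generations: int = 100
    ga_crossover: float = 0.5
    ga_mutation: float = 0.01
    ga_tournament: int = 2
    n_calibration: int | None = None  # None -> 193/293 proportion
    plain_terminal_vars: int = 14  # plain-VCPA exhaustive-search cap

    def __post_init__(self) -> None:
        if self.omega < 1:
            raise ValueError("omega must be positive")
        if not 0 < self.mpa_top_fraction < 1:
            raise ValueError("mpa_top_fraction must lie in (0, 1)")
        if not 0 < self.bms_prob < 1:
            raise ValueError("bms_prob must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.edf_runs < 2:
            raise ValueError("need at least 2 EDF runs")
        if self.ga_population < 2 or self.ga_population % 2:
            raise ValueError("ga_population must be even and >= 2")

    def resolve_calibration(self, n: int) -> int:
        """Calibration-set size for ``n`` samples (193 when n=293)."""
        if self.n_calibration is not None:
            if not 1 < self.n_calibration < n:
                raise ValueError("n_calibration must leave a nonempty test set")
            return self.n_calibration
        return max(2, min(n - 1, int(round(n * 193 / 293))))


@dataclass
class SelectionResult:
    """Outcome of a replicated VCPA-GA run on one derivative order."""

    order: float
    selected: np.ndarray  # column indices into the screened matrix
    wavelengths: np.ndarray | None  # nm, if a grid was supplied
    nvar: int
    nlvs: int
    rmsec: float
    rmsecv: float
    rmsep: float
    frequency: np.ndarray  # per-band selection frequency across replications
    replicates: pd.DataFrame  # one row per replication
    calibration_index: np.ndarray
    test_index: np.ndarray

    def summary_dict(self) -> dict:
        return {
            "order": self.order,
            "Nvar": int(self.nvar),
            "Nlvs": int(self.nlvs),
            "RMSEC": float(self.rmsec),
            "RMSECV": float(self.rmsecv),
            "RMSEP": float(self.rmsep),
            "wavelengths_nm": None
            if self.wavelengths is None
            else [int(w) for w in self.wavelengths],
        }


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def bms_sample(
    p: int, K: int, prob: float = 0.5, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """K binary inclusion vectors over p bands; rows with <2 bands are redrawn."""
    if p < 2:
        raise ValueError("need at least 2 bands")
    if not 0 < prob < 1:
        raise ValueError("prob must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = (rng.random((K, p)) < prob)
    bad = M.sum(axis=1) < 2
    while bad.any():
        M[bad] = rng.random((int(bad.sum()), p)) < prob
        bad = M.sum(axis=1) < 2
    return M


def edf_schedule(p0: int, p_end: int, L: int) -> np.ndarray:
    """Retained-variable counts r_i = p0·e^(−k·i), i = 0…L−1, ending at p_end.

    The decay constant k is fixed by the endpoints; rounding is repaired so
    the counts are nonincreasing integers running from exactly p0 to p_end.
    """
    if not p0 > p_end >= 1:
        raise ValueError("need p0 > p_end >= 1")
    if L < 2:
        raise ValueError("need at least 2 schedule points")
    k = np.log(p0 / p_end) / (L - 1)
    counts = np.rint(p0 * np.exp(-k * np.arange(L))).astype(np.int64)
    counts[0], counts[-1] = p0, p_end
    counts = np.maximum(np.minimum.accumulate(counts), p_end)
    return counts


def mpa_frequencies(
    subsets: np.ndarray, scores: np.ndarray, top_fraction: float = 0.10
) -> np.ndarray:
    """Per-band appearance frequency among the best-scoring subsets.

    Subsets are ranked by ascending score (RMSECV); ties at the cutoff break
    by subset index (stable sort).  At least one subset is always kept.
    """
    subsets = np.asarray(subsets)
    scores = np.asarray(scores, dtype=float)
    if len(subsets) != len(scores):
        raise ValueError("subsets and scores must align")
    n_top = max(1, int(len(scores) * top_fraction))
    order = np.argsort(scores, kind="stable")
    return subsets[order[:n_top]].mean(axis=0)


def vcpa_shrink(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SelectionConfig,
    seed: int = 0,
    target: int | None = None,
) -> np.ndarray:
    """EDF-driven shrinkage of the band space down to ``target`` (default ω).

    Returns the sorted indices of the surviving bands.  If the band count is
    already at or below the target the input indices come back unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    goal = cfg.omega if target is None else target
    survivors = np.arange(p)
    if p <= goal:
        return survivors
    rng = np.random.default_rng(seed)
    fold_id = make_folds(y, cfg.cv_folds, int(rng.integers(2**31)))
    schedule = edf_schedule(p, goal, cfg.edf_runs)
    XT = np.ascontiguousarray(X.T)
    yc = np.ascontiguousarray(y)
    for r_target in schedule[1:]:
        if survivors.size <= r_target:
            continue
        XT_surv = np.ascontiguousarray(XT[survivors])
        M = bms_sample(survivors.size, cfg.bms_draws, cfg.bms_prob, rng)
        scores = np.empty(cfg.bms_draws)
        for k in range(cfg.bms_draws):
            scores[k] = cv_score_T(XT_surv[M[k]], yc, fold_id, cfg.max_latent)
        freq = mpa_frequencies(M, scores, cfg.mpa_top_fraction)
        # highest frequency wins; ties break toward the lower band index
        order = np.lexsort((np.arange(survivors.size), -freq))
        survivors = np.sort(survivors[order[:r_target]])
    return survivors


def _repair(chrom: np.ndarray, rng: np.random.Generator) -> None:
    if not chrom.any():
        chrom[rng.integers(chrom.size)] = True


def ga_optimize(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SelectionConfig,
    seed: int = 0,
    fold_id: np.ndarray | None = None,
) -> np.ndarray:
    """GA refinement over the ω-band space; returns selected column indices.

    Fitness is the (negated) minimum PLS RMSECV of the chromosome's band
    subset; folds are fixed for the whole run so fitness is deterministic and
    memoisable.  Elitism of one guarantees the best RMSECV is nonincreasing
    across generations.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    p = X.shape[1]
    XT = np.ascontiguousarray(X.T)
    rng = np.random.default_rng(seed)
    if fold_id is None:
        fold_id = make_folds(y, cfg.cv_folds, int(rng.integers(2**31)))
    else:
        rng.integers(2**31)  # keep the downstream draw sequence aligned
    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key not in cache:
            cache[key] = cv_score_T(XT[chrom], y, fold_id, cfg.max_latent)
        return cache[key]

    pop = rng.random((cfg.ga_population, p)) < 0.5
    for c in pop:
        _repair(c, rng)
    scores = np.array([fitness(c) for c in pop])
    for _gen in range(cfg.ga_generations):
        elite = pop[np.argmin(scores)].copy()
        new = [elite]
        while len(new) < cfg.ga_population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(cfg.ga_population, size=cfg.ga_tournament)
                parents.append(pop[contenders[np.argmin(scores[contenders])]].copy())
            a, b = parents
            if rng.random() < cfg.ga_crossover and p > 1:
                cut = int(rng.integers(1, p))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for c in (a, b):
                flip = rng.random(p) < cfg.ga_mutation
                c[flip] = ~c[flip]
                _repair(c, rng)
                if len(new) < cfg.ga_population:
                    new.append(c)
        pop = np.array(new)
        scores = np.array([fitness(c) for c in pop])
    best = pop[np.argmin(scores)]
    return np.flatnonzero(best)


def exhaustive_best_subset(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SelectionConfig,
    seed: int = 0,
    max_vars: int = 14,
) -> np.ndarray:
    """Best subset by full enumeration (plain-VCPA terminal step).

    Enumerates every nonempty subset of the ≤``max_vars`` columns of X and
    returns the one with the lowest PLS RMSECV (first-found wins ties).
    """
    p = X.shape[1]
    if p > max_vars:
        raise ValueError(f"exhaustive search capped at {max_vars} variables, got {p}")
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    fold_id = make_folds(y, cfg.cv_folds, int(rng.integers(2**31)))
    best_score, best_subset = np.inf, None
    for size in range(1, p + 1):
        for combo in itertools.combinations(range(p), size):
            cols = np.array(combo)
            score = cv_score(X[:, cols], y, fold_id, cfg.max_latent)
            if score < best_score:
                best_score, best_subset = score, cols
    return best_subset


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _split_calibration(n: int, n_cal: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return np.sort(perm[:n_cal]), np.sort(perm[n_cal:])


def _run_replicated(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SelectionConfig,
    seed: int,
    wavelengths: np.ndarray | None,
    order: float,
    refine,
) -> SelectionResult:
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n, p = X.shape
    n_cal = cfg.resolve_calibration(n)
    rng = np.random.default_rng(seed)
    cal_idx, test_idx = _split_calibration(n, n_cal, rng)
    X_cal, y_cal = X[cal_idx], y[cal_idx]
    X_test, y_test = X[test_idx], y[test_idx]

    rep_seeds = rng.integers(2**31, size=cfg.replications)
    records = []
    counts = np.zeros(p)
    for r, rep_seed in enumerate(rep_seeds):
        # leakage guard: selection must only ever see calibration rows
        assert X_cal.shape[0] == n_cal
        subset = refine(X_cal, y_cal, int(rep_seed))
        cv = pls_cv(
            X_cal[:, subset], y_cal, cfg.max_latent, cfg.cv_folds, int(rep_seed)
        )
        rmsep = float(
            np.sqrt(np.mean((y_test - cv.model.predict(X_test[:, subset])) ** 2))
        )
        counts[subset] += 1
        records.append(
            {
                "replication": r,
                "seed": int(rep_seed),
                "nvar": int(subset.size),
                "nlvs": cv.nlvs,
                "rmsec": cv.rmsec,
                "rmsecv": cv.rmsecv,
                "rmsep": rmsep,
                "subset": subset,
            }
        )
    reps = pd.DataFrame.from_records(records)
    best = int(reps["rmsecv"].idxmin())
    subset = reps.loc[best, "subset"]
    cv = pls_cv(
        X_cal[:, subset], y_cal, cfg.max_latent, cfg.cv_folds,
        int(reps.loc[best, "seed"]),
    )
    rmsep = float(
        np.sqrt(np.mean((y_test - cv.model.predict(X_test[:, subset])) ** 2))
    )
    return SelectionResult(
        order=order,
        selected=np.asarray(subset),
        wavelengths=None if wavelengths is None else np.asarray(wavelengths)[subset],
        nvar=int(subset.size),
        nlvs=cv.nlvs,
        rmsec=cv.rmsec,
        rmsecv=cv.rmsecv,
        rmsep=rmsep,
        frequency=counts / cfg.replications,
        replicates=reps,
        calibration_index=cal_idx,
        test_index=test_idx,
    )


def vcpa_ga_select(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SelectionConfig | None = None,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    order: float = 0.0,
) -> SelectionResult:
    """Replicated VCPA shrinkage + GA refinement with held-out RMSEP.

    The samples are split once into calibration and test sets; all R
    replications of (shrink → GA) run on the calibration set only, the
    replication with the lowest calibration RMSECV defines the final subset,
    and RMSEP is the error of its PLS model on the untouched test set.
    """
    cfg = cfg or SelectionConfig()

    def refine(Xc, yc, rep_seed):
        survivors = vcpa_shrink(Xc, yc, cfg, rep_seed)
        if survivors.size <= 2:
            return survivors
        ga_idx = ga_optimize(Xc[:, survivors], yc, cfg, rep_seed + 1)
        return survivors[ga_idx]

    return _run_replicated(X, y, cfg, seed, wavelengths, order, refine)


def vcpa_select(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SelectionConfig | None = None,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    order: float = 0.0,
) -> SelectionResult:
    """Plain VCPA: shrink to ≤14 survivors, then exhaustive best-subset."""
    cfg = cfg or SelectionConfig()

    def refine(Xc, yc, rep_seed):
        survivors = vcpa_shrink(Xc, yc, cfg, rep_seed, target=cfg.plain_terminal_vars)
        best = exhaustive_best_subset(
            Xc[:, survivors], yc, cfg, rep_seed + 1, max_vars=cfg.plain_terminal_vars
        )
        return survivors[best]

    return _run_replicated(X, y, cfg, seed, wavelengths, order, refine)
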