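"""Three-parameter thermodynamic model of dimeric-binding PPI scores.

The measured phenotype (PPI score, growth generations relative to the
wild-type interaction) is modelled as arising from a two-state binding
equilibrium.  With the dimensionless parameters

* ``a_total``  = A_T / AB_wt  — total protein A over wild-type complex,
* ``b_total``  = B_T / AB_wt,
* ``bg``       = b / AB_wt    — background growth over wild-type complex,

and the derived quantities ``K = bg``, ``X = (K + a_total)/(K + 1)``,
``Y = (K + b_total)/(K + 1)``, the binding free-energy change of a variant
relative to wild type is

    ddG = RT * log[ (X - p)(Y - p) / ( (p(K+1) - K) (X - 1)(Y - 1) ) ]

for a PPI score ``p``, and inverting gives ``p`` as the smaller root of a
quadratic in ``p`` (the larger root exceeds the maximum score the
parameters allow).  Free-energy changes of double mutants are assumed
additive, ``ddG_d = ddG_s1 + ddG_s2``, so the model predicts the double's
score from its two singles' scores with three free parameters.  All
energies are expressed in units of RT (RT = 1, arbitrary units).

Scores live in the open interval ``(K/(K+1), min(X, Y))``: the lower bound
is pure background growth, the upper bound is every molecule of the
limiting protein in complex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import split_double

__all__ = [
    "ThermoParams",
    "GridSpec",
    "FitResult",
    "DEFAULT_GRID",
    "CV_GRID",
    "ddg_from_ppi",
    "ppi_from_ddg",
    "predict_double_ppi",
    "fit_params_grid",
    "fit_params_refine",
    "assemble_fit_data",
    "monte_carlo_cv",
    "residual_interaction_scores",
    "variance_explained",
    "nonrandom_variance_fraction",
]


@dataclass(frozen=True)
class ThermoParams:
    """The three free parameters of the model (all relative to AB_wt)."""

    a_total: float
    b_total: float
    bg: float
    rt: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a_total > 1 and self.b_total > 1):
            raise ValueError("total protein must exceed the wild-type complex")
        if not self.bg > 0:
            raise ValueError("background growth must be positive")
        if not self.rt > 0:
            raise ValueError("rt must be positive")

    @property
    def K(self) -> float:
        return self.bg

    @property
    def X(self) -> float:
        return (self.K + self.a_total) / (self.K + 1.0)

    @property
    def Y(self) -> float:
        return (self.K + self.b_total) / (self.K + 1.0)

    @property
    def lower(self) -> float:
        """Lower asymptote of the score, K/(K+1): pure background growth."""
        return self.K / (self.K + 1.0)

    @property
    def upper(self) -> float:
        """Upper asymptote, min(X, Y): limiting protein fully in complex."""
        return min(self.X, self.Y)

    def astuple(self) -> tuple[float, float, float]:
        return (self.a_total, self.b_total, self.bg)


def ddg_from_ppi(ppi, params: ThermoParams):
    """Free-energy change (RT units) of a variant from its PPI score.

    Scores at or below the lower asymptote map to +inf, at or above the
    upper asymptote to -inf (sentinels, not errors).  Exact inverse of
    :func:`ppi_from_ddg` on the open interval.
    """
    p = np.asarray(ppi, dtype=float)
    K, X, Y, rt = params.K, params.X, params.Y, params.rt
    lo, hi = params.lower, params.upper
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (X - p) * (Y - p)
        den = (p * (K + 1.0) - K) * (X - 1.0) * (Y - 1.0)
        out = rt * np.log(num / den)
    out = np.where(p <= lo, np.inf, out)
    out = np.where(p >= hi, -np.inf, out)
    return out if out.ndim else float(out)


def _forward_from_expddg(E, params: ThermoParams):
    """Smaller quadratic root of the model given ``E = exp(ddG / RT)``.

    Evaluated in the numerically stable form 2C / (B + sqrt(B^2 - 4C)).
    ``E = inf`` maps to the lower asymptote and ``E = 0`` to the upper one;
    NaN (conflicting infinite energies upstream) propagates.
    """
    E = np.asarray(E, dtype=float)
    K, X, Y = params.K, params.X, params.Y
    c = (X - 1.0) * (Y - 1.0)
    with np.errstate(invalid="ignore", over="ignore"):
        B = c * (K + 1.0) * E + X + Y
        C = K * c * E + X * Y
        disc = B * B - 4.0 * C
        disc = np.where(disc < 0, 0.0, disc)  # guard roundoff at ddg -> -inf
        p = 2.0 * C / (B + np.sqrt(disc))
    p = np.where(np.isposinf(E), params.lower, p)
    return p if p.ndim else float(p)


def ppi_from_ddg(ddg, params: ThermoParams):
    """PPI score from a free-energy change (smaller root of the quadratic).

    Strictly decreasing in ``ddg``; ``ddg = 0`` returns exactly 1; the
    output lies in the open interval ``(K/(K+1), min(X, Y))`` for finite
    ``ddg`` and hits the asymptotes at +-inf.
    """
    ddg = np.asarray(ddg, dtype=float)
    with np.errstate(over="ignore"):
        E = np.exp(ddg / params.rt)
    out = _forward_from_expddg(E, params)
    # pin the exact wild type: the algebra guarantees p(0) = 1
    out = np.where(ddg == 0.0, 1.0, out)
    return out if out.ndim else float(out)


def _sum_ddg(d1, d2, errors: str):
    """Additive double-mutant energy with sentinel semantics.

    +inf dominates a finite term; (-inf) + (+inf) is ill-defined and either
    raises (``errors="raise"``) or yields NaN (``errors="nan"``).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    with np.errstate(invalid="ignore"):
        s = d1 + d2
    conflict = np.isinf(d1) & np.isinf(d2) & (np.sign(d1) != np.sign(d2))
    if conflict.any():
        if errors == "raise":
            raise ValueError(
                "conflicting infinite free-energy changes (+inf and -inf) "
                "for the two single mutants"
            )
        s = np.where(conflict, np.nan, s)
    return s


def predict_double_ppi(ppi_s1, ppi_s2, params: ThermoParams, errors: str = "raise"):
    """Predicted double-mutant PPI score from the two single-mutant scores.

    Equivalent to ``ppi_from_ddg(ddg_from_ppi(s1) + ddg_from_ppi(s2))``,
    with out-of-interval singles clamped to the asymptotes: a single at or
    below the lower asymptote forces the prediction to ``K/(K+1)``, one at
    or above the upper asymptote forces ``min(X, Y)`` (unless the other is
    at the opposite extreme, see ``errors``).  Symmetric in its arguments.
    """
    d = _sum_ddg(ddg_from_ppi(ppi_s1, params), ddg_from_ppi(ppi_s2, params), errors)
    return ppi_from_ddg(d, params)


# --------------------------------------------------------------------------
# Grid fitting


@dataclass(frozen=True)
class GridSpec:
    """Exhaustive-search grid over the three free parameters."""

    a_range: tuple[float, float] = (1.1, 2.0)
    a_step: float = 0.01
    b_range: tuple[float, float] = (1.1, 2.0)
    b_step: float = 0.01
    bg_range: tuple[float, float] = (0.3, 1.2)
    bg_step: float = 0.001

    def __post_init__(self) -> None:
        for (lo, hi), step in (
            (self.a_range, self.a_step),
            (self.b_range, self.b_step),
            (self.bg_range, self.bg_step),
        ):
            if step <= 0:
                raise ValueError("grid steps must be positive")
            if hi < lo:
                raise ValueError("grid ranges must be non-empty")

    @staticmethod
    def _axis(rng: tuple[float, float], step: float) -> np.ndarray:
        lo, hi = rng
        n = int(round((hi - lo) / step)) + 1
        vals = lo + step * np.arange(n)
        return vals[vals <= hi + 1e-12]

    def a_values(self) -> np.ndarray:
        return self._axis(self.a_range, self.a_step)

    def b_values(self) -> np.ndarray:
        return self._axis(self.b_range, self.b_step)

    def bg_values(self) -> np.ndarray:
        return self._axis(self.bg_range, self.bg_step)

    @property
    def n_points(self) -> int:
        return len(self.a_values()) * len(self.b_values()) * len(self.bg_values())


#: Grid used for the full-data fit.
DEFAULT_GRID = GridSpec()
#: Coarser grid used inside Monte-Carlo cross-validation.
CV_GRID = GridSpec((1.1, 1.6), 0.01, (1.1, 1.6), 0.01, (0.3, 1.0), 0.01)


@dataclass
class FitResult:
    """Best grid point and its objective (variance explained)."""

    params: ThermoParams
    variance_explained: float
    n_observations: int
    grid: GridSpec
    objective_grid: np.ndarray | None = field(default=None, repr=False)


def variance_explained(observed, predicted) -> float:
    """Fraction of variance explained: 1 - SS_res / SS_tot.

    SS_tot is taken around the observed mean.  Pairs where the prediction
    is NaN are excluded from both sums.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    ok = ~(np.isnan(obs) | np.isnan(pred))
    obs, pred = obs[ok], pred[ok]
    if obs.size < 2:
        raise ValueError("need at least 2 paired observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed scores have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _grid_objective(
    s1: np.ndarray, s2: np.ndarray, obs: np.ndarray, grid: GridSpec
) -> tuple[ThermoParams, float, np.ndarray]:
    """Sweep the grid, maximizing variance explained of the doubles.

    The per-point cost is kept linear in the number of observations by
    exponentiating the singles' energies once per point (the double's
    exp(ddG) is the product of the two singles' factors).  Ties are broken
    towards lexicographically smallest (bg, a_total, b_total) by iterating
    in ascending order with strict improvement.
    """
    u1, inv1 = np.unique(s1, return_inverse=True)
    u2, inv2 = np.unique(s2, return_inverse=True)
    mean_obs = obs.mean()
    ss_tot_full = float(np.sum((obs - mean_obs) ** 2))
    if ss_tot_full == 0.0:
        raise ValueError("observed doubles have zero variance")

    bg_vals = grid.bg_values()
    a_vals = grid.a_values()
    b_vals = grid.b_values()
    shape = (len(bg_vals), len(a_vals), len(b_vals))
    objective = np.full(shape, -np.inf)

    best = (-np.inf, None)
    for i, j, k in itertools.product(*(range(n) for n in shape)):
        params = ThermoParams(a_vals[j], b_vals[k], bg_vals[i])
        with np.errstate(over="ignore", invalid="ignore"):
            w1 = np.exp(ddg_from_ppi(u1, params))
            w2 = np.exp(ddg_from_ppi(u2, params))
            E = w1[inv1] * w2[inv2]  # inf * 0 -> NaN marks conflicts
        pred = _forward_from_expddg(E, params)
        bad = np.isnan(pred)
        if bad.any():
            ok = ~bad
            ss_res = float(np.sum((obs[ok] - pred[ok]) ** 2))
            ss_tot = float(np.sum((obs[ok] - mean_obs) ** 2))
        else:
            ss_res = float(np.sum((obs - pred) ** 2))
            ss_tot = ss_tot_full
        ve = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
        objective[i, j, k] = ve
        if ve > best[0]:
            best = (ve, params)
    if best[1] is None:
        raise ValueError("no valid grid point")
    return best[1], best[0], objective


def fit_params_grid(
    s1,
    s2,
    observed,
    grid: GridSpec = DEFAULT_GRID,
    keep_objective: bool = False,
) -> FitResult:
    """Exhaustive grid search for the three free parameters.

    ``s1``, ``s2`` and ``observed`` are aligned 1-D arrays: the two
    single-mutant scores and the observed double-mutant score of each
    (pooled, typically per-replicate) observation.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if not (s1.shape == s2.shape == obs.shape and s1.ndim == 1):
        raise ValueError("s1, s2 and observed must be aligned 1-D arrays")
    ok = ~(np.isnan(s1) | np.isnan(s2) | np.isnan(obs))
    if not ok.any():
        raise ValueError("no double has both singles measured")
    s1, s2, obs = s1[ok], s2[ok], obs[ok]
    params, ve, objective = _grid_objective(s1, s2, obs, grid)
    return FitResult(
        params=params,
        variance_explained=ve,
        n_observations=int(obs.size),
        grid=grid,
        objective_grid=objective if keep_objective else None,
    )


def fit_params_refine(
    s1,
    s2,
    observed,
    coarse: GridSpec,
    fine_steps: tuple[float, float, float] = (0.01, 0.01, 0.01),
    halo: int = 1,
) -> FitResult:
    """Coarse grid sweep followed by a fine sweep around the optimum.

    The fine grid spans ``halo`` coarse steps around the coarse optimum
    (clipped to the coarse ranges) at the requested fine steps.  Returns
    the fine-grid fit; the effective resolution is ``fine_steps``.
    """
    res = fit_params_grid(s1, s2, observed, coarse)
    a0, b0, g0 = res.params.astuple()

    def _window(center, step, lims):
        lo = max(lims[0], center - halo * step)
        hi = min(lims[1], center + halo * step)
        return (round(lo, 9), round(hi, 9))

    fine_grid = GridSpec(
        _window(a0, coarse.a_step, coarse.a_range), fine_steps[0],
        _window(b0, coarse.b_step, coarse.b_range), fine_steps[1],
        _window(g0, coarse.bg_step, coarse.bg_range), fine_steps[2],
    )
    return fit_params_grid(s1, s2, observed, fine_grid)


def assemble_fit_data(
    singles: pd.DataFrame,
    doubles: pd.DataFrame,
    replicate_cols: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Pool per-replicate (s1, s2, observed) rows for fitting.

    ``singles`` and ``doubles`` are PPI-score tables indexed by serialized
    variant keys with one column per replicate (``ppi_r1`` ...).  Each
    double contributes one row per replicate; predictions then use the
    matching replicate's single-mutant scores.  Doubles lacking either
    single are dropped (returned in the exclusion frame).
    """
    if replicate_cols is None:
        replicate_cols = [c for c in doubles.columns if c.startswith("ppi_r")]
        if not replicate_cols:
            raise ValueError("no per-replicate score columns (ppi_r*) found")
    pairs = [split_double(k) for k in doubles.index]
    k1 = pd.Index(p[0] for p in pairs)
    k2 = pd.Index(p[1] for p in pairs)
    have = k1.isin(singles.index) & k2.isin(singles.index)
    excluded = pd.DataFrame(
        {"reason": "missing single"}, index=doubles.index[~have]
    )
    s1 = singles.loc[k1[have], replicate_cols].to_numpy(float)
    s2 = singles.loc[k2[have], replicate_cols].to_numpy(float)
    obs = doubles.loc[doubles.index[have], replicate_cols].to_numpy(float)
    return s1.ravel(), s2.ravel(), obs.ravel(), excluded


def monte_carlo_cv(
    singles: pd.DataFrame,
    doubles: pd.DataFrame,
    grid: GridSpec = CV_GRID,
    n_repeats: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo cross-validation of the grid fit.

    Each repeat samples half of each protein's single mutants; doubles
    whose both singles are in the sampled halves form the fitting set and
    doubles whose both singles are in the held-out halves form the test
    set (guaranteeing independence).  Returns one row per repeat with the
    fitted parameters and the test-set variance explained (NaN when a set
    is empty); medians summarize the repeats.
    """
    rng = np.random.default_rng(rng)
    pairs = [split_double(k) for k in doubles.index]
    singles_by_protein: dict[str, np.ndarray] = {}
    for prot in ("A", "B"):
        keys = np.array(sorted({k for k in singles.index if k.startswith(prot)}))
        singles_by_protein[prot] = keys
    if len(singles_by_protein["B"]) == 0:  # cis library: split protein A only
        singles_by_protein.pop("B")

    records = []
    for rep in range(n_repeats):
        train: set[str] = set()
        test: set[str] = set()
        for keys in singles_by_protein.values():
            perm = rng.permutation(len(keys))
            half = len(keys) // 2
            train.update(keys[perm[:half]])
            test.update(keys[perm[half:]])
        in_train = np.array([p[0] in train and p[1] in train for p in pairs])
        in_test = np.array([p[0] in test and p[1] in test for p in pairs])
        row: dict[str, float] = {"repeat": rep}
        if not in_train.any() or not in_test.any():
            row.update(a_total=np.nan, b_total=np.nan, bg=np.nan, test_ve=np.nan)
            records.append(row)
            continue
        s1, s2, obs, _ = assemble_fit_data(singles, doubles.loc[in_train])
        fit = fit_params_grid(s1, s2, obs, grid)
        t1, t2, tobs, _ = assemble_fit_data(singles, doubles.loc[in_test])
        pred = predict_double_ppi(t1, t2, fit.params, errors="nan")
        row.update(
            a_total=fit.params.a_total,
            b_total=fit.params.b_total,
            bg=fit.params.bg,
            test_ve=variance_explained(tobs, pred),
        )
        records.append(row)
    return pd.DataFrame(records).set_index("repeat")


def cv_summary(cv: pd.DataFrame) -> dict[str, float]:
    """Median fitted parameters and median test variance explained."""
    return {
        "a_total": float(cv["a_total"].median()),
        "b_total": float(cv["b_total"].median()),
        "bg": float(cv["bg"].median()),
        "test_ve": float(cv["test_ve"].median()),
        "n_valid": int(cv["test_ve"].notna().sum()),
    }


def residual_interaction_scores(
    doubles: pd.DataFrame,
    singles: pd.DataFrame,
    params: ThermoParams,
    replicate_cols: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Thermodynamic-residual genetic interaction scores.

    Per replicate, the residual is observed minus the model prediction
    from the matching replicate's single-mutant scores; the mean across
    replicates is attached.  Doubles lacking a measured single are
    returned separately with a reason.
    """
    if replicate_cols is None:
        replicate_cols = [c for c in doubles.columns if c.startswith("ppi_r")]
    pairs = [split_double(k) for k in doubles.index]
    k1 = pd.Index(p[0] for p in pairs)
    k2 = pd.Index(p[1] for p in pairs)
    have = k1.isin(singles.index) & k2.isin(singles.index)
    excluded = pd.DataFrame({"reason": "missing single"}, index=doubles.index[~have])

    kept = doubles.loc[doubles.index[have]]
    s1 = singles.loc[k1[have], replicate_cols].to_numpy(float)
    s2 = singles.loc[k2[have], replicate_cols].to_numpy(float)
    obs = kept[list(replicate_cols)].to_numpy(float)
    pred = predict_double_ppi(s1, s2, params, errors="nan")
    resid = obs - pred
    gi = pd.DataFrame(
        resid,
        index=kept.index,
        columns=[c.replace("ppi_", "gi_") for c in replicate_cols],
    )
    gi["gi_mean"] = np.nanmean(resid, axis=1)
    gi["model"] = "thermodynamic"
    return gi, excluded


def nonrandom_variance_fraction(
    rep_scores: pd.DataFrame, replicate_cols: Sequence[str] | None = None
) -> float:
    """Reproducible fraction of score variance.

    Mean of the squared Pearson correlations between the per-replicate
    double-mutant scores over all replicate pairs (on rows complete for
    the pair).
    """
    if replicate_cols is None:
        replicate_cols = [c for c in rep_scores.columns if c.startswith("ppi_r")]
    mat = rep_scores[list(replicate_cols)].to_numpy(float)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    r2s = []
    for i, j in itertools.combinations(range(mat.shape[1]), 2):
        ok = ~(np.isnan(mat[:, i]) | np.isnan(mat[:, j]))
        if ok.sum() < 2:
            raise ValueError("fewer than 2 common variants for a replicate pair")
        r = np.corrcoef(mat[ok, i], mat[ok, j])[0, 1]
        r2s.append(r * r)
    return float(np.mean(r2s))
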