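"""Genetic-interaction scores and permutation-based FDR.

A genetic interaction (epistasis) score measures how far a double
mutant's PPI score deviates from a null expectation built from its two
singles.  Two nulls are supported:

* **multiplicative** — expectation is the product of the single scores,
  computed independently in each replicate (this module);
* **thermodynamic** — expectation is the fitted binding model's
  prediction (:func:`deeppca.thermo.residual_interaction_scores`);
  residual scores flow through the same significance and FDR machinery.

Significance is a per-double one-sample t-test of the replicate scores
against 0.  The FDR at each observed p-value is estimated by permutation:
scores are shuffled within replicates independently, the t-tests are
re-run, and permuted discoveries at each threshold are counted as the
expected false discoveries among the real ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import _one_sample_t
from .variants import split_double

__all__ = [
    "multiplicative_gi",
    "gi_significance",
    "permutation_fdr",
    "attach_significance",
    "significant_calls",
    "true_case_estimate",
]


def multiplicative_gi(
    doubles: pd.DataFrame, singles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multiplicative genetic-interaction scores.

    Per replicate, ``GI_r = PPI_d,r - PPI_s1,r * PPI_s2,r``; the mean
    across replicates is attached.  Symmetric in the two singles.
    Doubles lacking a measured single are returned separately.
    """
    rep_cols = [c for c in doubles.columns if c.startswith("ppi_r")]
    pairs = [split_double(k) for k in doubles.index]
    k1 = pd.Index(p[0] for p in pairs)
    k2 = pd.Index(p[1] for p in pairs)
    have = k1.isin(singles.index) & k2.isin(singles.index)
    excluded = pd.DataFrame({"reason": "missing single"}, index=doubles.index[~have])

    kept = doubles.loc[doubles.index[have]]
    s1 = singles.loc[k1[have], rep_cols].to_numpy(float)
    s2 = singles.loc[k2[have], rep_cols].to_numpy(float)
    obs = kept[rep_cols].to_numpy(float)
    gi_mat = obs - s1 * s2
    gi = pd.DataFrame(
        gi_mat, index=kept.index, columns=[c.replace("ppi_", "gi_") for c in rep_cols]
    )
    gi["gi_mean"] = gi_mat.mean(axis=1)
    gi["model"] = "multiplicative"
    return gi, excluded


def gi_significance(gi: pd.DataFrame) -> pd.DataFrame:
    """Two-sided one-sample t-test of per-replicate GI scores against 0.

    Zero-variance replicate vectors get p = 1 and a ``degenerate`` flag.
    """
    rep_cols = [c for c in gi.columns if c.startswith("gi_r")]
    if len(rep_cols) < 2:
        raise ValueError("need at least 2 replicates")
    mat = gi[rep_cols].to_numpy(float)
    p, degenerate = _one_sample_t(mat, popmean=0.0)
    out = gi.copy()
    out["p_value"] = p
    out["degenerate"] = degenerate
    return out


def _t_pvalues(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[1]
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(t, df=n - 1)
    p[sd == 0] = 1.0
    return p


def permutation_fdr(
    gi_matrix: np.ndarray,
    p_values: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Permutation FDR at each observed p-value.

    In each permutation, the genetic-interaction scores are shuffled
    within each replicate column independently (breaking cross-replicate
    consistency) and the one-sample t-tests re-run.  At each observed
    p-value threshold the FDR is the permutation-mean count of permuted
    discoveries divided by the count of real discoveries, clipped to
    [0, 1] and made monotone non-decreasing in p by a cumulative maximum
    from the smallest p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mat = np.asarray(gi_matrix, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if mat.shape[0] != p.shape[0]:
        raise ValueError("gi_matrix and p_values must have the same rows")
    rng = np.random.default_rng(rng)

    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # real discoveries at each threshold (ties share the same count)
    real_counts = np.searchsorted(sorted_p, sorted_p, side="right")

    n, k = mat.shape
    fdr_sum = np.zeros(n)
    for _ in range(n_perm):
        perm = np.empty_like(mat)
        for j in range(k):
            perm[:, j] = mat[rng.permutation(n), j]
        perm_p = np.sort(_t_pvalues(perm))
        false_counts = np.searchsorted(perm_p, sorted_p, side="right")
        fdr_sum += false_counts / real_counts
    fdr_sorted = np.minimum(fdr_sum / n_perm, 1.0)
    fdr_sorted = np.maximum.accumulate(fdr_sorted)
    fdr = np.empty(n)
    fdr[order] = fdr_sorted
    return fdr


def attach_significance(
    gi: pd.DataFrame,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Convenience: t-test p-values plus permutation FDR on a GI table."""
    out = gi_significance(gi)
    rep_cols = [c for c in gi.columns if c.startswith("gi_r")]
    out["fdr"] = permutation_fdr(
        out[rep_cols].to_numpy(float),
        out["p_value"].to_numpy(float),
        n_perm=n_perm,
        rng=rng,
    )
    return out


def significant_calls(gi: pd.DataFrame, fdr_target: float = 0.2) -> pd.DataFrame:
    """Doubles whose permutation FDR meets the target, split by sign."""
    sig = gi[gi["fdr"] <= fdr_target].copy()
    sig["sign"] = np.where(sig["gi_mean"] > 0, "positive", "negative")
    return sig


def true_case_estimate(n_significant: int, avg_fdr: float) -> float:
    """Estimated number of true interactions among significant calls."""
    if not 0.0 <= avg_fdr <= 1.0:
        raise ValueError("avg_fdr must lie in [0, 1]")
    return n_significant * (1.0 - avg_fdr)
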