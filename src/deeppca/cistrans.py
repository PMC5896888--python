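"""Cis/trans comparability machinery.

Double mutants within one protein (*cis*) and across the interface
(*trans*) can differ in outcome either because the constituent single
mutants differ in effect or because genetic interactions genuinely differ
between the two geometries.  This module provides the controls that
separate the two:

* restriction of both libraries to substitutions reachable by a single
  nucleotide change from the wild-type sequence (the cis mutagenesis only
  produces those),
* matched sub-sampling equalizing the 2-D distribution of the two
  constituent single-mutant scores between libraries,
* class-proportion comparison with an empirical sign-flip p-value,
* decomposition of the reproducible (non-random) double-mutant score
  variance into multiplicative, thermodynamic and residual components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scoring import CLASS_LABELS, CLASS_THRESHOLDS, classify
from .thermo import nonrandom_variance_fraction, variance_explained
from .variants import parse_variant

__all__ = [
    "reachable_amino_acids",
    "single_nt_reachable",
    "MatchedSample",
    "match_distributions",
    "compare_class_proportions",
    "variance_decomposition",
]

_BASES = "ACGT"


def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    fwd = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        fwd[stop] = "*"
    return fwd


def reachable_amino_acids(codon: str) -> set[str]:
    """Amino acids reachable from a codon by exactly one base change.

    Excludes the codon's own translation and stops.
    """
    codon = codon.upper()
    fwd = _codon_table()
    if codon not in fwd:
        raise ValueError(f"unknown codon {codon!r}")
    own = fwd[codon]
    out = set()
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            aa = fwd[codon[:i] + b + codon[i + 1:]]
            if aa not in ("*", own):
                out.add(aa)
    return out


def single_nt_reachable(
    variants: Iterable[str],
    wt_nt: dict[str, str],
) -> list[str]:
    """Keep variants whose every substitution is one base from wild type.

    ``wt_nt`` maps protein ("A"/"B") to the wild-type nucleotide sequence
    of its mutated region (length 3 x n_positions).  A substitution is
    retained iff some codon of the mutant amino acid differs from the
    wild-type codon at exactly one base; doubles need both substitutions
    reachable.  Idempotent.
    """
    cache: dict[tuple[str, int], set[str]] = {}

    def _reachable(protein: str, position: int) -> set[str]:
        key = (protein, position)
        if key not in cache:
            seq = wt_nt[protein]
            codon = seq[3 * (position - 1): 3 * position]
            if len(codon) != 3:
                raise ValueError(
                    f"position {position} outside the wild-type sequence of {protein}"
                )
            cache[key] = reachable_amino_acids(codon)
        return cache[key]

    kept = []
    for key in variants:
        vk = parse_variant(key)
        if all(m.mut_aa in _reachable(m.protein, m.position) for m in vk.mutations):
            kept.append(key)
    return kept


# --------------------------------------------------------------------------
# Matched sub-sampling


@dataclass
class MatchedSample:
    """Retained double-mutant keys of one matched sub-sample."""

    cis_keys: pd.Index
    trans_keys: pd.Index
    breaks: np.ndarray  # bin edges shared by both dimensions
    cis_flip: pd.Series | None = None  # axis assignment of the cis pairs


def _bin_ids(s1, s2, breaks: np.ndarray) -> np.ndarray:
    n_bins = len(breaks) - 1
    b1 = np.clip(np.digitize(s1, breaks[1:-1]), 0, n_bins - 1)
    b2 = np.clip(np.digitize(s2, breaks[1:-1]), 0, n_bins - 1)
    return b1 * n_bins + b2


def match_distributions(
    cis: pd.DataFrame,
    trans: pd.DataFrame,
    n_bins: int = 20,
    n_subsamples: int = 1000,
    rng: np.random.Generator | int | None = None,
    randomize_cis_axes: bool = True,
) -> list[MatchedSample]:
    """Sub-sample both libraries to matched single-mutant score profiles.

    ``cis`` and ``trans`` are double-mutant tables (indexed by key) with
    columns ``s1_score`` and ``s2_score`` — the PPI scores of the two
    constituent single mutants.  Both dimensions are binned into
    ``n_bins`` evenly spaced bins between the pooled minimum and maximum
    single-mutant score.  In each sub-sample, cis pairs are assigned to
    the two axes at random (the pair is unordered within one protein),
    and within every 2-D bin the better-represented library is randomly
    down-sampled to the other's count, so the per-bin counts are equal by
    construction.
    """
    if len(cis) == 0 or len(trans) == 0:
        raise ValueError("both libraries must be non-empty")
    rng = np.random.default_rng(rng)
    pooled = np.concatenate(
        [
            cis[["s1_score", "s2_score"]].to_numpy(float).ravel(),
            trans[["s1_score", "s2_score"]].to_numpy(float).ravel(),
        ]
    )
    breaks = np.linspace(pooled.min(), pooled.max(), n_bins + 1)

    c1 = cis["s1_score"].to_numpy(float)
    c2 = cis["s2_score"].to_numpy(float)
    t_bins = _bin_ids(
        trans["s1_score"].to_numpy(float), trans["s2_score"].to_numpy(float), breaks
    )

    samples = []
    for _ in range(n_subsamples):
        if randomize_cis_axes:
            flip = rng.random(len(cis)) < 0.5
        else:
            flip = np.zeros(len(cis), dtype=bool)
        a = np.where(flip, c2, c1)
        b = np.where(flip, c1, c2)
        c_bins = _bin_ids(a, b, breaks)

        keep_cis = np.zeros(len(cis), dtype=bool)
        keep_trans = np.zeros(len(trans), dtype=bool)
        for bin_id in np.union1d(np.unique(c_bins), np.unique(t_bins)):
            ci = np.flatnonzero(c_bins == bin_id)
            ti = np.flatnonzero(t_bins == bin_id)
            m = min(len(ci), len(ti))
            if m == 0:
                continue
            if len(ci) > m:
                ci = rng.choice(ci, size=m, replace=False)
            if len(ti) > m:
                ti = rng.choice(ti, size=m, replace=False)
            keep_cis[ci] = True
            keep_trans[ti] = True
        samples.append(
            MatchedSample(
                cis_keys=cis.index[keep_cis],
                trans_keys=trans.index[keep_trans],
                breaks=breaks,
                cis_flip=pd.Series(flip, index=cis.index),
            )
        )
    return samples


def compare_class_proportions(
    samples: Sequence[MatchedSample],
    cis_mean: pd.Series,
    trans_mean: pd.Series,
    thresholds: Sequence[float] = CLASS_THRESHOLDS,
) -> pd.DataFrame:
    """Effect-class proportions of the matched libraries and empirical p.

    Proportions per class are averaged over sub-samples.  The p-value of
    a class is the proportion of sub-samples whose cis-trans difference
    has the opposite sign to the average difference; zero such
    sub-samples is reported as ``p < 1/n_subsamples`` (``p_label``).
    A class with zero average difference has no direction and its p is NaN.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sub-sample")
    props = {"cis": [], "trans": []}
    for s in samples:
        for lib, keys, means in (
            ("cis", s.cis_keys, cis_mean),
            ("trans", s.trans_keys, trans_mean),
        ):
            cls = classify(means.loc[keys].to_numpy(), thresholds)
            counts = pd.Series(cls).value_counts(normalize=True)
            props[lib].append(counts.reindex(CLASS_LABELS, fill_value=0.0))
    cis_p = pd.DataFrame(props["cis"])
    trans_p = pd.DataFrame(props["trans"])
    diffs = cis_p.to_numpy() - trans_p.to_numpy()
    avg_diff = diffs.mean(axis=0)

    n = len(samples)
    rows = []
    for j, label in enumerate(CLASS_LABELS):
        if avg_diff[j] == 0.0:
            p, p_label = np.nan, "n.s. (no direction)"
        else:
            opposite = int((np.sign(diffs[:, j]) == -np.sign(avg_diff[j])).sum())
            p = opposite / n
            p_label = f"<{1}/{n}" if opposite == 0 else f"{p:g}"
        rows.append(
            {
                "effect_class": label,
                "cis_proportion": float(cis_p.iloc[:, j].mean()),
                "trans_proportion": float(trans_p.iloc[:, j].mean()),
                "difference": float(avg_diff[j]),
                "p_value": p,
                "p_label": p_label,
            }
        )
    return pd.DataFrame(rows).set_index("effect_class")


# --------------------------------------------------------------------------
# Variance decomposition


def variance_decomposition(
    doubles: pd.DataFrame,
    mult_pred: pd.DataFrame,
    thermo_pred: pd.DataFrame,
    replicate_cols: Sequence[str] | None = None,
) -> dict[str, float]:
    """Decompose double-mutant score variance into model components.

    ``doubles`` holds the observed per-replicate scores; ``mult_pred``
    and ``thermo_pred`` the per-replicate predictions of the
    multiplicative and thermodynamic nulls (aligned indices/columns).
    Returns fractions of the *non-random* (replicate-reproducible)
    variance: multiplicative-explained, the thermodynamic model's
    additional share, and the residual attributed to structural
    interactions, plus the raw variance-explained numbers.
    """
    if replicate_cols is None:
        replicate_cols = [c for c in doubles.columns if c.startswith("ppi_r")]
    obs = doubles[list(replicate_cols)].to_numpy(float).ravel()
    vm = variance_explained(obs, mult_pred[list(replicate_cols)].to_numpy(float).ravel())
    vt = variance_explained(obs, thermo_pred[list(replicate_cols)].to_numpy(float).ravel())
    nonrandom = nonrandom_variance_fraction(doubles, replicate_cols)
    if nonrandom <= 0:
        raise ValueError("degenerate (zero) non-random variance")
    return {
        "nonrandom_fraction": nonrandom,
        "multiplicative_ve": vm,
        "thermo_ve": vt,
        "multiplicative_explained_frac": vm / nonrandom,
        "thermo_explained_frac": vt / nonrandom,
        "thermo_additional_frac": (vt - vm) / nonrandom,
        "residual_frac": (nonrandom - vt) / nonrandom,
    }
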