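"""From UMI count tables to corrected, classified PPI scores.

Pipeline stages, matching the competition-assay analysis:

1. optional synonymous aggregation (codon-level -> amino-acid-level counts),
2. per-sample frequencies (computed on the *full* table so every sequenced
   molecule contributes to the denominator),
3. variant filtering (input UMIs >= 10 in all replicates, output UMIs >= 1
   in all replicates; wild type and stop variants excluded downstream but
   the wild type retained for normalization),
4. raw PPI scores: ``n_i = log2(f_out/f_in) + g_r`` doublings per variant,
   ``PPI = n_i / n_wt`` — generations relative to the wild-type
   interaction, so the wild type scores exactly 1,
5. background-growth correction aligning the detrimental mode across
   replicates (and, jointly, across libraries),
6. replicate summary, one-sample t-tests against 1, BH FDR, and effect
   classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants import WT_LABEL, parse_variant

__all__ = [
    "CLASS_THRESHOLDS",
    "ModeAlignment",
    "FilterResult",
    "ScoreResult",
    "read_count_table",
    "write_count_table",
    "aggregate_synonymous",
    "filter_variants",
    "ppi_scores",
    "detect_modes",
    "align_background_mode",
    "summarize_and_classify",
    "score_pipeline",
    "cross_protein_concordance",
]

#: Effect-class boundaries on the replicate-mean corrected score:
#: detrimental <= 0.64 < intermediate <= 0.96 < neutral <= 1.04 < strengthening.
CLASS_THRESHOLDS = (0.64, 0.96, 1.04)
CLASS_LABELS = ("detrimental", "intermediate", "neutral", "strengthening")

_MUT_COLS = ["protein1", "pos1", "wt1", "mut1", "protein2", "pos2", "wt2", "mut2"]


@dataclass
class ModeAlignment:
    """Detected detrimental-mode locations and the alignment target."""

    modes: dict[str, float]  # per replicate column
    target: float  # M: max of modes across replicates (and libraries)


@dataclass
class FilterResult:
    kept: pd.DataFrame
    excluded: pd.DataFrame  # index: variant, column: reason
    wt_counts: pd.Series


@dataclass
class ScoreResult:
    scores: pd.DataFrame  # PPIScoreTable
    raw: pd.DataFrame  # uncorrected per-replicate scores
    alignment: ModeAlignment
    excluded: pd.DataFrame


# --------------------------------------------------------------------------
# I/O


def read_count_table(path) -> pd.DataFrame:
    """Read a count TSV with explicit mutation columns into a keyed table.

    Expected columns: ``protein1 pos1 wt1 mut1 protein2 pos2 wt2 mut2``
    (second group empty for singles, both empty for the wild-type row)
    followed by ``input_r* ``/``output_r*`` count columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={c: "string" for c in _MUT_COLS})
    keys = []
    for _, row in df.iterrows():
        parts = []
        for p, pos, wt, mut in (("protein1", "pos1", "wt1", "mut1"),
                                ("protein2", "pos2", "wt2", "mut2")):
            if pd.notna(row[p]) and str(row[p]).strip():
                parts.append(
                    f"{row[p]}{int(float(row[pos]))}{row[wt]}>{row[mut]}"
                )
        keys.append(":".join(parts) if parts else WT_LABEL)
    counts = df.drop(columns=[c for c in _MUT_COLS if c in df.columns])
    counts.index = pd.Index(keys, name="variant")
    return counts


def write_count_table(counts: pd.DataFrame, path) -> None:
    """Write a keyed count table back to the explicit-column TSV schema."""
    rows = []
    for key in counts.index:
        vk = parse_variant(key)
        rec = dict.fromkeys(_MUT_COLS, "")
        for i, m in enumerate(vk.mutations, start=1):
            rec[f"protein{i}"] = m.protein
            rec[f"pos{i}"] = m.position
            rec[f"wt{i}"] = m.wt_aa
            rec[f"mut{i}"] = m.mut_aa
        rows.append(rec)
    out = pd.concat(
        [pd.DataFrame(rows, index=counts.index), counts], axis=1
    )
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Aggregation and filtering


def aggregate_synonymous(codon_counts: pd.DataFrame) -> pd.DataFrame:
    """Sum codon-level UMI counts over synonymous variants.

    The input is keyed like an amino-acid table but with codons in place
    of the mutant amino acids (e.g. ``A3E>AAA``); codons are translated
    with the standard genetic code and counts summed per amino-acid key.
    A codon translating back to the wild-type amino acid is a synonymous
    wild-type sequence, so that mutation drops out of the key (down to
    the ``WT`` row if none remains).  Per-column totals are conserved.
    """
    from Bio.Data.CodonTable import standard_dna_table

    fwd = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        fwd[stop] = "*"

    def _translate_key(key: str) -> str:
        if key == WT_LABEL:
            return key
        parts = []
        for part in key.split(":"):
            head, codon = part.split(">")
            codon = codon.upper()
            if len(codon) == 3:
                if codon not in fwd:
                    raise ValueError(f"untranslatable codon {codon!r} in {key!r}")
                codon = fwd[codon]
            if codon == head[-1]:  # synonymous with the wild-type residue
                continue
            parts.append(f"{head}>{codon}")
        return ":".join(parts) if parts else WT_LABEL

    aa_keys = [_translate_key(k) for k in codon_counts.index]
    out = codon_counts.groupby(pd.Index(aa_keys, name="variant")).sum()
    if "codon_multiplicity" not in codon_counts.columns:
        mult = pd.Series(aa_keys).value_counts()
        out["codon_multiplicity"] = mult.reindex(out.index).to_numpy()
    return out


def _rep_cols(counts: pd.DataFrame, prefix: str) -> list[str]:
    cols = sorted(c for c in counts.columns if c.startswith(prefix))
    if not cols:
        raise ValueError(f"no {prefix}* columns found")
    return cols


def filter_variants(counts: pd.DataFrame, min_input: float = 10) -> FilterResult:
    """Apply the input-depth, output-detection, stop and wild-type filters.

    Keeps rows with input count >= ``min_input`` in *all* replicates and
    output count >= 1 in *all* replicates.  Stop-containing variants and
    the wild-type row are excluded from downstream score tables; the
    wild-type counts are returned for normalization.
    """
    if WT_LABEL not in counts.index:
        raise ValueError("wild-type row required for normalization")
    in_cols = _rep_cols(counts, "input_r")
    out_cols = _rep_cols(counts, "output_r")
    wt_counts = counts.loc[WT_LABEL, in_cols + out_cols]

    df = counts.drop(index=WT_LABEL)
    reasons = pd.Series("", index=df.index, dtype=object)
    has_stop = df.index.str.contains(r"\*", regex=True)
    low_in = (df[in_cols] < min_input).any(axis=1).to_numpy()
    zero_out = (df[out_cols] < 1).any(axis=1).to_numpy()
    reasons[has_stop] = "stop codon"
    reasons[~has_stop & low_in] = "low input"
    reasons[~has_stop & ~low_in & zero_out] = "zero output"
    drop = reasons != ""
    excluded = pd.DataFrame({"reason": reasons[drop]})
    return FilterResult(kept=df.loc[~drop], excluded=excluded, wt_counts=wt_counts)


# --------------------------------------------------------------------------
# PPI scores


def ppi_scores(
    counts: pd.DataFrame,
    generations: Sequence[float],
    min_input: float = 10,
) -> tuple[pd.DataFrame, FilterResult]:
    """Raw per-replicate PPI scores from a full count table.

    Frequencies are computed on the full table (before filtering) so the
    denominator counts every sequenced molecule; ``generations`` supplies
    the population doublings g_r of each replicate.  A variant's score is
    its net doublings ``log2(f_out/f_in) + g_r`` relative to the wild
    type's, so the wild type scores exactly 1 in every replicate.
    """
    in_cols = _rep_cols(counts, "input_r")
    out_cols = _rep_cols(counts, "output_r")
    if len(generations) != len(in_cols):
        raise ValueError("need one generations value per replicate")
    f_in = counts[in_cols] / counts[in_cols].sum(axis=0)
    f_out = counts[out_cols] / counts[out_cols].sum(axis=0)

    filt = filter_variants(counts, min_input=min_input)
    kept = filt.kept.index
    scores = {}
    for r, (ic, oc) in enumerate(zip(in_cols, out_cols)):
        g = float(generations[r])
        with np.errstate(divide="ignore"):
            n = np.log2(f_out.loc[kept, oc].to_numpy() / f_in.loc[kept, ic].to_numpy()) + g
            n_wt = float(np.log2(f_out.loc[WT_LABEL, oc] / f_in.loc[WT_LABEL, ic]) + g)
        if n_wt <= 0:
            raise ValueError("wild-type net doublings <= 0: degenerate experiment")
        scores[f"ppi_r{r + 1}"] = n / n_wt
    raw = pd.DataFrame(scores, index=kept)
    return raw, filt


# --------------------------------------------------------------------------
# Background-growth (detrimental-mode) alignment


def detect_modes(
    raw: pd.DataFrame,
    ceiling: float = 0.9,
    n_grid: int = 512,
    min_density_frac: float = 0.5,
) -> dict[str, float]:
    """Leftmost substantial local maximum of a Gaussian KDE per replicate.

    Uses Silverman's bandwidth on a 512-point grid spanning the score
    range.  Only maxima below ``ceiling`` qualify as the detrimental
    mode, and — to ignore satellite bumps created by low-count noise in
    the left tail — only maxima whose density reaches at least
    ``min_density_frac`` of the densest sub-ceiling maximum.  Returns NaN
    for a column with no qualifying mode.
    """
    modes: dict[str, float] = {}
    for col in raw.columns:
        x = raw[col].dropna().to_numpy()
        kde = stats.gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(x.min(), x.max(), n_grid)
        dens = kde(grid)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
        local_max = np.flatnonzero(interior) + 1
        if dens[0] > dens[1]:
            local_max = np.concatenate([[0], local_max])
        below = local_max[grid[local_max] < ceiling]
        if below.size:
            below = below[dens[below] >= min_density_frac * dens[below].max()]
        modes[col] = float(grid[below[0]]) if below.size else np.nan
    return modes


def align_background_mode(
    raw: pd.DataFrame,
    joint: pd.DataFrame | None = None,
    ceiling: float = 0.9,
    n_grid: int = 512,
) -> tuple[pd.DataFrame, ModeAlignment]:
    """Align the detrimental mode of each replicate to a common value.

    The correction is the affine map
    ``corrected = (PPI - s) / (PPI_wt - s)`` with ``s = (m - M)/(1 - M)``,
    where ``m`` is the replicate's detected mode and ``M`` the maximum
    mode across replicates (and across both libraries when ``joint`` is
    given).  It pins the wild type at 1 (PPI_wt = 1) and maps a score of
    exactly ``m`` to ``M``.  If no detrimental mode is detectable the
    replicate is left uncorrected with a warning.
    """
    modes = detect_modes(raw, ceiling=ceiling, n_grid=n_grid)
    all_modes = list(modes.values())
    if joint is not None:
        all_modes += list(detect_modes(joint, ceiling=ceiling, n_grid=n_grid).values())
    finite = [m for m in all_modes if np.isfinite(m)]
    if not finite:
        warnings.warn("no detrimental mode detected; identity correction applied")
        return raw.copy(), ModeAlignment(modes=modes, target=np.nan)
    M = max(finite)

    corrected = raw.copy()
    for col, m in modes.items():
        if not np.isfinite(m):
            warnings.warn(f"no detrimental mode in {col}; left uncorrected")
            continue
        s = (m - M) / (1.0 - M)
        corrected[col] = (raw[col] - s) / (1.0 - s)
    return corrected, ModeAlignment(modes=modes, target=M)


# --------------------------------------------------------------------------
# Summary, significance, classification


def classify(mean_scores, thresholds: Sequence[float] = CLASS_THRESHOLDS):
    """Effect class of replicate-mean scores (boundaries inclusive left)."""
    t1, t2, t3 = thresholds
    return pd.cut(
        np.asarray(mean_scores, dtype=float),
        bins=[-np.inf, t1, t2, t3, np.inf],
        labels=CLASS_LABELS,
    )


def _one_sample_t(mat: np.ndarray, popmean: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided one-sample t p-values per row; zero-variance rows -> p=1."""
    n = mat.shape[1]
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - popmean) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = 1.0
    return p, degenerate


def summarize_and_classify(
    corrected: pd.DataFrame,
    thresholds: Sequence[float] = CLASS_THRESHOLDS,
) -> pd.DataFrame:
    """Replicate summary, t-test against the wild-type score of 1, BH FDR
    and effect class on the replicate-mean corrected score."""
    rep_cols = [c for c in corrected.columns if c.startswith("ppi_r")]
    mat = corrected[rep_cols].to_numpy(float)
    out = corrected.copy()
    out["mean"] = mat.mean(axis=1)
    if mat.shape[1] >= 2:
        out["sem"] = stats.sem(mat, axis=1)
        p, degenerate = _one_sample_t(mat, popmean=1.0)
        out["p_value"] = p
        out["degenerate"] = degenerate
        out["fdr"] = multipletests(p, method="fdr_bh")[1]
    else:
        out["sem"] = np.nan
        out["p_value"] = np.nan
        out["degenerate"] = True
        out["fdr"] = np.nan
    out["effect_class"] = classify(out["mean"], thresholds)
    return out


def score_pipeline(
    counts: pd.DataFrame,
    generations: Sequence[float],
    min_input: float = 10,
    joint_raw: pd.DataFrame | None = None,
    mode_ceiling: float = 0.9,
    thresholds: Sequence[float] = CLASS_THRESHOLDS,
) -> ScoreResult:
    """Counts -> filtered raw scores -> mode-aligned -> classified table.

    ``joint_raw`` optionally supplies a second library's raw score table
    whose modes participate in the alignment target (joint correction of
    two libraries to the same detrimental-mode value).
    """
    raw, filt = ppi_scores(counts, generations, min_input=min_input)
    corrected, alignment = align_background_mode(
        raw, joint=joint_raw, ceiling=mode_ceiling
    )
    scores = summarize_and_classify(corrected, thresholds)
    return ScoreResult(
        scores=scores, raw=raw, alignment=alignment, excluded=filt.excluded
    )


# --------------------------------------------------------------------------
# Cross-protein concordance of identical substitutions


def cross_protein_concordance(
    singles_a: pd.DataFrame,
    singles_b: pd.DataFrame,
    disruptive_threshold: float = CLASS_THRESHOLDS[0],
    neutral_threshold: float = CLASS_THRESHOLDS[1],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare identical substitutions at the same position in both proteins.

    Substitutions are matched on (position, mutant amino acid).  For each
    matched pair a paired t-test across replicates (BH-corrected) tests
    whether the substitution's effect differs between the proteins; 2x2
    Fisher tests report concordance odds ratios for shared disruptive
    (mean <= ``disruptive_threshold``) and near-neutral-or-strengthening
    (mean > ``neutral_threshold``) calls.
    """
    rep_cols = [c for c in singles_a.columns if c.startswith("ppi_r")]

    def _by_sub(df: pd.DataFrame) -> dict[tuple[int, str], str]:
        out = {}
        for k in df.index:
            m = parse_variant(k).mutations[0]
            out[(m.position, m.mut_aa)] = k
        return out

    a_map, b_map = _by_sub(singles_a), _by_sub(singles_b)
    shared = sorted(set(a_map) & set(b_map))
    if not shared:
        raise ValueError("no matched substitutions between the two proteins")

    ka = [a_map[s] for s in shared]
    kb = [b_map[s] for s in shared]
    mat_a = singles_a.loc[ka, rep_cols].to_numpy(float)
    mat_b = singles_b.loc[kb, rep_cols].to_numpy(float)
    p, degenerate = _one_sample_t(mat_a - mat_b, popmean=0.0)
    table = pd.DataFrame(
        {
            "position": [s[0] for s in shared],
            "mut_aa": [s[1] for s in shared],
            "key_a": ka,
            "key_b": kb,
            "mean_a": mat_a.mean(axis=1),
            "mean_b": mat_b.mean(axis=1),
            "p_value": p,
            "degenerate": degenerate,
        }
    )
    table["fdr"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]

    def _fisher(pred_a: np.ndarray, pred_b: np.ndarray, label: str) -> dict:
        tab = [
            [int((pred_a & pred_b).sum()), int((pred_a & ~pred_b).sum())],
            [int((~pred_a & pred_b).sum()), int((~pred_a & ~pred_b).sum())],
        ]
        odds, pval = stats.fisher_exact(tab, alternative="two-sided")
        return {"concordance": label, "odds_ratio": odds, "p_value": pval,
                "n11": tab[0][0], "n10": tab[0][1], "n01": tab[1][0],
                "n00": tab[1][1]}

    mean_a, mean_b = mat_a.mean(axis=1), mat_b.mean(axis=1)
    fisher = pd.DataFrame(
        [
            _fisher(mean_a <= disruptive_threshold,
                    mean_b <= disruptive_threshold, "disruptive"),
            _fisher(mean_a > neutral_threshold,
                    mean_b > neutral_threshold, "neutral_or_strengthening"),
        ]
    )
    return table, fisher
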