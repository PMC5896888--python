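"""Closed-form library-design arithmetic.

Calculators for the combinatorics and expected variant frequencies of the
two mutagenesis strategies used in double deep mutational scanning of a
protein pair:

* **NNS saturation mutagenesis** — one mutagenic primer per codon position,
  each replacing the wild-type codon by one of 32 NNS codons (any base at
  codon positions 1-2, G or C at position 3).  If the wild-type codon ends
  in G or C, one of the 32 outcomes regenerates the wild type.
* **Doped-oligonucleotide synthesis** — every base of the region is
  replaced by one of the three alternative bases with a fixed per-base
  doping rate.

All frequencies are exact :class:`fractions.Fraction` values when the
inputs are exact; display rounding is the caller's concern.  The module
also covers the experiment-planning arithmetic (population doublings from
optical densities, expected cells per variant at a bottleneck).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction


@dataclass(frozen=True)
class GeneDesign:
    """NNS mutagenesis design of one gene region.

    Parameters
    ----------
    n_positions
        Number of mutated codons (one mutagenic primer per codon).
    n_codons_per_position
        Equally likely codon outcomes per primer (32 for NNS).
    n_wt_encoding
        Positions whose primer can regenerate the wild-type codon
        (i.e. wild-type codon already ends in G or C).
    """

    n_positions: int
    n_codons_per_position: int = 32
    n_wt_encoding: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.n_codons_per_position < 1:
            raise ValueError("n_codons_per_position must be >= 1")
        if not 0 <= self.n_wt_encoding <= self.n_positions:
            raise ValueError("n_wt_encoding must be within [0, n_positions]")


@dataclass(frozen=True)
class GeneDesignSummary:
    """Outcome counts and frequencies of an NNS gene design."""

    n_outcomes: int
    n_unique_mutants: int
    wt_frequency: Fraction
    mutant_frequency: Fraction


@dataclass(frozen=True)
class PairDesignSummary:
    """Counts and frequencies of the combined two-gene library design."""

    n_double_mutants: int
    n_single_a: int
    n_single_b: int
    freq_double: Fraction
    freq_single_a: Fraction
    freq_single_b: Fraction
    freq_wt: Fraction

    @property
    def f_low(self) -> Fraction:
        """Frequency of the rarest designed class (a double codon mutant)."""
        return self.freq_double


@dataclass(frozen=True)
class DopedDesign:
    """Doped-oligonucleotide design: region length and per-base doping rate."""

    length_nt: int
    doping_rate: float

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError("length_nt must be >= 1")
        if not 0 <= float(self.doping_rate) <= 1:
            raise ValueError("doping_rate must be within [0, 1]")


def nns_gene_design(design: GeneDesign) -> GeneDesignSummary:
    """Outcome space of NNS mutagenesis of one gene.

    One primer among ``n_positions`` is used per molecule, each yielding
    ``n_codons_per_position`` equally likely codons, so there are
    ``n_positions * n_codons_per_position`` equally likely sequence
    outcomes, of which ``n_wt_encoding`` regenerate the wild type.
    """
    n_outcomes = design.n_positions * design.n_codons_per_position
    n_unique = n_outcomes - design.n_wt_encoding
    return GeneDesignSummary(
        n_outcomes=n_outcomes,
        n_unique_mutants=n_unique,
        wt_frequency=Fraction(design.n_wt_encoding, n_outcomes),
        mutant_frequency=Fraction(1, n_outcomes),
    )


def pairwise_library_design(
    a: GeneDesignSummary, b: GeneDesignSummary
) -> PairDesignSummary:
    """Combine two independently mutagenized genes into one library design."""
    return PairDesignSummary(
        n_double_mutants=a.n_unique_mutants * b.n_unique_mutants,
        n_single_a=a.n_unique_mutants,
        n_single_b=b.n_unique_mutants,
        freq_double=a.mutant_frequency * b.mutant_frequency,
        freq_single_a=a.mutant_frequency * b.wt_frequency,
        freq_single_b=b.mutant_frequency * a.wt_frequency,
        freq_wt=a.wt_frequency * b.wt_frequency,
    )


def aa_mutant_space(n_positions: int, n_subs: int) -> dict[str, int]:
    """Single and trans-double amino-acid mutant counts for identical designs.

    ``n_singles`` counts per protein; ``n_trans_doubles`` combines one single
    from each of two proteins of identical design.
    """
    if n_positions < 1 or n_subs < 1:
        raise ValueError("counts must be >= 1")
    n_singles = n_positions * n_subs
    return {"n_singles": n_singles, "n_trans_doubles": n_singles**2}


def doped_class_pmf(design: DopedDesign, k: int) -> float:
    """Probability that exactly ``k`` bases of the doped region are mutant.

    Each base is non-wild-type independently with probability
    ``doping_rate``; the class probability is the binomial pmf
    ``C(L, k) p^k (1-p)^(L-k)``.
    """
    L, p = design.length_nt, float(design.doping_rate)
    if not 0 <= k <= L:
        raise ValueError(f"k must be within [0, {L}]")
    return math.comb(L, k) * p**k * (1.0 - p) ** (L - k)


def doped_variant_count(length_nt: int, k: int) -> int:
    """Distinct nucleotide variants with exactly ``k`` substituted bases."""
    if not 0 <= k <= length_nt:
        raise ValueError("k must be within [0, length_nt]")
    return math.comb(length_nt, k) * 3**k


def doped_per_variant_frequency(design: DopedDesign, k: int) -> float:
    """Expected frequency of one specific ``k``-substitution variant.

    All variants of a substitution class are equally likely because each
    doped base takes each of the three alternatives with probability p/3.
    """
    return doped_class_pmf(design, k) / doped_variant_count(design.length_nt, k)


def optimal_doping_rate(length_nt: int, k: int) -> float:
    """Doping rate maximizing the frequency of the ``k``-mutant class.

    The binomial pmf in p is maximized at the analytic argmax ``k / L``.
    """
    if not 1 <= k <= length_nt:
        raise ValueError("k must be within [1, length_nt]")
    return k / length_nt


def generations_from_od(od_start: float, od_end: float, n_cycles: int = 1) -> float:
    """Population doublings of ``n_cycles`` growth cycles between two ODs."""
    if od_start <= 0 or od_end <= 0:
        raise ValueError("optical densities must be positive")
    if od_end < od_start:
        raise ValueError("od_end must be >= od_start")
    return n_cycles * math.log2(od_end / od_start)


def cells_per_variant(
    od: float, cells_per_od_ml: float, volume_ml: float, variant_freq: float
) -> float:
    """Expected cells carrying one specific variant at a culture bottleneck."""
    for v in (od, cells_per_od_ml, volume_ml, variant_freq):
        if v < 0:
            raise ValueError("all factors must be non-negative")
    return od * cells_per_od_ml * volume_ml * float(variant_freq)
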