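"""Variant identity: mutations, variant keys and wild-type region sequences.

A variant is identified by the list of its amino-acid substitutions, each
located on one of the two interacting proteins (``A`` and ``B``), at a
1-based position inside the mutated region (32 codons per protein in the
reference design).  Single mutants carry one substitution, doubles carry
two; *cis* doubles have both substitutions in protein A, *trans* doubles
one in each protein.

Keys serialize to compact strings (``A3E>K``, ``A3E>K:B4R>E``, ``WT``)
used as DataFrame indices throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

WT_LABEL = "WT"

_MUT_RE = re.compile(r"^([AB])(\d+)([A-Z\*])>([A-Z\*])$")


@dataclass(frozen=True, order=True)
class Mutation:
    """A single amino-acid substitution on one protein."""

    protein: str  # "A" or "B"
    position: int  # 1-based index within the mutated region
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.protein not in ("A", "B"):
            raise ValueError(f"protein must be 'A' or 'B', got {self.protein!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.mut_aa == self.wt_aa:
            raise ValueError("mutant amino acid equals wild type")

    def __str__(self) -> str:
        return f"{self.protein}{self.position}{self.wt_aa}>{self.mut_aa}"


@dataclass(frozen=True)
class VariantKey:
    """An (unordered) set of 0, 1 or 2 substitutions identifying a variant."""

    mutations: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        muts = tuple(sorted(self.mutations))
        object.__setattr__(self, "mutations", muts)
        if len(muts) > 2:
            raise ValueError("at most two substitutions per variant")
        if len(muts) == 2:
            a, b = muts
            if (a.protein, a.position) == (b.protein, b.position):
                raise ValueError("double mutant repeats a position")

    @property
    def arity(self) -> int:
        return len(self.mutations)

    @property
    def is_wildtype(self) -> bool:
        return self.arity == 0

    @property
    def is_cis(self) -> bool:
        return self.arity == 2 and all(m.protein == "A" for m in self.mutations)

    @property
    def is_trans(self) -> bool:
        return self.arity == 2 and {m.protein for m in self.mutations} == {"A", "B"}

    def singles(self) -> tuple["VariantKey", ...]:
        """Constituent single-mutant keys of a double (or the key itself)."""
        if self.arity != 2:
            return (self,)
        return tuple(VariantKey((m,)) for m in self.mutations)

    def __str__(self) -> str:
        if not self.mutations:
            return WT_LABEL
        return ":".join(str(m) for m in self.mutations)


def parse_variant(key: str) -> VariantKey:
    """Parse a serialized variant key (``WT``, ``A3E>K`` or ``A3E>K:B4R>E``)."""
    key = key.strip()
    if key in ("", WT_LABEL):
        return VariantKey(())
    muts = []
    for part in key.split(":"):
        m = _MUT_RE.match(part)
        if m is None:
            raise ValueError(f"malformed mutation {part!r}")
        muts.append(Mutation(m.group(1), int(m.group(2)), m.group(3), m.group(4)))
    return VariantKey(tuple(muts))


def single_key(protein: str, position: int, wt_aa: str, mut_aa: str) -> str:
    return str(VariantKey((Mutation(protein, position, wt_aa, mut_aa),)))


def double_key(m1: Mutation, m2: Mutation) -> str:
    return str(VariantKey((m1, m2)))


def split_double(key: str) -> tuple[str, str]:
    """Serialized single-mutant keys of a serialized double-mutant key."""
    vk = parse_variant(key)
    if vk.arity != 2:
        raise ValueError(f"{key!r} is not a double mutant")
    s1, s2 = vk.singles()
    return str(s1), str(s2)


# --------------------------------------------------------------------------
# Synthetic wild-type sequences
#
# The real bait/prey leucine-zipper sequences are not bundled; these are
# synthetic stand-ins with a coiled-coil-like heptad composition (Leu/Ile at
# core a/d positions, charged residues at e/g) so that structure annotation
# and nucleotide-reachability code paths behave realistically in tests and
# simulations.  Any user-supplied sequence can replace them.

_HEPTAD_CHOICES = {
    "a": "LIVL",
    "b": "EQAN",
    "c": "ASKD",
    "d": "LLIM",
    "e": "KEQR",
    "f": "SNTQ",
    "g": "EKDE",
}

#: One codon per amino acid used to back-translate synthetic regions.
PREFERRED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

HEPTAD_LETTERS = "abcdefg"


def heptad_letter(position: int, register_offset: int = 0) -> str:
    """Heptad letter of a 1-based position given the register offset.

    ``register_offset = 0`` places position 1 at letter ``a``.
    """
    return HEPTAD_LETTERS[(position - 1 + register_offset) % 7]


def synthetic_zipper(n_positions: int, phase: int = 0) -> str:
    """Deterministic synthetic coiled-coil-like amino-acid sequence."""
    seq = []
    for pos in range(1, n_positions + 1):
        letter = heptad_letter(pos)
        choices = _HEPTAD_CHOICES[letter]
        seq.append(choices[(pos + phase) % len(choices)])
    return "".join(seq)


def back_translate(aa_seq: str) -> str:
    """Nucleotide sequence using one fixed codon per amino acid."""
    return "".join(PREFERRED_CODON[aa] for aa in aa_seq)


DEFAULT_N_POSITIONS = 32
DEFAULT_WT_A = synthetic_zipper(DEFAULT_N_POSITIONS, phase=0)
DEFAULT_WT_B = synthetic_zipper(DEFAULT_N_POSITIONS, phase=2)
DEFAULT_WT_NT_A = back_translate(DEFAULT_WT_A)
DEFAULT_WT_NT_B = back_translate(DEFAULT_WT_B)


def all_single_mutations(
    wt_seq: str, protein: str, substitutions: Iterable[str] | None = None
) -> list[Mutation]:
    """All single substitutions of a region (19 per position by default)."""
    muts = []
    for pos, wt_aa in enumerate(wt_seq, start=1):
        subs = substitutions if substitutions is not None else AMINO_ACIDS
        for mut_aa in subs:
            if mut_aa != wt_aa:
                muts.append(Mutation(protein, pos, wt_aa, mut_aa))
    return muts
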