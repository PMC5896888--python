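"""Synthetic deepPCA experiment generator.

Produces UMI count tables with known ground truth so that every
downstream stage (scoring, model fitting, epistasis calling, enrichment)
is testable without sequencing data.  The generative chain is:

1. **Energy landscape** — each single mutant draws a binding free-energy
   change ddG from a two-component mixture: a near-neutral component
   centred at 0 and a detrimental component at large positive ddG
   (reproducing the bimodal single-mutant score distribution, with ~20%
   and ~15% of substitutions severely detrimental in the two proteins).
   Optional sparse couplings add a ddG term to all mutant pairs at chosen
   position pairs ("structural" interactions, zero by default so doubles
   are exactly additive in energy).
2. **True scores** — singles and doubles map through the thermodynamic
   model (``thermo.ppi_from_ddg``) at the configured true parameters.
3. **Competitive growth** — each variant undergoes ``d_i = PPI_i * g``
   population doublings over ``g`` wild-type doublings (plus an optional
   per-replicate additive offset on ``d_i`` emulating background-growth
   batch effects that the mode-alignment correction must remove).
4. **Sequencing** — input counts are multinomial at the design
   frequencies (from :mod:`deeppca.libdesign`), output counts multinomial
   at the post-growth frequencies, per replicate.  The realized
   population doublings ``log2(sum_i f_i 2^{d_i})`` are recorded per
   replicate for the scoring module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import libdesign
from .thermo import ThermoParams, ppi_from_ddg
from .variants import DEFAULT_WT_A, DEFAULT_WT_B, WT_LABEL, Mutation, VariantKey

__all__ = [
    "SimConfig",
    "EnergyLandscape",
    "TrueState",
    "SimResult",
    "sample_landscape",
    "true_tables",
    "simulate_counts",
    "simulate_experiment",
]

#: Fraction of NNS-mutated codons whose wild type ends in G/C (17/32 of
#: bait and 24/32 of prey codons in the reference trans design); used to
#: build design frequencies at any region size.
NNS_WT_FRACTION = {"A": 17 / 32, "B": 24 / 32}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated double deep mutational scan."""

    n_positions: int = 32
    n_subs: int = 19
    mode: str = "trans"  # "trans": A x B doubles; "cis": A x A doubles
    params: ThermoParams = field(
        default_factory=lambda: ThermoParams(1.30, 1.25, 0.700)
    )
    # landscape mixture: P(detrimental) per protein, component shapes (RT units)
    frac_detrimental_a: float = 0.20
    frac_detrimental_b: float = 0.15
    neutral_scale: float = 0.35
    detrimental_loc: float = 6.0
    detrimental_scale: float = 1.5
    # sparse structural couplings: ddG added to every mutant pair at each
    # selected position pair
    n_coupled_pairs: int = 0
    coupling_ddg: float = -1.5
    # growth and sequencing
    generations: float = 10.0
    depth: int = 2_000_000
    n_replicates: int = 3
    mode_shifts: tuple[float, ...] = (0.0, 0.0, 0.0)
    n_doubles: int | None = None  # subsample of the full double space
    sampling: bool = True  # False: expected counts (infinite-depth limit)

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.generations <= 0:
            raise ValueError("depth and generations must be positive")
        if self.mode not in ("trans", "cis"):
            raise ValueError("mode must be 'trans' or 'cis'")
        if len(self.mode_shifts) < self.n_replicates:
            raise ValueError("need one mode shift per replicate")
        for f in (self.frac_detrimental_a, self.frac_detrimental_b):
            if not 0.0 <= f <= 1.0:
                raise ValueError("mixture weights must lie in [0, 1]")


@dataclass
class EnergyLandscape:
    """Ground-truth ddG per single mutant plus sparse pair couplings."""

    singles_a: pd.Series  # index: serialized single keys, values: ddG
    singles_b: pd.Series  # empty in cis mode
    couplings: dict[tuple[int, int], float]  # (posA, posB[or posA2]) -> ddG


@dataclass
class TrueState:
    """True PPI scores and design frequencies of every simulated variant."""

    singles: pd.DataFrame  # index key; columns: true_ppi
    doubles: pd.DataFrame  # index key; columns: s1, s2, true_ppi
    frequencies: pd.Series  # index key (incl. WT); input design frequency


@dataclass
class SimResult:
    counts: pd.DataFrame  # CountTable (rows keyed by variant, incl. WT)
    truth: TrueState
    landscape: EnergyLandscape
    realized_doublings: np.ndarray  # per replicate, log2 of total growth
    config: SimConfig


def _wt_sequences(config: SimConfig) -> tuple[str, str]:
    if config.n_positions > len(DEFAULT_WT_A):
        raise ValueError("n_positions exceeds the bundled synthetic region")
    return (
        DEFAULT_WT_A[: config.n_positions],
        DEFAULT_WT_B[: config.n_positions],
    )


def _substitutions(wt_aa: str, n_subs: int) -> list[str]:
    from .variants import AMINO_ACIDS

    subs = [aa for aa in AMINO_ACIDS if aa != wt_aa]
    return subs[:n_subs]


def _protein_singles(wt_seq: str, protein: str, n_subs: int) -> list[Mutation]:
    muts = []
    for pos, wt_aa in enumerate(wt_seq, start=1):
        for aa in _substitutions(wt_aa, n_subs):
            muts.append(Mutation(protein, pos, wt_aa, aa))
    return muts


def sample_landscape(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> EnergyLandscape:
    """Draw a ground-truth single-mutant ddG landscape (seeded)."""
    rng = np.random.default_rng(rng)
    wt_a, wt_b = _wt_sequences(config)

    def _draw(muts: Sequence[Mutation], frac_detrimental: float) -> pd.Series:
        n = len(muts)
        detr = rng.random(n) < frac_detrimental
        ddg = rng.normal(0.0, config.neutral_scale, size=n)
        ddg[detr] = rng.normal(
            config.detrimental_loc, config.detrimental_scale, size=int(detr.sum())
        )
        return pd.Series(ddg, index=[str(VariantKey((m,))) for m in muts])

    singles_a = _draw(
        _protein_singles(wt_a, "A", config.n_subs), config.frac_detrimental_a
    )
    if config.mode == "trans":
        singles_b = _draw(
            _protein_singles(wt_b, "B", config.n_subs), config.frac_detrimental_b
        )
    else:
        singles_b = pd.Series(dtype=float)

    couplings: dict[tuple[int, int], float] = {}
    if config.n_coupled_pairs > 0:
        npos = config.n_positions
        if config.mode == "trans":
            all_pairs = [(i, j) for i in range(1, npos + 1) for j in range(1, npos + 1)]
        else:
            all_pairs = [
                (i, j) for i in range(1, npos + 1) for j in range(i + 1, npos + 1)
            ]
        chosen = rng.choice(len(all_pairs), size=config.n_coupled_pairs, replace=False)
        for idx in chosen:
            couplings[all_pairs[int(idx)]] = config.coupling_ddg
    return EnergyLandscape(singles_a, singles_b, couplings)


def _double_space(config: SimConfig, landscape: EnergyLandscape) -> pd.DataFrame:
    """All (or a seeded-subsampled set of) double-mutant key pairs."""
    a_keys = landscape.singles_a.index.to_numpy()
    if config.mode == "trans":
        b_keys = landscape.singles_b.index.to_numpy()
        i, j = np.meshgrid(np.arange(len(a_keys)), np.arange(len(b_keys)), indexing="ij")
        s1, s2 = a_keys[i.ravel()], b_keys[j.ravel()]
    else:
        from .variants import parse_variant

        pos = np.array([parse_variant(k).mutations[0].position for k in a_keys])
        i, j = np.meshgrid(np.arange(len(a_keys)), np.arange(len(a_keys)), indexing="ij")
        keep = pos[i.ravel()] < pos[j.ravel()]  # cis: distinct positions, unordered
        s1, s2 = a_keys[i.ravel()[keep]], a_keys[j.ravel()[keep]]
    return pd.DataFrame({"s1": s1, "s2": s2})


def true_tables(
    landscape: EnergyLandscape,
    params: ThermoParams,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> TrueState:
    """Map the landscape through the model and attach design frequencies."""
    from .variants import parse_variant

    rng = np.random.default_rng(rng)
    all_singles = pd.concat([landscape.singles_a, landscape.singles_b])
    singles = pd.DataFrame(
        {"true_ppi": ppi_from_ddg(all_singles.to_numpy(), params)},
        index=all_singles.index,
    )

    doubles = _double_space(config, landscape)
    if config.n_doubles is not None and config.n_doubles < len(doubles):
        take = rng.choice(len(doubles), size=config.n_doubles, replace=False)
        doubles = doubles.iloc[np.sort(take)].reset_index(drop=True)

    ddg1 = all_singles.loc[doubles["s1"]].to_numpy()
    ddg2 = all_singles.loc[doubles["s2"]].to_numpy()
    ddg_d = ddg1 + ddg2
    if landscape.couplings:
        p1 = np.array(
            [parse_variant(k).mutations[0].position for k in doubles["s1"]]
        )
        p2 = np.array(
            [parse_variant(k).mutations[0].position for k in doubles["s2"]]
        )
        for (pa, pb), c in landscape.couplings.items():
            hit = (p1 == pa) & (p2 == pb)
            if config.mode == "cis":
                hit |= (p1 == pb) & (p2 == pa)
            ddg_d = np.where(hit, ddg_d + c, ddg_d)
    keys = [
        str(
            VariantKey(
                parse_variant(a).mutations + parse_variant(b).mutations
            )
        )
        for a, b in zip(doubles["s1"], doubles["s2"])
    ]
    doubles_df = pd.DataFrame(
        {
            "s1": doubles["s1"].to_numpy(),
            "s2": doubles["s2"].to_numpy(),
            "true_ppi": ppi_from_ddg(ddg_d, params),
        },
        index=pd.Index(keys, name="variant"),
    )

    frequencies = _design_frequencies(config, singles.index, doubles_df.index)
    return TrueState(singles=singles, doubles=doubles_df, frequencies=frequencies)


def _design_frequencies(
    config: SimConfig, single_keys: pd.Index, double_keys: pd.Index
) -> pd.Series:
    """Input frequencies from the NNS library design, renormalized over the
    variants actually simulated (codon unit, one codon per substitution)."""
    def _wt_encoding(protein: str) -> int:
        return int(round(config.n_positions * NNS_WT_FRACTION[protein]))

    design_a = libdesign.nns_gene_design(
        libdesign.GeneDesign(config.n_positions, 32, _wt_encoding("A"))
    )
    if config.mode == "trans":
        design_b = libdesign.nns_gene_design(
            libdesign.GeneDesign(config.n_positions, 32, _wt_encoding("B"))
        )
        pair = libdesign.pairwise_library_design(design_a, design_b)
        weights = {"double": pair.freq_double, "wt": pair.freq_wt}
        w_single = {"A": pair.freq_single_a, "B": pair.freq_single_b}
    else:
        # cis: both mutations in protein A; weight classes analogously
        pair = libdesign.pairwise_library_design(design_a, design_a)
        weights = {"double": pair.freq_double, "wt": pair.freq_wt}
        w_single = {"A": pair.freq_single_a, "B": pair.freq_single_a}

    vals = {}
    for k in single_keys:
        vals[k] = w_single[k[0]]
    for k in double_keys:
        vals[k] = weights["double"]
    vals[WT_LABEL] = weights["wt"]
    freqs = pd.Series(vals, dtype=float)
    return freqs / freqs.sum()


def simulate_counts(
    state: TrueState,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample input/output UMI counts for each replicate.

    Returns the count table (columns ``input_r*``, ``output_r*``; rows
    keyed by variant, wild type included) and the realized population
    doublings per replicate, ``log2(sum_i f_in,i 2^{d_i})``.
    """
    rng = np.random.default_rng(rng)
    keys = state.frequencies.index
    f_in = state.frequencies.to_numpy()
    true_ppi = pd.concat(
        [
            state.singles["true_ppi"],
            state.doubles["true_ppi"],
            pd.Series({WT_LABEL: 1.0}),
        ]
    ).loc[keys].to_numpy()

    g = config.generations
    data = {}
    realized = np.empty(config.n_replicates)
    for r in range(config.n_replicates):
        d = true_ppi * g + config.mode_shifts[r]
        growth = f_in * np.exp2(d)
        z = growth.sum()
        realized[r] = np.log2(z)
        f_out = growth / z
        if config.sampling:
            counts_in = rng.multinomial(config.depth, f_in).astype(float)
            counts_out = rng.multinomial(config.depth, f_out).astype(float)
        else:
            counts_in = f_in * config.depth
            counts_out = f_out * config.depth
        data[f"input_r{r + 1}"] = counts_in
        data[f"output_r{r + 1}"] = counts_out
    counts = pd.DataFrame(data, index=pd.Index(keys, name="variant"))
    return counts, realized


def simulate_experiment(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> SimResult:
    """Full generator: landscape -> true scores -> growth -> counts."""
    rng = np.random.default_rng(rng)
    landscape = sample_landscape(config, rng)
    truth = true_tables(landscape, config.params, config, rng)
    counts, realized = simulate_counts(truth, config, rng)
    return SimResult(
        counts=counts,
        truth=truth,
        landscape=landscape,
        realized_doublings=realized,
        config=config,
    )
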