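"""Structural annotation and enrichment of strong genetic interactions.

Coiled-coil positions are annotated by heptad register (letters a-g,
cycling with period 7): *a/d* form the hydrophobic core, *e/g* the
inter-helix salt bridges and *b/c/f* the solvent-facing far side.
Inter-residue distances are the minimal side-chain heavy-atom distances
measured from a PDB-format structure (glycine falls back to its
alpha-carbon).  Strong genetic interactions (|score| > 0.1 and
permutation FDR < 0.2 by default) are then tested for enrichment by
Fisher's exact test in three families — per position pair, per
position-type pair and per distance threshold — with BH FDR controlled
independently per family and sign.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio
from statsmodels.stats.multitest import multipletests

from .variants import heptad_letter, parse_variant

__all__ = [
    "PositionAnnotation",
    "heptad_annotation",
    "annotate_positions",
    "min_sidechain_distances",
    "call_strong",
    "enrichment_tests",
    "DEFAULT_DISTANCE_THRESHOLDS",
]

POSITION_CLASS = {
    "a": "core", "d": "core",
    "e": "salt-bridge", "g": "salt-bridge",
    "b": "far-side", "c": "far-side", "f": "far-side",
}

#: Distance thresholds in Angstrom; 5 A is the contact definition.
DEFAULT_DISTANCE_THRESHOLDS = (5.0, 8.0, 10.0)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class PositionAnnotation:
    position: int
    heptad_number: int
    letter: str
    position_class: str


def heptad_annotation(position: int, register_offset: int = 0) -> PositionAnnotation:
    """Heptad letter, heptad number and position class of one position.

    ``register_offset`` maps position 1 onto the heptad register
    (offset 0 places position 1 at letter *a*).
    """
    letter = heptad_letter(position, register_offset)
    heptad_number = (position - 1 + register_offset) // 7 + 1
    return PositionAnnotation(position, heptad_number, letter, POSITION_CLASS[letter])


def annotate_positions(
    n_positions: int, register_offset: int = 0
) -> pd.DataFrame:
    """Annotation table for positions 1..n of one protein."""
    rows = [heptad_annotation(p, register_offset) for p in range(1, n_positions + 1)]
    return pd.DataFrame(
        {
            "position": [r.position for r in rows],
            "heptad": [r.heptad_number for r in rows],
            "letter": [r.letter for r in rows],
            "position_class": [r.position_class for r in rows],
        }
    ).set_index("position")


# --------------------------------------------------------------------------
# Distances


def min_sidechain_distances(
    pdb_path,
    mapping: pd.DataFrame,
    model_index: int = 0,
) -> pd.DataFrame:
    """Minimal side-chain heavy-atom distance (A) between mapped positions.

    ``mapping`` columns: ``chain``, ``resseq`` (PDB residue number),
    ``protein``, ``position``.  Residues absent from the structure are
    recorded as missing (NaN row/column), not errors.  Glycine, which has
    no side-chain heavy atoms, uses its alpha-carbon.  The result is a
    symmetric DataFrame indexed by ``protein:position`` labels.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", pdb_path)[model_index]

    labels, coords = [], []
    for _, row in mapping.iterrows():
        label = f"{row['protein']}:{int(row['position'])}"
        labels.append(label)
        try:
            residue = model[row["chain"]][int(row["resseq"])]
        except KeyError:
            coords.append(None)
            continue
        atoms = [
            a.coord
            for a in residue.get_atoms()
            if a.element != "H" and a.get_name() not in BACKBONE_ATOMS
        ]
        if not atoms and "CA" in residue:
            atoms = [residue["CA"].coord]
        coords.append(np.asarray(atoms, dtype=float) if atoms else None)

    n = len(labels)
    dist = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        if coords[i] is None or coords[j] is None:
            continue
        d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :], axis=-1)
        dist[i, j] = dist[j, i] = float(d.min())
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=labels, columns=labels)


# --------------------------------------------------------------------------
# Strong calls and enrichment


def call_strong(
    gi: pd.DataFrame,
    magnitude: float = 0.1,
    fdr: float = 0.2,
) -> pd.DataFrame:
    """Flag strong positive/negative interactions.

    Strong means |mean score| strictly greater than ``magnitude`` AND
    permutation FDR strictly below ``fdr``.
    """
    out = pd.DataFrame(index=gi.index)
    out["sign"] = np.where(gi["gi_mean"] > 0, "positive", "negative")
    out["strong"] = (gi["gi_mean"].abs() > magnitude) & (gi["fdr"] < fdr)
    return out


def _positions_of(key: str) -> tuple[str, str]:
    vk = parse_variant(key)
    if vk.arity != 2:
        raise ValueError(f"{key!r} is not a double mutant")
    m1, m2 = vk.mutations
    return f"{m1.protein}:{m1.position}", f"{m2.protein}:{m2.position}"


def _fisher(in_feature: np.ndarray, strong: np.ndarray) -> dict | None:
    tab = np.array(
        [
            [int((in_feature & strong).sum()), int((in_feature & ~strong).sum())],
            [int((~in_feature & strong).sum()), int((~in_feature & ~strong).sum())],
        ]
    )
    if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        return None  # empty margin: test undefined
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    orr = odds_ratio(tab, kind="conditional")
    return {
        "odds_ratio": float(orr.statistic),
        "p_value": float(p),
        "n_strong_in": int(tab[0, 0]),
        "n_in": int(tab[0].sum()),
        "n_strong": int(tab[:, 0].sum()),
        "n_total": int(tab.sum()),
    }


def enrichment_tests(
    calls: pd.DataFrame,
    annotations: dict[str, pd.DataFrame],
    distances: pd.DataFrame | None = None,
    distance_thresholds=DEFAULT_DISTANCE_THRESHOLDS,
    fdr_target: float = 0.1,
) -> pd.DataFrame:
    """Fisher enrichment of strong calls in three feature families.

    ``calls`` is the output of :func:`call_strong` indexed by double-mutant
    key; ``annotations`` maps protein ("A"/"B") to its position-annotation
    table; ``distances`` is the matrix from
    :func:`min_sidechain_distances`.  For each sign, every feature (a
    position pair, a position-type pair, or proximity at a threshold)
    yields a 2x2 table of [in-feature vs not] x [strong vs not]; the
    conditional-MLE odds ratio and the two-sided Fisher p are reported
    with BH FDR controlled independently per family and sign.
    """
    pos_pairs = [_positions_of(k) for k in calls.index]
    pa = np.array([p[0] for p in pos_pairs])
    pb = np.array([p[1] for p in pos_pairs])

    def _class_of(label: str) -> str:
        prot, pos = label.split(":")
        return annotations[prot].loc[int(pos), "position_class"]

    class_a = np.array([_class_of(x) for x in pa])
    class_b = np.array([_class_of(x) for x in pb])

    records = []
    for sign in ("positive", "negative"):
        sign_mask = (calls["sign"] == sign).to_numpy()
        strong = (calls["strong"] & sign_mask).to_numpy()

        # family 1: each observed position pair vs all other pairs
        for pair in sorted(set(zip(pa, pb))):
            in_pair = (pa == pair[0]) & (pb == pair[1])
            res = _fisher(in_pair, strong)
            if res is None:
                records.append(
                    {"family": "position_pair", "sign": sign,
                     "feature": f"{pair[0]}|{pair[1]}", "skipped": True}
                )
                continue
            records.append(
                {"family": "position_pair", "sign": sign,
                 "feature": f"{pair[0]}|{pair[1]}", "skipped": False, **res}
            )

        # family 2: unordered position-type pairs
        type_pairs = sorted(
            {tuple(sorted(t)) for t in zip(class_a, class_b)}
        )
        for tp in type_pairs:
            in_tp = np.array(
                [tuple(sorted(t)) == tp for t in zip(class_a, class_b)]
            )
            res = _fisher(in_tp, strong)
            if res is None:
                records.append({"family": "position_type", "sign": sign,
                                "feature": f"{tp[0]}|{tp[1]}", "skipped": True})
                continue
            records.append({"family": "position_type", "sign": sign,
                            "feature": f"{tp[0]}|{tp[1]}", "skipped": False, **res})

        # family 3: within vs beyond each distance threshold
        if distances is not None:
            pair_dist = np.array(
                [distances.loc[x, y] for x, y in zip(pa, pb)], dtype=float
            )
            for thr in distance_thresholds:
                known = ~np.isnan(pair_dist)
                within = known & (pair_dist <= thr)
                res = _fisher(within[known], strong[known])
                if res is None:
                    records.append({"family": "distance", "sign": sign,
                                    "feature": f"<={thr}A", "skipped": True})
                    continue
                records.append({"family": "distance", "sign": sign,
                                "feature": f"<={thr}A", "skipped": False, **res})

    table = pd.DataFrame(records)
    for col in ("p_value", "odds_ratio"):
        if col not in table.columns:
            table[col] = np.nan
    table["fdr"] = np.nan
    for (_, _), idx in table.groupby(["family", "sign"]).groups.items():
        sub = table.loc[idx]
        ok = sub["skipped"] == False  # noqa: E712
        if ok.any():
            table.loc[sub.index[ok], "fdr"] = multipletests(
                sub.loc[ok, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    table["significant"] = table["fdr"] < fdr_target
    return table
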