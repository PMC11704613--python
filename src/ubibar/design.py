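"""Mass-spaced barcode library design.

Tags of a fixed length are enumerated as residue *compositions* (the intact
mass depends only on the multiset of residues, not their order), sorted by
mass, and selected by a greedy low-to-high sweep that keeps each accepted
composition at least ``spacing`` Da above the previous one.  The greedy sweep
is the maximum-cardinality solution for 1-D minimum-gap selection, so no
larger library exists at the same spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import (
    AMINO_ACIDS,
    MET_CLEAVAGE_RISK_RESIDUES,
    MET_RESIDUE_MASS,
    RESIDUE_MASS,
    UBIQUITIN_SEQUENCE,
    chain_mass,
    validate_sequence,
)


@dataclass(frozen=True)
class BarcodeRecord:
    """One designed barcode: tag sequence, construct masses and design flags."""

    tag: str
    full_mass: float
    met_cleaved_mass: float
    met_cleavage_risk: bool
    library_index: int


def enumerate_tag_masses(length: int = 6, alphabet: str = AMINO_ACIDS) -> pd.DataFrame:
    """Enumerate all residue compositions of a tag and their summed masses.

    Returns one row per residue multiset with columns ``composition`` (the
    residues in sorted order) and ``tag_mass`` (sum of residue monoisotopic
    masses, Da; no terminal water — tags are insertions into an intact chain).
    Rows are sorted by mass, ties by composition string.
    """
    if length < 1:
        raise ValueError("tag length must be >= 1")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    letters = sorted(set(alphabet))
    for aa in letters:
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown residue {aa!r} in alphabet")
    comps = ["".join(c) for c in combinations_with_replacement(letters, length)]
    masses = np.zeros(len(comps))
    # vectorized: mass of a composition = sum of per-letter counts x residue mass
    per_letter = {aa: RESIDUE_MASS[aa] for aa in letters}
    for i, comp in enumerate(comps):
        m = 0.0
        for aa in comp:
            m += per_letter[aa]
        masses[i] = m
    table = pd.DataFrame({"composition": comps, "tag_mass": masses})
    table = table.sort_values(["tag_mass", "composition"], kind="mergesort")
    return table.reset_index(drop=True)


def composition_to_tag(composition: str, avoid_met_risk: bool = False) -> str | None:
    """Deterministic tag sequence for a residue multiset.

    The lexicographically smallest permutation (the sorted composition itself);
    with ``avoid_met_risk`` the smallest residue outside the small-side-chain
    set leads, so the initiator Met is retained.  Returns None when the
    composition has no admissible first residue.
    """
    if not avoid_met_risk:
        return composition
    for i, aa in enumerate(composition):
        if aa not in MET_CLEAVAGE_RISK_RESIDUES:
            return aa + composition[:i] + composition[i + 1:]
    return None


def select_spaced_barcodes(
    table: pd.DataFrame,
    n_target: int = 500,
    spacing: float = 1.0,
    mass_window: tuple[float, float] | None = None,
    avoid_met_risk: bool = False,
    scaffold: str = UBIQUITIN_SEQUENCE,
) -> list[BarcodeRecord]:
    """Greedy low-to-high sweep selecting compositions >= ``spacing`` Da apart.

    ``mass_window`` (lo, hi) restricts the *construct* full mass.  Emits at
    most ``n_target`` records; a shortfall is reported with a warning.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    scaffold_mass = chain_mass(scaffold)
    records: list[BarcodeRecord] = []
    last_mass = -np.inf
    for comp, tag_mass in zip(table["composition"].to_numpy(), table["tag_mass"].to_numpy()):
        if tag_mass - last_mass < spacing:
            continue
        full_mass = scaffold_mass + tag_mass
        if mass_window is not None and not (mass_window[0] <= full_mass <= mass_window[1]):
            continue
        tag = composition_to_tag(comp, avoid_met_risk)
        if tag is None:
            continue
        records.append(
            BarcodeRecord(
                tag=tag,
                full_mass=full_mass,
                met_cleaved_mass=full_mass - MET_RESIDUE_MASS,
                met_cleavage_risk=tag[0] in MET_CLEAVAGE_RISK_RESIDUES,
                library_index=len(records),
            )
        )
        last_mass = tag_mass
        if len(records) >= n_target:
            break
    if len(records) < n_target:
        warnings.warn(
            f"only {len(records)} of {n_target} requested barcodes achievable "
            f"at spacing {spacing} Da",
            stacklevel=2,
        )
    return records


def design_library(
    length: int = 6,
    n_target: int = 500,
    spacing: float = 1.0,
    alphabet: str = AMINO_ACIDS,
    mass_window: tuple[float, float] | None = None,
    avoid_met_risk: bool = False,
    scaffold: str = UBIQUITIN_SEQUENCE,
) -> list[BarcodeRecord]:
    """Enumerate compositions and select a mass-spaced library in one call."""
    table = enumerate_tag_masses(length=length, alphabet=alphabet)
    return select_spaced_barcodes(
        table,
        n_target=n_target,
        spacing=spacing,
        mass_window=mass_window,
        avoid_met_risk=avoid_met_risk,
        scaffold=scaffold,
    )


# ---------------------------------------------------------------------------
# Library QC and I/O
# ---------------------------------------------------------------------------

def cross_form_collisions(
    library: list[BarcodeRecord],
    tol: float = 0.05,
    na_max: int = 4,
) -> set[int]:
    """Library indices whose full or Met-cleaved mass (plus Na-adduct ladders)
    is within ``tol`` Da of a *different* entry's form — i.e. barcodes whose
    MS1 call would be ambiguous.  Useful when picking strains for a screen."""
    from .chem import NA_ADDUCT_SHIFT

    forms: list[tuple[float, int]] = []
    for rec in library:
        for base in (rec.full_mass, rec.met_cleaved_mass):
            for k in range(na_max + 1):
                forms.append((base + k * NA_ADDUCT_SHIFT, rec.library_index))
    forms.sort()
    ambiguous: set[int] = set()
    masses = np.array([f[0] for f in forms])
    owners = np.array([f[1] for f in forms])
    for i, (m, owner) in enumerate(zip(masses, owners)):
        j = i + 1
        while j < len(masses) and masses[j] - m <= tol:
            if owners[j] != owner:
                ambiguous.add(int(owner))
                ambiguous.add(int(owners[j]))
            j += 1
    return ambiguous


def library_to_frame(library: list[BarcodeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "library_index": [r.library_index for r in library],
            "tag": [r.tag for r in library],
            "full_mass": [round(r.full_mass, 4) for r in library],
            "met_cleaved_mass": [round(r.met_cleaved_mass, 4) for r in library],
            "met_cleavage_risk": [int(r.met_cleavage_risk) for r in library],
        }
    )


def write_library_tsv(library: list[BarcodeRecord], path: str | Path) -> None:
    library_to_frame(library).to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> list[BarcodeRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        BarcodeRecord(
            tag=row.tag,
            full_mass=float(row.full_mass),
            met_cleaved_mass=float(row.met_cleaved_mass),
            met_cleavage_risk=bool(row.met_cleavage_risk),
            library_index=int(row.library_index),
        )
        for row in df.itertuples()
    ]


def write_library_fasta(
    library: list[BarcodeRecord], path: str | Path, scaffold: str = UBIQUITIN_SEQUENCE
) -> None:
    """FASTA of full construct protein sequences (Met + tag + scaffold body)."""
    validate_sequence(scaffold)
    with open(path, "w") as fh:
        for rec in library:
            seq = scaffold[0] + rec.tag + scaffold[1:]
            fh.write(f">barcode_{rec.library_index:04d}_{rec.tag} {rec.full_mass:.2f} Da\n")
            fh.write(seq + "\n")
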