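"""Exact monoisotopic mass arithmetic for peptides and barcode constructs.

Everything downstream (ion m/z grids, spectrum simulation, deconvolution
scoring, barcode calling) is built on the element and residue tables defined
here.  Masses are monoisotopic throughout; average-mass mode is out of scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# ---------------------------------------------------------------------------
# Atomic constants (IUPAC/CODATA monoisotopic masses, Da)
# ---------------------------------------------------------------------------

#: Monoisotopic mass of each supported element, Da.
ELEMENT_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "Na": 22.98976928,
}

#: Mass of a proton (charge carrier in positive ESI), Da.  Distinct from the
#: hydrogen atom mass by one electron mass, which matters at 4-decimal m/z.
PROTON_MASS = 1.00727646688

#: Hydrogen atom mass, Da (used for the Na-for-H adduct exchange).
H_MASS = ELEMENT_MASS["H"]

#: Sodium atom mass, Da.
NA_MASS = ELEMENT_MASS["Na"]

#: Mass added per sodium adduct: neutral Na-for-H exchange, Da.
NA_ADDUCT_SHIFT = NA_MASS - H_MASS  # 21.98194425

#: 13C - 12C mass difference, Da; grid step of the aggregated isotope model.
C13_SHIFT = 13.0033548378 - 12.0  # 1.0033548378

WATER_MASS = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]  # 18.0105646859

#: Natural isotope abundances per element, keyed by the integer number of
#: extra neutrons relative to the lightest isotope.  All heavy isotopes are
#: mapped onto the 13C mass grid (aggregated-isotopologue approximation).
ISOTOPE_ABUNDANCE: dict[str, dict[int, float]] = {
    "H": {0: 0.999885, 1: 0.000115},
    "C": {0: 0.9893, 1: 0.0107},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425, 4: 0.0001},
    "Na": {0: 1.0},
}

# ---------------------------------------------------------------------------
# Residue tables (20 canonical amino acids, residue = amino acid - H2O)
# ---------------------------------------------------------------------------

RESIDUE_FORMULA: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

AMINO_ACIDS = "".join(sorted(RESIDUE_FORMULA))  # "ACDEFGHIKLMNPQRSTVWY"


def _formula_mass(formula: dict[str, int]) -> float:
    return sum(n * ELEMENT_MASS[el] for el, n in formula.items())


#: Monoisotopic residue masses, Da, derived from the elemental formulas above.
RESIDUE_MASS: dict[str, float] = {
    aa: _formula_mass(f) for aa, f in RESIDUE_FORMULA.items()
}

#: Residue mass of methionine, Da: the shift removed by N-terminal Met
#: cleavage (methionine aminopeptidase).
MET_RESIDUE_MASS = RESIDUE_MASS["M"]  # 131.04049

#: Human ubiquitin, 76 aa (UniProt P0CG48 monomer) — the barcode scaffold.
UBIQUITIN_SEQUENCE = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

#: First residues favoring Met cleavage by methionine aminopeptidase
#: (small side chains at position 2 of the nascent chain).
MET_CLEAVAGE_RISK_RESIDUES = frozenset("ACGPSTV")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class ElementalComposition(Counter):
    """Integer element counts; addition is element-wise (Counter semantics)."""

    def __init__(self, counts: dict[str, int] | None = None, **kwargs: int):
        super().__init__()
        merged = dict(counts or {})
        merged.update(kwargs)
        for el, n in merged.items():
            if el not in ELEMENT_MASS:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0 or int(n) != n:
                raise ValueError(f"count for {el} must be a non-negative integer, got {n}")
            if n:
                self[el] = int(n)

    @property
    def mass(self) -> float:
        """Monoisotopic mass of the composition, Da."""
        return sum(n * ELEMENT_MASS[el] for el, n in self.items())

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = ElementalComposition()
        for el in set(self) | set(other):
            out[el] = self.get(el, 0) + other.get(el, 0)
        return out


def validate_sequence(seq: str) -> str:
    """Check a peptide sequence against the 20 canonical one-letter codes."""
    if not isinstance(seq, str) or len(seq) == 0:
        raise ValueError("peptide sequence must be a non-empty string")
    for i, aa in enumerate(seq):
        if aa not in RESIDUE_MASS:
            raise ValueError(
                f"unknown amino-acid letter {aa!r} at position {i + 1} in {seq!r}"
            )
    return seq


def peptide_composition(seq: str, *, chain: bool = True) -> ElementalComposition:
    """Elemental composition of a peptide; ``chain=True`` adds the terminal H2O."""
    validate_sequence(seq)
    comp = ElementalComposition()
    for aa in seq:
        comp = comp + ElementalComposition(RESIDUE_FORMULA[aa])
    if chain:
        comp = comp + ElementalComposition({"H": 2, "O": 1})
    return comp


def chain_mass(seq: str) -> float:
    """Monoisotopic mass of an intact peptide chain, Da.

    Sum of residue masses plus one water.  Additive under concatenation:
    ``chain_mass(a + b) == chain_mass(a) + chain_mass(b) - WATER_MASS``.
    """
    validate_sequence(seq)
    return sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def residue_sum(seq: str) -> float:
    """Sum of residue monoisotopic masses (no terminal water), Da."""
    validate_sequence(seq)
    return sum(RESIDUE_MASS[aa] for aa in seq)


@dataclass(frozen=True)
class BarcodeConstruct:
    """A tagged-ubiquitin barcode protein and its two observable masses.

    ``full_mass`` is the scaffold chain mass plus the summed residue masses of
    the N-terminal tag (insertion adds residues only, no extra water);
    ``met_cleaved_mass`` is the same minus one methionine residue, the form
    produced by methionine aminopeptidase.
    """

    tag: str
    scaffold: str = UBIQUITIN_SEQUENCE
    full_mass: float = field(init=False)
    met_cleaved_mass: float = field(init=False)

    def __post_init__(self) -> None:
        validate_sequence(self.tag)
        validate_sequence(self.scaffold)
        object.__setattr__(self, "full_mass", chain_mass(self.scaffold) + residue_sum(self.tag))
        object.__setattr__(self, "met_cleaved_mass", self.full_mass - MET_RESIDUE_MASS)

    @property
    def sequence(self) -> str:
        """Full protein sequence: initiator Met, tag, then the scaffold body."""
        return self.scaffold[0] + self.tag + self.scaffold[1:]

    @property
    def composition(self) -> ElementalComposition:
        return peptide_composition(self.sequence)

    @property
    def met_cleavage_risk(self) -> bool:
        """True when the residue after the initiator Met has a small side chain."""
        return self.tag[0] in MET_CLEAVAGE_RISK_RESIDUES


def construct_masses(tag: str, *, tag_length: int = 6,
                     scaffold: str = UBIQUITIN_SEQUENCE) -> BarcodeConstruct:
    """Build the barcode construct for a tag of the configured length."""
    validate_sequence(tag)
    if len(tag) != tag_length:
        raise ValueError(
            f"tag must be {tag_length} residues long, got {len(tag)} ({tag!r})"
        )
    return BarcodeConstruct(tag=tag, scaffold=scaffold)


# ---------------------------------------------------------------------------
# Isotope patterns (aggregated-isotopologue model on the 13C grid)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopePattern:
    """Relative isotopologue abundances on the 1xC13_SHIFT mass grid."""

    monoisotopic_mass: float
    abundances: np.ndarray  # index k -> abundance of the M+k peak

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(len(self.abundances))

    def peak_masses(self) -> np.ndarray:
        return self.monoisotopic_mass + self.offsets * C13_SHIFT

    @property
    def most_abundant_offset(self) -> int:
        return int(np.argmax(self.abundances))


def _distribution_power(dist: np.ndarray, n: int, cap: int) -> np.ndarray:
    """dist convolved with itself n times (exponentiation by squaring)."""
    result = np.array([1.0])
    base = dist.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:cap]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:cap]
    return result


def isotope_pattern(comp: ElementalComposition, max_peaks: int = 40) -> IsotopePattern:
    """Isotopologue distribution of a composition by per-element convolution.

    All heavy isotopes are placed on the integer 13C grid; the result is
    truncated to ``max_peaks`` entries and renormalized to sum to 1.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    if sum(comp.values()) == 0:
        raise ValueError("composition is empty")
    cap = max_peaks + 8  # headroom before the final truncation
    pattern = np.array([1.0])
    for el, n in comp.items():
        iso = ISOTOPE_ABUNDANCE[el]
        width = max(iso) + 1
        dist = np.zeros(width)
        for k, a in iso.items():
            dist[k] = a
        pattern = np.convolve(pattern, _distribution_power(dist, n, cap))[:cap]
    pattern = pattern[:max_peaks]
    pattern = pattern / pattern.sum()
    return IsotopePattern(monoisotopic_mass=comp.mass, abundances=pattern)


#: Averagine residue: the canonical average-amino-acid elemental model used
#: to approximate isotope envelopes of proteins of unknown sequence.
AVERAGINE_UNIT = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_UNIT_MASS = 111.1254


def averagine_composition(mass: float) -> ElementalComposition:
    """Integer elemental composition approximating a protein of given mass."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    n_units = mass / AVERAGINE_UNIT_MASS
    counts = {el: max(0, round(n_units * f)) for el, f in AVERAGINE_UNIT.items()}
    counts["C"] = max(1, counts["C"])
    return ElementalComposition(counts)


def averagine_pattern(mass: float, max_peaks: int = 40) -> IsotopePattern:
    """Theoretical isotope envelope for an unknown protein of given mass."""
    return isotope_pattern(averagine_composition(mass), max_peaks=max_peaks)


# ---------------------------------------------------------------------------
# External interfaces: scaffold override and table export
# ---------------------------------------------------------------------------

def load_scaffold_fasta(path: str | Path) -> str:
    """Read a single-record protein FASTA to use as the barcode scaffold."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"scaffold FASTA must hold exactly 1 record, found {len(records)}")
    return validate_sequence(str(records[0].seq).upper())


def export_mass_tables(directory: str | Path) -> None:
    """Write the element and residue mass tables as TSV for audit."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "element_masses.tsv", "w") as fh:
        fh.write("element\tmonoisotopic_mass\n")
        for el, m in ELEMENT_MASS.items():
            fh.write(f"{el}\t{m:.10f}\n")
    with open(directory / "residue_masses.tsv", "w") as fh:
        fh.write("residue\tmonoisotopic_mass\tformula\n")
        for aa in AMINO_ACIDS:
            formula = "".join(f"{el}{n}" for el, n in sorted(RESIDUE_FORMULA[aa].items()))
            fh.write(f"{aa}\t{RESIDUE_MASS[aa]:.6f}\t{formula}\n")
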