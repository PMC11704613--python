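"""Theoretical ion features: charge states, sodium adducts, 13C isotopes.

Positive ESI protein ions carry z protons; sodium adducts are modeled as
neutral Na-for-H exchanges (+21.98194 Da each on the neutral mass), so

    m/z = (M + k_iso * C13_SHIFT + k_na * NA_ADDUCT_SHIFT + z * m_proton) / z.

Metabolites are singly charged: [M+H]+ in positive mode, [M-H]- in negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    C13_SHIFT,
    NA_ADDUCT_SHIFT,
    PROTON_MASS,
    BarcodeConstruct,
    averagine_pattern,
)

#: Instrument scan range of the quadrupole-TOF acquisition, Th.
DEFAULT_MZ_WINDOW = (50.0, 1700.0)

#: Default protein charge-state range observed for tagged ubiquitin.
DEFAULT_Z_RANGE = (8, 9, 10, 11, 12)

#: Default maximum sodium-adduct count visible in the spectra.
DEFAULT_NA_MAX = 7


@dataclass(frozen=True)
class IonFeature:
    """One theoretical m/z point of a barcode construct."""

    species: str  # "full" or "met_cleaved"
    charge: int
    n_na: int
    n_iso: int
    mz: float
    in_window: bool = True


def mz_from_mass(mass: float, charge: int, n_na: int = 0, n_iso: int = 0) -> float:
    """m/z of a protonated ion with optional Na adducts and 13C isotopes."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + n_iso * C13_SHIFT + n_na * NA_ADDUCT_SHIFT + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int, n_na: int = 0, n_iso: int = 0) -> float:
    """Invert :func:`mz_from_mass`: neutral monoisotopic mass from one m/z."""
    return charge * (mz - PROTON_MASS) - n_na * NA_ADDUCT_SHIFT - n_iso * C13_SHIFT


def default_iso_max(mass: float, coverage: float = 0.99) -> int:
    """Smallest isotope index bound covering ``coverage`` of the envelope.

    Uses the averagine approximation of the isotope distribution at ``mass``.
    """
    pattern = averagine_pattern(mass, max_peaks=80).abundances
    cum = np.cumsum(pattern)
    return int(np.searchsorted(cum, coverage)) + 1


def barcode_feature_set(
    construct: BarcodeConstruct,
    z_range: Sequence[int] = DEFAULT_Z_RANGE,
    na_max: int = DEFAULT_NA_MAX,
    iso_max: int | None = None,
    include_met_cleaved: bool = True,
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
) -> list[IonFeature]:
    """Full Cartesian grid of theoretical m/z features, sorted by m/z.

    Count = |species| * |z_range| * (na_max+1) * (iso_max+1).  Features outside
    ``mz_window`` are flagged via ``in_window``, not dropped.
    """
    if len(z_range) == 0:
        raise ValueError("z_range must be non-empty")
    if na_max < 0 or (iso_max is not None and iso_max < 0):
        raise ValueError("na_max and iso_max must be >= 0")
    species = {"full": construct.full_mass}
    if include_met_cleaved:
        species["met_cleaved"] = construct.met_cleaved_mass
    features: list[IonFeature] = []
    for name, mass in species.items():
        k_iso_max = default_iso_max(mass) if iso_max is None else iso_max
        for z in z_range:
            for k_na in range(na_max + 1):
                for k_iso in range(k_iso_max + 1):
                    mz = mz_from_mass(mass, z, k_na, k_iso)
                    features.append(
                        IonFeature(
                            species=name,
                            charge=z,
                            n_na=k_na,
                            n_iso=k_iso,
                            mz=mz,
                            in_window=mz_window[0] <= mz <= mz_window[1],
                        )
                    )
    features.sort(key=lambda f: f.mz)
    return features


def metabolite_mz(mass: float, mode: str) -> float:
    """Singly charged metabolite m/z: [M+H]+ (positive) or [M-H]- (negative)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if mode == "positive":
        return mass + PROTON_MASS
    if mode == "negative":
        return mass - PROTON_MASS
    raise ValueError(f"mode must be 'positive' or 'negative', got {mode!r}")


def features_to_frame(features: Iterable[IonFeature]) -> pd.DataFrame:
    rows = [
        (f.species, f.charge, f.n_na, f.n_iso, round(f.mz, 4), int(f.in_window))
        for f in features
    ]
    return pd.DataFrame(
        rows, columns=["species", "charge", "n_na", "n_iso", "mz", "in_window"]
    )


def write_features_tsv(features: Iterable[IonFeature], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, sep="\t", index=False)
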