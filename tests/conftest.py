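"""Shared fixtures: constructs, libraries and simulated FI-MS batches."""

from __future__ import annotations

import numpy as np
import pytest

from ubibar import chem, design, spectra
from ubibar.chem import NA_ADDUCT_SHIFT


@pytest.fixture(scope="session")
def lvfyha():
    return chem.construct_masses("LVFYHA")


@pytest.fixture(scope="session")
def full_library():
    """The complete 1-Da-spaced library over all length-6 compositions."""
    return design.design_library(n_target=600, spacing=1.0)


@pytest.fixture(scope="session")
def small_library():
    """A quick library over a reduced alphabet for cheap calling tests."""
    return design.design_library(length=3, n_target=50, spacing=2.0, alphabet="GASVLF")


def met_safe_indices(library, call_tol: float = 0.05, na_max: int = 4,
                     margin: float = 0.01) -> list[int]:
    """Library entries whose Met-cleaved mass cannot be mistaken for another
    entry's full form (plus Na ladder) at the calling tolerance.

    A Met-cleaved-only strain is resolvable at MS1 only if its observed mass
    has no foreign full-mass interpretation; full-expressing strains are
    always resolvable thanks to the 1 Da library spacing.
    """
    full = np.array([r.full_mass for r in library])
    met = full - chem.MET_RESIDUE_MASS
    ladders = np.concatenate([full + k * NA_ADDUCT_SHIFT for k in range(na_max + 1)])
    owners = np.tile(np.arange(len(full)), na_max + 1)
    safe = []
    for i, m in enumerate(met):
        dist = np.abs(ladders - m)
        dist[owners == i] = np.inf
        if dist.min() > call_tol + margin:
            safe.append(i)
    return safe


def simulate_strain(construct, met_fraction: float, seed: int,
                    mz_window: tuple[float, float], n_scans: int = 5,
                    expressed: bool = True) -> list[spectra.Spectrum]:
    """One synthetic positive-mode injection for a (possibly empty) strain."""
    cfg = spectra.SimulationConfig(
        barcodes=(
            [spectra.BarcodeSignal(construct=construct, met_cleaved_fraction=met_fraction)]
            if expressed else []
        ),
        mz_window=mz_window,
        z_range=(9, 10),
        n_scans=n_scans,
        seed=seed,
        polarities=("positive",),
    )
    scans, _ = spectra.simulate_fims_run(cfg)
    return scans
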