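"""Simplified spectral deconvolution of intact-protein MS1 peak lists.

Isotope series (runs of peaks spaced C13_SHIFT/z) are detected per charge
state, each series is converted to a neutral monoisotopic mass by aligning
its intensity profile against the theoretical averagine isotope envelope
(cosine similarity locates the monoisotopic index, which for a 9-10 kDa
protein usually lies below the detection threshold), and candidates from
different charge states are merged.  Sodium-adduct ladders (+21.98194 Da
steps) are kept as separate masses but cross-linked, because barcode calling
exploits them.  The top masses by summed intensity are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import C13_SHIFT, NA_ADDUCT_SHIFT, PROTON_MASS, averagine_pattern
from .spectra import PeakList

DEFAULT_Z_RANGE = tuple(range(1, 21))
DEFAULT_MZ_TOL = 0.005      # Th, per-gap tolerance for series detection
DEFAULT_COSINE_THRESHOLD = 0.8
DEFAULT_MASS_TOL = 0.05     # Da, candidate merge tolerance
DEFAULT_TOP_K = 5
MIN_SERIES_LENGTH = 3


@dataclass
class IsotopeSeries:
    """A maximal run of peaks spaced C13_SHIFT/z, assigned charge z."""

    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    peak_indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class MassCandidate:
    monoisotopic_mass: float
    intensity: float
    charge: int
    n_peaks: int
    cosine: float
    low_confidence: bool
    peak_indices: tuple[int, ...]


@dataclass
class DeconvolvedMass:
    """One reported neutral mass with its supporting evidence."""

    monoisotopic_mass: float
    summed_intensity: float
    supporting_charges: frozenset[int]
    n_isotope_peaks: int
    na_ladder_detected: bool = False
    na_ladder_base: float | None = None
    low_confidence: bool = False


def find_isotope_series(
    peaks: PeakList,
    z_range: tuple[int, ...] = DEFAULT_Z_RANGE,
    mz_tol: float = DEFAULT_MZ_TOL,
) -> list[IsotopeSeries]:
    """Detect maximal runs of >=3 peaks spaced C13_SHIFT/z +- mz_tol.

    Each charge state is scanned independently; within one charge a peak
    belongs to at most one series.  Series sharing most of their peaks across
    charges are deduplicated later by cosine quality.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    order = np.argsort(peaks.mz)
    mz = peaks.mz[order]
    intensity = peaks.height[order]
    series: list[IsotopeSeries] = []
    for z in z_range:
        gap = C13_SHIFT / z
        used = np.zeros(len(mz), dtype=bool)
        for start in range(len(mz)):
            if used[start]:
                continue
            chain = [start]
            while True:
                target = mz[chain[-1]] + gap
                j = np.searchsorted(mz, target)
                best, best_err = -1, mz_tol
                for cand in (j - 1, j):
                    if 0 <= cand < len(mz) and not used[cand] and cand != chain[-1]:
                        err = abs(mz[cand] - target)
                        if err <= best_err:
                            best, best_err = cand, err
                if best < 0:
                    break
                chain.append(best)
            if len(chain) >= MIN_SERIES_LENGTH:
                used[chain] = True
                idx = np.array(chain)
                series.append(
                    IsotopeSeries(
                        charge=z,
                        mz=mz[idx],
                        intensity=intensity[idx],
                        peak_indices=tuple(int(order[i]) for i in idx),
                    )
                )
    return series


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def series_to_mass(
    series: IsotopeSeries,
    cosine_threshold: float = DEFAULT_COSINE_THRESHOLD,
    ambiguity_delta: float = 0.01,
) -> MassCandidate | None:
    """Locate the monoisotopic index of a series and return its neutral mass.

    The observed intensity profile is slid across the theoretical averagine
    envelope at the series' approximate mass; the best-cosine offset gives the
    isotope index of the series' first peak, hence the monoisotopic mass

        M = z * (mz_first - m_proton) - offset * C13_SHIFT.

    Candidates scoring below ``cosine_threshold`` are rejected (returned as
    None).  When the runner-up offset scores within ``ambiguity_delta`` of
    the best, the candidate is flagged low-confidence — the +-1 Da isotope
    mis-assignment regime familiar from real deconvolution output (short or
    truncated envelopes cannot pin down the monoisotopic index).
    """
    if len(series) < MIN_SERIES_LENGTH:
        raise ValueError("series must contain at least 3 peaks")
    z = series.charge
    approx_mass = z * (series.mz[0] - PROTON_MASS)
    n_obs = len(series)
    pattern = averagine_pattern(max(approx_mass, 100.0), max_peaks=n_obs + 40).abundances
    max_offset = len(pattern) - n_obs
    scores = np.array([
        _cosine(series.intensity, pattern[o:o + n_obs]) for o in range(max_offset + 1)
    ])
    best = int(np.argmax(scores))
    best_score = scores[best]
    if best_score < cosine_threshold:
        return None
    runner_up = np.max(np.delete(scores, best)) if len(scores) > 1 else 0.0
    mass = z * (series.mz[0] - PROTON_MASS) - best * C13_SHIFT
    return MassCandidate(
        monoisotopic_mass=mass,
        intensity=float(series.intensity.sum()),
        charge=z,
        n_peaks=n_obs,
        cosine=best_score,
        low_confidence=bool(best_score - runner_up < ambiguity_delta),
        peak_indices=series.peak_indices,
    )


def _dedupe_candidates(candidates: list[MassCandidate]) -> list[MassCandidate]:
    """Drop candidates sharing >50% of their peaks with a better-scoring one."""
    kept: list[MassCandidate] = []
    for cand in sorted(candidates, key=lambda c: -c.cosine):
        peaks = set(cand.peak_indices)
        if any(len(peaks & set(k.peak_indices)) > 0.5 * len(peaks) for k in kept):
            continue
        kept.append(cand)
    return kept


def aggregate_masses(
    candidates: list[MassCandidate],
    mass_tol: float = DEFAULT_MASS_TOL,
    top_k: int = DEFAULT_TOP_K,
    na_max: int = 7,
) -> list[DeconvolvedMass]:
    """Merge candidates within ``mass_tol`` and rank by summed intensity.

    Merging uses the intensity-weighted mean mass and unions the supporting
    charges.  Masses offset by k * 21.98194 Da from a lighter reported mass
    are flagged as sodium-adduct ladder members, not merged.  Output is sorted
    by summed intensity (descending), ties by lower mass, truncated to
    ``top_k``.
    """
    if not candidates:
        return []
    candidates = sorted(candidates, key=lambda c: c.monoisotopic_mass)
    groups: list[list[MassCandidate]] = [[candidates[0]]]
    for cand in candidates[1:]:
        ref = groups[-1][0].monoisotopic_mass
        if cand.monoisotopic_mass - ref <= mass_tol:
            groups[-1].append(cand)
        else:
            groups.append([cand])
    merged: list[DeconvolvedMass] = []
    for group in groups:
        weights = np.array([c.intensity for c in group])
        masses = np.array([c.monoisotopic_mass for c in group])
        dominant = group[int(np.argmax(weights))]
        merged.append(
            DeconvolvedMass(
                monoisotopic_mass=float(np.average(masses, weights=weights)),
                summed_intensity=float(weights.sum()),
                supporting_charges=frozenset(c.charge for c in group),
                n_isotope_peaks=max(c.n_peaks for c in group),
                low_confidence=dominant.low_confidence,
            )
        )
    # sodium-ladder cross-links
    merged.sort(key=lambda m: m.monoisotopic_mass)
    for i, heavy in enumerate(merged):
        for light in merged[:i]:
            delta = heavy.monoisotopic_mass - light.monoisotopic_mass
            k = round(delta / NA_ADDUCT_SHIFT)
            if 1 <= k <= na_max and abs(delta - k * NA_ADDUCT_SHIFT) <= mass_tol:
                heavy.na_ladder_detected = True
                heavy.na_ladder_base = light.monoisotopic_mass
                break
    merged.sort(key=lambda m: (-m.summed_intensity, m.monoisotopic_mass))
    return merged[:top_k]


def deconvolve_peaks(
    peaks: PeakList,
    z_range: tuple[int, ...] = DEFAULT_Z_RANGE,
    mz_tol: float = DEFAULT_MZ_TOL,
    cosine_threshold: float = DEFAULT_COSINE_THRESHOLD,
    mass_tol: float = DEFAULT_MASS_TOL,
    top_k: int = DEFAULT_TOP_K,
) -> list[DeconvolvedMass]:
    """Full deconvolution pipeline: series -> candidates -> merged top masses."""
    if len(peaks) == 0:
        return []
    series = find_isotope_series(peaks, z_range=z_range, mz_tol=mz_tol)
    candidates = [
        c for s in series
        if (c := series_to_mass(s, cosine_threshold=cosine_threshold)) is not None
    ]
    candidates = _dedupe_candidates(candidates)
    return aggregate_masses(candidates, mass_tol=mass_tol, top_k=top_k)


def masses_to_frame(masses: list[DeconvolvedMass]):
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": np.arange(1, len(masses) + 1),
            "monoisotopic_mass": [round(m.monoisotopic_mass, 4) for m in masses],
            "summed_intensity": [m.summed_intensity for m in masses],
            "charges": [",".join(map(str, sorted(m.supporting_charges))) for m in masses],
            "n_isotope_peaks": [m.n_isotope_peaks for m in masses],
            "na_ladder": [int(m.na_ladder_detected) for m in masses],
            "low_confidence": [int(m.low_confidence) for m in masses],
        }
    )


def write_masses_tsv(masses: list[DeconvolvedMass], path: str | Path) -> None:
    masses_to_frame(masses).to_csv(path, sep="\t", index=False)
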