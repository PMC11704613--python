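"""FI-MS spectrum handling: mzML I/O, scan summation, baseline, peak picking,
and a synthetic flow-injection run generator used for all testing.

A flow-injection acquisition has no chromatographic dimension: each injection
yields ~40 MS1 scans of the same analyte mixture.  Processing reduces one
injection to a single summed spectrum (the highest-TIC scans), removes the
slowly varying baseline, and picks centroided peaks by height and prominence.
"""

from __future__ import annotations

import base64
import json
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .chem import BarcodeConstruct, isotope_pattern
from .ions import metabolite_mz, mz_from_mass

DEFAULT_TOP_N = 32          # scans summed per injection
DEFAULT_MIN_HEIGHT = 5000.0
DEFAULT_MIN_PROMINENCE = 5000.0
DEFAULT_BASELINE_WINDOW = 50.0   # Th
DEFAULT_BASELINE_QUANTILE = 0.10


@dataclass
class Spectrum:
    """One profile MS1 scan (or a summed injection spectrum)."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz array must be strictly increasing")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")

    @property
    def tic(self) -> float:
        """Total ion count of the scan."""
        return float(self.intensity.sum())


@dataclass
class PeakList:
    """Centroided peaks (apex grid positions) with height and prominence."""

    mz: np.ndarray
    height: np.ndarray
    prominence: np.ndarray
    polarity: str = "positive"
    min_height: float = DEFAULT_MIN_HEIGHT
    min_prominence: float = DEFAULT_MIN_PROMINENCE

    def __len__(self) -> int:
        return len(self.mz)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"mz": self.mz, "height": self.height, "prominence": self.prominence}
        )


# ---------------------------------------------------------------------------
# mzML / mzXML reading (pyteomics) and a minimal MS1 mzML writer
# ---------------------------------------------------------------------------

def _decode_binary(text: str, accessions: set[str]) -> np.ndarray:
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _read_mzml_scans(path: Path):
    """Iterate (ms_level, polarity, mz, intensity) from an mzML file.

    A compact namespace-agnostic reader covering the MS1 subset of the format:
    64/32-bit float binary arrays, zlib or no compression.
    """
    import xml.etree.ElementTree as ET

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    for _, elem in ET.iterparse(str(path), events=("end",)):
        if local(elem.tag) != "spectrum":
            continue
        spectrum_accessions = set()
        ms_level = None
        for cv in elem.iter():
            if local(cv.tag) == "cvParam":
                acc = cv.get("accession", "")
                spectrum_accessions.add(acc)
                if acc == "MS:1000511":
                    ms_level = int(cv.get("value", "0"))
        pol = "negative" if "MS:1000129" in spectrum_accessions else "positive"
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter():
            if local(bda.tag) != "binaryDataArray":
                continue
            accs = {cv.get("accession", "") for cv in bda.iter() if local(cv.tag) == "cvParam"}
            binary = next((c for c in bda.iter() if local(c.tag) == "binary"), None)
            if binary is None or binary.text is None:
                continue
            data = _decode_binary(binary.text, accs)
            if "MS:1000514" in accs:
                arrays["mz"] = data
            elif "MS:1000515" in accs:
                arrays["intensity"] = data
        if "mz" in arrays and "intensity" in arrays:
            yield ms_level, pol, arrays["mz"], arrays["intensity"]
        elem.clear()


def read_ms1(path: str | Path, polarity: str | None = None) -> list[Spectrum]:
    """Read MS1 scans from an mzML (or mzXML) file, optionally one polarity.

    Profile data are retained as-is.  A file without MS1 scans returns an
    empty list with a warning.  A truncated or malformed file raises a parse
    error naming the offending position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    spectra: list[Spectrum] = []
    if suffix == ".mzxml":
        from pyteomics import mzxml

        with mzxml.read(str(path)) as reader:
            for scan in reader:
                if int(scan.get("msLevel", 0)) != 1:
                    continue
                pol = "positive" if scan.get("polarity", "+") == "+" else "negative"
                if polarity is not None and pol != polarity:
                    continue
                spectra.append(Spectrum(scan["m/z array"], scan["intensity array"], pol))
    else:
        for ms_level, pol, mz, intensity in _read_mzml_scans(path):
            if ms_level != 1:
                continue
            if polarity is not None and pol != polarity:
                continue
            spectra.append(Spectrum(mz, intensity, pol))
    if not spectra:
        warnings.warn(f"no matching MS1 scans in {path}", stacklevel=2)
    return spectra


def _b64(array: np.ndarray, fmt: str) -> str:
    packed = struct.pack(f"<{len(array)}{fmt}", *array)
    return base64.b64encode(zlib.compress(packed)).decode()


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write MS1 scans as a minimal mzML file (zlib-compressed 64-bit arrays)."""
    path = Path(path)
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        "  <run id=\"run\">",
        f'    <spectrumList count="{len(spectra)}">',
    ]
    for i, spec in enumerate(spectra):
        pol_acc, pol_name = (
            ("MS:1000130", "positive scan")
            if spec.polarity == "positive"
            else ("MS:1000129", "negative scan")
        )
        mz_b64 = _b64(spec.mz, "d")
        int_b64 = _b64(spec.intensity, "d")
        parts += [
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(spec.mz)}">',
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>',
            '        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>',
            f'        <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>',
            f'        <cvParam cvRef="MS" accession="MS:1000285" name="total ion current" value="{spec.tic}"/>',
            '        <binaryDataArrayList count="2">',
            f'          <binaryDataArray encodedLength="{len(mz_b64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>',
            f"            <binary>{mz_b64}</binary>",
            "          </binaryDataArray>",
            f'          <binaryDataArray encodedLength="{len(int_b64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>',
            f"            <binary>{int_b64}</binary>",
            "          </binaryDataArray>",
            "        </binaryDataArrayList>",
            "      </spectrum>",
        ]
    parts += ["    </spectrumList>", "  </run>", "</mzML>"]
    path.write_text("\n".join(parts))


# ---------------------------------------------------------------------------
# Injection reduction: summation, baseline, peak picking
# ---------------------------------------------------------------------------

def sum_top_tic(spectra: Sequence[Spectrum], n: int = DEFAULT_TOP_N) -> Spectrum:
    """Sum the ``n`` highest-TIC scans on a common m/z grid.

    Scans are resampled by linear interpolation onto the grid of the input
    with the finest spacing.  Fewer than ``n`` scans available: all are used,
    with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(spectra) == 0:
        raise ValueError("no spectra to sum")
    polarity = spectra[0].polarity
    if any(s.polarity != polarity for s in spectra):
        raise ValueError("cannot sum spectra of mixed polarity")
    order = np.argsort([-s.tic for s in spectra], kind="stable")
    if len(spectra) < n:
        warnings.warn(
            f"only {len(spectra)} scans available, fewer than the requested {n}; summing all",
            stacklevel=2,
        )
    chosen = [spectra[i] for i in order[:n]]
    # common grid: the grid of the most finely sampled scan
    spacings = [np.min(np.diff(s.mz)) if len(s.mz) > 1 else np.inf for s in chosen]
    grid = chosen[int(np.argmin(spacings))].mz
    total = np.zeros_like(grid)
    for s in chosen:
        if len(s.mz) == len(grid) and np.array_equal(s.mz, grid):
            total += s.intensity
        else:
            total += np.interp(grid, s.mz, s.intensity, left=0.0, right=0.0)
    return Spectrum(grid, total, polarity)


def baseline_adjust(
    spec: Spectrum,
    window: float = DEFAULT_BASELINE_WINDOW,
    quantile: float = DEFAULT_BASELINE_QUANTILE,
) -> Spectrum:
    """Subtract a rolling-window quantile baseline, clipping at zero.

    The baseline is the ``quantile`` of the intensity within consecutive
    ``window``-Th segments, linearly interpolated between segment centers.
    A window wider than the full m/z range degrades to global-quantile
    subtraction.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if not (0 <= quantile < 0.5):
        raise ValueError("quantile must be in [0, 0.5)")
    mz, intensity = spec.mz, spec.intensity
    span = mz[-1] - mz[0] if len(mz) > 1 else 0.0
    if span <= window:
        baseline = np.quantile(intensity, quantile)
        adjusted = np.clip(intensity - baseline, 0.0, None)
        return Spectrum(mz, adjusted, spec.polarity)
    edges = np.arange(mz[0], mz[-1] + window, window)
    centers, levels = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (mz >= lo) & (mz < hi)
        if mask.any():
            centers.append(0.5 * (lo + hi))
            levels.append(np.quantile(intensity[mask], quantile))
    baseline = np.interp(mz, centers, levels)
    adjusted = np.clip(intensity - baseline, 0.0, None)
    return Spectrum(mz, adjusted, spec.polarity)


def pick_peaks(
    spec: Spectrum,
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> PeakList:
    """Local maxima passing both height and prominence thresholds.

    Peak m/z is the apex grid position; no sub-grid fitting is performed.
    """
    idx, props = find_peaks(spec.intensity, height=min_height, prominence=min_prominence)
    return PeakList(
        mz=spec.mz[idx],
        height=props["peak_heights"],
        prominence=props["prominences"],
        polarity=spec.polarity,
        min_height=min_height,
        min_prominence=min_prominence,
    )


def process_injection(
    spectra: Sequence[Spectrum],
    top_n: int = DEFAULT_TOP_N,
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
    baseline_quantile: float = DEFAULT_BASELINE_QUANTILE,
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> tuple[Spectrum, PeakList]:
    """Sum-baseline-pick pipeline for one FI-MS injection."""
    summed = sum_top_tic(spectra, n=top_n)
    adjusted = baseline_adjust(summed, window=baseline_window, quantile=baseline_quantile)
    return adjusted, pick_peaks(adjusted, min_height, min_prominence)


# ---------------------------------------------------------------------------
# Synthetic FI-MS generator
# ---------------------------------------------------------------------------

@dataclass
class BarcodeSignal:
    """One expressed barcode in a simulated sample."""

    construct: BarcodeConstruct
    intensity: float = 2.0e4       # per-scan apex-feature height, a.u.
    met_cleaved_fraction: float = 0.0


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic FI-MS run.

    Emulates one flow-injection acquisition on a quadrupole-TOF: ~40 MS1
    scans per polarity over 50-1700 Th, protein barcode ions in positive mode
    with a Gaussian charge envelope (z centered between 9 and 10), a
    geometrically decaying sodium-adduct ladder (0-7 Na), full 13C isotope
    envelopes, singly charged metabolite ions in both modes, slow baseline
    drift and additive detector noise.
    """

    barcodes: list[BarcodeSignal] = field(default_factory=list)
    metabolite_masses: dict[str, float] = field(default_factory=dict)
    metabolite_log_mean: float = 11.0   # ln-scale mean of per-scan peak height
    metabolite_log_sd: float = 0.8
    z_range: tuple[int, ...] = (8, 9, 10, 11, 12)
    z_center: float = 9.5
    z_sigma: float = 1.2
    na_max: int = 7
    na_decay: float = 0.5               # geometric ladder ratio per adduct
    iso_max: int = 24
    mz_window: tuple[float, float] = (50.0, 1700.0)
    grid_step: float = 0.001            # Th
    peak_fwhm: float = 0.02             # Th, profile peak width
    n_scans: int = 40
    scan_tic_cv: float = 0.15           # scan-to-scan lognormal intensity CV
    baseline_amplitude: float = 300.0
    noise_sd: float = 50.0
    seed: int = 0
    polarities: tuple[str, ...] = ("positive", "negative")


def _place_gaussians(grid: np.ndarray, step: float, mzs: np.ndarray,
                     heights: np.ndarray, sigma: float, out: np.ndarray) -> None:
    """Add Gaussian profile peaks (apex = height) onto a uniform grid."""
    half = int(np.ceil(4 * sigma / step))
    offsets = np.arange(-half, half + 1) * step
    kernel_base = np.exp(-0.5 * (offsets / sigma) ** 2)
    n = len(grid)
    lo_mz = grid[0]
    for mz, h in zip(mzs, heights):
        center = int(round((mz - lo_mz) / step))
        i0, i1 = center - half, center + half + 1
        k0 = max(0, -i0)
        k1 = len(kernel_base) - max(0, i1 - n)
        if k0 >= k1:
            continue
        # shift kernel by the sub-grid offset of the true mz
        frac = mz - (lo_mz + center * step)
        kernel = np.exp(-0.5 * ((offsets[k0:k1] - frac) / sigma) ** 2)
        out[max(0, i0):min(n, i1)] += h * kernel


def simulate_fims_run(cfg: SimulationConfig) -> tuple[list[Spectrum], dict]:
    """Generate synthetic FI-MS scans plus a ground-truth feature manifest.

    Returns scans for each configured polarity and a manifest listing every
    injected feature (kind, polarity, exact m/z, per-scan apex height and the
    identity behind it), enabling oracle tests of the downstream pipeline.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mz_window
    grid = lo + np.arange(int(round((hi - lo) / cfg.grid_step)) + 1) * cfg.grid_step
    sigma = cfg.peak_fwhm / 2.3548
    manifest: dict = {"features": [], "config": {"seed": cfg.seed, "n_scans": cfg.n_scans,
                                                 "mz_window": list(cfg.mz_window),
                                                 "grid_step": cfg.grid_step}}

    # --- assemble the noise-free feature list per polarity -----------------
    features_by_pol: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pol in cfg.polarities:
        mzs: list[float] = []
        heights: list[float] = []
        if pol == "positive":
            for sig in cfg.barcodes:
                species = [("full", sig.construct.full_mass, 1.0 - sig.met_cleaved_fraction),
                           ("met_cleaved", sig.construct.met_cleaved_mass, sig.met_cleaved_fraction)]
                pattern = isotope_pattern(sig.construct.composition, max_peaks=cfg.iso_max + 1)
                iso = pattern.abundances / pattern.abundances.max()
                for name, mass, frac in species:
                    if frac <= 0:
                        continue
                    for z in cfg.z_range:
                        env = np.exp(-0.5 * ((z - cfg.z_center) / cfg.z_sigma) ** 2)
                        for k_na in range(cfg.na_max + 1):
                            w_na = cfg.na_decay ** k_na
                            for k_iso in range(len(iso)):
                                h = sig.intensity * frac * env * w_na * iso[k_iso]
                                if h < 1.0:
                                    continue
                                mz = mz_from_mass(mass, z, k_na, k_iso)
                                if not (lo <= mz <= hi):
                                    continue
                                mzs.append(mz)
                                heights.append(h)
                                manifest["features"].append({
                                    "kind": "barcode", "polarity": pol,
                                    "tag": sig.construct.tag, "species": name,
                                    "charge": z, "n_na": k_na, "n_iso": k_iso,
                                    "mass": mass, "mz": mz, "height_per_scan": h,
                                })
        for met_id, mass in cfg.metabolite_masses.items():
            mz = metabolite_mz(mass, pol)
            if not (lo <= mz <= hi):
                continue
            h = float(rng.lognormal(cfg.metabolite_log_mean, cfg.metabolite_log_sd))
            mzs.append(mz)
            heights.append(h)
            manifest["features"].append({
                "kind": "metabolite", "polarity": pol, "metabolite_id": met_id,
                "mass": mass, "mz": mz, "height_per_scan": h,
            })
        features_by_pol[pol] = (np.array(mzs), np.array(heights))

    # --- render scans -------------------------------------------------------
    scans: list[Spectrum] = []
    for pol in cfg.polarities:
        mzs, heights = features_by_pol[pol]
        clean = np.zeros_like(grid)
        if len(mzs):
            _place_gaussians(grid, cfg.grid_step, mzs, heights, sigma, clean)
        phase = rng.uniform(0, 2 * np.pi)
        baseline = cfg.baseline_amplitude * (
            1.0 + 0.5 * np.sin(2 * np.pi * (grid - lo) / max(hi - lo, 1.0) * 3 + phase)
        )
        for _ in range(cfg.n_scans):
            scale = rng.lognormal(0.0, cfg.scan_tic_cv) if cfg.scan_tic_cv > 0 else 1.0
            intensity = clean * scale + baseline
            if cfg.noise_sd > 0:
                intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=len(grid))
            np.clip(intensity, 0.0, None, out=intensity)
            scans.append(Spectrum(grid, intensity, pol))
    return scans, manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1))
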