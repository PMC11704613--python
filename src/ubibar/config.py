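"""Structured pipeline configuration and the end-to-end orchestration.

All stage defaults collect the study conditions in one place: 32 top-TIC
scans summed, 5000/5000 peak height/prominence, 3 mDa metabolite annotation
tolerance, top-5 deconvolved masses, 0.05 Da call tolerance with up to 4
sodium adducts, 4-fold / p<0.01 significance, charge states 8-12, 0-7
sodium adducts, 1 Da library spacing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import ubibar

logger = logging.getLogger("ubibar")


@dataclass
class DesignConfig:
    length: int = 6
    n_target: int = 500
    spacing: float = 1.0           # Da, nearest-neighbor mass gap
    avoid_met_risk: bool = False
    mass_window: tuple[float, float] | None = None


@dataclass
class FeatureConfig:
    z_lo: int = 8
    z_hi: int = 12
    na_max: int = 7
    iso_max: int | None = None     # None -> 99% envelope coverage
    include_met_cleaved: bool = True


@dataclass
class ProcessConfig:
    top_n: int = 32                # highest-TIC scans summed per injection
    baseline_window: float = 50.0  # Th
    baseline_quantile: float = 0.10
    min_height: float = 5000.0
    min_prominence: float = 5000.0


@dataclass
class DeconvConfig:
    z_lo: int = 1
    z_hi: int = 20
    mz_tol: float = 0.005          # Th
    cosine_threshold: float = 0.8
    mass_tol: float = 0.05         # Da
    top_k: int = 5


@dataclass
class CallConfig:
    call_tol: float = 0.05         # Da
    na_max_call: int = 4


@dataclass
class MetabConfig:
    tol: float = 0.003             # Th (3 mDa)


@dataclass
class StatsConfig:
    fc_cutoff: float = 4.0
    p_cutoff: float = 0.01
    fdr: bool = False


@dataclass
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    process: ProcessConfig = field(default_factory=ProcessConfig)
    deconv: DeconvConfig = field(default_factory=DeconvConfig)
    call: CallConfig = field(default_factory=CallConfig)
    metab: MetabConfig = field(default_factory=MetabConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    verbosity: str = "INFO"

    _BLOCKS = {
        "design": DesignConfig, "features": FeatureConfig, "process": ProcessConfig,
        "deconv": DeconvConfig, "call": CallConfig, "metab": MetabConfig,
        "stats": StatsConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from nested dicts, rejecting unknown keys."""
        cfg = cls()
        for key, value in data.items():
            if key in ("seed", "verbosity"):
                setattr(cfg, key, value)
                continue
            block_cls = cls._BLOCKS.get(key)
            if block_cls is None:
                raise ValueError(f"unknown configuration section {key!r}")
            known = {f.name for f in dataclasses.fields(block_cls)}
            unknown = set(value) - known
            if unknown:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            block = getattr(cfg, key)
            for k, v in value.items():
                setattr(block, k, tuple(v) if isinstance(v, list) else v)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def provenance_header(self) -> str:
        return f"# ubibar {ubibar.__version__} config={self.config_hash}\n"


def write_table(df: pd.DataFrame, path: str | Path, config: PipelineConfig) -> None:
    """Write a TSV with a tool-version + config-hash provenance header."""
    with open(path, "w") as fh:
        fh.write(config.provenance_header())
        df.to_csv(fh, sep="\t", index=False)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample


def run_pipeline(
    config: PipelineConfig,
    sample_sheet: pd.DataFrame,
    library: "list",
    metabolite_table: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
    control_group: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Process -> deconvolve -> call -> annotate -> stats for a sample batch.

    ``sample_sheet`` columns: sample, group, file_pos and optionally file_neg
    (mzML paths).  Re-running with an identical config and inputs reproduces
    identical outputs.  Any stage failure aborts with the stage name and
    sample id.
    """
    from . import calling, deconv, spectra
    from .calling import annotate_metabolites, annotation_matrix, call_barcode

    required = {"sample", "group", "file_pos"}
    if not required <= set(sample_sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    # fail fast on missing inputs before processing anything
    for row in sample_sheet.itertuples():
        for col in ("file_pos", "file_neg"):
            path = getattr(row, col, None)
            if isinstance(path, str) and path and not Path(path).exists():
                raise FileNotFoundError(f"sample {row.sample!r}: missing file {path}")

    calls = []
    hits_by_sample: dict[str, pd.DataFrame] = {}
    top_masses_rows = []
    z_range = tuple(range(config.deconv.z_lo, config.deconv.z_hi + 1))
    for row in sample_sheet.itertuples():
        sample = str(row.sample)
        peaks_by_pol: dict[str, spectra.PeakList] = {}
        for col, pol in (("file_pos", "positive"), ("file_neg", "negative")):
            path = getattr(row, col, None)
            if not isinstance(path, str) or not path:
                continue
            try:
                scans = spectra.read_ms1(path, polarity=pol)
                _, peaks = spectra.process_injection(
                    scans,
                    top_n=config.process.top_n,
                    baseline_window=config.process.baseline_window,
                    baseline_quantile=config.process.baseline_quantile,
                    min_height=config.process.min_height,
                    min_prominence=config.process.min_prominence,
                )
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError("process", sample, exc) from exc
            peaks_by_pol[pol] = peaks
        try:
            masses = deconv.deconvolve_peaks(
                peaks_by_pol.get("positive", spectra.PeakList(
                    mz=pd.Series(dtype=float).to_numpy(),
                    height=pd.Series(dtype=float).to_numpy(),
                    prominence=pd.Series(dtype=float).to_numpy())),
                z_range=z_range,
                mz_tol=config.deconv.mz_tol,
                cosine_threshold=config.deconv.cosine_threshold,
                mass_tol=config.deconv.mass_tol,
                top_k=config.deconv.top_k,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("deconv", sample, exc) from exc
        for rank, m in enumerate(masses, 1):
            top_masses_rows.append(
                {"sample": sample, "rank": rank,
                 "monoisotopic_mass": round(m.monoisotopic_mass, 4),
                 "summed_intensity": m.summed_intensity})
        try:
            calls.append(call_barcode(
                masses, library,
                call_tol=config.call.call_tol,
                na_max_call=config.call.na_max_call,
                sample_id=sample,
            ))
        except Exception as exc:  # noqa: BLE001
            raise StageError("call", sample, exc) from exc
        if metabolite_table is not None:
            try:
                hits_by_sample[sample] = annotate_metabolites(
                    peaks_by_pol.get("positive"), peaks_by_pol.get("negative"),
                    metabolite_table, tol=config.metab.tol,
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError("metab", sample, exc) from exc

    results: dict[str, pd.DataFrame] = {
        "calls": calling.calls_to_frame(calls),
        "top_masses": pd.DataFrame(top_masses_rows),
    }
    if hits_by_sample:
        matrix = annotation_matrix(hits_by_sample)
        results["intensity_matrix"] = matrix
        groups = sample_sheet.set_index("sample")["group"].astype(str)
        groups.index = groups.index.astype(str)
        ctrl = control_group or groups.iloc[0]
        if (groups == ctrl).sum() >= 1 and len(set(groups)) > 1:
            try:
                results["differential"] = calling.differential_stats(
                    matrix, groups, ctrl,
                    fc_cutoff=config.stats.fc_cutoff,
                    p_cutoff=config.stats.p_cutoff,
                    fdr=config.stats.fdr,
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError("stats", "<batch>", exc) from exc
        if len(matrix) >= 2:
            results["pca_scores"] = calling.pca_scores(matrix).reset_index(names="sample")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        for name, df in results.items():
            out = df.reset_index(names="sample") if name == "intensity_matrix" else df
            write_table(out, outdir / f"{name}.tsv", config)
    return results
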