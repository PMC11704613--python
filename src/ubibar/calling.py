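"""Barcode calling against a library, metabolite annotation and differential
statistics.

A sample's top deconvolved masses are tested against every library entry's
full and Met-cleaved construct masses plus sodium-adduct ladders; the best
interpretation classifies the sample as full-matched, Met-cleaved-matched or
not-matched.  Metabolite peaks are annotated by exact monoisotopic mass
([M+H]+ / [M-H]-) against a metabolite mass table; per-metabolite fold
changes versus a control group are tested with a two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chem import NA_ADDUCT_SHIFT
from .deconv import DeconvolvedMass
from .design import BarcodeRecord
from .ions import metabolite_mz
from .spectra import PeakList

DEFAULT_CALL_TOL = 0.05       # Da; observed barcode errors never exceeded this
DEFAULT_NA_MAX_CALL = 4       # adducts considered when matching
DEFAULT_ANNOTATION_TOL = 0.003  # Th (3 mDa)
DEFAULT_FC_CUTOFF = 4.0
DEFAULT_P_CUTOFF = 0.01

STATUS_FULL = "full_matched"
STATUS_MET = "met_cleaved_matched"
STATUS_NONE = "not_matched"


@dataclass
class BarcodeCall:
    """The barcode-identity decision for one sample."""

    sample_id: str
    best_barcode: int | None
    status: str
    matched_rank: int | None = None
    mass_error: float | None = None
    na_count_used: int | None = None
    tag: str | None = None
    diagnostic: str = ""


def call_barcode(
    top_masses: list[DeconvolvedMass],
    library: list[BarcodeRecord],
    call_tol: float = DEFAULT_CALL_TOL,
    na_max_call: int = DEFAULT_NA_MAX_CALL,
    sample_id: str = "",
) -> BarcodeCall:
    """Match ranked deconvolved masses against all library barcode forms.

    Every mass is tested against each entry's full and Met-cleaved masses plus
    k * 21.98194 Da sodium shifts (k <= ``na_max_call``) at ``call_tol``.  The
    winning interpretation has the lowest deconvolution rank; at equal rank a
    full (uncleaved) form beats a Met-cleaved one, fewer adducts beat more,
    then smallest |error| decides.
    """
    if not library:
        raise ValueError("barcode library is empty")
    if not top_masses:
        return BarcodeCall(sample_id, None, STATUS_NONE,
                           diagnostic="no deconvolved masses")
    # (rank, species_pref, na_count, |error|) -> candidate
    best_key: tuple | None = None
    best: BarcodeCall | None = None
    for rank, dm in enumerate(top_masses, start=1):
        for rec in library:
            for species, base in (("full", rec.full_mass), ("met", rec.met_cleaved_mass)):
                # nearest adduct count for this mass, clamped to the ladder
                k = round((dm.monoisotopic_mass - base) / NA_ADDUCT_SHIFT)
                if not 0 <= k <= na_max_call:
                    continue
                err = dm.monoisotopic_mass - (base + k * NA_ADDUCT_SHIFT)
                if abs(err) > call_tol:
                    continue
                key = (rank, species != "full", k, abs(err))
                if best_key is None or key < best_key:
                    best_key = key
                    best = BarcodeCall(
                        sample_id=sample_id,
                        best_barcode=rec.library_index,
                        status=STATUS_FULL if species == "full" else STATUS_MET,
                        matched_rank=rank,
                        mass_error=err,
                        na_count_used=k,
                        tag=rec.tag,
                    )
        if best is not None:
            break  # a match at this rank cannot be beaten by a later rank
    if best is None:
        return BarcodeCall(sample_id, None, STATUS_NONE,
                           diagnostic="no library form within tolerance")
    return best


def calls_to_frame(calls: list[BarcodeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample_id for c in calls],
            "status": [c.status for c in calls],
            "library_index": [c.best_barcode for c in calls],
            "tag": [c.tag for c in calls],
            "matched_rank": [c.matched_rank for c in calls],
            "mass_error": [None if c.mass_error is None else round(c.mass_error, 4) for c in calls],
            "na_count_used": [c.na_count_used for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# Metabolite annotation
# ---------------------------------------------------------------------------

def load_bundled_metabolite_table() -> pd.DataFrame:
    """Small bundled metabolite monoisotopic-mass table (E. coli primary
    metabolism; columns: metabolite_id, name, monoisotopic_mass)."""
    with resources.files("ubibar.data").joinpath("metabolites_ecoli.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def read_metabolite_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"metabolite_id", "monoisotopic_mass"}
    if not required <= set(table.columns):
        raise ValueError(f"metabolite table must have columns {sorted(required)}")
    return table


def annotate_metabolites(
    peaks_pos: PeakList | None,
    peaks_neg: PeakList | None,
    mass_table: pd.DataFrame,
    tol: float = DEFAULT_ANNOTATION_TOL,
) -> pd.DataFrame:
    """Annotate peaks by exact mass per ionization mode and merge the modes.

    Matching is two-sided at ``tol`` Th against [M+H]+ (positive peaks) and
    [M-H]- (negative peaks).  A peak within tolerance of several isobaric
    metabolites yields one hit per metabolite.  A metabolite annotated in both
    modes keeps only its negative-mode hit.
    """
    if len(mass_table) == 0:
        warnings.warn("empty metabolite mass table; no annotations", stacklevel=2)
        return pd.DataFrame(
            columns=["metabolite_id", "theoretical_mass", "mode", "mz", "mz_error", "height"]
        )
    hits: list[dict] = []
    for mode, peaks in (("positive", peaks_pos), ("negative", peaks_neg)):
        if peaks is None or len(peaks) == 0:
            continue
        targets = np.array([metabolite_mz(m, mode) for m in mass_table["monoisotopic_mass"]])
        order = np.argsort(targets)
        sorted_targets = targets[order]
        for mz, height in zip(peaks.mz, peaks.height):
            lo = np.searchsorted(sorted_targets, mz - tol)
            hi = np.searchsorted(sorted_targets, mz + tol, side="right")
            for j in range(lo, hi):
                row = mass_table.iloc[order[j]]
                hits.append(
                    {
                        "metabolite_id": row["metabolite_id"],
                        "theoretical_mass": float(row["monoisotopic_mass"]),
                        "mode": mode,
                        "mz": float(mz),
                        "mz_error": float(mz - sorted_targets[j]),
                        "height": float(height),
                    }
                )
    result = pd.DataFrame(hits)
    if len(result) == 0:
        return pd.DataFrame(
            columns=["metabolite_id", "theoretical_mass", "mode", "mz", "mz_error", "height"]
        )
    # negative mode wins when a metabolite is annotated in both modes
    has_negative = set(result.loc[result["mode"] == "negative", "metabolite_id"])
    keep = (result["mode"] == "negative") | (~result["metabolite_id"].isin(has_negative))
    result = result[keep].reset_index(drop=True)
    # one height per metabolite: the most intense annotated peak in the kept mode
    result = (
        result.sort_values("height", ascending=False)
        .drop_duplicates("metabolite_id")
        .sort_values("metabolite_id")
        .reset_index(drop=True)
    )
    return result


def annotation_matrix(per_sample_hits: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-sample annotation tables into a samples x metabolites matrix
    of peak heights (missing metabolites -> NaN)."""
    series = {
        sample: hits.set_index("metabolite_id")["height"]
        for sample, hits in per_sample_hits.items()
    }
    return pd.DataFrame(series).T.sort_index()


# ---------------------------------------------------------------------------
# Differential statistics and PCA
# ---------------------------------------------------------------------------

def differential_stats(
    intensities: pd.DataFrame,
    groups: pd.Series,
    control_group: str,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-metabolite fold change and Welch t-test versus the control group.

    ``intensities`` is samples x metabolites; ``groups`` maps sample -> group
    label.  Missing values are excluded pairwise.  Significance requires
    fold change > ``fc_cutoff`` or < 1/``fc_cutoff`` and p < ``p_cutoff``
    (raw p by default; ``fdr=True`` adds Benjamini-Hochberg q-values and
    tests those instead).
    """
    groups = groups.reindex(intensities.index)
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} absent from sample groups")
    control = intensities.loc[groups == control_group]
    rows: list[dict] = []
    for group_name in [g for g in pd.unique(groups) if g != control_group]:
        case = intensities.loc[groups == group_name]
        for metabolite in intensities.columns:
            x = case[metabolite].dropna().to_numpy()
            y = control[metabolite].dropna().to_numpy()
            control_mean = y.mean() if len(y) else np.nan
            case_mean = x.mean() if len(x) else np.nan
            undefined = not np.isfinite(control_mean) or control_mean == 0
            fc = np.nan if undefined else case_mean / control_mean
            if len(x) >= 2 and len(y) >= 2:
                p = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
            else:
                p = np.nan
            rows.append(
                {
                    "group": group_name,
                    "metabolite_id": metabolite,
                    "fold_change": fc,
                    "log2fc": np.log2(fc) if np.isfinite(fc) and fc > 0 else np.nan,
                    "p_value": p,
                    "undefined_fc": undefined,
                }
            )
    result = pd.DataFrame(rows)
    if len(result) == 0:
        result["significant"] = []
        return result
    p_for_test = result["p_value"]
    if fdr:
        from statsmodels.stats.multitest import multipletests

        mask = result["p_value"].notna()
        q = np.full(len(result), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(
                result.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        result["q_value"] = q
        p_for_test = result["q_value"]
    big = (result["fold_change"] > fc_cutoff) | (result["fold_change"] < 1.0 / fc_cutoff)
    result["significant"] = (big & (p_for_test < p_cutoff)).fillna(False)
    return result


def pca_scores(intensities: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the first principal components of the log-transformed,
    mean-centered intensity matrix (missing values imputed with the
    per-metabolite minimum)."""
    if len(intensities) < 2:
        raise ValueError("PCA requires at least 2 samples")
    from sklearn.decomposition import PCA

    filled = intensities.apply(lambda col: col.fillna(col.min()), axis=0)
    filled = filled.dropna(axis=1, how="any")
    logged = np.log10(filled + 1.0)
    centered = logged - logged.mean(axis=0)
    n_components = min(n_components, min(centered.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centered.to_numpy())
    out = pd.DataFrame(
        scores,
        index=intensities.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    out.attrs["explained_variance"] = pca.explained_variance_
    return out
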