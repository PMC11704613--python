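# Methods

This document records the model, the parameter defaults, and the numerical
choices behind `ubibar`, including what the bundled simulator does and does not
emulate.

## 1. Mass model

All masses are monoisotopic. Constants (Da):

| quantity | value |
| --- | --- |
| proton mass (charge carrier) | 1.00727646688 |
| H atom mass | 1.0078250319 |
| ¹³C–¹²C shift | 1.0033548378 |
| Na-for-H adduct shift (m_Na − m_H) | 21.98194425 |
| water (terminal groups) | 18.0105646859 |

Residue masses are derived from elemental formulas, not hard-coded, so the
isotope machinery and the scalar masses cannot drift apart. A peptide chain's
mass is the sum of residue masses plus one water.

**Construct topology.** A barcode construct is the 76-residue ubiquitin
scaffold with the 6-residue tag inserted directly after the initiator
methionine: sequence = `M` + tag + scaffold[1:]. Because the tag is an
insertion into an intact chain, its mass contribution is exactly the sum of its
residue masses (no extra water). The Met-cleaved form (loss of Met1 by
methionine aminopeptidase) is the full mass minus the Met residue mass,
131.04049 Da. Cleavage risk is flagged when the residue following Met1 is small
(A, C, G, P, S, T or V).

Reference values used throughout the tests: tag `LVFYHA` gives a full mass of
9,290.00 Da (2-decimal) and a Met-cleaved mass of 9,158.96 Da; the 10+ ion sits
at 930.01 Th and the 9+ ion at 1,033.23 Th.

## 2. Isotope patterns

Isotopologues are aggregated on the ¹³C nucleon grid (spacing 1.0033548 Da):
each element's isotope distribution is convolved into the pattern using
exponentiation-by-squaring of per-element polynomials, which is exact for the
aggregated model and fast for proteins (thousands of atoms). For series whose
elemental composition is unknown, an averagine pseudo-residue
(C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇ per 111.1254 Da) approximates the
envelope; for ~9 kDa constructs the exact-vs-averagine cosine exceeds 0.99.

An independent brute-force oracle (atom-by-atom polynomial expansion) is kept
in the test suite and checked against the implementation for molecules up to 30
atoms at 1e-10 absolute tolerance.

## 3. Library design

All multisets of 6 residues over the 20 standard amino acids are enumerated —
C(25,6) = 177,100 compositions — sorted by summed residue mass, and swept low
to high, keeping each composition at least `spacing` Da above the last kept.
At 1 Da spacing this selects **595** barcodes; requesting more than is
achievable returns the maximum with a warning, never silently fewer
constraints. One concrete tag per composition is chosen deterministically
(lexicographically smallest permutation; optionally excluding
Met-cleavage-risk first residues). The greedy sweep is provably optimal for
1-D spacing selection and is verified against an exhaustive pure-Python oracle
on reduced alphabets.

## 4. Ion features

For neutral mass M, charge z, k_na sodium adducts and k_iso ¹³C substitutions:

```
m/z = (M + k_na · 21.98194425 + k_iso · 1.0033548378 + z · 1.00727646688) / z
```

Default grids: z = 8–12, k_na = 0–7, k_iso up to 99% cumulative envelope
coverage (about 12–14 for 9 kDa). Features outside the 50–1700 Th scan window
are flagged, not dropped. Metabolites are matched as [M+H]⁺ / [M−H]⁻ singly
charged ions.

## 5. Spectrum processing

Per injection: the 32 highest-TIC MS1 scans are summed (resampled onto the
finest common m/z grid by linear interpolation), a rolling-window quantile
baseline (50 Th window, 10th percentile) is subtracted and clipped at zero, and
peaks are picked with `scipy.signal.find_peaks` at minimum height 5000 and
minimum prominence 5000 (prominence suppresses shoulders of tall peaks that
pure height thresholds would keep).

mzML reading is a small namespace-agnostic MS1 reader (ElementTree iterparse,
zlib/base64 binary arrays, standard accession numbers for m/z, intensity,
polarity and MS level); mzXML is read via pyteomics. This keeps the package
free of optional mzML-writer dependencies that are not needed offline.

## 6. Deconvolution

A deliberately simplified, FLASHDeconv-inspired scheme:

1. **Series detection.** For each charge hypothesis z, maximal runs of ≥ 3
   picked peaks spaced 1.0033548/z ± 0.005 Th.
2. **Monoisotopic alignment.** The series' intensity vector is compared by
   cosine similarity against the averagine envelope at every plausible
   monoisotopic offset; the best offset dates the monoisotopic peak, giving
   M = z·(mz_first − m_proton) − offset·1.0033548. Candidates with best cosine
   < 0.8 are rejected.
3. **Harmonic removal.** Candidates sharing > 50% of their peaks keep only the
   higher-cosine interpretation (kills z/2, z/3 harmonics).
4. **Aggregation.** Candidates within 0.05 Da merge across charge states
   (intensity-weighted mean mass); results are ranked by summed intensity and
   truncated to the top 5. Masses 21.982·k Da above a stronger mass are flagged
   as sodium-ladder members and cross-linked to the base, never merged.

**Low-confidence criterion.** The ±1 isotope mis-assignment risk is surfaced,
not silently corrected: a mass is flagged low-confidence when the best
alignment cosine exceeds the runner-up offset's cosine by less than 0.01
(absolute). A ratio criterion was rejected because adjacent-offset cosines for
9 kDa envelopes are intrinsically ~0.97 of the best even for perfect data. Note
that an envelope whose monoisotopic peak is simply missing is still recovered
*correctly* by the alignment; a genuine +1.0034 Da error requires the intensity
pattern itself to be shifted, and short apex-only runs (little envelope
asymmetry) are the typical low-confidence case.

## 7. Barcode calling

Each of the top-5 masses is tested against every library entry's full and
Met-cleaved masses plus k·21.982 Da (k ≤ 4) at 0.05 Da tolerance. The winning
interpretation minimizes, in order: deconvolution rank, then species (full
before Met-cleaved), then adduct count, then |error|.

**Why full-before-Met:** with a 1 Da-spaced library, about 40% of entries'
Met-cleaved masses fall within 0.05 Da of some *other* entry's full (or
adducted full) mass. Preferring the full interpretation at equal rank makes
calls for full-expressing strains provably unambiguous; strains expressing
*only* the Met-cleaved form are resolvable at MS1 only when their cleaved mass
has no foreign full-form interpretation (the library QC function
`cross_form_collisions` reports exactly which entries those are, and the test
batches draw Met-only strains from that safe subset). Calling also assumes the
injected strain carries a tag from the supplied library; a foreign construct
can legitimately match another entry's Met-cleaved form.

## 8. Metabolite annotation and statistics

Peaks are matched against a metabolite monoisotopic-mass table (a ~50-compound
E. coli table is bundled; any TSV with `metabolite_id` and `monoisotopic_mass`
works) at 3 mDa, as [M+H]⁺ in positive and [M−H]⁻ in negative mode. Isobaric
metabolites each receive a hit; a metabolite annotated in both modes keeps the
negative-mode hit (fewer adduct ambiguities in negative ESI for acids). Per
metabolite and group, fold change versus the control group mean and a Welch
(unequal-variance) t-test are computed with pairwise missing-value exclusion;
significance requires fold change > 4 or < 1/4 and p < 0.01
(Benjamini–Hochberg q-values optional). PCA scores are computed on
log10(x + 1)-transformed, mean-centered intensities.

## 9. Simulator

`simulate_fims_run` generates MS1 scans on a 1 mTh grid: for each barcode, a
Gaussian charge envelope (center 9.5, width 1.2 charges), a geometric
sodium-adduct decay (ratio 0.5), and the *exact* per-composition isotope
envelope; peaks are Gaussian with 0.02 Th FWHM placed with sub-grid offsets.
Metabolites get lognormal heights in both polarities. Scans vary by a TIC
coefficient of variation (0.15), over a sinusoidal baseline plus Gaussian
noise. All randomness flows from a single `numpy.random.default_rng(seed)`, so
runs are exactly reproducible. A manifest records every feature's kind, m/z
and height for ground-truth checks.

Emulated: isotope/charge/adduct structure, baseline, additive noise,
scan-to-scan intensity variation, Met-cleavage mixtures, both polarities.
Not emulated: chromatographic or injection-time profiles, detector saturation,
space-charge m/z shifts, isotope fine structure within a nucleon number,
non-Na adducts, in-source fragmentation.

## 10. Problem sizes in tests

The full-scale settings (40 scans, 32 summed, z 8–12, 50–1700 Th window) are
package defaults. The test and acceptance batches deliberately scale down the
*simulation* — 5 scans, z 9–10, a ~870–1090 Th window — to keep a 100-strain
suite within a CPU-minutes budget; the processing and calling code paths under
test are identical, and the 32-scan reduction logic is covered separately with
a fewer-scans warning. Deconvolution in the round-trip tests searches z 5–15,
a superset of the simulated charges, so charge assignment is genuinely tested.

## 11. Limitations

- MS1-only: no fragmentation evidence; isobaric tags are excluded by design
  spacing, not resolved.
- The calling-preference rule (Section 7) is a documented design choice where
  the full/Met-cleaved ambiguity is otherwise unresolvable at MS1.
- The averagine alignment assumes protein-like compositions; unusual
  sulfur-rich analytes would degrade the cosine score rather than mis-assign.
- The bundled metabolite table is a small demonstration set, not a
  genome-scale model.
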