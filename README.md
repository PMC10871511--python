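# eifrag

Combinatorial electron-ionization (EI) fragment prediction and spectrum
fingerprint scoring for unfunctionalized amino acids and short peptides.

## The problem

Electron ionization shatters a peptide into many small fragments, and under
direct-exposure-probe EI-MS (DEP-EI-MS) even unfunctionalized peptides can be
volatilized into the beam. The resulting spectra are rich but hard to read:
dozens of peaks, many of which converge to similar low m/z values. `eifrag`
is for chemists who synthesize short peptides and want to check, from a crude
sample's EI spectrum, whether the intended sequence is plausibly present —
without access to softer ESI/MALDI instrumentation.

## The model

Every species is an integer elemental-composition vector
`[#C, #H, #N, #O, #S, z]`; monoisotopic masses give the m/z at unit positive
charge (the molecular ion M⁺ is the radical cation, so its m/z equals the
neutral monoisotopic mass). Fragments are generated by systematically
combining three ingredients:

* **Backbone cleavage** of the original peptide: Type A (Cα–C(=O)),
  Type B (the amide bond) and Type C (N–Cα, observed only at the aromatic
  residues F/W/Y). Cleavage is homolytic — each piece keeps exactly the
  atoms on its side of the severed bond — and for Types A and B both
  complementary pieces are kept as candidate cations.
* **C-terminal carboxyl degradations**: −CO₂H (M−45), −OH (M−17),
  −H₂O (M−18), each optionally combined with alkene formation (−H) at
  K/P/I, giving the observed combined M−46.
* **Side-chain events** from an editable plain-text catalogue: *relative*
  neutral/radical losses (ammonia from N/Q, β-elimination from S/T/C,
  side-chain carboxyl losses from D/E, guanidino losses from R, whole
  side-chain loss leaving the common C₂H₄NO₂⁺ backbone cation at m/z 74, …)
  which shift the parent mass and can combine, at most one per residue
  position; and *charged* (non-relative) side-chain cations (benzyl C₇H₇⁺
  at 91.1 from F, C₄H₅N₂⁺ at 81.0 from H, …) whose m/z is fixed regardless
  of sequence context and which terminate their pathway.

Side-chain fragmentation recurses over all backbone and C-terminal products;
duplicates (same formula via the same event multiset) and negative-atom-count
species are filtered. Each surviving fragment carries its full mechanism
path, e.g. `typeB@Q1-F2 > side ammonia loss@Q1`.

Observed peak lists are then annotated against this fingerprint with a
±0.25 m/z instrumental tolerance, known protecting-group contaminant peaks
(Fmoc, Trt, Pbf, Boc/OtBu) are masked, and a threshold fitness score reports
the percentage of peaks at ≥5% or ≥25% of the base-peak intensity that match
a prediction.

## Worked example

Predict the fingerprint of the tripeptide QFA (55 unique fragments,
including the intact molecular ion at 364.1747):

```
$ eifrag predict --sequence QFA | head -8
# sequence: QFA	catalogue: built-in
m/z	composition	path
44.9977	CHO2+	typeA@A3
57.0215	C2H3NO+	typeB@Q1-F2 > side chain loss@Q1
72.0324	C2H4N2O+	typeC@F2 > side chain loss@Q1
88.0399	C3H6NO2+	typeB@F2-A3
91.0548	C7H7+	charged side chain loss@F2
101.0715	C4H9N2O+	typeA@Q1
```

Simulate a noisy crude-sample spectrum of QFA (80% of the fingerprint
observed, Gaussian m/z jitter, Fmoc contaminant peaks, random background)
and score it against its own sequence and against the unrelated CIA:

```
$ eifrag simulate --config fixture.cfg --out qfa_sim.txt
$ eifrag score --spectrum qfa_sim.txt --sequence QFA --contaminants fmoc
spectrum	sequence	threshold	n_considered	n_matched	percent	mean_abs_error	sd_abs_error
qfa_sim.txt	QFA	0.05	20	17	85.0	0.0373	0.0312
qfa_sim.txt	QFA	0.25	9	8	88.9	0.0431	0.0384
$ eifrag score --spectrum qfa_sim.txt --sequence CIA --contaminants fmoc
spectrum	sequence	threshold	n_considered	n_matched	percent	mean_abs_error	sd_abs_error
qfa_sim.txt	CIA	0.05	20	3	15.0	0.0385	0.0522
qfa_sim.txt	CIA	0.25	9	2	22.2	0.0498	0.0684
```

The true sequence explains 85–89% of the thresholded non-contaminant peaks;
the composition-disjoint decoy explains 15–22% — the fingerprint
discriminates. (`fixture.cfg` here contained `sequence = QFA`,
`fraction_of_predictions_observed = 0.8`, `mz_jitter_sd = 0.08`,
`n_background_peaks = 15`, `contaminant_set = fmoc`, `seed = 1`.)

The same operations are available as a library: `enumerate_fragments`,
`match_peaks`, `score_spectrum`, `generate_synthetic_spectrum`. New
fragmentation mechanisms can be added without touching code via
`--definitions FILE`; see `src/eifrag/data/mechanisms.txt` for the dialect
and the default catalogue.

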