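# Methods

## Model overview

`eifrag` predicts the set of fragment m/z values ("fingerprint") that a
short, unfunctionalized peptide can produce under 70-eV-class electron
ionization, and scores observed peak lists against that fingerprint. The
model is purely combinatorial: it applies a catalogue of empirically
grounded fragmentation events in all allowed combinations and keeps
exhaustive bookkeeping of which events produced each fragment. It predicts
*which* m/z values can occur, not their intensities.

All species are six-component integer vectors `[#C,#H,#N,#O,#S,z]`.
Monoisotopic atomic masses are C 12.000000, H 1.0078250319, N 14.0030740052,
O 15.9949146221, S 31.97207069 Da. For singly charged cations the electron
mass (0.00055 Da) is neglected; the error is three orders of magnitude below
the 0.25 Th matching tolerance. Only |z| = 1 species have a defined m/z in
this version; the charge field is carried structurally so that multiply
charged arithmetic can be added later. The molecular ion M⁺ is the radical
cation: its m/z equals the neutral monoisotopic mass with z = +1 and no
proton added.

Peptides are assembled N-terminus-first from free-amino-acid formulas, one
water subtracted per peptide bond. The residue table (20 proteinogenic
residues, free-molecule formulas and side-chain class labels) ships as a
plain-text file and can be replaced by the user for nonstandard residues.
One display caveat: assembled tetrapeptide masses are rounded half-up to
two decimals, e.g. WFA computes to 422.1954 and is reported 422.20.

## Fragmentation events

Two event kinds exist:

* **Relative** events subtract a neutral or radical loss from the parent,
  so the observed m/z is an M−x change; their products can fragment
  further and the losses combine across events.
* **Charged (non-relative)** events detect the expelled side-chain piece
  itself as the cation. Their m/z is a constant independent of sequence
  context, they cannot combine with anything, and they terminate their
  pathway. One catalogue caveat: the His "alkene" side-chain cation
  C₅H₅N₂⁺ computes to 93.05, which at one-decimal display is 93.0; the
  catalogue carries the computed mass.

The built-in catalogue covers: ammonia loss (N/Q), β-elimination (S/T lose
H₂O, C loses H₂S), side-chain carboxyl losses whole/partial-radical/partial
(D/E), Met partial side-chain loss (−C₂H₅S), whole side-chain loss for the
16 residues where it is established (A, G, P and Y are deliberately
excluded pending evidence; the definition file makes this overridable), Lys
cyclization (−NH₃), Arg guanidino losses (−CH₂N₂, −CH₆N₃), the three
C-terminal carboxyl degradations, alkene formation (−H, K/P/I, only in
combination with a C-terminal loss), and eleven charged side-chain cations
for F/Y/W/H/M/L. Glycine has no residue-specific events, which bounds what
any model of this family can say about Gly-rich sequences.

Mechanism definitions live in a pipe-delimited text file
(`residues | label | kind | C,H,N,O,S,z`, `CTERM` pseudo-residue for
C-terminal scope) so the catalogue can grow without code changes. Three
words are reserved: `type` (backbone cleavage; forbidden in labels),
`charged` (the non-relative kind), and `side` (marks a side-chain event; a
residue-scoped relative record without it is a C-terminal companion event,
currently only alkene formation).

## Enumeration conventions

Several conventions are genuinely open in this model family; the ones
below are this package's choices, fixed as defaults and exercised by the
test suite. The tripeptide QFA, whose complete flow enumerates to 55
unique fragments, is the package's reference enumeration.

* **Cleavage pieces.** Homolytic cuts, no hydrogen rearrangement: each
  piece keeps exactly the atoms on its side of the bond. Types A and B
  emit both complementary pieces (charge retention is unknown, and an
  exhaustive fingerprint tolerates false candidates). Type C emits the
  retained N-side piece only: the released C-terminal piece carries the
  aromatic side chain, and its detectable cations are exactly the charged
  side-chain ions already in the catalogue, so emitting it as a backbone
  fragment would double-count that chemistry.
* **Cleavage depth.** Backbone cleavage and the C-terminal degradations
  apply once, to the original peptide; side-chain fragmentation recurses
  over every pooled fragment and all children. Internal multi-cut
  fragments are out of scope.
* **Side-event eligibility.** A fragment's eligible positions are the
  residues *fully contained* in its span; a piece truncated through a
  residue's backbone no longer offers that residue's events. At most one
  side-chain event fires per residue position along any pathway —
  side-chain losses remove most of the R group, so stacking two events on
  one residue would double-subtract atoms that are no longer there.
* **C-terminal events.** One C-terminal degradation per pathway, eligible
  only while the original C-terminal carboxyl is intact. Alkene formation
  (K/P/I) is emitted only fused to a C-terminal event, consuming that
  residue's side-event slot.
* **Deduplication.** The key is (composition vector, sorted multiset of
  mechanism labels): the same chemistry applied in a different order
  collapses, while genuinely different mechanism routes to the same
  formula are both kept (e.g. M−45 of a peptide arises both from Type A
  at the last residue and from the whole-carboxyl C-terminal loss — two
  rows at one m/z). Charged ions are recorded once per residue position
  with the event as their whole path, since the end fragment is identical
  no matter which parent expelled it. Negative-atom-count species
  (overlapping losses) and empty compositions are removed before output.
* **Ordering.** Output is sorted by (m/z, path text), making enumeration
  deterministic and dedup idempotent.

An independent brute-force enumerator (plain subset application of the
event rules, no recursion) reproduces the engine's output for every single
amino acid; mass conservation along every recorded path is checked
exactly.

## Matching and scoring

A peak matches a prediction when |Δm/z| ≤ tolerance; the default 0.25 Th
is the instrument-class maximum error and the boundary is inclusive (the
comparison is ≤, and this is configurable). Each peak matches at most its
nearest prediction (ties: smaller error, then smaller predicted m/z);
several peaks may share one prediction, because the fitness score counts
matched *peaks*. Peaks within tolerance of a contaminant list (shipped
lists: Fmoc, Trt, Pbf, Boc/OtBu protecting-group peaks) are masked first
and never scored; the base-peak intensity used for thresholding is taken
after masking, so a dominant reagent peak cannot distort the threshold.
The fitness score at threshold t ∈ {5%, 25%} is
100 × (matched peaks ≥ t × base intensity) / (all peaks ≥ t × base
intensity), reported with the mean and standard deviation of the matched
absolute errors, and undefined (reported as not applicable) when no peak
meets the threshold. Across several spectra both aggregations are
available — the unweighted mean of per-spectrum percentages and the pooled
per-peak percentage — since they differ whenever spectra contribute
unequal peak counts.

## Synthetic spectra

The fixture generator emulates a crude-sample DEP-EI spectrum: a seeded
random subset of the sequence's own predicted m/z values (default: the
whole fingerprint), Gaussian m/z jitter (default sd = tolerance/3, so
planted peaks stay matchable), log-uniform intensities spanning three
decades (mimicking EI's wide dynamic range), optionally one of the four
protecting-group peak sets, and uniform background peaks over the 60–350
m/z scan range. Predictions below 60 m/z are real model outputs and are
not clamped unless requested.

What passing tests on these fixtures shows: the pipeline plumbing is
correct end to end (a no-noise self-fixture scores exactly 100% at both
thresholds) and the fingerprint discriminates sequences (noisy QFA
fixtures score strictly higher against QFA than against the
composition-disjoint CIA across 20 seeds). What it does not show: real
spectra contain isotope satellites, rearrangement chemistry and
mechanism classes absent from the catalogue, and intensity structure the
generator does not model, so real-data match percentages will be lower
and residue-dependent.

## Limitations

* No intensity or abundance prediction; all fragments are reported as
  equally plausible.
* Coverage is weakest for Gly (no residue-specific events) and Arg (the
  catalogue's guanidino events are a partial description).
* Singly charged positive ions only; average (isotope-weighted) masses
  and isotope patterns are out of scope.
* Backbone cleavage is single-cut; internal fragments from two backbone
  cuts are not enumerated.
* The peak-list reader handles whitespace-delimited text with
  configurable column indices, not vendor or mzML formats.
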