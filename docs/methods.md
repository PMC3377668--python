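# Methods

## Digestion model

Trypsin cleaves C-terminal to K and R except before P. Because the
crosslinker reacts with lysine ε-amines *before* digestion, a modified
lysine cannot be cleaved: every crosslink site therefore sits on a peptide
carrying a missed cleavage at that residue, and enumeration uses peptides
with up to `max_missed_cleavages = 3` missed cuts (enough for every
crosslinkable peptide of the bundled benchmark construct; raise it for
lysine-dense sequences). Crosslinkable sites are the protein N-terminal
α-amine plus every non-C-terminal lysine of a peptide — a C-terminal lysine
was cleaved, hence unmodified. Peptide-level α-amines created *by*
digestion do not exist at the reaction stage and are never sites; this is
an inference (consistent with every benchmark crosslink) rather than a
documented rule. Methionine oxidation is an optional variable modification
(+15.99491 Da, all combinations per peptide). Nonstandard residue codes
(B, J, O, U, X, Z) are rejected outright.

Masses are monoisotopic throughout: IUPAC residue masses (5 dp), water
18.010565, proton 1.007276. These constants reproduce the published
benchmark crosslink MH⁺ values to 2 decimals, except two printed table
rows (2379.21, 2393.24) that compute ~5 mDa lower with any standard
constant set and are treated as rounding slips in the source table.

## Crosslinker arithmetic

BS³ bridging two amines adds the suberate bridge C₈H₁₀O₂ = 138.06808 Da;
a hydrolyzed dead-end adds bridge + H₂O = 156.07864 Da; a Tris-quenched
dead-end (off by default) adds bridge + Tris = 259.14197 Da. The H12/D12
doublet spacing is fixed at the working value 12.0757 Da — deliberately
*not* re-derived from 12×(²H−¹H) = 12.0753, because the spacing functions
as the doublet filter's reference constant, not as a computed mass.
Species carrying a crosslink plus one extra dead-end linker (optional)
contain two isotope-coded linkers and in reality form a triplet; they are
enumerated at single-linker spacing and flagged `extra_deadends=1` rather
than guessing a two-linker doublet model.

## Doublet filter

Spacing error is expressed in ppm **of the light m/z** (7 ppm at m/z 1712
≈ 12 mDa), matching the rationale that the relative spacing of two peaks
recorded in the same spectrum is much more accurate than the absolute
calibration. Detection is strictly per fraction, before merging; a peak may
serve as light member of one doublet and heavy member of another
(disambiguation is the matcher's job). The intensity parameter uses raw
centroid intensities; no deisotoping or area integration is attempted. No
minimum S/N or no-intervening-peak constraint is imposed. Defaults are the
strictest published combination: 7 ppm spacing, intensity parameter ≤ 0.22,
50 ppm precursor tolerance, 600–5000 Da window.

The diagnostic funnel logged by MS mode counts distinct
(fraction, light m/z) entries under: no doublet restriction (any peak
matching the theoretical list), matched doublets at 20 ppm, at 7 ppm, and
at 7 ppm + intensity cut.

## Fragment model

Singly charged b/y ions only — MALDI-TOF/TOF produces predominantly singly
charged fragments — with no neutral losses, immonium or internal ions. A
fragment spanning the crosslinked residue gains the bridge plus the intact
partner peptide (type 2), the bridge alone when spanning both sites of a
loop link (fragments spanning exactly one loop site would still be
ring-closed and are omitted), or the dead-end delta (type 0); such
fragments carry both light and heavy m/z. Matching is greedy
nearest-first, one observed peak per theoretical ion form, at a default
0.3 Da tolerance (TOF/TOF-typical; not a documented value). Precursors are
matched against both light and heavy MH⁺ because the timed ion selector
co-transmits both doublet members. No probabilistic score is computed; a
candidate is flagged "validated" at ≥ 4 matched fragments including ≥ 1
crosslinker doublet — an implementation choice, exposed in the config.
One published annotated fragment ("EKDTDx") appears to be an internal
fragment; internal fragments are deliberately out of model and that ion is
simply not generated.

## Mixed-isotope classification

δ(¹⁵N−¹⁴N) = 0.99703 Da per nitrogen. Combination masses use the light
linker only (mixed-isotope experiments use the non-coded reagent). Verdict
rules: outer peaks (AA, BB) present within the intensity-balance bound and
mixed forms absent → intra; all four present → inter, *including* unequal
1:x mixed intensities, since a partially exchanged oligomer population
still implies genuinely inter-monomeric links; anything else →
undetermined (partial patterns are never force-classified, a category the
original intra/inter labeling did not need). When n_A = n_B the mixed
forms coincide; the inter call then requires the middle peak consistent
with the *sum* of two species (ratio test at twice the balance tolerance).
The caveat that a 2-peak pattern could in principle be inter-monomeric but
intra-dimeric (stable dimers exchanging as units) is a reporting footnote,
not a verdict category.

## Synthetic data

The generator's defaults are the study conditions the screen is meant for:
64 (or 192) LC fractions, Gaussian elution profiles (σ = 1.5 fractions)
with the deuterated form leading by 0.5 fractions (direction documented,
magnitude an implementation choice), log-normal intensity noise
(CV = 0.2), 30 uniform noise peaks per fraction, 20 near-doublet decoys,
600–5000 Da. Unmodified peptides (most abundant), dead-end and loop-link
doublets, and planted type-2 doublets are all written, and a manifest
attributes every peak to exactly one source.

Two physical facts are modeled structurally rather than as free noise:
the two members of a doublet share one MALDI spot, so intensity noise is
decomposed into a shared per-(species, fraction) factor and a small
(CV/5) per-peak factor; and absolute calibration error (5 ppm, 1σ) is
applied jointly to both members, preserving the doublet spacing exactly —
which is precisely why the fixed-spacing filter works. Decoys come in
three classes, each defeating exactly one filter stage: spacing error
8.5–18 ppm (removed at 7 ppm), 25–200 ppm (removed at 20 ppm), and exact
spacing with grossly unbalanced intensities (removed by the intensity
cut); all are anchored at theoretical candidate masses so they pass the
plain mass match, which is the false-positive class the filters exist for.

What the simulator does **not** model: isotope envelopes, ion
suppression/detector saturation, chimeric peaks, retention-time-correlated
chemistry, or calibration failure localized to specific wells. Passing
recovery tests on this data therefore demonstrates the correctness of the
screening logic under the stated signal model, not instrument-level
performance.

The bundled 184-residue test protein is a synthetic construct: the
published crosslinkable regions are spliced at their true coordinates and
the two undetermined gaps are filled with lysine-free G/S/A/R spacers that
digest into inert peptides (see `synthetic_constructs.py`).

## Numerical and design choices

- Spacing/tolerance comparisons are inclusive (≤); ties in fragment
  matching are broken by smallest absolute error, then input order.
- Doublet lists are ordered (mz_light, |spacing error|); enumeration order
  is deterministic, so identical inputs give bitwise-identical outputs.
- Fraction clustering in `merge_doublets` is single-linkage on light mass
  at the precursor tolerance.
- All simulator randomness flows from one `numpy` Generator seeded from a
  single integer; no global RNG state is touched.
- Problem sizes used in the shipped tests (e.g. 192-fraction recovery run,
  1000 mixed-isotope classifications, full type-2 self-validation sweep of
  the benchmark construct) complete in seconds and were chosen as the
  smallest sizes that exercise every code path at realistic density.

## Known limitations

- BS³ only; the DTSSP (Δ8) chemistry would need its own `CrosslinkerSpec`
  and is not wired in.
- No FDR/decoy-database scoring — the validation report exposes raw
  fragment counts, by design.
- Semi-tryptic peptides, other proteases, and N-terminal methionine
  excision are out of scope.
- The mixed-isotope classifier assumes complete ¹⁵N incorporation;
  partial labeling would smear the combination masses.
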