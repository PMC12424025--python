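# lipiduvpd

Structural annotation of protein-bound phospholipids from multistage
native mass spectrometry with ultraviolet photodissociation (UVPD).

Native MS can isolate an intact protein–lipid complex in the gas phase,
release the bound lipids by collisional activation, and interrogate each
released lipid through further MS stages. Intact masses alone stop at the
sum-composition level (e.g. "PE 34:1"); this package implements the
downstream annotation that turns multistage fragment spectra into fully
resolved structures — lipid class, acyl chains, *sn*-positions and the
location of double bonds and cyclopropane rings — for the bacterial
glycerophospholipids PE, PG, PC, PA and cardiolipin (CDL).

## The annotation stages

1. **Sum compositions** (`assign_sum_compositions`): peaks of the
   released-lipid MS² spectrum, after internal linear recalibration
   (`recalibrate_linear`), are matched against an enumerated search space
   of class × total carbons:unsaturation × adduct at ±5 ppm.
2. **Class and adduct** (`identify_class_adduct`): positive-mode HCD MS³
   neutral losses are diagnostic — PE(+H) loses 141.019 Da
   (phosphoethanolamine), PE(+Na) additionally 43.042 Da (aziridine),
   PG(+Na) loses 172.014 and 193.996 Da (glycerophosphate, free acid and
   sodium salt).
3. **Acyl chains** (`identify_acyl_chains`): negative-mode HCD MS³
   carboxylate anion pairs [C<sub>n</sub>H<sub>2n−1−2y</sub>O<sub>2</sub>]⁻
   that sum up to the precursor resolve the chains; a carboxylate
   intensity ratio ≥ 2.5 : 1 yields a putative *sn*-2/*sn*-1 call.
   UVPD acyl losses (`chains_from_uvpd_losses`) are a fallback.
4. **Modification localization** (`generate_pair_library`, `scan_pairs`,
   `localize_modifications`): 213 nm UVPD cleaves C–C bonds around a
   modification, giving a fragment-ion pair whose spacing is diagnostic —
   exactly 24.000 Da (C₂) for a C=C bond in deprotonated ions, exactly
   14.016 Da (CH₂) for a cyclopropane ring in either polarity, and
   (aberrantly) 14.016 Da for C=C in protonated or sodiated PE, where each
   pair of protonated PE also recurs as a −H₃PO₄ (97.977 Da) satellite.
   The absolute pair masses encode the position. A library of all
   hypothetical pairs is scanned against the spectrum (both members
   required — single 14-Da-spaced peaks also arise from successive
   alkyl-chain cleavages), matches are scored by summed base-peak-relative
   intensity, and modifications are pinned to chains, optionally with the
   bacterial biosynthesis prior that cyclopropane rings sit on odd-carbon
   chains.
5. ***sn*-isomer quantification** (`dioxolane_mz`, `sn1_crossring_mz`,
   `fit_calibration`, `quantify_sn`): CID of a sodiated lipid expels the
   head group and closes a dioxolane ring; UVPD of the reisolated
   dioxolane (MS⁴) yields cross-ring fragments whose masses depend on the
   *sn*-1 chain ([FA + C₃H₄ + Na]⁺: *m/z* 319 for FA 16:0, 345 for
   FA 18:1). The intensity ratio R = I₍ₐ₎/(I₍ₐ₎+I₍ᵦ₎) is linear in the
   isomer fraction; a least-squares calibration on standard mixtures
   converts an observed R into isomer fractions.

A seedable generator (`simulate_uvpd`, `simulate_hcd`) produces synthetic
spectra with known ground truth — diagnostic pairs, satellites, 14-Da
alkyl ladders, noise and m/z jitter — so the whole pipeline is testable
without instrument data.

## Worked example

Simulate a UVPD spectrum of protonated PE 16:0/18:1 with the double bond
at Δ11, then annotate it blind from the chain composition:

```sh
$ lipiduvpd simulate --precursor "PE 16:0/18:1(Δ11)" --adduct +H --seed 7 --out-dir demo
wrote 3 spectra for PE 16:0/18:1(Δ11) to demo
$ lipiduvpd annotate-uvpd --precursor "PE 16:0_18:1" --adduct +H \
      --spectrum "demo/PE_16:0-18:1(Δ11)_uvpd.tsv"
{
  "precursor": "PE 16:0_18:1",
  "adduct": "+H",
  "assignment": "PE 16:0_18:1(Δ11)",
  "id_level": "modification_localized",
  "chain_ambiguous": false,
  "warnings": [],
  "matches": [
    {
      "hypothesis": "Δ11@18:1",
      "kind": "double_bond",
      "position": 11,
      "mz_low": 618.3791,
      "mz_high": 632.4387,
      "mass_errors": [-0.0338, 0.0102],
      "score": 0.7,
      ...
```

The top-scoring pair at *m/z* 618.4 / 632.4 (spacing 14.016 Da, the
aberrant protonated-PE behavior) places the C=C bond at Δ11 of the 18:1
chain; the assignment is unambiguous because the 16:0 chain cannot host a
modification. Lower-scoring entries such as the pair 97.98 Da below are
linked as H₃PO₄-loss satellites (`"satellite_of": [1, "double_bond", 11]`)
rather than reported as a second double bond.

Quantify an *sn*-isomer mixture from a calibration CSV and an observed
MS⁴ intensity ratio of 0.9:

```sh
$ lipiduvpd quantify-sn --calibration cal.csv --ratio 0.9 --chains 16:0,18:1
{
  ...
  "fraction_a_sn1": 0.9263,
  "fraction_b_sn1": 0.0737,
  "call": "16:0/18:1"
}
```

i.e. ~93% of the lipid carries 16:0 at *sn*-1 (slash notation: positions
assigned; an underscore would mean an unresolved mixture).

## Shorthand grammar

`CLASS total:unsat` (sum composition) or `CLASS chain(SEP chain)+` with
`SEP` either `/` (*sn*-1 listed first, positions known) or `_` (unknown).
Chains are `carbons:unsat_equiv` with optional located modifications
`(ΔN)` (double bond), `(cyN)` (cyclopropane), or vendor-style `(NZ)`.
Cyclopropane rings count as one unsaturation equivalent, so
`PE 33:1` covers `PE 16:0_17:1(cy9)`. Positions are numbered from the
carboxyl carbon.

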