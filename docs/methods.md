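# Methods

## Mass conventions

All masses are monoisotopic, from the NIST table bundled with pyteomics.
Ion m/z values include the electron mass (a proton is 1.007276 Da, a
sodium cation 22.989218 Da); this is invisible at the 1-dp precision of
ion-trap reports but kept exact internally. Glycerophospholipids are
assembled compositionally: glycerol + two esterified fatty acids (−H₂O
each) + phosphate (−H₂O) + head-group residue (−H₂O; ethanolamine,
glycerol or choline — phosphatidic acid has none). Cardiolipin is two
phosphatidic-acid moieties bridged by glycerol (−2 H₂O), modeled as
[M−H]⁻ only; other charge states are rejected. A cyclopropane ring
removes two hydrogens exactly like a double bond, so it counts as one
unsaturation equivalent in `x:y` totals — this is what makes
PE 33:1 ≡ PE 16:0_17:1(cy9) consistent.

## Diagnostic fragmentation rules

The UVPD pair library is generated per chain (length L) and position,
as precursor-minus-neutral-loss with the charge retained:

| modification | ions | neutral losses | spacing |
|---|---|---|---|
| C=C at Δn, standard | deprotonated (PG, CDL, PE⁻) | alkane C(L−n−1)H(2(L−n−1)+2) and alkenyl C(L−n+1)H(2(L−n+1)−2) | 24.000 Da (C₂) |
| cyclopropane at p | any | alkenes C(L−p)H(2(L−p)) and C(L−p−1)H(2(L−p−1)) | 14.016 Da (CH₂) |
| C=C at Δn, aberrant | protonated/sodiated PE | alkanes C(L−n)H(2(L−n)+2) and C(L−n−1)H(2(L−n−1)+2) | 14.016 Da (CH₂) |

For protonated PE every pair is duplicated as a satellite shifted by
−97.977 Da (H₃PO₄ loss). The loss compositions were chosen as the unique
H-transfer assignment that reproduces all published ion-trap pair masses
for these rules to ≤ 0.05 Da (one printed value, 677.5, deviates by 0.1 —
within ion-trap mass accuracy); they are pinned by unit tests. Because
only the carbons beyond the modification enter the losses, pair masses
depend on position solely through L − position: cy9 in a 17-carbon chain
and cy11 in a 19-carbon chain of the same precursor are exactly
degenerate. This degeneracy is why chain attribution of a localized
modification can remain ambiguous and why a biosynthetic prior exists
(below).

Class/adduct diagnostics (positive-mode HCD): PE(+H) −141.019
(C₂H₈NO₄P); PE(+Na) −43.042 (C₂H₅N) and −141.019; PG(+Na) −172.014
(C₃H₉O₆P) and −193.996 (C₃H₈NaO₆P). Signatures with several losses
require all of them by default (`require_all`), so that PE(+Na) is not
mistaken for PE(+H); when several signatures fire, the more specific one
(more losses) wins.

Dioxolane route: the sodiated dioxolane is [M+Na − head group]⁺ with
class-specific losses (PE 141.019, PG 172.014, PC 183.066), so lipids of
different classes with the same chains converge on one dioxolane. The
quantified sn-1 cross-ring fragment is [FA + C₃H₄ + Na]⁺. The other two
cross-ring products of the ring cleavage are not used for quantification;
their compositions are not fixed by the data this package is tested
against, and the single published ratio R = I(sn-1-a)/(I(sn-1-a)+I(sn-1-b))
is sufficient for the linear calibration.

## Tolerances and thresholds

| parameter | default | rationale |
|---|---|---|
| MS² sum-composition match | ±5 ppm | Orbitrap at R = 500,000 |
| MS³/MS⁴ fragment match | ±0.3 Da | linear ion trap; printed pair values deviate up to 0.1 Da |
| MS² intensity floor | 1% base peak | suppress noise peaks before candidate enumeration |
| calibrant pre-match for recalibration | ±0.3 Da | coarse window before the linear fit |
| sn hint ratio | 2.5 : 1 (sn-2 : sn-1) | carboxylate release favors sn-2 |
| sn dominance threshold | 0.9 | slash vs underscore notation in reports |
| localization score floor | 25% of best same-kind hypothesis | ladder pairs score far below genuine pairs |
| search space | chains 12–24 C, 0–3 unsat; CDL 60–80 C, 0–8 | covers the bacterial species the workflow targets |

Internal linear recalibration (mz′ = a·mz + b, least squares over all
matched calibrants) is applied at the MS² stage only; MS³/MS⁴ ion-trap
spectra inherit raw m/z and rely on the ±0.3 Da window. Fewer than two
calibrant matches makes recalibration a flagged no-op; identical
calibrant m/z is an error.

## Scanning and localization logic

A pair match requires **both** members within tolerance; single peaks are
never evidence, because successive alkyl-chain cleavages also generate
14-Da-spaced series. Matches are scored by (I_low + I_high)/I_basepeak
and ranked; ties break toward lower position, then C=C over cyclopropane.

In positive-mode PE both modification kinds give 14-Da pairs, but the
C=C (alkane-loss) fragments sit 2.016 Da below the cyclopropane
(alkene-loss) fragments, so each match is compared against the nearest
opposite-kind hypothesis at the same satellite status; the closer one
names the kind, and a margin below tolerance flags (not drops) the match.
Satellite handling is the same competition in disguise: a pair 97.977 Da
below a parent pair could also be read as a double bond seven methylenes
away (98.110 Da, 0.133 Da apart); whichever theoretical interpretation
fits the observed peaks better wins, and satellite-linked matches are
excluded from localization.

Localization merges evidence across polarities with per-kind weights
(cyclopropane ×2 in negative mode, C=C ×2 in positive mode — reflecting
which polarity yields the more abundant diagnostic fragments for each
kind), accepts hypotheses greedily by score with each accepted pair
claiming its observed peaks (lower-ranked hypotheses that reuse a claimed
peak are overlapping explanations, e.g. off-by-one ladder hybrids, and
are skipped), and assigns one modification per unsaturated chain. When
several chains could host a modification:

* with the bacterial prior (`bacterial_odd_chain_cyclopropane`),
  cyclopropane goes to an odd-carbon chain and C=C to an even-carbon
  chain — cyclopropane lipids arise by methylating a double bond of an
  even-chain fatty acid, so the ring lives on the odd chain;
* without it, positions are reported but the species stays at chain
  composition with the attribution flagged ambiguous.

Chains that are compositionally identical (the four 18:1 chains of
CDL 72:4) share the assignment symmetrically without ambiguity. Surplus
strong hypotheses beyond the unsaturation count are reported as a
contradiction and block the id-level upgrade; "strong" is judged against
accepted evidence of the same spacing class, because a weak 14-Da pair in
a spectrum with an accepted 14-Da assignment is overwhelmingly ladder
background, while 24-Da pairs have no ladder origin and contradict at
half the weakest accepted score.

## sn-isomer calibration

R = slope·f + intercept is fitted by ordinary least squares on
replicate-mean ratios (an optional multiplicative scaling factor absorbs
stock-concentration differences between the two standards before the
fit). The fit must be strictly increasing; inversion clips to [0, 1] and
the reported uncertainty is fit RMS divided by slope. Endpoint behavior
(R ≈ 0.02 at f = 0 and 0.97 at f = 1 for the POPC/OPPC-style titration)
is a test fixture, not a hard-coded model.

## Synthetic spectra

The generator emulates ion-trap fragment spectra of released bacterial
phospholipids: the surviving precursor as base peak; diagnostic pairs at
20–100% base peak with cyclopropane pairs twice as intense as C=C pairs
(mirroring their observed relative abundance); −H₃PO₄ satellites at half
the parent pair for protonated PE; acyl losses (free acid and ketene); a
14-Da alkyl-cleavage ladder at ≤ 10%; uniform noise peaks at ≤ 5%; and
per-peak Gaussian m/z jitter (σ = 0.05 Da). Negative-mode HCD spectra
carry carboxylates with a configurable sn-2 : sn-1 asymmetry (default
3.0, above the 2.5 calling threshold); positive-mode HCD spectra carry
the class-diagnostic losses. Everything is deterministic given the seed.

These are fixture conventions, not a physical fragmentation model: there
are no isotope envelopes (monoisotopic isolation is assumed), no
intensity physics, no detector noise correlations and no chimeric
precursors. Passing round trips therefore demonstrate the correctness of
the mass arithmetic, matching, scoring and disambiguation logic under
realistic m/z scatter and interference patterns — not performance on
real instrument data.

The standard validation panel (`lipiduvpd.evaluate`) cycles protonated
PE 16:0/18:1(Δ5–13), deprotonated PE 16:0/17:1(cy7–11), deprotonated
PG 18:1(Δ5–13)_19:1(cy7–11) and deprotonated CDL 72:4 (4 × 18:1(Δn));
200 seeded trials run in a few seconds and recover ≥ 95% of cases
end-to-end (100% with noise, jitter and ladder disabled).

## Numerical and design notes

* Formula arithmetic is exact integer element counting; subtraction below
  zero raises rather than clamping, catching impossible neutral losses.
* Pair positions run from 2 (position 1 sits at the carboxyl carbon);
  fragments below m/z 100 are dropped from the library (ion-trap
  low-mass cutoff territory).
* Sodiated PE follows the same aberrant 14-Da rule as protonated PE, with
  pair masses offset by the Na−H mass difference; −H₃PO₄ satellites are
  generated for protonated PE only.
* mzML I/O is deliberately minimal: centroided spectra, 32/64-bit float
  arrays, zlib or no compression, and the metadata the pipeline consumes
  (MS level, polarity, selected-ion m/z, activation). Profile-mode input
  is rejected with instructions to centroid. Vendor formats and peak
  picking are out of scope.
* Ambiguity is preserved, never silently resolved: isobaric
  sum-composition candidates (e.g. PC n:u vs PE (n+3):u, exactly
  degenerate) are all returned flagged; kind margins below tolerance are
  flagged; CDL chains are never sn-called.

## Known limitations

Double-bond geometry (Z/E) is not determined. Ether/lyso lipids,
sphingolipids, hydroxylation and methyl branching are out of scope.
Mixture deconvolution beyond "most abundant pair wins" is not attempted.
Quantification across lipid classes is not meaningful here because
ionization efficiencies differ. The sn-2 : sn-1 carboxylate hint is
heuristic ("putative"); the MS⁴ dioxolane route supersedes it when
available.
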