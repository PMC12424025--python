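"""Stage 3: localization of double bonds and cyclopropane rings by UVPD.

213 nm photodissociation of intact phospholipid ions cleaves C-C bonds
around an acyl-chain modification, producing a pair of fragment ions whose
spacing is diagnostic of the modification kind and whose absolute masses
encode its position (counted from the carboxyl carbon):

* a C=C bond at position n in deprotonated ions (PG, CDL, deprotonated PE)
  yields a pair spaced by exactly 24.000 Da (C2): the neutral losses are
  the terminal alkane of L-n-1 carbons and the terminal alkenyl chain of
  L-n+1 carbons;
* a cyclopropane ring at position p yields, in either polarity, a pair
  spaced by 14.016 Da (CH2): alkene losses of L-p and L-p-1 carbons;
* protonated and sodiated PE behave aberrantly: a C=C at position n gives
  a 14-Da pair of alkane losses (L-n and L-n-1 carbons) instead of the
  24-Da pair, and for protonated PE each pair recurs as a satellite pair
  shifted down by the mass of H3PO4 (97.977 Da).

Because the fragments keep the charge, pair masses only depend on the
modification position through the number of chain carbons beyond it
(L - position). This degeneracy is why, e.g., cy9 in a 17:1 chain and
cy11 in a 19:1 chain of the same precursor produce identical pairs.

The annotator generates the full pair library over every chain and legal
position, scans a UVPD spectrum for complete pairs (single peaks are not
accepted: successive alkyl-chain cleavages also produce 14-Da-spaced
series), scores matches by summed base-peak-relative intensity, and
resolves chain attribution, optionally with the bacterial biosynthesis
prior that cyclopropane rings live on odd-carbon chains (they are made by
methylating a double bond of an even-chain fatty acid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .chem import (
    CYCLOPROPANE,
    DOUBLE_BOND,
    AcylChain,
    ElementalFormula,
    LipidIon,
    LipidSpecies,
    Modification,
)
from .spectra import CentroidSpectrum, match_peak

__all__ = [
    "FragmentPair",
    "PairMatch",
    "LocalizationResult",
    "generate_pair_library",
    "scan_pairs",
    "discriminate_cc_vs_cyclopropane",
    "flag_h3po4_satellites",
    "localize_modifications",
    "H3PO4_MASS",
    "SEVEN_CH2_MASS",
    "DEFAULT_POLARITY_WEIGHTS",
]

H3PO4_MASS = ElementalFormula.parse("H3PO4").mass  # 97.977
SEVEN_CH2_MASS = ElementalFormula.parse("C7H14").mass  # 98.110
_C2_MASS = ElementalFormula.parse("C2").mass  # 24.000
_CH2_MASS = ElementalFormula.parse("CH2").mass  # 14.016

# Mode preference per modification kind, applied when merging evidence
# across polarities: cyclopropane pairs are most abundant from deprotonated
# precursors; C=C pairs of PE from protonated precursors.
DEFAULT_POLARITY_WEIGHTS: Mapping[tuple[str, str], float] = {
    (CYCLOPROPANE, "negative"): 2.0,
    (DOUBLE_BOND, "positive"): 2.0,
}


def _alkane(n: int) -> ElementalFormula:
    return ElementalFormula({"C": n, "H": 2 * n + 2})


def _alkene(n: int) -> ElementalFormula:
    return ElementalFormula({"C": n, "H": 2 * n})


def _alkenyl(n: int) -> ElementalFormula:
    return ElementalFormula({"C": n, "H": 2 * n - 2})


@dataclass(frozen=True)
class FragmentPair:
    """A theoretical diagnostic pair for one modification hypothesis."""

    ion: LipidIon
    chain_index: int
    kind: str  # double_bond / cyclopropane
    position: int
    loss_light: ElementalFormula  # smaller loss -> higher-m/z fragment
    loss_heavy: ElementalFormula  # larger loss  -> lower-m/z fragment
    spacing_class: str  # "24" or "14"
    satellite: str = "none"  # or "minus_H3PO4"

    @property
    def mz_high(self) -> float:
        mz = self.ion.theoretical_mz - self.loss_light.mass
        return mz - H3PO4_MASS if self.satellite == "minus_H3PO4" else mz

    @property
    def mz_low(self) -> float:
        mz = self.ion.theoretical_mz - self.loss_heavy.mass
        return mz - H3PO4_MASS if self.satellite == "minus_H3PO4" else mz

    @property
    def spacing(self) -> float:
        return self.mz_high - self.mz_low

    def hypothesis(self) -> tuple[int, str, int]:
        return (self.chain_index, self.kind, self.position)

    def label(self) -> str:
        tag = f"Δ{self.position}" if self.kind == DOUBLE_BOND else f"cy{self.position}"
        sat = " (-H3PO4 satellite)" if self.satellite != "none" else ""
        chain = self.ion.species.chains[self.chain_index]
        return f"{tag}@{chain.carbons}:{chain.unsat_equiv}{sat}"


def _pair_rules(ion: LipidIon, chain: AcylChain, kind: str, position: int):
    """Neutral-loss pair (light, heavy) and spacing class for a hypothesis."""
    L = chain.carbons
    if kind == CYCLOPROPANE:
        return _alkene(L - position - 1), _alkene(L - position), "14"
    aberrant = ion.species.lipid_class == "PE" and ion.adduct in ("+H", "+Na")
    if aberrant:
        return _alkane(L - position - 1), _alkane(L - position), "14"
    return _alkane(L - position - 1), _alkenyl(L - position + 1), "24"


def generate_pair_library(
    ion: LipidIon,
    kinds: Sequence[str] = (DOUBLE_BOND, CYCLOPROPANE),
    include_satellites: bool = True,
    min_fragment_mz: float = 100.0,
) -> list[FragmentPair]:
    """All theoretical diagnostic pairs for an ion with resolved chains.

    Emits a pair per chain x kind x legal position, for chains that carry
    at least one unsaturation equivalent. Protonated-PE pairs are
    duplicated as -H3PO4 satellites. Requires chain_composition level or
    better (positions cannot be enumerated on a sum composition).
    """
    species = ion.species
    if species.id_level == "sum_composition":
        raise ValueError(
            "pair library requires resolved chains; run chain identification first"
        )
    out: list[FragmentPair] = []
    for ci, chain in enumerate(species.chains):
        if chain.unsat_equiv < 1:
            continue
        L = chain.carbons
        for kind in kinds:
            max_pos = L - 1 if kind == DOUBLE_BOND else L - 2
            for pos in range(2, max_pos + 1):
                light, heavy, spacing = _pair_rules(ion, chain, kind, pos)
                pair = FragmentPair(
                    ion=ion, chain_index=ci, kind=kind, position=pos,
                    loss_light=light, loss_heavy=heavy, spacing_class=spacing,
                )
                if pair.mz_low < min_fragment_mz:
                    continue
                out.append(pair)
                if (
                    include_satellites
                    and species.lipid_class == "PE"
                    and ion.adduct == "+H"
                ):
                    out.append(replace(pair, satellite="minus_H3PO4"))
    return out


@dataclass(frozen=True)
class PairMatch:
    """A library pair matched by two observed peaks."""

    pair: FragmentPair
    observed_mz: tuple[float, float]  # (low, high)
    observed_intensity: tuple[float, float]
    mass_errors: tuple[float, float]
    score: float  # summed base-peak-relative intensity, in [0, 2]
    kind_margin: float | None = None  # from C=C vs cyclopropane discrimination
    kind_ambiguous: bool = False
    satellite_of: tuple[int, str, int] | None = None

    @property
    def hypothesis(self) -> tuple[int, str, int]:
        return self.pair.hypothesis()


def scan_pairs(
    spectrum: CentroidSpectrum,
    library: Sequence[FragmentPair],
    tol: float = 0.3,
) -> list[PairMatch]:
    """Scan a UVPD spectrum against a pair library.

    Both pair members must be present within ``tol`` — a lone peak is not
    evidence, since alkyl-chain cleavage series are also spaced by 14 Da.
    Matches are scored by summed base-peak-normalized intensity and sorted
    by score; ties break toward lower position, then C=C over cyclopropane.
    """
    base = spectrum.base_peak_intensity
    if base <= 0:
        return []
    matches: list[PairMatch] = []
    for pair in library:
        i_lo = match_peak(spectrum, pair.mz_low, tol)
        i_hi = match_peak(spectrum, pair.mz_high, tol)
        if i_lo is None or i_hi is None or i_lo == i_hi:
            continue
        obs = (float(spectrum.mz[i_lo]), float(spectrum.mz[i_hi]))
        inten = (float(spectrum.intensity[i_lo]), float(spectrum.intensity[i_hi]))
        matches.append(
            PairMatch(
                pair=pair,
                observed_mz=obs,
                observed_intensity=inten,
                mass_errors=(obs[0] - pair.mz_low, obs[1] - pair.mz_high),
                score=(inten[0] + inten[1]) / base,
            )
        )
    matches.sort(
        key=lambda m: (
            -m.score,
            m.pair.position,
            m.pair.kind != DOUBLE_BOND,
            m.pair.satellite != "none",
        )
    )
    return matches


def discriminate_cc_vs_cyclopropane(
    matches: Sequence[PairMatch],
    ion: LipidIon,
    tol: float = 0.3,
) -> list[PairMatch]:
    """Label 14-Da matches of positive-mode PE as C=C or cyclopropane.

    In positive mode both modification kinds give 14-Da pairs, but their
    fragments differ by two hydrogens: the C=C (alkane-loss) pair sits
    2.016 Da below the cyclopropane (alkene-loss) pair of the same
    carbons-beyond-position. Each observed pair is therefore compared
    against the nearest hypothesis of the other kind (at the same
    satellite status); the closer interpretation names the kind and the
    mass margin is attached. A margin below ``tol`` flags the match
    ambiguous instead of dropping it.
    """
    library = generate_pair_library(ion)

    def mean_err(pair: FragmentPair, m: PairMatch) -> float:
        return (
            abs(m.observed_mz[0] - pair.mz_low) + abs(m.observed_mz[1] - pair.mz_high)
        ) / 2.0

    out: list[PairMatch] = []
    for m in matches:
        own_err = mean_err(m.pair, m)
        other_kind = CYCLOPROPANE if m.pair.kind == DOUBLE_BOND else DOUBLE_BOND
        candidates = [
            p for p in library
            if p.kind == other_kind and p.satellite == m.pair.satellite
        ]
        if not candidates:
            out.append(replace(m, kind_margin=None, kind_ambiguous=False))
            continue
        alt = min(candidates, key=lambda p: mean_err(p, m))
        alt_err = mean_err(alt, m)
        margin = abs(own_err - alt_err)
        if alt_err < own_err:
            m = replace(m, pair=alt)
        out.append(replace(m, kind_margin=margin, kind_ambiguous=margin < tol))
    return out


def flag_h3po4_satellites(matches: Sequence[PairMatch]) -> list[PairMatch]:
    """Link pairs one H3PO4 below another match as satellites.

    Protonated unsaturated PE sheds H3PO4 (97.977 Da) after UVPD, so each
    diagnostic pair recurs 98 Da lower. Such a pair must not be read as a
    second double bond seven methylenes away (a 7xCH2 shift, 98.110 Da —
    0.13 Da off the H3PO4 loss). Both interpretations sit in the library:
    the satellite entry of the parent hypothesis and the primary entry of
    the hypothesis seven positions down match the same observed peaks.
    Whenever the satellite entry fits the peaks at least as well and its
    parent pair was itself observed, the competing primary match is linked
    as a satellite rather than reported as an independent double bond.
    """
    sat_matches = [m for m in matches if m.pair.satellite == "minus_H3PO4"]
    primary_hyps = {m.hypothesis for m in matches if m.pair.satellite == "none"}
    out = []
    for m in matches:
        if m.pair.satellite != "none":
            out.append(m)
            continue
        link = None
        for s in sat_matches:
            if s.hypothesis == m.hypothesis:
                continue
            if s.hypothesis not in primary_hyps:  # parent pair unobserved
                continue
            same_peaks = (
                abs(s.observed_mz[0] - m.observed_mz[0]) < 1e-9
                and abs(s.observed_mz[1] - m.observed_mz[1]) < 1e-9
            )
            if not same_peaks:
                continue
            if sum(map(abs, s.mass_errors)) <= sum(map(abs, m.mass_errors)):
                link = s.hypothesis
                break
        out.append(replace(m, satellite_of=link) if link else m)
    return out


@dataclass(frozen=True)
class LocalizationResult:
    """Outcome of assigning detected modifications to chains."""

    species: LipidSpecies
    assignments: tuple[tuple[int, Modification], ...]  # (chain index, mod)
    chain_ambiguous: bool
    warnings: tuple[str, ...] = ()
    evidence: tuple[PairMatch, ...] = ()


def _dedupe_matches(matches: Iterable[PairMatch]) -> list[PairMatch]:
    """Drop satellites and satellite-tagged library entries, keep the best
    match per observed pair (an observed pair can fit several degenerate
    hypotheses; those are kept — they share the observed m/z but differ in
    hypothesis)."""
    return [
        m for m in matches
        if m.pair.satellite == "none" and m.satellite_of is None
    ]


def localize_modifications(
    species: LipidSpecies,
    matches_by_polarity: Mapping[str, Sequence[PairMatch]],
    prior: str = "none",
    polarity_weights: Mapping[tuple[str, str], float] = DEFAULT_POLARITY_WEIGHTS,
    relative_score_floor: float = 0.25,
) -> LocalizationResult:
    """Merge pair evidence across polarities and pin modifications to chains.

    One modification is localized per unsaturated chain. Evidence from
    both polarities is merged with per-kind weights (cyclopropane counts
    double in negative mode, C=C double in positive mode, by default).
    Hypotheses are accepted greedily by score, and each accepted pair
    claims its two observed peaks: lower-ranked hypotheses that reuse a
    claimed peak (off-by-one ladder hybrids, satellite echoes) are
    overlapping explanations, not independent modifications, and are
    skipped. Only hypotheses scoring at least ``relative_score_floor`` of
    the best one compete for a slot. Degenerate hypotheses — the same
    observed pair explained by either chain — are resolved by the
    bacterial odd-chain
    prior when enabled (``prior="bacterial_odd_chain_cyclopropane"``:
    cyclopropane goes to an odd-carbon chain, C=C to an even-carbon
    chain); otherwise the chain attribution is reported ambiguous. If
    more strong positions than unsaturation equivalents remain, all of
    them are reported and the species stays at chain composition with a
    warning.
    """
    # Merge matches into hypothesis entries. Degenerate library pairs (the
    # same observable explained through different chains) land on the same
    # (kind, L - position) key; within one polarity only the best match
    # counts, across polarities evidence adds up.
    weighted: dict[tuple[str, int], dict] = {}
    for polarity, matches in matches_by_polarity.items():
        per_pol: dict[tuple[str, int], float] = {}
        for m in _dedupe_matches(matches):
            w = polarity_weights.get((m.pair.kind, polarity), 1.0)
            chain = m.pair.ion.species.chains[m.pair.chain_index]
            key = (m.pair.kind, chain.carbons - m.pair.position)
            entry = weighted.setdefault(
                key,
                {
                    "score": 0.0,
                    "candidates": set(),
                    "matches": [],
                    "spacing": m.pair.spacing_class,
                },
            )
            entry["candidates"].add((m.pair.chain_index, m.pair.position))
            entry["matches"].append((polarity, m))
            per_pol[key] = max(per_pol.get(key, 0.0), w * m.score)
        for key, s in per_pol.items():
            weighted[key]["score"] += s

    if not weighted:
        return LocalizationResult(
            species=species, assignments=(), chain_ambiguous=False,
            warnings=("no pair evidence",),
        )

    n_slots = sum(1 for c in species.chains if c.unsat_equiv >= 1)
    ranked = sorted(weighted.items(), key=lambda kv: -kv[1]["score"])
    # abundances of the two kinds are not comparable (cyclopropane pairs
    # run hotter), so the score floor is applied within each kind
    best_by_kind: dict[str, float] = {}
    for (kind, _), entry in ranked:
        best_by_kind[kind] = max(best_by_kind.get(kind, 0.0), entry["score"])
    strong = [
        kv for kv in ranked
        if kv[1]["score"] >= relative_score_floor * best_by_kind[kv[0][0]]
    ]
    warnings: list[str] = []

    def peak_keys(entry: dict) -> set:
        return {
            (pol, mz) for pol, m in entry["matches"] for mz in m.observed_mz
        }

    assignments: list[tuple[int, Modification]] = []
    accepted: list[tuple[float, str]] = []  # (score, spacing class)
    ambiguous = False
    used_chains: set[int] = set()
    claimed: set = set()
    evidence: list[PairMatch] = []
    surplus: list[str] = []
    for (kind, lpos), entry in strong:
        pk = peak_keys(entry)
        if pk & claimed:
            # shares a peak with an already-accepted pair: an overlapping
            # explanation, not an independent modification
            continue
        if len(assignments) >= n_slots:
            # A genuine contradiction must rival the accepted evidence of
            # the same spacing class: 14-Da pairs can arise from alkyl
            # ladders, so a weak one never contradicts a strong one, and
            # absent any accepted 14-Da evidence it must rival the best
            # accepted pair outright. 24-Da pairs have no ladder origin
            # and contradict at half the weakest accepted score.
            same = [s for s, sp in accepted if sp == entry["spacing"]]
            if entry["spacing"] == "24":
                ref = 0.5 * min(s for s, _ in accepted)
            elif same:
                ref = 0.5 * min(same)
            else:
                ref = max(s for s, _ in accepted)
            if entry["score"] > ref:
                surplus.append(f"{kind} (L-pos={lpos}, score={entry['score']:.2f})")
            continue
        cands = {
            (ci, pos) for ci, pos in entry["candidates"]
            if ci not in used_chains
        }
        if prior == "bacterial_odd_chain_cyclopropane" and len(cands) > 1:
            want_odd = kind == CYCLOPROPANE
            filtered = {
                (ci, pos) for ci, pos in cands
                if (species.chains[ci].carbons % 2 == 1) == want_odd
            }
            if filtered:
                cands = filtered
        if not cands:
            warnings.append(f"no free chain for {kind} evidence")
            continue
        chain_sigs = {
            (species.chains[ci].carbons, species.chains[ci].unsat_equiv, pos)
            for ci, pos in cands
        }
        if len(cands) > 1 and len(chain_sigs) == 1:
            # equivalent chains (e.g. the four 18:1 chains of cardiolipin):
            # the modification belongs to each of them, no ambiguity
            targets = sorted(cands)[: n_slots - len(assignments)]
        elif len(cands) > 1:
            ambiguous = True
            targets = [sorted(cands)[0]]  # deterministic fallback
        else:
            targets = [next(iter(cands))]
        for ci, pos in targets:
            used_chains.add(ci)
            assignments.append((ci, Modification(kind, pos)))
            accepted.append((entry["score"], entry["spacing"]))
        claimed |= pk
        evidence.extend(m for _, m in entry["matches"])

    contradictory = bool(surplus)
    if contradictory:
        warnings.append(
            "more strong modification hypotheses than unsaturation equivalents: "
            + ", ".join(surplus)
        )
    if len(assignments) < n_slots:
        warnings.append("not all unsaturated chains localized")

    if (
        not assignments
        or contradictory
        or (ambiguous and prior == "none" and len(assignments) > 1)
    ):
        # positions known, chain attribution uncertain: stay below
        # modification_localized
        out_species = species
        if ambiguous:
            warnings.append("chain attribution ambiguous; positions reported only")
    else:
        new_chains = list(species.chains)
        ok = True
        for ci, mod in assignments:
            chain = new_chains[ci]
            try:
                new_chains[ci] = replace(chain, mods=chain.mods + (mod,))
            except ValueError as exc:
                warnings.append(str(exc))
                ok = False
        if ok:
            out_species = replace(
                species, chains=tuple(new_chains), id_level="modification_localized"
            )
        else:
            out_species = species
    return LocalizationResult(
        species=out_species,
        assignments=tuple(assignments),
        chain_ambiguous=ambiguous,
        warnings=tuple(warnings),
        evidence=tuple(evidence),
    )
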