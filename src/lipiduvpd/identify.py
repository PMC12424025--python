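"""Stage 1-2 annotation of released lipids.

Stage 1 assigns sum compositions (class + total carbons:unsaturation +
adduct) to peaks of the recalibrated MS2 spectrum of lipids released from
a protein-lipid complex. Stage 2 resolves each candidate further:

* positive-mode HCD MS3 identifies class and adduct from diagnostic
  neutral losses (PE(+H): 141.019; PE(+Na): 43.042 and 141.019;
  PG(+Na): 172.014 and 193.996 Da);
* negative-mode HCD MS3 identifies the acyl chains from carboxylate anion
  pairs that sum up to the precursor lipid, with a putative sn-position
  call when the carboxylate intensity ratio reaches 2.5:1 (sn-2:sn-1);
* UVPD MS3 acyl losses (free acid and ketene) are a fallback when no HCD
  spectrum is available; they never carry sn information.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import (
    AcylChain,
    ElementalFormula,
    LipidIon,
    LipidSpecies,
    PROTON_MASS,
    WATER,
    build_lipid_ion,
    carboxylate_mz,
)
from .spectra import CentroidSpectrum, match_peak

__all__ = [
    "SearchSpace",
    "CandidateAssignment",
    "ChainAssignment",
    "DIAGNOSTIC_LOSSES",
    "assign_sum_compositions",
    "identify_class_adduct",
    "identify_acyl_chains",
    "chains_from_uvpd_losses",
    "SN_RATIO_THRESHOLD",
]

SN_RATIO_THRESHOLD = 2.5  # sn-2 : sn-1 carboxylate intensity

# Class/adduct diagnostic neutral losses observed in positive-mode HCD.
# PE loses its phosphoethanolamine head group (and aziridine when sodiated);
# sodiated PG loses glycerophosphate as the free acid and the sodium salt.
DIAGNOSTIC_LOSSES: dict[tuple[str, str], tuple[ElementalFormula, ...]] = {
    ("PE", "+H"): (ElementalFormula.parse("C2H8NO4P"),),
    ("PE", "+Na"): (
        ElementalFormula.parse("C2H5N"),
        ElementalFormula.parse("C2H8NO4P"),
    ),
    ("PG", "+Na"): (
        ElementalFormula.parse("C3H9O6P"),
        ElementalFormula.parse("C3H8NaO6P"),
    ),
}


@dataclass(frozen=True)
class SearchSpace:
    """Bounds of the sum-composition enumeration.

    Defaults cover the bacterial glycerophospholipids released in the
    native-MS experiments: diacyl chains of 12-24 carbons with up to three
    unsaturation equivalents each, and cardiolipins of 60-80 total carbons
    with up to eight equivalents.
    """

    classes: tuple[str, ...] = ("PE", "PG", "PA", "PC")
    chain_carbons: tuple[int, int] = (12, 24)
    chain_unsat: tuple[int, int] = (0, 3)
    adducts_positive: tuple[str, ...] = ("+H", "+Na")
    adducts_negative: tuple[str, ...] = ("-H",)
    include_cdl: bool = True
    cdl_carbons: tuple[int, int] = (60, 80)
    cdl_unsat: tuple[int, int] = (0, 8)

    def iter_ions(self, polarity: str) -> Iterable[LipidIon]:
        adducts = self.adducts_positive if polarity == "positive" else self.adducts_negative
        cmin, cmax = self.chain_carbons
        umin, umax = self.chain_unsat
        for cls in self.classes:
            for total_c in range(2 * cmin, 2 * cmax + 1):
                for total_u in range(2 * umin, 2 * umax + 1):
                    for adduct in adducts:
                        yield build_lipid_ion(
                            cls,
                            [AcylChain(total_c, total_u)],
                            adduct,
                            id_level="sum_composition",
                        )
        if self.include_cdl and polarity == "negative":
            for total_c in range(self.cdl_carbons[0], self.cdl_carbons[1] + 1):
                for total_u in range(self.cdl_unsat[0], self.cdl_unsat[1] + 1):
                    yield build_lipid_ion(
                        "CDL",
                        [AcylChain(total_c, total_u)],
                        "-H",
                        id_level="sum_composition",
                    )


@dataclass(frozen=True)
class CandidateAssignment:
    """A putative sum-composition match for one released-lipid MS2 peak."""

    peak_mz: float
    peak_intensity: float
    ion: LipidIon
    mass_error_da: float
    mass_error_ppm: float
    ambiguous: bool = False

    def label(self) -> str:
        return f"{self.ion.species.sum_composition} ({self.ion.adduct})"


def assign_sum_compositions(
    ms2: CentroidSpectrum,
    search_space: SearchSpace | None = None,
    tol_ppm: float = 5.0,
    intensity_floor: float = 0.01,
) -> list[CandidateAssignment]:
    """Enumerate the search space against every MS2 peak above the floor.

    Returns matches within ``tol_ppm``, ranked by absolute ppm error;
    peaks hit by more than one composition are flagged ambiguous.
    """
    if search_space is None:
        search_space = SearchSpace()
    ions = list(search_space.iter_ions(ms2.polarity))
    if not ions:
        raise ValueError("empty sum-composition search space")
    floor = intensity_floor * ms2.base_peak_intensity
    results: list[CandidateAssignment] = []
    per_peak: dict[int, int] = {}
    for ion in ions:
        theo = ion.theoretical_mz
        tol_da = theo * tol_ppm * 1e-6
        idx = match_peak(ms2, theo, tol_da)
        if idx is None or ms2.intensity[idx] < floor:
            continue
        err = float(ms2.mz[idx] - theo)
        results.append(
            CandidateAssignment(
                peak_mz=float(ms2.mz[idx]),
                peak_intensity=float(ms2.intensity[idx]),
                ion=ion,
                mass_error_da=err,
                mass_error_ppm=err / theo * 1e6,
            )
        )
        per_peak[idx] = per_peak.get(idx, 0) + 1
    # flag peaks carrying >1 candidate (isobars within tolerance)
    flagged = []
    for cand in results:
        n = sum(
            1 for other in results if abs(other.peak_mz - cand.peak_mz) < 1e-9
        )
        if n > 1:
            cand = CandidateAssignment(
                cand.peak_mz, cand.peak_intensity, cand.ion,
                cand.mass_error_da, cand.mass_error_ppm, ambiguous=True,
            )
        flagged.append(cand)
    flagged.sort(key=lambda c: abs(c.mass_error_ppm))
    return flagged


# ---------------------------------------------------------------------------
# Class / adduct from positive-mode HCD neutral losses
# ---------------------------------------------------------------------------

def identify_class_adduct(
    ms3_pos: CentroidSpectrum,
    precursor: CandidateAssignment,
    tol: float = 0.3,
    require_all: bool = True,
) -> tuple[str, str] | None:
    """Class/adduct verdict from diagnostic neutral losses, or None.

    Tests each signature as peaks at ``precursor - loss``. With
    ``require_all`` (default) every loss of a signature must be present,
    which is what separates PE(+Na) (43 + 141) from PE(+H) (141 only).
    """
    if ms3_pos.polarity != "positive":
        raise ValueError("class/adduct identification uses positive-mode HCD spectra")
    pre_mz = precursor.peak_mz
    verdicts = []
    for (cls, adduct), losses in DIAGNOSTIC_LOSSES.items():
        found = [match_peak(ms3_pos, pre_mz - loss.mass, tol) is not None for loss in losses]
        ok = all(found) if require_all else any(found)
        if ok:
            verdicts.append(((cls, adduct), len(losses)))
    if not verdicts:
        return None
    # most specific signature (more losses) wins: PE(+Na) over PE(+H)
    verdicts.sort(key=lambda v: -v[1])
    return verdicts[0][0]


# ---------------------------------------------------------------------------
# Acyl chains from negative-mode carboxylates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainAssignment:
    """An acyl-chain composition supported by observed fragment evidence."""

    chains: tuple[AcylChain, ...]
    evidence_mz: tuple[float, ...]
    evidence_intensity: tuple[float, ...]
    score: float
    sn_call: str = "unassigned"  # "assigned" or "unassigned"
    sn_ratio: float | None = None

    def label(self) -> str:
        sep = "/" if self.sn_call == "assigned" else "_"
        chains = self.chains
        if self.sn_call == "assigned":
            chains = tuple(sorted(chains, key=lambda c: c.sn or 0))
        return sep.join(c.label() for c in chains)


def _chain_splits(total_c: int, total_u: int, n_chains: int, *,
                  cmin: int = 12, cmax: int = 24, umax: int = 3):
    """All multisets of ``n_chains`` (carbons, unsat) summing to the totals."""
    out = set()
    carbon_parts = itertools.combinations_with_replacement(range(cmin, cmax + 1), n_chains)
    for carbons in carbon_parts:
        if sum(carbons) != total_c:
            continue
        for unsats in itertools.product(range(0, min(umax, total_u) + 1), repeat=n_chains):
            if sum(unsats) != total_u:
                continue
            key = tuple(sorted(zip(carbons, unsats)))
            out.add(key)
    return sorted(out)


def identify_acyl_chains(
    ms3_neg: CentroidSpectrum,
    precursor: CandidateAssignment,
    tol: float = 0.3,
    sn_threshold: float = SN_RATIO_THRESHOLD,
    chain_carbons: tuple[int, int] = (12, 24),
    chain_unsat_max: int = 3,
) -> list[ChainAssignment]:
    """Resolve the sum composition into chains via carboxylate anion pairs.

    Every chain split of the precursor totals is tested; a split is
    accepted only when all of its distinct carboxylates are observed
    (pairs summing up to the correct lipid mass). Diacyl splits with a
    carboxylate intensity ratio >= ``sn_threshold`` get a putative
    sn-2/sn-1 call, the more intense carboxylate being sn-2; cardiolipin
    multisets are never sn-called. Results are ranked by summed
    carboxylate intensity.
    """
    if ms3_neg.polarity != "negative":
        raise ValueError("acyl-chain identification uses negative-mode HCD spectra")
    species = precursor.ion.species
    if species.id_level not in ("sum_composition", "chain_composition"):
        raise ValueError("precursor needs a sum composition")
    n_chains = 4 if species.lipid_class == "CDL" else 2
    cmin, cmax = chain_carbons
    results: list[ChainAssignment] = []
    for split in _chain_splits(
        species.total_carbons, species.total_unsat, n_chains,
        cmin=cmin, cmax=cmax, umax=chain_unsat_max,
    ):
        distinct = sorted(set(split))
        peaks = []
        ok = True
        for carbons, unsat in distinct:
            idx = match_peak(ms3_neg, carboxylate_mz(carbons, unsat), tol)
            if idx is None:
                ok = False
                break
            peaks.append(idx)
        if not ok:
            continue
        intens = {cu: float(ms3_neg.intensity[i]) for cu, i in zip(distinct, peaks)}
        score = sum(intens[cu] for cu in split)  # multiset-weighted
        sn_call, sn_ratio = "unassigned", None
        chains = tuple(AcylChain(c, u) for c, u in split)
        if n_chains == 2 and split[0] != split[1]:
            i_a, i_b = intens[split[0]], intens[split[1]]
            hi, lo = max(i_a, i_b), min(i_a, i_b)
            sn_ratio = hi / lo if lo > 0 else float("inf")
            if sn_ratio >= sn_threshold:
                sn_call = "assigned"
                # the dominant carboxylate is released from sn-2
                sn2 = split[0] if i_a >= i_b else split[1]
                chains = tuple(
                    AcylChain(c, u, sn=2 if (c, u) == sn2 else 1) for c, u in split
                )
        results.append(
            ChainAssignment(
                chains=chains,
                evidence_mz=tuple(float(ms3_neg.mz[i]) for i in peaks),
                evidence_intensity=tuple(float(ms3_neg.intensity[i]) for i in peaks),
                score=score,
                sn_call=sn_call,
                sn_ratio=sn_ratio,
            )
        )
    results.sort(key=lambda r: -r.score)
    return results


# ---------------------------------------------------------------------------
# Fallback: acyl chains from UVPD neutral acyl losses
# ---------------------------------------------------------------------------

def chains_from_uvpd_losses(
    uvpd: CentroidSpectrum,
    precursor: CandidateAssignment,
    tol: float = 0.3,
    chain_carbons: tuple[int, int] = (12, 24),
    chain_unsat_max: int = 3,
) -> list[ChainAssignment]:
    """Chain evidence from neutral acyl losses in a UVPD spectrum.

    Matches ``precursor - FA`` (free fatty acid) and ``precursor - ketene``
    (FA - H2O) for every chain split. Either loss counts as evidence for
    the chain, but a chain observed through both is not double-counted:
    its score takes the stronger of the two peaks. sn positions are never
    assigned on this route.
    """
    species = precursor.ion.species
    if species.id_level not in ("sum_composition", "chain_composition"):
        raise ValueError("precursor needs a sum composition")
    n_chains = 4 if species.lipid_class == "CDL" else 2
    pre_mz = precursor.peak_mz
    results: list[ChainAssignment] = []
    for split in _chain_splits(
        species.total_carbons, species.total_unsat, n_chains,
        cmin=chain_carbons[0], cmax=chain_carbons[1], umax=chain_unsat_max,
    ):
        evidence: list[tuple[float, float]] = []
        ok = True
        for carbons, unsat in sorted(set(split)):
            fa_mass = AcylChain(carbons, unsat).mass
            best: tuple[float, float] | None = None
            for loss in (fa_mass, fa_mass - WATER.mass):
                idx = match_peak(uvpd, pre_mz - loss, tol)
                if idx is not None:
                    cand = (float(uvpd.mz[idx]), float(uvpd.intensity[idx]))
                    if best is None or cand[1] > best[1]:
                        best = cand
            if best is None:
                ok = False
                break
            evidence.append(best)
        if not ok:
            continue
        results.append(
            ChainAssignment(
                chains=tuple(AcylChain(c, u) for c, u in split),
                evidence_mz=tuple(e[0] for e in evidence),
                evidence_intensity=tuple(e[1] for e in evidence),
                score=sum(e[1] for e in evidence),
            )
        )
    results.sort(key=lambda r: -r.score)
    return results


def carboxylate_sum_residual(precursor_mz: float, split: Sequence[AcylChain]) -> float:
    """``sum(carboxylate m/z) - precursor m/z`` for a diacyl split of a
    deprotonated lipid; constant per lipid class (head-group remainder)."""
    return sum(carboxylate_mz(c.carbons, c.unsat_equiv) for c in split) - precursor_mz
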