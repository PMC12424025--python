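"""Seedable synthetic HCD and UVPD spectra with known ground truth.

The generator emulates the ion-trap fragment spectra of released bacterial
phospholipids so that every pipeline stage can be exercised without
instrument data: UVPD spectra carry the true diagnostic pair(s) (plus
-H3PO4 satellites for protonated PE), a 14-Da alkyl-cleavage ladder,
acyl-loss peaks and uniform noise; HCD spectra carry the class/adduct
neutral-loss peaks (positive mode) or carboxylate pairs with a set
sn-2:sn-1 intensity ratio (negative mode). Peak positions take normal
m/z jitter; everything is deterministic given the seed.

Intensity conventions (fractions of the base peak): the surviving
precursor is the base peak; diagnostic pairs fall at 20-100% with
cyclopropane pairs twice as abundant as C=C pairs, mirroring the relative
abundances seen for lipids carrying both; ladder peaks stay below 10%.
These are fixture conventions, not a physical fragmentation model, and
real intensity structure (isotope envelopes, detector noise correlations)
is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import CYCLOPROPANE, DOUBLE_BOND, LipidIon, WATER, carboxylate_mz
from .identify import DIAGNOSTIC_LOSSES
from .spectra import CentroidSpectrum
from .uvpd import H3PO4_MASS, FragmentPair, generate_pair_library

__all__ = ["SimulationConfig", "simulate_uvpd", "simulate_hcd"]

_CH2 = 14.015650


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and nuisance structure for one synthetic spectrum.

    ``ions`` lists (LipidIon, mixture weight); each ion must carry located
    modifications (its chains' ``mods``), which define the true diagnostic
    pairs. Weights must sum to 1.
    """

    ions: tuple[tuple[LipidIon, float], ...]
    pair_intensity: tuple[float, float] = (0.2, 1.0)  # base-peak fraction range
    cy_boost: float = 2.0  # cyclopropane pairs vs C=C pairs
    satellite_intensity: float = 0.5  # of the primary pair (protonated PE)
    ladder_intensity: float = 0.1
    n_ladder: int = 12
    acyl_loss_intensity: float = 0.3
    n_noise: int = 20
    noise_intensity: float = 0.05
    mz_jitter: float = 0.05  # Da, ion-trap centroid scatter
    sn2_sn1_ratio: float = 3.0  # carboxylate asymmetry in negative HCD
    seed: int = 0

    def __post_init__(self) -> None:
        weights = [w for _, w in self.ions]
        if self.ions and abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.mz_jitter < 0:
            raise ValueError("m/z jitter must be >= 0")


def _true_pairs(ion: LipidIon) -> list[FragmentPair]:
    """Library entries matching the ion's located modifications."""
    library = generate_pair_library(ion, include_satellites=False)
    truth = {
        (ci, mod.kind, mod.position)
        for ci, chain in enumerate(ion.species.chains)
        for mod in chain.mods
    }
    return [p for p in library if p.hypothesis() in truth]


def simulate_uvpd(config: SimulationConfig) -> CentroidSpectrum:
    """Synthetic UVPD MS3 spectrum of the configured precursor ion(s)."""
    rng = np.random.default_rng(config.seed)
    if not config.ions:
        return CentroidSpectrum(np.array([]), np.array([]), ms_level=3,
                                polarity="positive", activation="UVPD")
    main_ion = config.ions[0][0]
    precursor = main_ion.theoretical_mz
    mz, inten = [precursor], [1.0]

    for ion, weight in config.ions:
        for pair in _true_pairs(ion):
            amp = rng.uniform(*config.pair_intensity) * weight
            if pair.kind == CYCLOPROPANE:
                amp *= config.cy_boost
            amp = min(amp, 1.0)
            # mild asymmetry between the two members
            split = rng.uniform(0.4, 0.6)
            mz += [pair.mz_low, pair.mz_high]
            inten += [amp * split, amp * (1 - split)]
            if ion.species.lipid_class == "PE" and ion.adduct == "+H":
                sat = amp * config.satellite_intensity
                mz += [pair.mz_low - H3PO4_MASS, pair.mz_high - H3PO4_MASS]
                inten += [sat * split, sat * (1 - split)]
        # neutral acyl losses (free acid and ketene) for each chain
        for chain in ion.species.chains:
            for loss in (chain.mass, chain.mass - WATER.mass):
                mz.append(ion.theoretical_mz - loss)
                inten.append(config.acyl_loss_intensity * weight * rng.uniform(0.5, 1.0))

    # 14-Da alkyl-cleavage ladder walking down from the precursor
    start = precursor - rng.integers(2, 5) * _CH2
    for k in range(config.n_ladder):
        mz.append(start - k * _CH2)
        inten.append(config.ladder_intensity * rng.uniform(0.3, 1.0))

    lo = max(100.0, precursor - 600.0)
    for _ in range(config.n_noise):
        mz.append(rng.uniform(lo, precursor - 5.0))
        inten.append(config.noise_intensity * rng.uniform(0.1, 1.0))

    mz = np.array(mz, dtype=float)
    if config.mz_jitter > 0:
        mz = mz + rng.normal(0.0, config.mz_jitter, size=mz.shape)
    return CentroidSpectrum(
        mz, np.array(inten), ms_level=3,
        polarity=main_ion.polarity, precursor_mz=precursor, activation="UVPD",
    )


def simulate_hcd(config: SimulationConfig, polarity: str) -> CentroidSpectrum:
    """Synthetic HCD MS3 spectrum: class-diagnostic neutral losses in
    positive mode, carboxylate pairs (with the configured sn-2:sn-1
    asymmetry, sn-2 chain more intense) in negative mode."""
    rng = np.random.default_rng(config.seed + 1)
    if not config.ions:
        return CentroidSpectrum(np.array([]), np.array([]), ms_level=3,
                                polarity=polarity, activation="HCD")
    main_ion = config.ions[0][0]
    precursor = main_ion.theoretical_mz
    mz, inten = [precursor], [1.0]

    for ion, weight in config.ions:
        species = ion.species
        if polarity == "positive":
            losses = DIAGNOSTIC_LOSSES.get((species.lipid_class, ion.adduct), ())
            for loss in losses:
                mz.append(ion.theoretical_mz - loss.mass)
                inten.append(0.8 * weight * rng.uniform(0.7, 1.0))
        else:
            chains = species.chains
            base = 0.6 * weight
            for i, chain in enumerate(chains):
                amp = base
                if len(chains) == 2:
                    # listed order is (sn-1, sn-2); sn-2 released preferentially
                    amp = base * (config.sn2_sn1_ratio if (chain.sn or i + 1) == 2 else 1.0)
                mz.append(carboxylate_mz(chain.carbons, chain.unsat_equiv))
                inten.append(amp)

    lo = max(100.0, precursor - 600.0)
    for _ in range(config.n_noise):
        mz.append(rng.uniform(lo, precursor - 5.0))
        inten.append(config.noise_intensity * rng.uniform(0.1, 1.0))

    mz = np.array(mz, dtype=float)
    if config.mz_jitter > 0:
        mz = mz + rng.normal(0.0, config.mz_jitter, size=mz.shape)
    return CentroidSpectrum(
        mz, np.array(inten), ms_level=3,
        polarity=polarity, precursor_mz=precursor, activation="HCD",
    )
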