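"""Theoretical b/y fragment ladders, isocyanic-acid neutral losses,
precursor m/z, and a coarse averagine-style isotope envelope.

Only the b and y series are produced: the site-confidence rule downstream
is defined on these two series, and HCD spectra of tryptic peptides are
dominated by them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .chem import (
    C13_MINUS_C12,
    PROTEIN_NTERM,
    PROTON,
    RESIDUE_MASS,
    WATER,
    CARBAMYL,
    ModifiedPeptide,
)

__all__ = [
    "HNCO",
    "FragmentIon",
    "IsotopeEnvelope",
    "fragment_ladder",
    "neutral_loss_variants",
    "precursor_mz",
    "neutral_mass_from_mz",
    "isotope_envelope",
]

#: isocyanic acid, the neutral lost from carbamylated lysine on fragmentation
HNCO = 43.0058136592

#: average carbon count per dalton of peptide mass (averagine composition)
AVERAGINE_CARBON_PER_DA = 0.0444

#: natural abundance of carbon-13
P_C13 = 0.0107


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int
    charge: int
    mz: float
    contains_positions: frozenset[int]
    neutral_loss: str | None = None

    @property
    def label(self) -> str:
        nl = "-HNCO" if self.neutral_loss else ""
        return f"{self.series}{self.index}{nl}^{self.charge}"


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative isotopologue intensities M+0, M+1, ... normalized to max 1."""

    monoisotopic_mass: float
    relative_intensities: tuple[float, ...]

    def mz_values(self, charge: int) -> list[float]:
        return [
            precursor_mz(self.monoisotopic_mass + k * C13_MINUS_C12, charge)
            for k in range(len(self.relative_intensities))
        ]


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """m/z of the [M+zH]^z+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def neutral_mass_from_mz(mz: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON


def fragment_ladder(p: ModifiedPeptide, max_fragment_charge: int = 2) -> list[FragmentIon]:
    """All b_i / y_j ions (i, j in 1..n-1) at charges 1..max_fragment_charge.

    Modification deltas are carried by the fragment that contains the
    modified position; an N-terminal protein modification travels with the
    b series (and with no y ion but y_n, which is not emitted).
    """
    n = len(p.sequence)
    residue = np.array([RESIDUE_MASS[ch] for ch in p.sequence])
    delta = np.zeros(n)
    nterm_delta = 0.0
    for pos, mod in p.mods:
        if pos == PROTEIN_NTERM:
            nterm_delta += mod.delta_mass
        else:
            delta[pos - 1] += mod.delta_mass
    prefix = np.cumsum(residue + delta)
    total = prefix[-1]
    ions: list[FragmentIon] = []
    for z in range(1, max_fragment_charge + 1):
        for i in range(1, n):
            b_neutral = prefix[i - 1] + nterm_delta
            ions.append(
                FragmentIon(
                    series="b",
                    index=i,
                    charge=z,
                    mz=(b_neutral + z * PROTON) / z,
                    contains_positions=frozenset(range(1, i + 1)),
                )
            )
            j = i  # y_j pairs with b_{n-j}
            y_neutral = total - prefix[n - j - 1] + WATER
            ions.append(
                FragmentIon(
                    series="y",
                    index=j,
                    charge=z,
                    mz=(y_neutral + z * PROTON) / z,
                    contains_positions=frozenset(range(n - j + 1, n + 1)),
                )
            )
    return ions


def neutral_loss_variants(ions: list[FragmentIon], p: ModifiedPeptide) -> list[FragmentIon]:
    """HNCO-loss copies of every ion that contains a carbamylated lysine."""
    carb = set(p.carbamyl_positions())
    if not carb:
        return []
    variants = []
    for ion in ions:
        if ion.neutral_loss is None and carb & ion.contains_positions:
            variants.append(
                FragmentIon(
                    series=ion.series,
                    index=ion.index,
                    charge=ion.charge,
                    mz=ion.mz - HNCO / ion.charge,
                    contains_positions=ion.contains_positions,
                    neutral_loss="HNCO",
                )
            )
    return variants


def isotope_envelope(neutral_mass: float, n_peaks: int = 4) -> IsotopeEnvelope:
    """Coarse isotope envelope from a binomial model of the carbon count.

    The carbon count is estimated from the averagine composition
    (:data:`AVERAGINE_CARBON_PER_DA` carbons per dalton); M+k intensity is
    the binomial probability of k carbon-13 atoms.  Adequate for planting
    the acetyl M+1 confusable peak; not a fine-structure model.
    """
    if neutral_mass <= 0:
        raise ValueError(f"mass must be positive, got {neutral_mass}")
    if n_peaks < 3:
        raise ValueError("need at least 3 isotopologues")
    n_carbon = max(1, round(neutral_mass * AVERAGINE_CARBON_PER_DA))
    probs = binom.pmf(np.arange(n_peaks), n_carbon, P_C13)
    rel = probs / probs.max()
    return IsotopeEnvelope(monoisotopic_mass=neutral_mass, relative_intensities=tuple(rel))
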