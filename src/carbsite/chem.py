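"""Monoisotopic mass bookkeeping and in-silico tryptic digestion.

Residue masses are the standard monoisotopic residue masses (amino acid
minus water).  All peptide-level masses are neutral monoisotopic masses in
daltons; average masses are deliberately unsupported because the workflow
targets high-resolution Orbitrap data.

Coordinates are 1-based and inclusive throughout: ``start_pos`` is the
position of a peptide's first residue in its protein, and modification
positions are 1-based indices into the peptide (with the string
``"protein_nterm"`` for an N-terminal protein modification).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from pyteomics import mass as _pt_mass

__all__ = [
    "WATER",
    "PROTON",
    "C13_MINUS_C12",
    "PROTEIN_NTERM",
    "RESIDUE_MASS",
    "Modification",
    "ModifiedPeptide",
    "CARBAMIDOMETHYL",
    "CARBAMYL",
    "ACETYL",
    "OXIDATION",
    "DEAMIDATION",
    "modification_table",
    "variable_modifications",
    "peptide_neutral_mass",
    "peptide_key",
    "digest",
    "variable_mod_combinations",
]

WATER = 18.0105646863
PROTON = 1.00727646688
#: mass difference between a carbon-13 and a carbon-12 atom
C13_MINUS_C12 = 1.0033548378

#: sentinel modification position for the protein N-terminus
PROTEIN_NTERM = "protein_nterm"

#: monoisotopic residue masses for the 20 standard amino acids
RESIDUE_MASS: dict[str, float] = {
    aa: _pt_mass.std_aa_mass[aa]
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}


@dataclass(frozen=True)
class Modification:
    """A chemical modification with a fixed monoisotopic mass delta.

    ``targets`` holds one-letter residue codes and/or the terminus marker
    :data:`PROTEIN_NTERM`.
    """

    name: str
    delta_mass: float
    targets: frozenset[str]
    fixed: bool = False

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"modification {self.name!r} targets nothing")

    def applies_to(self, residue_or_terminus: str) -> bool:
        return residue_or_terminus in self.targets


CARBAMIDOMETHYL = Modification("carbamidomethyl", 57.0214637236, frozenset("C"), fixed=True)
CARBAMYL = Modification("carbamyl", 43.0058136592, frozenset("K"))
ACETYL = Modification("acetyl", 42.0105646863, frozenset({"K", PROTEIN_NTERM}))
OXIDATION = Modification("oxidation", 15.9949146221, frozenset("M"))
DEAMIDATION = Modification("deamidation", 0.9840155848, frozenset("NQ"))


def modification_table() -> list[Modification]:
    """The full search modification set: fixed carbamidomethyl-C plus the
    variable set carbamyl-K, acetyl-K/protein-N-term, oxidation-M and
    deamidation-N/Q."""
    return [CARBAMIDOMETHYL, CARBAMYL, ACETYL, OXIDATION, DEAMIDATION]


def variable_modifications() -> list[Modification]:
    return [m for m in modification_table() if not m.fixed]


ModSite = tuple[int | str, Modification]

#: registry for parsing canonical modification strings
MOD_BY_NAME: dict[str, Modification] = {
    m.name: m
    for m in (CARBAMIDOMETHYL, CARBAMYL, ACETYL, OXIDATION, DEAMIDATION)
}


def parse_mods(text: str) -> tuple[ModSite, ...]:
    """Parse a ``pos:name;pos:name`` modification string (inverse of the
    encoding used by :func:`peptide_key` and the PSM table)."""
    if not text or text != text:  # empty or NaN
        return ()
    out: list[ModSite] = []
    for token in str(text).split(";"):
        pos_s, _, name = token.partition(":")
        if name not in MOD_BY_NAME:
            raise ValueError(f"unknown modification name {name!r}")
        pos: int | str = PROTEIN_NTERM if pos_s in ("0", PROTEIN_NTERM) else int(pos_s)
        out.append((pos, MOD_BY_NAME[name]))
    return tuple(out)


@dataclass(frozen=True)
class ModifiedPeptide:
    """A tryptic peptide with protein coordinates and localized modifications.

    ``mods`` is kept sorted by position (terminus first) so equal peptide
    forms compare equal and produce identical keys.
    """

    sequence: str
    protein_accession: str = ""
    start_pos: int = 1
    missed_cleavages: int = 0
    mods: tuple[ModSite, ...] = ()
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = sorted(set(self.sequence) - set(RESIDUE_MASS))
        if bad:
            raise ValueError(f"unknown residue letter(s) {''.join(bad)!r} in {self.sequence!r}")
        seen: set[int | str] = set()
        for pos, mod in self.mods:
            if pos == PROTEIN_NTERM:
                if PROTEIN_NTERM not in mod.targets:
                    raise ValueError(f"{mod.name} does not target the protein N-terminus")
            else:
                if not 1 <= pos <= len(self.sequence):
                    raise ValueError(f"mod position {pos} outside peptide of length {len(self.sequence)}")
                if not mod.applies_to(self.sequence[pos - 1]):
                    raise ValueError(
                        f"{mod.name} does not target residue {self.sequence[pos - 1]!r} at {pos}"
                    )
            if pos in seen:
                raise ValueError(f"more than one modification at position {pos}")
            seen.add(pos)
        object.__setattr__(self, "mods", tuple(sorted(self.mods, key=_mod_sort_key)))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end_pos(self) -> int:
        return self.start_pos + len(self.sequence) - 1

    def covers(self, protein_position: int) -> bool:
        return self.start_pos <= protein_position <= self.end_pos

    def mod_at(self, position: int | str) -> Modification | None:
        for pos, mod in self.mods:
            if pos == position:
                return mod
        return None

    def carbamyl_positions(self) -> list[int]:
        """1-based peptide positions carrying a carbamyl group."""
        return [p for p, m in self.mods if isinstance(p, int) and m.name == CARBAMYL.name]

    def with_mods(self, mods: Iterable[ModSite]) -> "ModifiedPeptide":
        return replace(self, mods=tuple(mods))


def _mod_sort_key(site: ModSite):
    pos, _ = site
    return (0, 0) if pos == PROTEIN_NTERM else (1, pos)


def peptide_key(p: ModifiedPeptide) -> str:
    """Canonical string for one peptide form, e.g. ``AFKAWAVAR|3:carbamyl``.

    The protein N-terminus is encoded as position 0.  Unmodified peptides
    are keyed by the bare sequence.
    """
    if not p.mods:
        return p.sequence
    parts = []
    for pos, mod in p.mods:
        parts.append(f"{0 if pos == PROTEIN_NTERM else pos}:{mod.name}")
    return p.sequence + "|" + ";".join(parts)


def peptide_neutral_mass(p: ModifiedPeptide | str) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    if isinstance(p, str):
        p = ModifiedPeptide(sequence=p)
    total = WATER
    for ch in p.sequence:
        total += RESIDUE_MASS[ch]
    for _, mod in p.mods:
        total += mod.delta_mass
    return total


def digest(
    protein_sequence: str,
    protein_accession: str = "",
    max_missed: int = 2,
    min_length: int = 6,
    cleave_before_proline: bool = False,
    is_decoy: bool = False,
) -> list[ModifiedPeptide]:
    """Tryptic digestion: cleave C-terminal to K/R, by default not before P.

    Emits every product with at most ``max_missed`` internal cleavage sites
    and at least ``min_length`` residues, recording 1-based ``start_pos`` and
    the missed-cleavage count.  A sequence without any cleavage site yields
    the whole protein (if long enough).
    """
    seq = protein_sequence.strip().upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = sorted(set(seq) - set(RESIDUE_MASS))
    if bad:
        raise ValueError(f"unknown residue letter(s) {''.join(bad)!r} in protein {protein_accession!r}")
    # cut points: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(1, len(seq)):
        prev = seq[i - 1]
        if prev in "KR" and (cleave_before_proline or seq[i] != "P"):
            cuts.append(i)
    cuts.append(len(seq))
    peptides: list[ModifiedPeptide] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(cuts))):
            start, end = cuts[a], cuts[b]
            if end - start < min_length:
                continue
            peptides.append(
                ModifiedPeptide(
                    sequence=seq[start:end],
                    protein_accession=protein_accession,
                    start_pos=start + 1,
                    missed_cleavages=b - a - 1,
                    is_decoy=is_decoy,
                )
            )
    return peptides


def apply_fixed_mods(p: ModifiedPeptide) -> ModifiedPeptide:
    """Attach carbamidomethyl to every cysteine (alkylation is quantitative)."""
    mods = list(p.mods)
    taken = {pos for pos, _ in mods}
    for i, ch in enumerate(p.sequence, start=1):
        if ch == "C" and i not in taken:
            mods.append((i, CARBAMIDOMETHYL))
    return p.with_mods(mods)


def variable_mod_combinations(
    p: ModifiedPeptide,
    variable_mods: Sequence[Modification] | None = None,
    max_mods_per_peptide: int = 5,
) -> list[ModifiedPeptide]:
    """Enumerate all variable-modification assignments of a peptide.

    At most one variable modification per position, at most
    ``max_mods_per_peptide`` variable modifications in total; the fixed
    carbamidomethyl is applied to every cysteine unconditionally and does not
    count toward the cap.  Protein N-terminal acetylation is offered only
    when the peptide starts the protein (``start_pos == 1``).
    """
    if variable_mods is None:
        variable_mods = variable_modifications()
    base = apply_fixed_mods(p)
    fixed_sites = list(base.mods)
    # slot -> list of applicable variable mods
    slots: list[tuple[int | str, list[Modification]]] = []
    if p.start_pos == 1:
        opts = [m for m in variable_mods if m.applies_to(PROTEIN_NTERM)]
        if opts:
            slots.append((PROTEIN_NTERM, opts))
    for i, ch in enumerate(p.sequence, start=1):
        if ch == "C":
            continue  # occupied by the fixed modification
        opts = [m for m in variable_mods if m.applies_to(ch)]
        if opts:
            slots.append((i, opts))

    forms: list[ModifiedPeptide] = []

    def recurse(slot_idx: int, chosen: list[ModSite]) -> None:
        if slot_idx == len(slots):
            forms.append(base.with_mods(fixed_sites + chosen))
            return
        pos, opts = slots[slot_idx]
        recurse(slot_idx + 1, chosen)  # leave the slot unmodified
        if len(chosen) < max_mods_per_peptide:
            for mod in opts:
                chosen.append((pos, mod))
                recurse(slot_idx + 1, chosen)
                chosen.pop()

    recurse(0, [])
    return forms
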