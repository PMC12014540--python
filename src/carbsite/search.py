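"""Peptide-spectrum matching with ppm tolerances, target-decoy FDR, and
the carbamyl versus acetyl-carbon-13 precursor discrimination.

The precursor window is 5 ppm and the fragment window 20 ppm by default.
Carbamylation (+43.00581 Da) and acetylation (+42.01056 Da) differ by
0.99525 Da, which is 0.00811 Da less than one carbon-13 spacing: at 5 ppm
the M+1 isotopologue of an acetylated peptide can only be confused with a
carbamylated precursor above ~1622 Da neutral mass.  PSMs in that regime
are flagged ``ambiguous`` rather than silently reported.

Scoring is a deliberately simple, deterministic function — matched-ion
count plus explained-intensity fraction — documented in full so every
downstream number is reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .chem import (
    C13_MINUS_C12,
    CARBAMYL,
    Modification,
    ModifiedPeptide,
    digest,
    peptide_key,
    peptide_neutral_mass,
    variable_mod_combinations,
    variable_modifications,
)
from .fragments import fragment_ladder, neutral_loss_variants, neutral_mass_from_mz
from .spectra_io import Ms2Spectrum

__all__ = [
    "SearchConfig",
    "MatchedIon",
    "PeptideSpectrumMatch",
    "PeptideIndex",
    "build_index",
    "read_fasta",
    "match_spectrum",
    "search_spectrum",
    "search_spectra",
    "acetyl_isotope_check",
    "filter_fdr",
    "write_psm_table",
]

#: carbamyl minus acetyl mass difference, Da
CARB_MINUS_ACETYL = 0.9952489729
#: gap between a carbamylated precursor and the 13C-acetyl confusable, Da
ACETYL_C13_GAP = C13_MINUS_C12 - CARB_MINUS_ACETYL

DECOY_PREFIX = "rev_"


@dataclass(frozen=True)
class SearchConfig:
    precursor_tol_ppm: float = 5.0
    fragment_tol_ppm: float = 20.0
    fdr: float = 0.01
    max_missed: int = 2
    min_length: int = 6
    max_mods_per_peptide: int = 5
    max_fragment_charge: int = 2
    #: isotopologue offsets tried when the precursor was picked off-monoisotope
    isotope_corrections: tuple[int, ...] = (0, 1, 2)
    #: hard-reject ambiguous carbamyl/13C-acetyl precursors instead of flagging
    reject_ambiguous: bool = False
    cleave_before_proline: bool = False
    decoy_scheme: str = "reverse-protein"  # or "reverse-peptide"

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")


@dataclass(frozen=True)
class MatchedIon:
    ion: object  # FragmentIon
    observed_mz: float
    observed_intensity: float
    ppm_error: float


@dataclass(frozen=True)
class PeptideSpectrumMatch:
    spectrum_id: str
    peptide: ModifiedPeptide
    score: float
    matched_ions: tuple[MatchedIon, ...]
    precursor_ppm_error: float
    isotope_offset: int = 0
    is_decoy: bool = False
    #: 'distinguishable' | 'ambiguous' for carbamyl peptides, 'n/a' otherwise
    verdict: str = "n/a"

    def matched(self, series: str, index: int, neutral_loss: str | None = None) -> bool:
        """Was the theoretical ion (any charge) matched to a peak?"""
        return any(
            m.ion.series == series
            and m.ion.index == index
            and m.ion.neutral_loss == neutral_loss
            for m in self.matched_ions
        )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Protein sequences keyed by the first token of each FASTA header."""
    proteins: dict[str, str] = {}
    for record in SeqIO.parse(os.fspath(path), "fasta"):
        proteins[record.id.split()[0].split("|")[0]] = str(record.seq).upper()
    return proteins


class PeptideIndex:
    """All modified peptide forms of a protein collection, keyed by neutral
    mass for tolerance queries, with reversed-sequence decoys."""

    def __init__(self, forms: Sequence[ModifiedPeptide]):
        masses = np.array([peptide_neutral_mass(p) for p in forms])
        order = np.argsort(masses, kind="stable")
        self.masses = masses[order]
        self.forms: list[ModifiedPeptide] = [forms[i] for i in order]

    def __len__(self) -> int:
        return len(self.forms)

    @property
    def n_targets(self) -> int:
        return sum(not p.is_decoy for p in self.forms)

    @property
    def n_decoys(self) -> int:
        return sum(p.is_decoy for p in self.forms)

    def query(self, neutral_mass: float, tol_ppm: float) -> list[ModifiedPeptide]:
        """All forms with |delta| <= tol_ppm relative to the query mass."""
        half = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self.masses, neutral_mass - half, side="left")
        hi = np.searchsorted(self.masses, neutral_mass + half, side="right")
        return self.forms[lo:hi]


def _decoy_proteins(proteins: dict[str, str]) -> dict[str, str]:
    return {DECOY_PREFIX + acc: seq[::-1] for acc, seq in proteins.items()}


def build_index(
    proteins: dict[str, str] | str | os.PathLike,
    cfg: SearchConfig | None = None,
    variable_mods: Sequence[Modification] | None = None,
    with_decoys: bool = True,
) -> PeptideIndex:
    """Digest every protein, enumerate modification forms, add decoys.

    ``proteins`` may be an accession->sequence mapping or a FASTA path.
    Decoys come from full protein reversal by default
    (``cfg.decoy_scheme == "reverse-peptide"`` instead reverses each target
    peptide keeping its C-terminal residue, which guarantees one decoy per
    target form).
    """
    cfg = cfg or SearchConfig()
    if not isinstance(proteins, dict):
        proteins = read_fasta(proteins)
    if variable_mods is None:
        variable_mods = variable_modifications()

    forms: list[ModifiedPeptide] = []

    def expand(peptides: Iterable[ModifiedPeptide]) -> None:
        for pep in peptides:
            forms.extend(
                variable_mod_combinations(pep, variable_mods, cfg.max_mods_per_peptide)
            )

    target_sequences: set[str] = set()
    for acc, seq in proteins.items():
        peps = digest(
            seq, acc, cfg.max_missed, cfg.min_length, cfg.cleave_before_proline
        )
        target_sequences.update(p.sequence for p in peps)
        expand(peps)

    if with_decoys:
        if cfg.decoy_scheme == "reverse-protein":
            for acc, seq in _decoy_proteins(proteins).items():
                peps = [
                    p
                    for p in digest(
                        seq, acc, cfg.max_missed, cfg.min_length, cfg.cleave_before_proline,
                        is_decoy=True,
                    )
                    if p.sequence not in target_sequences
                ]
                expand(peps)
        elif cfg.decoy_scheme == "reverse-peptide":
            for acc, seq in proteins.items():
                for p in digest(
                    seq, acc, cfg.max_missed, cfg.min_length, cfg.cleave_before_proline
                ):
                    rev = p.sequence[:-1][::-1] + p.sequence[-1]
                    if rev in target_sequences:
                        continue
                    expand(
                        [
                            ModifiedPeptide(
                                sequence=rev,
                                protein_accession=DECOY_PREFIX + acc,
                                start_pos=p.start_pos,
                                missed_cleavages=p.missed_cleavages,
                                is_decoy=True,
                            )
                        ]
                    )
        else:
            raise ValueError(f"unknown decoy scheme {cfg.decoy_scheme!r}")
    return PeptideIndex(forms)


def _theoretical_ions(p: ModifiedPeptide, max_fragment_charge: int):
    ladder = fragment_ladder(p, max_fragment_charge)
    return ladder + neutral_loss_variants(ladder, p)


def _score_candidate(
    spectrum: Ms2Spectrum,
    candidate: ModifiedPeptide,
    cfg: SearchConfig,
    peak_mz: np.ndarray,
    peak_intensity: np.ndarray,
    total_intensity: float,
) -> tuple[float, tuple[MatchedIon, ...]]:
    matched: list[MatchedIon] = []
    matched_peaks: set[int] = set()
    for ion in _theoretical_ions(candidate, cfg.max_fragment_charge):
        if peak_mz.size == 0:
            break
        j = int(np.searchsorted(peak_mz, ion.mz))
        best_idx, best_err = -1, np.inf
        for k in (j - 1, j):
            if 0 <= k < peak_mz.size:
                err = abs(peak_mz[k] - ion.mz)
                if err < best_err:
                    best_idx, best_err = k, err
        if best_idx < 0:
            continue
        ppm = (peak_mz[best_idx] - ion.mz) / ion.mz * 1e6
        if abs(ppm) <= cfg.fragment_tol_ppm:
            matched.append(
                MatchedIon(ion, float(peak_mz[best_idx]), float(peak_intensity[best_idx]), ppm)
            )
            matched_peaks.add(best_idx)
    if not matched:
        return 0.0, ()
    explained = float(peak_intensity[sorted(matched_peaks)].sum())
    frac = explained / total_intensity if total_intensity > 0 else 0.0
    return len(matched) + frac, tuple(matched)


def match_spectrum(
    spectrum: Ms2Spectrum,
    candidates: Sequence[ModifiedPeptide],
    cfg: SearchConfig | None = None,
    observed_neutral_mass: float | None = None,
    isotope_offset: int = 0,
) -> PeptideSpectrumMatch | None:
    """Score each candidate against the spectrum and return the best PSM.

    Theoretical ions (b/y ladders plus HNCO-loss variants) are matched
    greedily to the nearest observed peak within the fragment tolerance;
    each theoretical ion claims at most one peak.  Score = matched-ion
    count + fraction of total peak intensity explained.  Ties break toward
    fewer modifications, then lexicographic peptide key.
    """
    cfg = cfg or SearchConfig()
    if not candidates or not spectrum.peaks:
        return None
    if observed_neutral_mass is None:
        observed_neutral_mass = neutral_mass_from_mz(
            spectrum.precursor_mz, spectrum.precursor_charge
        )
    peak_mz = np.array([mz for mz, _ in spectrum.peaks])
    peak_intensity = np.array([i for _, i in spectrum.peaks])
    total = float(peak_intensity.sum())

    best: PeptideSpectrumMatch | None = None
    best_key: tuple | None = None
    for cand in candidates:
        score, matched = _score_candidate(
            spectrum, cand, cfg, peak_mz, peak_intensity, total
        )
        if score <= 0:
            continue
        theo = peptide_neutral_mass(cand)
        ppm = (observed_neutral_mass - theo) / theo * 1e6
        key = (-score, len(cand.mods), peptide_key(cand))
        if best_key is None or key < best_key:
            best_key = key
            best = PeptideSpectrumMatch(
                spectrum_id=spectrum.spectrum_id,
                peptide=cand,
                score=score,
                matched_ions=matched,
                precursor_ppm_error=ppm,
                isotope_offset=isotope_offset,
                is_decoy=cand.is_decoy,
            )
    return best


def search_spectrum(
    spectrum: Ms2Spectrum, index: PeptideIndex, cfg: SearchConfig | None = None
) -> PeptideSpectrumMatch | None:
    """Query the index at each isotope-corrected precursor mass and keep the
    best-scoring PSM across corrections."""
    cfg = cfg or SearchConfig()
    observed = neutral_mass_from_mz(spectrum.precursor_mz, spectrum.precursor_charge)
    best: PeptideSpectrumMatch | None = None
    for k in cfg.isotope_corrections:
        corrected = observed - k * C13_MINUS_C12
        candidates = index.query(corrected, cfg.precursor_tol_ppm)
        psm = match_spectrum(spectrum, candidates, cfg, corrected, isotope_offset=k)
        if psm is None:
            continue
        if (
            best is None
            or psm.score > best.score
            or (psm.score == best.score and psm.isotope_offset < best.isotope_offset)
        ):
            best = psm
    if best is not None and best.peptide.carbamyl_positions():
        best = replace(best, verdict=acetyl_isotope_check(best, cfg))
    return best


def search_spectra(
    spectra: Iterable[Ms2Spectrum], index: PeptideIndex, cfg: SearchConfig | None = None
) -> list[PeptideSpectrumMatch]:
    cfg = cfg or SearchConfig()
    return [
        psm for s in spectra if (psm := search_spectrum(s, index, cfg)) is not None
    ]


def acetyl_isotope_check(
    psm: PeptideSpectrumMatch, cfg: SearchConfig | None = None
) -> str:
    """Can this carbamylated precursor be confused with 13C-acetyl?

    The acetylated counterpart sits 0.99525 Da below the carbamylated mass;
    its M+1 isotopologue sits 0.00811 Da above the carbamylated precursor.
    The PSM is ``distinguishable`` iff that gap exceeds the precursor
    tolerance in ppm, which happens below ~1622 Da at 5 ppm.
    """
    cfg = cfg or SearchConfig()
    if not psm.peptide.carbamyl_positions():
        raise ValueError("acetyl_isotope_check requires a carbamylated peptide")
    m_carb = peptide_neutral_mass(psm.peptide)
    m_acetyl = m_carb - CARB_MINUS_ACETYL
    gap_ppm = abs(m_acetyl + C13_MINUS_C12 - m_carb) / m_carb * 1e6
    return "distinguishable" if gap_ppm > cfg.precursor_tol_ppm else "ambiguous"


def filter_fdr(
    psms: Sequence[PeptideSpectrumMatch], cfg: SearchConfig | None = None
) -> list[PeptideSpectrumMatch]:
    """Target-decoy FDR filter at the configured peptide-level FDR.

    PSMs are sorted by descending score and the largest accepted prefix with
    (#decoys / #targets) <= fdr is kept; decoys are then removed.  With
    ``reject_ambiguous`` set, ambiguous carbamyl/13C-acetyl PSMs are dropped
    before thresholding.
    """
    cfg = cfg or SearchConfig()
    pool = list(psms)
    if cfg.reject_ambiguous:
        pool = [p for p in pool if p.verdict != "ambiguous"]
    ranked = sorted(pool, key=lambda p: (-p.score, p.is_decoy, p.spectrum_id))
    n_decoy = 0
    n_target = 0
    best_cut = 0
    for i, psm in enumerate(ranked, start=1):
        if psm.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        if n_target > 0 and n_decoy / n_target <= cfg.fdr:
            best_cut = i
    return [p for p in ranked[:best_cut] if not p.is_decoy]


PSM_TABLE_COLUMNS = [
    "spectrum_id", "accession", "peptide", "start_pos", "missed_cleavages",
    "mods", "score", "precursor_ppm", "isotope_offset", "n_matched",
    "carb_positions", "continuity", "neutral_loss", "verdict", "is_decoy",
]


def write_psm_table(psms: Sequence[PeptideSpectrumMatch], path: str | os.PathLike) -> None:
    """PSM TSV including per-carbamyl-site evidence columns, so downstream
    stages (site table, quantification) can run from the file alone."""
    import pandas as pd

    from .sites import continuity_check, neutral_loss_evidence

    rows = []
    for p in psms:
        carb = sorted(p.peptide.carbamyl_positions())
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "accession": p.peptide.protein_accession,
                "peptide": p.peptide.sequence,
                "start_pos": p.peptide.start_pos,
                "missed_cleavages": p.peptide.missed_cleavages,
                "mods": ";".join(
                    f"{0 if pos == 'protein_nterm' else pos}:{mod.name}"
                    for pos, mod in p.peptide.mods
                ),
                "score": round(p.score, 4),
                "precursor_ppm": round(p.precursor_ppm_error, 3),
                "isotope_offset": p.isotope_offset,
                "n_matched": len(p.matched_ions),
                "carb_positions": ";".join(str(i) for i in carb),
                "continuity": ";".join(
                    "1" if continuity_check(p, i) else "0" for i in carb
                ),
                "neutral_loss": int(neutral_loss_evidence(p)) if carb else 0,
                "verdict": p.verdict,
                "is_decoy": p.is_decoy,
            }
        )
    pd.DataFrame(rows, columns=PSM_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def peptides_from_psm_table(psm_df) -> list[ModifiedPeptide]:
    """Reconstruct the identified peptide forms from a written PSM table."""
    from .chem import parse_mods

    forms: dict[tuple, ModifiedPeptide] = {}
    for row in psm_df.itertuples(index=False):
        key = (row.peptide, row.mods if isinstance(row.mods, str) else "")
        if key in forms:
            continue
        forms[key] = ModifiedPeptide(
            sequence=row.peptide,
            protein_accession=row.accession,
            start_pos=int(row.start_pos),
            missed_cleavages=int(row.missed_cleavages),
            mods=parse_mods(row.mods if isinstance(row.mods, str) else ""),
            is_decoy=bool(row.is_decoy),
        )
    return list(forms.values())
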