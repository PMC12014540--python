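"""XIC-based carbamylation frequencies and protein-level summaries.

The per-site statistic is the fraction of parent-peptide signal carried by
the carbamylated forms: summed XIC areas of every identified peptide form
covering the site with a carbamyl group at that site, divided by the summed
areas of *all* identified forms of those parent peptides independent of
modification state (unmodified, carbamylated, and any other variable
modification), pooled across charge states and missed-cleavage contexts.

Protein-level summaries follow standard label-free practice: LFQ by summing
unique-peptide areas (proteins with fewer than two unique peptides are
dropped), iBAQ by dividing by the count of theoretically observable fully
tryptic peptides, replicate aggregation by the median on the log2 scale,
a valid-values filter, and imputation of missing values from a downshifted
normal distribution (width 0.3, shift 1.8 in column-standard-deviation
units), the convention for proteins near the detection limit.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import CARBAMYL, ModifiedPeptide, digest, peptide_key
from .spectra_io import XicRecord

__all__ = [
    "SiteFrequency",
    "ProteinQuant",
    "site_frequency",
    "site_frequency_table",
    "carbamylation_degree",
    "lfq_protein_intensity",
    "theoretical_peptide_count",
    "ibaq",
    "replicate_median",
    "filter_valid_values",
    "impute_missing",
    "write_site_frequency_table",
]

logger = logging.getLogger(__name__)

Site = tuple[str, int]  # (protein accession, 1-based protein position)


@dataclass(frozen=True)
class SiteFrequency:
    sample_id: str
    protein_accession: str
    protein_position: int
    carb_intensity: float
    total_intensity: float
    frequency_percent: float

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("total intensity must be positive for an emitted row")
        if self.carb_intensity > self.total_intensity + 1e-9:
            raise ValueError("carbamylated intensity exceeds total intensity")


@dataclass(frozen=True)
class ProteinQuant:
    protein_accession: str
    sample_id: str
    lfq_intensity: float
    ibaq_intensity: float | None
    n_unique_peptides: int


def _covering_forms(
    site: Site, identified_forms: Iterable[ModifiedPeptide]
) -> tuple[dict[str, ModifiedPeptide], dict[str, ModifiedPeptide]]:
    """Split identified forms covering the site into (carbamylated-at-site,
    all forms), keyed by canonical peptide key."""
    acc, pos = site
    covering: dict[str, ModifiedPeptide] = {}
    carb: dict[str, ModifiedPeptide] = {}
    for form in identified_forms:
        if form.protein_accession != acc or not form.covers(pos):
            continue
        key = peptide_key(form)
        covering[key] = form
        i = pos - form.start_pos + 1
        mod = form.mod_at(i)
        if mod is not None and mod.name == CARBAMYL.name:
            carb[key] = form
    return carb, covering


def site_frequency(
    site: Site,
    sample_id: str,
    xic_records: Sequence[XicRecord],
    identified_forms: Iterable[ModifiedPeptide],
) -> SiteFrequency | None:
    """Carbamylation frequency of one site in one sample, in percent.

    Returns ``None`` with a logged warning when no parent-peptide signal is
    present in the sample.
    """
    carb, covering = _covering_forms(site, identified_forms)
    num = 0.0
    den = 0.0
    for rec in xic_records:
        if rec.sample_id != sample_id:
            continue
        if rec.peptide_key in covering:
            den += rec.area
            if rec.peptide_key in carb:
                num += rec.area
    if den <= 0:
        logger.warning(
            "site %s:K%d has no parent-peptide XIC signal in sample %s; skipped",
            site[0], site[1], sample_id,
        )
        return None
    return SiteFrequency(
        sample_id=sample_id,
        protein_accession=site[0],
        protein_position=site[1],
        carb_intensity=num,
        total_intensity=den,
        frequency_percent=100.0 * num / den,
    )


def site_frequency_table(
    sites: Iterable[Site],
    xic_records: Sequence[XicRecord],
    identified_forms: Iterable[ModifiedPeptide],
) -> list[SiteFrequency]:
    forms = list(identified_forms)
    samples = sorted({r.sample_id for r in xic_records})
    rows: list[SiteFrequency] = []
    for site in sorted(set(sites)):
        for sample in samples:
            sf = site_frequency(site, sample, xic_records, forms)
            if sf is not None:
                rows.append(sf)
    return rows


def carbamylation_degree(
    freqs: Sequence[SiteFrequency], method: str = "mean"
) -> dict[str, float]:
    """Per-sample degree of carbamylation: the mean (or median) of the
    sample's site frequencies, in percent."""
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {method!r}")
    by_sample: dict[str, list[float]] = defaultdict(list)
    for sf in freqs:
        by_sample[sf.sample_id].append(sf.frequency_percent)
    agg = np.mean if method == "mean" else np.median
    return {sample: float(agg(vals)) for sample, vals in sorted(by_sample.items())}


def lfq_protein_intensity(
    identified_forms: Iterable[ModifiedPeptide],
    xic_records: Sequence[XicRecord],
    min_unique_peptides: int = 2,
    sequence_to_accessions: Mapping[str, set[str]] | None = None,
) -> list[ProteinQuant]:
    """Protein LFQ per sample: summed areas of peptides unique to the protein.

    A peptide sequence mapping to more than one accession contributes to no
    protein.  Proteins observed with fewer than ``min_unique_peptides``
    distinct unique sequences in a sample are dropped.
    """
    identified_forms = list(identified_forms)
    forms = {peptide_key(f): f for f in identified_forms}
    if sequence_to_accessions is None:
        # built before key-deduplication: a sequence claimed by several
        # proteins must be recognized as shared even though forms from
        # different proteins share one canonical key
        seq_acc: dict[str, set[str]] = defaultdict(set)
        for f in identified_forms:
            seq_acc[f.sequence].add(f.protein_accession)
        sequence_to_accessions = seq_acc

    area: dict[tuple[str, str], float] = defaultdict(float)  # (sample, acc)
    uniq_seqs: dict[tuple[str, str], set[str]] = defaultdict(set)
    for rec in xic_records:
        form = forms.get(rec.peptide_key)
        if form is None:
            continue
        accs = sequence_to_accessions.get(form.sequence, set())
        if len(accs) != 1:
            continue  # shared peptide: counts toward no protein
        key = (rec.sample_id, form.protein_accession)
        area[key] += rec.area
        uniq_seqs[key].add(form.sequence)

    out = [
        ProteinQuant(
            protein_accession=acc,
            sample_id=sample,
            lfq_intensity=area[(sample, acc)],
            ibaq_intensity=None,
            n_unique_peptides=len(uniq_seqs[(sample, acc)]),
        )
        for (sample, acc) in sorted(area)
        if len(uniq_seqs[(sample, acc)]) >= min_unique_peptides
    ]
    return out


def theoretical_peptide_count(
    protein_sequence: str, min_length: int = 6, max_length: int = 30
) -> int:
    """iBAQ divisor: fully tryptic peptides, no missed cleavages, length 6-30."""
    peps = digest(protein_sequence, max_missed=0, min_length=min_length)
    return sum(1 for p in peps if len(p.sequence) <= max_length)


def ibaq(
    lfq_intensity: float,
    protein_sequence: str,
    min_length: int = 6,
    max_length: int = 30,
) -> float:
    n = theoretical_peptide_count(protein_sequence, min_length, max_length)
    if n == 0:
        raise ValueError("protein has no theoretically observable peptide")
    return lfq_intensity / n


def replicate_median(
    matrix: pd.DataFrame, replicate_grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Median over technical replicates per condition, on log2 intensities.

    ``replicate_grouping`` maps column name -> condition label.  Missing
    values are ignored; a condition with no observed replicate stays missing.
    """
    unknown = set(matrix.columns) - set(replicate_grouping)
    if unknown:
        raise ValueError(f"columns without replicate group: {sorted(unknown)}")
    return matrix.T.groupby([replicate_grouping[c] for c in matrix.columns]).median().T


def filter_valid_values(
    matrix: pd.DataFrame, groups: Mapping[str, str], min_valid: int = 2
) -> pd.DataFrame:
    """Keep rows with at least ``min_valid`` observed values in >= 1 group."""
    labels = [groups[c] for c in matrix.columns]
    counts = matrix.notna().T.groupby(labels).sum().T
    return matrix.loc[(counts >= min_valid).any(axis=1)]


def impute_missing(
    matrix: pd.DataFrame,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw missing log2 intensities from a downshifted normal, per column.

    For a column with observed mean m and standard deviation s, missing
    entries are drawn from Normal(m - shift*s, (width*s)^2).  Deterministic
    given the seed.  Columns with fewer than 3 observed values are rejected
    (their moments are too unstable to define an imputation distribution).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = matrix.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_missing = out[col].isna().sum()
        if n_missing == 0:
            continue
        if len(observed) < 3:
            raise ValueError(
                f"column {col!r} has {len(observed)} observed values; "
                "need >= 3 to impute"
            )
        m, s = float(observed.mean()), float(observed.std(ddof=1))
        draws = rng.normal(m - shift * s, width * s, size=int(n_missing))
        out.loc[out[col].isna(), col] = draws
    return out


def write_site_frequency_table(freqs: Sequence[SiteFrequency], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "accession": f.protein_accession,
                "site": f"K{f.protein_position}",
                "carb_intensity": round(f.carb_intensity, 4),
                "total_intensity": round(f.total_intensity, 4),
                "frequency_percent": round(f.frequency_percent, 4),
            }
            for f in freqs
        ],
        columns=[
            "sample_id", "accession", "site",
            "carb_intensity", "total_intensity", "frequency_percent",
        ],
    ).to_csv(path, sep="\t", index=False)
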