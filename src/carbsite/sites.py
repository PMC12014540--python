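"""Site-confidence rules for carbamylated lysines and the site report.

A carbamylation site is reported as confident only when, within a single
ion series of at least one supporting PSM, the fragment ions bracketing the
modified lysine are both matched — i.e. the residue's mass increment is
pinned directly by observed ions.  The isocyanic-acid neutral loss is
recorded as corroborating evidence but is not required.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "SiteAssignment",
    "continuity_check",
    "neutral_loss_evidence",
    "assemble_site_table",
    "site_table_from_psm_table",
    "write_site_table",
    "annotate_site",
    "load_site_catalog",
    "site_catalog_path",
]


@dataclass(frozen=True)
class SiteAssignment:
    protein_accession: str
    protein_position: int  # 1-based residue index in the protein
    annotated_sequence: str  # peptide with the site lysine in lowercase
    continuity_ok: bool
    neutral_loss_seen: bool
    isotope_distinguishable: bool
    supporting_psm_ids: tuple[str, ...]


def continuity_check(psm, site_position_in_peptide: int) -> bool:
    """Bracketing-pair reading of "ion series continuous on both sides".

    For a carbamylated lysine at peptide position ``i`` of an ``n``-mer the
    rule asks, in one series at any observed charge, for both ions flanking
    the residue: b_{i-1} and b_i, or y_{n-i} and y_{n-i+1}.  A terminal
    residue has only one flanking fragment in the informative series (the
    precursor pins the other side), so i = 1 requires y_{n-1} and i = n
    requires b_{n-1}.  Neutral-loss ions do not count toward continuity.
    """
    i = site_position_in_peptide
    p = psm.peptide
    n = len(p.sequence)
    if i not in p.carbamyl_positions():
        raise ValueError(f"peptide {p.sequence} carries no carbamyl at position {i}")
    b_ok = False
    if i > 1:
        b_ok = psm.matched("b", i - 1) and (i == n or psm.matched("b", i))
    y_ok = False
    if i < n:
        y_ok = psm.matched("y", n - i) and (i == 1 or psm.matched("y", n - i + 1))
    return b_ok or y_ok


def neutral_loss_evidence(psm) -> bool:
    """True iff at least one matched ion is an HNCO-loss variant."""
    return any(m.ion.neutral_loss == "HNCO" for m in psm.matched_ions)


def annotate_site(sequence: str, position_in_peptide: int) -> str:
    """Mark the modified residue in lowercase, e.g. ``AFkAWAVAR``."""
    i = position_in_peptide
    return sequence[: i - 1] + sequence[i - 1].lower() + sequence[i:]


def assemble_site_table(
    psms: list,
    require_distinguishable: bool = False,
) -> list[SiteAssignment]:
    """Group accepted carbamyl PSMs into per-site rows.

    A site is kept when at least one supporting PSM passes the continuity
    check: matched fragments bracketing the lysine pin its mass increment
    to the fragment tolerance (20 ppm of a fragment, i.e. ~0.01 Da), which
    separates carbamyl from acetyl (0.995 Da apart) outright.  The
    precursor-level carbamyl/13C-acetyl verdict is therefore reported as an
    annotation; ``require_distinguishable=True`` additionally gates rows on
    it for a stricter, precursor-confirmed table.  Neutral loss is
    reported, not required.  Output is sorted by accession then position;
    identical input yields identical output.
    """
    groups: dict[tuple[str, int], dict] = {}
    for psm in psms:
        if psm.is_decoy:
            continue
        p = psm.peptide
        for i in sorted(p.carbamyl_positions()):
            pos = p.start_pos + i - 1
            entry = groups.setdefault(
                (p.protein_accession, pos),
                {
                    "annotated": annotate_site(p.sequence, i),
                    "continuity": False,
                    "nl": False,
                    "distinguishable": False,
                    "psms": [],
                },
            )
            entry["continuity"] = entry["continuity"] or continuity_check(psm, i)
            entry["nl"] = entry["nl"] or neutral_loss_evidence(psm)
            entry["distinguishable"] = (
                entry["distinguishable"] or psm.verdict == "distinguishable"
            )
            entry["psms"].append(psm.spectrum_id)

    table: list[SiteAssignment] = []
    for (acc, pos), entry in sorted(groups.items()):
        if not entry["continuity"]:
            continue
        if require_distinguishable and not entry["distinguishable"]:
            continue
        table.append(
            SiteAssignment(
                protein_accession=acc,
                protein_position=pos,
                annotated_sequence=entry["annotated"],
                continuity_ok=True,
                neutral_loss_seen=entry["nl"],
                isotope_distinguishable=entry["distinguishable"],
                supporting_psm_ids=tuple(sorted(set(entry["psms"]))),
            )
        )
    return table


def site_table_from_psm_table(psm_df: pd.DataFrame) -> list[SiteAssignment]:
    """Rebuild the site table from a written PSM table.

    Uses the per-PSM evidence columns (``carb_positions``, ``continuity``,
    ``neutral_loss``, ``verdict``) so the validate stage can run standalone
    on files, without rescoring spectra.
    """
    groups: dict[tuple[str, int], dict] = {}
    for row in psm_df.itertuples(index=False):
        if getattr(row, "is_decoy", False):
            continue
        raw = row.carb_positions
        if raw is None or raw != raw or str(raw) == "":  # NaN-safe emptiness
            continue
        positions = [int(float(x)) for x in str(raw).split(";")]
        flags = [x.split(".")[0] == "1" for x in str(row.continuity).split(";")]
        for pep_pos, cont in zip(positions, flags):
            pos = int(row.start_pos) + pep_pos - 1
            entry = groups.setdefault(
                (row.accession, pos),
                {
                    "annotated": annotate_site(row.peptide, pep_pos),
                    "continuity": False,
                    "nl": False,
                    "distinguishable": False,
                    "psms": [],
                },
            )
            entry["continuity"] = entry["continuity"] or cont
            entry["nl"] = entry["nl"] or bool(row.neutral_loss)
            entry["distinguishable"] = (
                entry["distinguishable"] or row.verdict == "distinguishable"
            )
            entry["psms"].append(row.spectrum_id)
    table = []
    for (acc, pos), entry in sorted(groups.items()):
        if not entry["continuity"]:
            continue
        table.append(
            SiteAssignment(
                protein_accession=acc,
                protein_position=pos,
                annotated_sequence=entry["annotated"],
                continuity_ok=True,
                neutral_loss_seen=entry["nl"],
                isotope_distinguishable=entry["distinguishable"],
                supporting_psm_ids=tuple(sorted(set(entry["psms"]))),
            )
        )
    return table


SITE_TABLE_COLUMNS = [
    "accession",
    "site",
    "annotated_sequence",
    "continuity_ok",
    "neutral_loss_seen",
    "isotope_distinguishable",
    "n_psms",
]


def write_site_table(sites: list[SiteAssignment], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "accession": s.protein_accession,
                "site": f"K{s.protein_position}",
                "annotated_sequence": s.annotated_sequence,
                "continuity_ok": s.continuity_ok,
                "neutral_loss_seen": s.neutral_loss_seen,
                "isotope_distinguishable": s.isotope_distinguishable,
                "n_psms": len(s.supporting_psm_ids),
            }
            for s in sites
        ],
        columns=SITE_TABLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def site_catalog_path() -> os.PathLike:
    """Path of the packaged catalog of carbamylation sites identified in
    rheumatoid-arthritis synovial fluid (accession, protein name, annotated
    peptide, K-position)."""
    return resources.files("carbsite.data") / "rasf_carbamylation_sites.tsv"


def load_site_catalog(path: str | os.PathLike | None = None) -> pd.DataFrame:
    df = pd.read_csv(path if path is not None else site_catalog_path(), sep="\t")
    expected = {"accession", "protein_name", "annotated_sequence", "site"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"site catalog missing column(s) {sorted(missing)}")
    return df
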