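"""Stage orchestration: simulate -> search -> validate -> quantify -> stats.

Each stage reads and writes plain MGF/TSV files in one output directory, so
every stage can be re-run standalone and the whole pipeline is byte-
reproducible given the same config and seed.  Stage-level record counts are
logged and collected into ``provenance.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .quant import (
    carbamylation_degree,
    ibaq,
    lfq_protein_intensity,
    site_frequency_table,
    write_site_frequency_table,
)
from .search import (
    SearchConfig,
    build_index,
    filter_fdr,
    peptides_from_psm_table,
    search_spectra,
    write_psm_table,
)
from .simulate import SimConfig, generate_truth, simulate_cohort, simulate_run
from .sites import site_table_from_psm_table, write_site_table
from .spectra_io import read_mgf, read_xic_table
from .stats import (
    correlation_report,
    mann_whitney_u,
    median_fold_change,
    read_cohort_table,
    wilcoxon_signed_rank,
)

__all__ = [
    "FILES",
    "load_config",
    "run_pipeline",
    "stage_simulate",
    "stage_search",
    "stage_validate",
    "stage_quantify",
    "stage_stats",
    "presence_absence_sets",
    "site_catalog_counts",
]

logger = logging.getLogger(__name__)

FILES = {
    "mgf": "run.mgf",
    "xic": "xic.tsv",
    "cohort": "cohort.tsv",
    "fasta": "proteins.fasta",
    "psms": "psms.tsv",
    "sites": "site_table.tsv",
    "site_freq": "site_frequency.tsv",
    "protein_quant": "protein_quant.tsv",
    "correlations": "correlation_report.tsv",
    "group_stats": "group_stats.tsv",
    "presence": "presence_absence.tsv",
    "provenance": "provenance.json",
}


def load_config(path: str | os.PathLike | None) -> tuple[SimConfig, SearchConfig]:
    """One YAML file with optional ``simulate:`` and ``search:`` sections."""
    if path is None:
        return SimConfig(), SearchConfig()
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    sim = SimConfig.from_dict(payload.get("simulate", {}))
    search = SearchConfig(**payload.get("search", {}))
    return sim, search


def presence_absence_sets(sets_by_group: dict[str, set]) -> dict[str, int]:
    """Exclusive-region sizes of the three-set partition.

    Keys are '&'-joined group names, e.g. ``"RA-SF"`` for proteins found
    only there and ``"RA-SF&RA-plasma"`` for proteins in both but not the
    third group; all seven regions are reported.
    """
    if len(sets_by_group) != 3:
        raise ValueError("presence/absence partition is defined for exactly 3 groups")
    names = list(sets_by_group)
    universe = set().union(*sets_by_group.values())
    regions: dict[str, int] = {}
    for mask in range(1, 8):
        members = [names[i] for i in range(3) if mask >> i & 1]
        region = set(universe)
        for i in range(3):
            if mask >> i & 1:
                region &= sets_by_group[names[i]]
            else:
                region -= sets_by_group[names[i]]
        regions["&".join(members)] = len(region)
    return regions


def site_catalog_counts(catalog: pd.DataFrame) -> tuple[int, int]:
    """(unique carbamylation sites, unique proteins) in a site catalog."""
    n_sites = len(catalog[["accession", "site"]].drop_duplicates())
    return n_sites, catalog["accession"].nunique()


def _write_fasta(proteins: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteins.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def stage_simulate(sim_cfg: SimConfig, seed: int, outdir: Path) -> dict:
    truth = generate_truth(sim_cfg, seed)
    spectra, xic = simulate_run(
        truth, sim_cfg, seed,
        mgf_path=outdir / FILES["mgf"], xic_path=outdir / FILES["xic"],
    )
    simulate_cohort(truth, outdir / FILES["cohort"])
    _write_fasta(truth.proteins, outdir / FILES["fasta"])
    logger.info("simulate: %d spectra, %d XIC records, %d samples",
                len(spectra), len(xic), len(truth.samples))
    return {"n_spectra": len(spectra), "n_xic_records": len(xic)}


def stage_search(search_cfg: SearchConfig, outdir: Path, fasta=None) -> dict:
    index = build_index(fasta or outdir / FILES["fasta"], search_cfg)
    spectra = read_mgf(outdir / FILES["mgf"])
    psms = search_spectra(spectra, index, search_cfg)
    accepted = filter_fdr(psms, search_cfg)
    write_psm_table(accepted, outdir / FILES["psms"])
    logger.info("search: %d/%d spectra matched, %d PSMs accepted at %.1f%% FDR",
                len(psms), len(spectra), len(accepted), 100 * search_cfg.fdr)
    return {
        "n_index_forms": len(index),
        "n_psms": len(psms),
        "n_accepted_psms": len(accepted),
    }


def stage_validate(outdir: Path) -> dict:
    psm_df = pd.read_csv(outdir / FILES["psms"], sep="\t")
    table = site_table_from_psm_table(psm_df)
    write_site_table(table, outdir / FILES["sites"])
    logger.info("validate: %d confident carbamylation sites", len(table))
    return {"n_sites": len(table)}


def stage_quantify(outdir: Path, proteins: dict[str, str] | None = None) -> dict:
    from .search import read_fasta

    if proteins is None:
        proteins = read_fasta(outdir / FILES["fasta"])
    psm_df = pd.read_csv(outdir / FILES["psms"], sep="\t")
    forms = [p for p in peptides_from_psm_table(psm_df) if not p.is_decoy]
    xic = read_xic_table(outdir / FILES["xic"])

    site_df = pd.read_csv(outdir / FILES["sites"], sep="\t")
    sites = [
        (row.accession, int(str(row.site)[1:])) for row in site_df.itertuples(index=False)
    ]
    freqs = site_frequency_table(sites, xic, forms)
    write_site_frequency_table(freqs, outdir / FILES["site_freq"])

    quants = lfq_protein_intensity(forms, xic)
    pq = pd.DataFrame(
        [
            {
                "protein_accession": q.protein_accession,
                "sample_id": q.sample_id,
                "lfq_intensity": round(q.lfq_intensity, 4),
                "ibaq_intensity": round(ibaq(q.lfq_intensity, proteins[q.protein_accession]), 4)
                if q.protein_accession in proteins
                else float("nan"),
                "n_unique_peptides": q.n_unique_peptides,
            }
            for q in quants
        ],
        columns=[
            "protein_accession", "sample_id", "lfq_intensity",
            "ibaq_intensity", "n_unique_peptides",
        ],
    )
    pq.to_csv(outdir / FILES["protein_quant"], sep="\t", index=False)

    # presence/absence partition of quantified proteins across the 3 fluids
    cohort = read_cohort_table(outdir / FILES["cohort"])
    group_of = dict(zip(cohort["sample_id"], cohort["group"]))
    by_group: dict[str, set] = {g: set() for g in ("RA-SF", "RA-plasma", "HC-plasma")}
    for q in quants:
        g = group_of.get(q.sample_id)
        if g in by_group:
            by_group[g].add(q.protein_accession)
    regions = presence_absence_sets(by_group)
    pd.DataFrame(
        [{"region": k, "n_proteins": v} for k, v in regions.items()]
    ).to_csv(outdir / FILES["presence"], sep="\t", index=False)
    logger.info("quantify: %d site-frequency rows, %d protein-quant rows",
                len(freqs), len(pq))
    return {
        "n_site_frequency_rows": len(freqs),
        "n_protein_quant_rows": len(pq),
        "presence_absence": regions,
    }


def stage_stats(outdir: Path) -> dict:
    stats_cohort = read_cohort_table(outdir / FILES["cohort"])
    report = correlation_report(stats_cohort)
    report.to_csv(outdir / FILES["correlations"], sep="\t", index=False)

    sf = stats_cohort[stats_cohort["group"] == "RA-SF"]
    rap = stats_cohort[stats_cohort["group"] == "RA-plasma"]
    rows = []
    if len(sf) and len(rap):
        u, p = mann_whitney_u(sf["carb_degree"].dropna(), rap["carb_degree"].dropna())
        rows.append(
            {"test": "mann_whitney_degree_SF_vs_RAplasma", "statistic": u, "p_value": p}
        )
        if "patient" in stats_cohort.columns:
            paired = sf.merge(rap, on="patient", suffixes=("_sf", "_pl"))
            if len(paired) >= 3:
                w, p = wilcoxon_signed_rank(
                    list(zip(paired["mpo_activity_sf"], paired["mpo_activity_pl"]))
                )
                rows.append(
                    {
                        "test": "wilcoxon_mpo_SF_vs_RAplasma_paired",
                        "statistic": w,
                        "p_value": p,
                    }
                )
        fc = median_fold_change(sf["mpo_activity"], rap["mpo_activity"])
        rows.append(
            {
                "test": "median_fold_change_mpo_SF_over_RAplasma",
                "statistic": round(fc, 4),
                "p_value": float("nan"),
            }
        )
    pd.DataFrame(rows, columns=["test", "statistic", "p_value"]).to_csv(
        outdir / FILES["group_stats"], sep="\t", index=False
    )
    n_sig = int(report["significant"].sum())
    logger.info("stats: %d/%d correlations significant", n_sig, len(report))
    return {"n_significant_correlations": n_sig}


def run_pipeline(
    sim_cfg: SimConfig | None = None,
    search_cfg: SearchConfig | None = None,
    seed: int = 0,
    outdir: str | os.PathLike = "carbsite_out",
) -> dict:
    """Execute all stages in order; returns the merged stage summaries."""
    sim_cfg = sim_cfg or SimConfig()
    search_cfg = search_cfg or SearchConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    summary.update(stage_simulate(sim_cfg, seed, out))
    summary.update(stage_search(search_cfg, out))
    summary.update(stage_validate(out))
    summary.update(stage_quantify(out))
    summary.update(stage_stats(out))

    cfg_payload = {"simulate": asdict(sim_cfg), "search": asdict(search_cfg)}
    cfg_text = yaml.safe_dump(json.loads(json.dumps(cfg_payload)), sort_keys=True)
    provenance = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "summary": {k: v for k, v in summary.items() if not isinstance(v, dict)},
    }
    with open(out / FILES["provenance"], "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return summary
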