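"""Ground-truthed synthetic data with the statistical structure the
analysis assumes.

The generator emulates a cohort of synovial-fluid and plasma samples in
which albumin lysines carry known carbamylation fractions, the per-sample
degree of carbamylation is linked to myeloperoxidase (MPO) activity, and
identification is driven by synthetic HCD-style MS2 spectra (b/y ladders,
isocyanic-acid neutral-loss peaks on carbamylated forms, ppm jitter, peak
dropout, random noise peaks) plus an XIC area table for quantification.
Acetylated confounder forms are planted, sometimes with the precursor
reported on the carbon-13 (M+1) isotopologue, so the carbamyl/acetyl
precursor trap genuinely exists in the data.

Default condition choices (documented in the methods note):

* albumin is present in every sample; its 17 catalogued carbamylation
  sites are planted with true fractions drawn uniformly from 0.1-1.5%,
  the regime of the observed per-site frequencies;
* MPO activity is lognormal around group medians of 32.5 (RA synovial
  fluid), 0.9 (RA plasma) and 0.1 ng/mL (healthy-control plasma);
* the synovial-fluid group has 20 samples (the size of the quantification
  cohort) and each plasma group 12 (the size of the functional cohort);
* per-sample carbamylation scales linearly with MPO activity plus noise,
  so the planted Spearman correlation is positive.

All randomness flows from one master seed through named substreams
(truth / run / cohort), so each stage is independently reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .chem import (
    ACETYL,
    CARBAMYL,
    ModifiedPeptide,
    apply_fixed_mods,
    digest,
    peptide_key,
    peptide_neutral_mass,
)
from .fragments import C13_MINUS_C12, fragment_ladder, neutral_loss_variants, precursor_mz
from .search import read_fasta
from .sites import load_site_catalog
from .spectra_io import Ms2Spectrum, XicRecord, write_mgf, write_xic_table

__all__ = [
    "SimConfig",
    "SampleTruth",
    "GroundTruth",
    "albumin_sequence",
    "generate_truth",
    "simulate_run",
    "simulate_cohort",
    "substream",
]

_SUBSTREAMS = {"truth": 0, "run": 1, "cohort": 2}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[name],)))


def albumin_sequence() -> tuple[str, str]:
    """(accession, sequence) of the bundled albumin precursor."""
    from importlib import resources

    path = resources.files("carbsite.data") / "albumin_p02768.fasta"
    proteins = read_fasta(path)
    [(acc, seq)] = proteins.items()
    return acc, seq


@dataclass(frozen=True)
class SimConfig:
    # cohort structure
    group_sizes: dict = field(
        default_factory=lambda: {"RA-SF": 20, "RA-plasma": 12, "HC-plasma": 12}
    )
    mpo_group_medians: dict = field(
        default_factory=lambda: {"RA-SF": 32.5, "RA-plasma": 0.9, "HC-plasma": 0.1}
    )
    mpo_sigma_log: float = 0.4
    neutrophil_per_mpo: float = 1.5e6  # cells/mL per ng/mL of MPO activity
    neutrophil_sigma_log: float = 0.3
    carb_noise_cv: float = 0.15  # noise on the degree<-MPO link

    # planted modification landscape
    fraction_low: float = 0.001
    fraction_high: float = 0.015
    sites: tuple | None = None  # ((accession, position), ...); default: albumin catalog
    acetyl_fraction: float = 0.002
    isotope_trap_prob: float = 0.5  # acetyl precursor reported on M+1

    # background proteome (presence/absence + LFQ structure)
    n_extra_proteins: int = 6
    extra_protein_length: int = 240

    # XIC layer: biological spread is shared by all forms of a peptide in a
    # sample (it cancels in the frequency ratio); analytical integration
    # noise hits every XIC record independently
    base_area: float = 1.0e6
    biological_sigma_log: float = 0.5
    analytical_sigma_log: float = 0.10
    rt_delay_s: float = 120.0  # delayed retention of the carbamylated form
    rt_jitter_s: float = 5.0
    xic_charge: int = 2

    # MS2 layer
    spectra_per_form: int = 3
    precursor_charge: int = 2
    fragment_jitter_ppm: float = 5.0
    precursor_jitter_ppm: float = 1.0
    dropout_prob: float = 0.15
    n_noise_peaks: int = 10
    n_noise_spectra: int = 50
    peak_intensity_low: float = 50.0
    peak_intensity_high: float = 150.0
    nl_intensity_fraction: float = 0.3

    @classmethod
    def noise_free(cls, **overrides) -> "SimConfig":
        """Zero jitter, dropout and noise: the closure-test condition."""
        kwargs = dict(
            fragment_jitter_ppm=0.0,
            precursor_jitter_ppm=0.0,
            dropout_prob=0.0,
            n_noise_peaks=0,
            n_noise_spectra=0,
            isotope_trap_prob=0.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulate config key(s) {sorted(unknown)}")
        if "sites" in d and d["sites"] is not None:
            d = dict(d)
            d["sites"] = tuple((acc, int(pos)) for acc, pos in d["sites"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload.get("simulate", payload))


@dataclass(frozen=True)
class SampleTruth:
    sample_id: str
    group: str
    patient: int
    mpo_activity: float  # ng/mL
    neutrophil_count: float  # cells/mL
    carb_degree: float  # percent
    scale: float  # per-sample multiplier on site fractions


@dataclass(frozen=True)
class GroundTruth:
    seed: int
    proteins: dict  # accession -> sequence
    sites: tuple  # ((accession, position), ...)
    site_fractions: dict  # (accession, position) -> f_s in [0, 1]
    samples: tuple  # SampleTruth, ...
    background_groups: dict  # accession -> tuple of groups it appears in

    def planted_sites(self) -> list[tuple[str, int]]:
        return sorted(s for s in self.sites if self.site_fractions[s] > 0)

    def sample_fraction(self, site: tuple[str, int], sample: SampleTruth) -> float:
        return min(self.site_fractions[site] * sample.scale, 0.5)


_BG_ALPHABET = list("ADEFGHILNQRSTVWYKKRP")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BG_ALPHABET, size=length))


def _background_group_pattern(i: int) -> tuple[str, ...]:
    # cycle through the interesting regions of the three-set partition
    patterns = [
        ("RA-SF",),
        ("RA-SF", "RA-plasma"),
        ("RA-SF", "RA-plasma", "HC-plasma"),
        ("RA-plasma", "HC-plasma"),
        ("HC-plasma",),
        ("RA-SF", "HC-plasma"),
    ]
    return patterns[i % len(patterns)]


def generate_truth(cfg: SimConfig | None = None, seed: int = 0) -> GroundTruth:
    cfg = cfg or SimConfig()
    rng = substream(seed, "truth")

    acc, seq = albumin_sequence()
    proteins = {acc: seq}
    background_groups: dict[str, tuple[str, ...]] = {}
    for i in range(cfg.n_extra_proteins):
        bg_acc = f"SYN{i + 1:02d}"
        proteins[bg_acc] = _random_protein(rng, cfg.extra_protein_length)
        background_groups[bg_acc] = _background_group_pattern(i)

    if cfg.sites is None:
        catalog = load_site_catalog()
        albumin = catalog[catalog["accession"] == acc]
        sites = tuple(
            (acc, int(site[1:])) for site in albumin["site"]
        )
    else:
        sites = tuple(cfg.sites)
    for s_acc, pos in sites:
        if proteins[s_acc][pos - 1] != "K":
            raise ValueError(f"site {s_acc}:{pos} is not a lysine")
    fractions = {
        site: float(rng.uniform(cfg.fraction_low, cfg.fraction_high)) for site in sites
    }
    mean_f_percent = 100.0 * float(np.mean([fractions[s] for s in sites])) if sites else 0.0

    # per-sample MPO, neutrophils, and the degree<-MPO link
    samples: list[SampleTruth] = []
    raw_by_sample: dict[str, float] = {}
    alpha = 0.02  # percent degree per ng/mL; cancels in the normalization below
    for group, size in cfg.group_sizes.items():
        median = cfg.mpo_group_medians[group]
        for i in range(size):
            sid = f"{group}-{i + 1:02d}"
            mpo = median * float(np.exp(rng.normal(0.0, cfg.mpo_sigma_log)))
            neut = cfg.neutrophil_per_mpo * mpo * float(
                np.exp(rng.normal(0.0, cfg.neutrophil_sigma_log))
            )
            raw = alpha * mpo + float(rng.normal(0.0, cfg.carb_noise_cv * alpha * mpo))
            raw_by_sample[sid] = max(raw, 1e-9)
            samples.append(
                SampleTruth(
                    sample_id=sid,
                    group=group,
                    patient=i + 1,
                    mpo_activity=mpo,
                    neutrophil_count=neut,
                    carb_degree=0.0,  # filled after normalization
                    scale=0.0,
                )
            )
    sf_raws = [raw_by_sample[s.sample_id] for s in samples if s.group == "RA-SF"]
    norm = float(np.mean(sf_raws)) if sf_raws else 1.0
    sf_median = cfg.mpo_group_medians.get("RA-SF", 1.0)
    samples = [
        replace(
            s,
            # deterministic group-level attenuation of site fractions:
            # plasma carries far less carbamylation than synovial fluid
            scale=cfg.mpo_group_medians[s.group] / sf_median,
            carb_degree=mean_f_percent * raw_by_sample[s.sample_id] / norm,
        )
        for s in samples
    ]
    return GroundTruth(
        seed=seed,
        proteins=proteins,
        sites=sites,
        site_fractions=fractions,
        samples=tuple(samples),
        background_groups=background_groups,
    )


def _site_peptide(truth: GroundTruth, site: tuple[str, int]) -> ModifiedPeptide:
    """The tryptic peptide used to report a site: prefer the site internal
    (both flanking fragments exist in each series), then shortest."""
    acc, pos = site
    candidates = [p for p in digest(truth.proteins[acc], acc) if p.covers(pos)]
    if not candidates:
        raise ValueError(f"no tryptic peptide covers {acc}:{pos}")

    def rank(p: ModifiedPeptide):
        i = pos - p.start_pos + 1
        internal = 1 < i < len(p.sequence)
        return (not internal, len(p.sequence), p.start_pos)

    return min(candidates, key=rank)


def _background_peptides(truth: GroundTruth, acc: str, n: int = 3) -> list[ModifiedPeptide]:
    peps = [
        p
        for p in digest(truth.proteins[acc], acc, max_missed=0)
        if 7 <= len(p.sequence) <= 20
    ]
    return peps[:n]


@dataclass(frozen=True)
class _Form:
    peptide: ModifiedPeptide
    kind: str  # 'unmod' | 'carb' | 'acetyl' | 'background'
    site: tuple | None
    base_rt: float


def _plan_forms(truth: GroundTruth, cfg: SimConfig, rng: np.random.Generator) -> list[_Form]:
    forms: list[_Form] = []
    for site in truth.sites:
        pep = apply_fixed_mods(_site_peptide(truth, site))  # alkylated cysteines
        i = site[1] - pep.start_pos + 1
        rt = float(rng.uniform(600.0, 3000.0))
        forms.append(_Form(pep, "unmod", site, rt))
        if truth.site_fractions[site] > 0:
            forms.append(_Form(pep.with_mods([*pep.mods, (i, CARBAMYL)]), "carb", site, rt))
        if cfg.acetyl_fraction > 0:
            forms.append(_Form(pep.with_mods([*pep.mods, (i, ACETYL)]), "acetyl", site, rt))
    for acc in truth.background_groups:
        for pep in _background_peptides(truth, acc):
            forms.append(
                _Form(apply_fixed_mods(pep), "background", None, float(rng.uniform(600.0, 3000.0)))
            )
    return forms


def expected_site_frequencies(
    truth: GroundTruth, cfg: SimConfig | None = None
) -> dict[tuple[str, int], float]:
    """The true value (percent) of the site-frequency statistic implied by
    the planted area model, at unit per-sample scale.

    For a site covered only by its own reporting peptide this equals the
    planted fraction ``100*f_s``.  When another planted site's reporting
    peptide also spans the site (adjacent lysines sharing a missed-cleavage
    context), that peptide's forms legitimately enter the denominator and
    the estimand is correspondingly smaller than ``100*f_s`` — a property
    of the statistic, not an estimator error.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(0)  # consumed only for retention times
    forms = _plan_forms(truth, cfg, rng)
    out: dict[tuple[str, int], float] = {}
    for site in truth.sites:
        acc, pos = site
        num = 0.0
        den = 0.0
        for form in forms:
            if form.kind == "background" or form.peptide.protein_accession != acc:
                continue
            if not form.peptide.covers(pos):
                continue
            f = truth.site_fractions[form.site]
            frac = {
                "unmod": max(1.0 - f - cfg.acetyl_fraction, 0.0),
                "carb": f,
                "acetyl": cfg.acetyl_fraction,
            }[form.kind]
            den += frac
            i = pos - form.peptide.start_pos + 1
            mod = form.peptide.mod_at(i)
            if mod is not None and mod.name == CARBAMYL.name:
                num += frac
        if den > 0:
            out[site] = 100.0 * num / den
    return out


def _form_spectrum(
    form: _Form, cfg: SimConfig, rng: np.random.Generator, ordinal: int
) -> Ms2Spectrum:
    ladder = fragment_ladder(form.peptide, max_fragment_charge=1)
    ions = list(ladder)
    nl_parent_mz = {}
    for nl in neutral_loss_variants(ladder, form.peptide):
        ions.append(nl)
        nl_parent_mz[id(nl)] = nl.mz
    peaks: list[tuple[float, float]] = []
    for ion in ions:
        if cfg.dropout_prob > 0 and rng.random() < cfg.dropout_prob:
            continue
        inten = float(rng.uniform(cfg.peak_intensity_low, cfg.peak_intensity_high))
        if ion.neutral_loss is not None:
            inten *= cfg.nl_intensity_fraction
        mz = ion.mz
        if cfg.fragment_jitter_ppm > 0:
            mz *= 1.0 + rng.normal(0.0, cfg.fragment_jitter_ppm) * 1e-6
        peaks.append((float(mz), inten))
    for _ in range(cfg.n_noise_peaks):
        peaks.append((float(rng.uniform(150.0, 1500.0)), float(rng.uniform(1.0, 20.0))))

    z = cfg.precursor_charge
    mass = peptide_neutral_mass(form.peptide)
    mz = precursor_mz(mass, z)
    if form.kind == "acetyl" and cfg.isotope_trap_prob > 0 and rng.random() < cfg.isotope_trap_prob:
        mz += C13_MINUS_C12 / z  # precursor picked on the M+1 isotopologue
    if cfg.precursor_jitter_ppm > 0:
        mz *= 1.0 + rng.normal(0.0, cfg.precursor_jitter_ppm) * 1e-6
    rt = form.base_rt + (cfg.rt_delay_s if form.kind == "carb" else 0.0)
    return Ms2Spectrum(
        spectrum_id=f"syn.{peptide_key(form.peptide)}.{ordinal}",
        precursor_mz=float(mz),
        precursor_charge=z,
        retention_time=rt,
        peaks=peaks,
    )


def _noise_spectrum(cfg: SimConfig, rng: np.random.Generator, ordinal: int) -> Ms2Spectrum:
    peaks = [
        (float(rng.uniform(150.0, 1500.0)), float(rng.uniform(1.0, 50.0)))
        for _ in range(30)
    ]
    return Ms2Spectrum(
        spectrum_id=f"noise.{ordinal}",
        precursor_mz=float(rng.uniform(400.0, 1200.0)),
        precursor_charge=cfg.precursor_charge,
        retention_time=float(rng.uniform(600.0, 3000.0)),
        peaks=peaks,
    )


def simulate_run(
    truth: GroundTruth,
    cfg: SimConfig | None = None,
    seed: int | None = None,
    mgf_path: str | os.PathLike | None = None,
    xic_path: str | os.PathLike | None = None,
) -> tuple[list[Ms2Spectrum], list[XicRecord]]:
    """One identification run (pooled MS2 spectra) plus the per-sample XIC
    area table.

    XIC areas follow base abundance x form fraction x lognormal noise; the
    carbamylated form of a peptide elutes ``rt_delay_s`` after its parent.
    """
    cfg = cfg or SimConfig()
    if seed is None:
        seed = truth.seed
    rng = substream(seed, "run")
    forms = _plan_forms(truth, cfg, rng)

    spectra: list[Ms2Spectrum] = []
    for form in forms:
        for j in range(cfg.spectra_per_form):
            spectra.append(_form_spectrum(form, cfg, rng, j))
    for j in range(cfg.n_noise_spectra):
        spectra.append(_noise_spectrum(cfg, rng, j))

    records: list[XicRecord] = []
    bio_factor: dict[tuple[str, str, str], float] = {}
    for sample in truth.samples:
        for form in forms:
            parent = (sample.sample_id, form.peptide.protein_accession, form.peptide.sequence)
            if parent not in bio_factor:
                bio_factor[parent] = float(np.exp(rng.normal(0.0, cfg.biological_sigma_log)))
            abundance = cfg.base_area * bio_factor[parent]
            if form.kind == "background":
                if sample.group not in truth.background_groups[form.peptide.protein_accession]:
                    continue
                area = abundance * float(np.exp(rng.normal(0.0, cfg.analytical_sigma_log)))
                rt = form.base_rt
            else:
                f = truth.sample_fraction(form.site, sample)
                if form.kind == "unmod":
                    frac = max(1.0 - f - cfg.acetyl_fraction, 0.0)
                    rt = form.base_rt
                elif form.kind == "carb":
                    frac = f
                    rt = form.base_rt + cfg.rt_delay_s
                else:  # acetyl
                    frac = cfg.acetyl_fraction
                    rt = form.base_rt
                if frac <= 0:
                    continue
                area = abundance * frac * float(np.exp(rng.normal(0.0, cfg.analytical_sigma_log)))
            if cfg.rt_jitter_s > 0:
                rt += float(
                    np.clip(
                        rng.normal(0.0, cfg.rt_jitter_s),
                        -cfg.rt_delay_s / 3,
                        cfg.rt_delay_s / 3,
                    )
                )
            records.append(
                XicRecord(
                    sample_id=sample.sample_id,
                    peptide_key=peptide_key(form.peptide),
                    charge=cfg.xic_charge,
                    apex_rt=rt,
                    area=area,
                )
            )

    if mgf_path is not None:
        write_mgf(spectra, mgf_path)
    if xic_path is not None:
        write_xic_table(records, xic_path)
    return spectra, records


def simulate_cohort(truth: GroundTruth, path: str | os.PathLike | None = None):
    """Cohort table with per-sample group, MPO activity, neutrophil count
    and the truth-linked degree of carbamylation."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "patient": s.patient,
                "mpo_activity": round(s.mpo_activity, 4),
                "neutrophil_count": round(s.neutrophil_count, 1),
                "carb_degree": round(s.carb_degree, 6),
            }
            for s in truth.samples
        ]
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
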