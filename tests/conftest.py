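"""Shared fixtures: synthetic runs are generated once per session."""

from __future__ import annotations

import pytest

from carbsite.chem import CARBAMYL, ModifiedPeptide, apply_fixed_mods
from carbsite.search import SearchConfig, build_index, filter_fdr, search_spectra
from carbsite.simulate import SimConfig, generate_truth, simulate_run

MASTER_SEED = 0


@pytest.fixture(scope="session")
def carb_afkawavar() -> ModifiedPeptide:
    """Albumin K236 peptide carbamylated at its internal lysine."""
    return ModifiedPeptide(
        sequence="AFKAWAVAR",
        protein_accession="P02768",
        start_pos=234,
        missed_cleavages=1,
        mods=((3, CARBAMYL),),
    )


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free simulation searched end to end (closure conditions)."""
    cfg = SimConfig.noise_free()
    truth = generate_truth(cfg, MASTER_SEED)
    spectra, xic = simulate_run(truth, cfg, MASTER_SEED)
    index = build_index(truth.proteins)
    search_cfg = SearchConfig()
    accepted = filter_fdr(search_spectra(spectra, index, search_cfg), search_cfg)
    return {
        "cfg": cfg,
        "truth": truth,
        "spectra": spectra,
        "xic": xic,
        "index": index,
        "accepted": accepted,
    }


@pytest.fixture(scope="session")
def default_noise_run():
    """Default-noise simulation searched end to end (recovery conditions)."""
    cfg = SimConfig()
    truth = generate_truth(cfg, MASTER_SEED)
    spectra, xic = simulate_run(truth, cfg, MASTER_SEED)
    index = build_index(truth.proteins)
    search_cfg = SearchConfig()
    accepted = filter_fdr(search_spectra(spectra, index, search_cfg), search_cfg)
    return {
        "cfg": cfg,
        "truth": truth,
        "spectra": spectra,
        "xic": xic,
        "index": index,
        "accepted": accepted,
    }
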