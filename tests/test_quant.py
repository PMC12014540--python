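"""Site frequencies, protein LFQ/iBAQ, replicate aggregation, the
valid-values filter, and downshifted-normal imputation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from carbsite.chem import CARBAMYL, OXIDATION, ModifiedPeptide
from carbsite.quant import (
    SiteFrequency,
    carbamylation_degree,
    filter_valid_values,
    ibaq,
    impute_missing,
    lfq_protein_intensity,
    replicate_median,
    site_frequency,
    site_frequency_table,
    theoretical_peptide_count,
)
from carbsite.spectra_io import XicRecord


def rec(sample, key, area, charge=2, rt=100.0):
    return XicRecord(sample_id=sample, peptide_key=key, charge=charge,
                     apex_rt=rt, area=area)


class TestSiteFrequency:
    forms = [
        ModifiedPeptide(sequence="AFKAWAVAR", protein_accession="P02768",
                        start_pos=234, missed_cleavages=1),
        ModifiedPeptide(sequence="AFKAWAVAR", protein_accession="P02768",
                        start_pos=234, missed_cleavages=1, mods=((3, CARBAMYL),)),
    ]

    def test_percent_arithmetic(self):
        records = [
            rec("S1", "AFKAWAVAR", 9861.0),
            rec("S1", "AFKAWAVAR|3:carbamyl", 139.0),
        ]
        sf = site_frequency(("P02768", 236), "S1", records, self.forms)
        assert sf.frequency_percent == pytest.approx(100 * 139 / 10000)
        assert sf.total_intensity == pytest.approx(10000.0)

    def test_zero_carbamylated_area_gives_zero_percent(self):
        records = [rec("S1", "AFKAWAVAR", 500.0)]
        sf = site_frequency(("P02768", 236), "S1", records, self.forms)
        assert sf.frequency_percent == 0.0

    def test_fifty_fifty(self):
        records = [
            rec("S1", "AFKAWAVAR", 50.0),
            rec("S1", "AFKAWAVAR|3:carbamyl", 50.0),
        ]
        sf = site_frequency(("P02768", 236), "S1", records, self.forms)
        assert sf.frequency_percent == 50.0

    def test_denominator_includes_other_modified_forms(self):
        from carbsite.chem import ACETYL

        forms = self.forms + [
            ModifiedPeptide(sequence="AFKAWAVAR", protein_accession="P02768",
                            start_pos=234, missed_cleavages=1,
                            mods=((3, ACETYL),))
        ]
        records = [
            rec("S1", "AFKAWAVAR", 80.0),
            rec("S1", "AFKAWAVAR|3:carbamyl", 10.0),
            rec("S1", "AFKAWAVAR|3:acetyl", 10.0),
        ]
        sf = site_frequency(("P02768", 236), "S1", records, forms)
        assert sf.frequency_percent == pytest.approx(10.0)

    def test_unidentified_forms_do_not_count(self):
        # the oxidized record has no identified form backing it
        records = [
            rec("S1", "AFKAWAVAR", 90.0),
            rec("S1", "AFKAWAVAR|3:carbamyl", 10.0),
            rec("S1", "AFKAWAVAR|5:oxidation", 900.0),
        ]
        sf = site_frequency(("P02768", 236), "S1", records, self.forms)
        assert sf.frequency_percent == pytest.approx(10.0)

    def test_missing_signal_skips_site_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = site_frequency(("P02768", 236), "S9", [], self.forms)
        assert out is None
        assert "S9" in caplog.text

    def test_pooling_across_charges(self):
        records = [
            rec("S1", "AFKAWAVAR", 40.0, charge=2),
            rec("S1", "AFKAWAVAR", 40.0, charge=3),
            rec("S1", "AFKAWAVAR|3:carbamyl", 10.0, charge=2),
            rec("S1", "AFKAWAVAR|3:carbamyl", 10.0, charge=3),
        ]
        sf = site_frequency(("P02768", 236), "S1", records, self.forms)
        assert sf.frequency_percent == pytest.approx(20.0)

    def test_table_bounds_invariant(self, default_noise_run):
        from carbsite.chem import peptide_key

        run = default_noise_run
        forms = {}
        for p in run["accepted"]:
            forms.setdefault(peptide_key(p.peptide), p.peptide)
        freqs = site_frequency_table(
            run["truth"].planted_sites(), run["xic"], list(forms.values())
        )
        assert freqs
        for f in freqs:
            assert 0.0 <= f.frequency_percent <= 100.0
            assert f.carb_intensity <= f.total_intensity


class TestCarbamylationDegree:
    def _freqs(self):
        return [
            SiteFrequency("S1", "P02768", 236, 1.0, 100.0, 1.0),
            SiteFrequency("S1", "P02768", 249, 3.0, 100.0, 3.0),
            SiteFrequency("S2", "P02768", 236, 2.0, 100.0, 2.0),
        ]

    def test_mean_aggregation(self):
        assert carbamylation_degree(self._freqs()) == {"S1": 2.0, "S2": 2.0}

    def test_median_aggregation(self):
        out = carbamylation_degree(self._freqs(), method="median")
        assert out["S1"] == 2.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            carbamylation_degree(self._freqs(), method="mode")


class TestLfqIbaq:
    p1a = ModifiedPeptide(sequence="TAYIAK", protein_accession="A", start_pos=1)
    p1b = ModifiedPeptide(sequence="WWSAYIAK", protein_accession="A", start_pos=7)
    p2 = ModifiedPeptide(sequence="FFDEVNK", protein_accession="B", start_pos=1)

    def test_sum_of_unique_peptides(self):
        records = [rec("S1", "TAYIAK", 10.0), rec("S1", "WWSAYIAK", 30.0)]
        [q] = lfq_protein_intensity([self.p1a, self.p1b], records)
        assert q.lfq_intensity == 40.0 and q.n_unique_peptides == 2

    def test_protein_with_one_unique_peptide_dropped(self):
        records = [rec("S1", "TAYIAK", 10.0), rec("S1", "WWSAYIAK", 30.0),
                   rec("S1", "FFDEVNK", 5.0)]
        quants = lfq_protein_intensity([self.p1a, self.p1b, self.p2], records)
        assert [q.protein_accession for q in quants] == ["A"]

    def test_shared_peptide_counts_for_neither(self):
        shared_a = ModifiedPeptide(sequence="TAYIAK", protein_accession="A")
        shared_b = ModifiedPeptide(sequence="TAYIAK", protein_accession="B")
        records = [rec("S1", "TAYIAK", 10.0)]
        assert lfq_protein_intensity([shared_a, shared_b], records,
                                     min_unique_peptides=1) == []

    def test_permutation_invariance(self):
        records = [rec("S1", "TAYIAK", 10.0), rec("S1", "WWSAYIAK", 30.0)]
        a = lfq_protein_intensity([self.p1a, self.p1b], records)
        b = lfq_protein_intensity([self.p1b, self.p1a], list(reversed(records)))
        assert a == b

    def test_ibaq_divisor_enumeration(self):
        # only TAYIAK qualifies at zero missed cleavages and length 6-30
        assert theoretical_peptide_count("MKTAYIAKQR") == 1
        assert ibaq(42.0, "MKTAYIAKQR") == 42.0

    def test_ibaq_linearity(self):
        seq = "MKWVTFISLLFKRPSSAYSRGVFRKAAAAAAK"
        assert ibaq(20.0, seq) == pytest.approx(2 * ibaq(10.0, seq))

    def test_ibaq_rejects_unobservable_protein(self):
        with pytest.raises(ValueError):
            ibaq(10.0, "MKRK")


class TestMatrixOps:
    def test_replicate_median(self):
        m = pd.DataFrame(
            {"r1": [1.0, 5.0], "r2": [2.0, np.nan], "r3": [9.0, 7.0]},
            index=["prot1", "prot2"],
        )
        out = replicate_median(m, {"r1": "cond", "r2": "cond", "r3": "cond"})
        assert out.loc["prot1", "cond"] == 2.0
        assert out.loc["prot2", "cond"] == 6.0  # median of the two observed

    def test_replicate_median_identity_for_single_replicate(self):
        m = pd.DataFrame({"r1": [1.0, 2.0]}, index=["a", "b"])
        out = replicate_median(m, {"r1": "c"})
        assert list(out["c"]) == [1.0, 2.0]

    def test_filter_valid_values(self):
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        m = pd.DataFrame(
            {
                "a1": [1.0, np.nan, 1.0, np.nan],
                "a2": [2.0, np.nan, np.nan, np.nan],
                "b1": [np.nan, np.nan, 1.0, np.nan],
                "b2": [np.nan, np.nan, np.nan, np.nan],
            },
            index=["two_in_A", "all_missing", "one_per_group", "empty"],
        )
        out = filter_valid_values(m, groups, min_valid=2)
        assert list(out.index) == ["two_in_A"]

    def test_impute_deterministic_and_unchanged_when_complete(self):
        rng_m = pd.DataFrame({"s": [20.0, 21.0, 22.0, np.nan]})
        a = impute_missing(rng_m, seed=42)
        b = impute_missing(rng_m, seed=42)
        assert a.equals(b)
        complete = pd.DataFrame({"s": [20.0, 21.0, 22.0]})
        assert impute_missing(complete, seed=0).equals(complete)

    def test_impute_rejects_underdetermined_column(self):
        m = pd.DataFrame({"s": [20.0, np.nan, np.nan]})
        with pytest.raises(ValueError, match="'s'"):
            impute_missing(m)

    def test_imputed_moments_match_downshifted_normal(self):
        """Over 1e5 draws the imputed mean is within 0.02 s of m - 1.8 s."""
        observed = np.array([20.0, 21.0, 22.0, 23.0, 24.0])
        m, s = observed.mean(), observed.std(ddof=1)
        col = np.concatenate([observed, np.full(100_000, np.nan)])
        out = impute_missing(pd.DataFrame({"x": col}), seed=7)
        imputed = out["x"].to_numpy()[5:]
        assert imputed.mean() == pytest.approx(m - 1.8 * s, abs=0.02 * s)
        assert imputed.std() == pytest.approx(0.3 * s, rel=0.05)
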