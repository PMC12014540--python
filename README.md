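# carbsite

Detection and quantification of **lysine carbamylation** from tandem-MS
peak lists, with the downstream statistics that link a sample's degree of
carbamylation to myeloperoxidase (MPO) activity.

Carbamylation is the non-enzymatic addition of a carbamoyl group (HNCO,
+43.00581 Da monoisotopic) to a lysine ε-amine, forming homocitrulline. It
is irreversible, enriched at sites of neutrophilic inflammation — MPO
oxidizes thiocyanate to cyanate, which carbamylates nearby proteins — and
the resulting neo-epitopes are targets of anti-carbamylated-protein
autoantibodies in rheumatoid arthritis (RA). Calling the modification
confidently is delicate because acetylation (+42.01056 Da) differs by only
0.995 Da, and the ¹³C isotopologue of an acetylated precursor sits a mere
0.00811 Da from the carbamylated monoisotope.

`carbsite` is aimed at analysts who want a transparent, fully testable
reimplementation of this workflow at desk scale: every stage runs on plain
text interchange files (MGF peak lists, TSV tables), and a synthetic-data
generator with known ground truth makes each claim checkable.

## What it implements

* **Mass bookkeeping & digestion** (`carbsite.chem`) — monoisotopic residue
  masses, the search modification set (fixed carbamidomethyl-C; variable
  carbamyl-K, acetyl-K/protein-N-term, oxidation-M, deamidation-N/Q),
  tryptic digestion with ≤2 missed cleavages and minimum length 6.
* **Fragment theory** (`carbsite.fragments`) — b/y ladders, isocyanic-acid
  neutral-loss variants of carbamyl-containing ions, coarse averagine-style
  isotope envelopes.
* **Search** (`carbsite.search`) — 5 ppm precursor / 20 ppm fragment
  tolerance matching with precursor isotope correction, a documented
  deterministic score (matched-ion count + explained-intensity fraction),
  reversed-sequence target–decoy filtering at 1% peptide FDR, and the
  carbamyl vs ¹³C-acetyl precursor verdict.
* **Site confidence** (`carbsite.sites`) — a site is confident only when a
  b- or y-series is continuous across the modified lysine (the bracketing
  fragments are both matched); the neutral loss and the isotope verdict are
  reported as corroborating evidence.
* **Quantification** (`carbsite.quant`) — per-site carbamylation frequency:
  summed XIC areas of carbamylated forms over all identified forms of the
  parent peptide, independent of modification state; protein LFQ (sum of
  unique-peptide areas, ≥2 unique peptides), iBAQ, replicate medians, the
  valid-values filter, and downshifted-normal imputation
  (width = 0.3, shift = 1.8).
* **Statistics** (`carbsite.stats`) — Spearman's rho, Mann-Whitney U and
  Wilcoxon matched-pairs signed-rank implemented from their rank
  definitions (exact enumeration for small samples), plus median fold
  change.
* **Synthetic data** (`carbsite.simulate`) — a ground-truthed generator of
  MS2 spectra, XIC tables and a patient cohort in which albumin lysines
  carry known carbamylation fractions and the degree of carbamylation is
  linked to MPO activity.

A reference catalog of 52 carbamylation sites on 32 proteins identified in
RA synovial fluid, and the 609-residue albumin precursor sequence used for
site numbering, ship as package data.

## Worked example

Run the whole pipeline — simulate, search, validate, quantify, stats — on
synthetic data:

```sh
carbsite all --seed 7 --outdir out
```

which prints the per-stage record counts:

```
n_spectra: 257
n_xic_records: 2736
n_index_forms: 45793
n_psms: 207
n_accepted_psms: 207
n_sites: 18
n_site_frequency_rows: 792
n_protein_quant_rows: 208
presence_absence: {'RA-SF': 1, 'RA-plasma': 0, 'RA-SF&RA-plasma': 1, 'HC-plasma': 1, 'RA-SF&HC-plasma': 1, 'RA-plasma&HC-plasma': 1, 'RA-SF&RA-plasma&HC-plasma': 2}
n_significant_correlations: 3
```

257 synthetic spectra were searched against 45,793 candidate peptide forms
(targets plus reversed decoys); all 207 true-peptide spectra were accepted
at 1% FDR and the 50 noise spectra matched nothing. The 17 planted albumin
sites were all recovered (plus one noise-induced extra at this seed — the
default simulation includes fragment jitter, peak dropout and noise peaks).
`out/site_table.tsv` begins:

```
accession  site  annotated_sequence  continuity_ok  neutral_loss_seen  isotope_distinguishable  n_psms
P02768     K205  AACLLPkLDELR        True           True               True                     3
P02768     K214  DEGkASSAK           True           True               True                     3
P02768     K229  CASLQkFGER          True           True               True                     3
P02768     K236  AFkAWAVAR           True           True               True                     3
```

(the lowercase `k` marks the carbamylated lysine). The site-frequency table
gives per-sample frequencies in percent; at this seed the three highest
mean frequencies across synovial-fluid samples are K426 1.54%, K236 1.38%
and K549 1.28% — the planted fractions were drawn from 0.1–1.5%. The
correlation panel (`out/correlation_report.tsv`):

```
pair                        group  n   rho     p_value    significant
carb_degree_vs_mpo          RA-SF  20  0.8421  3.22e-06   True
mpo_vs_neutrophils          RA-SF  20  0.8090  1.57e-05   True
carb_degree_vs_neutrophils  RA-SF  20  0.6797  9.78e-04   True
```

recovers the planted positive association between the degree of
carbamylation and MPO activity, and `out/group_stats.tsv` reports a
32.5-fold higher median MPO activity in synovial fluid than in plasma at
this seed (Mann-Whitney p = 3.3e-06; paired Wilcoxon on the matched
patients p = 4.9e-04).

Each stage can also be run standalone (`carbsite simulate|search|validate|
quantify|stats`) against the same output directory, and
`carbsite catalog-counts` summarizes the packaged site catalog.

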