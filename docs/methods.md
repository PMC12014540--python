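# Methods

This note documents the models, rules and parameter choices behind
`carbsite`, and what the synthetic benchmark does and does not show.

## Chemistry and digestion

All masses are monoisotopic; average masses are unsupported because the
workflow targets high-resolution Orbitrap-class data. Residue masses come
from the standard amino-acid table; modification deltas are fixed
constants of the chemistry:

| modification      | delta (Da)  | targets                  | role     |
|-------------------|------------:|--------------------------|----------|
| carbamidomethyl   | +57.021464  | C                        | fixed    |
| carbamyl          | +43.005814  | K                        | variable |
| acetyl            | +42.010565  | K, protein N-terminus    | variable |
| oxidation         | +15.994915  | M                        | variable |
| deamidation       |  +0.984016  | N, Q                     | variable |

Digestion is tryptic: cleavage C-terminal to K/R, by default suppressed
before proline (a `cleave_before_proline` switch gives the Trypsin/P
variant), at most 2 missed cleavages, minimum peptide length 6. Up to 5
variable modifications per peptide, at most one per position; the fixed
carbamidomethyl occupies every cysteine and does not count toward the cap.
Protein and peptide coordinates are 1-based and inclusive; albumin sites
are numbered on the 609-residue preproprotein, so the K of AFKAWAVAR is
K236.

## Search

Candidates are retrieved from a mass-sorted index of all modified peptide
forms within 5 ppm of the observed neutral mass; because precursors are
sometimes picked on an isotopologue, the query is repeated at
M − k·1.0033548 Da for k ∈ {0, 1, 2} and the best-scoring interpretation
wins. Fragment matching pairs every theoretical b/y ion (charges 1–2,
plus HNCO-loss variants of carbamyl-containing ions) with the nearest
observed peak within 20 ppm, one peak per theoretical ion.

The score is deliberately simple and fully specified: *matched-ion count
plus the fraction of total peak intensity explained* (each peak counted
once). Ties break toward fewer modifications, then the lexicographic
peptide key, so results are deterministic. A published search engine's
proprietary scorer is intentionally not imitated; for synthetic
validation the simple score separates true from random matches by a wide
margin, which is what the FDR benchmark measures.

Decoys are full reversed proteins by default (decoy peptides identical to
a target sequence are excluded). A `reverse-peptide` scheme — each target
peptide reversed keeping its C-terminal residue — is available and
guarantees exactly one decoy per target form; with full protein reversal
the decoy peptide population is only approximately the same size, because
the length filter acts on shifted cleavage products. FDR filtering sorts
by score and keeps the largest prefix in which #decoys/#targets ≤ 1%,
then discards decoys.

### Carbamyl vs ¹³C-acetyl

Carbamyl exceeds acetyl by 0.995249 Da, which is 0.008106 Da short of one
¹³C–¹²C spacing. The M+1 isotopologue of an acetylated peptide therefore
falls within a 5 ppm precursor window of the carbamylated form whenever
the neutral mass exceeds 0.008106/5×10⁻⁶ ≈ 1621 Da. Carbamyl PSMs above
that boundary are flagged `ambiguous`, below it `distinguishable`.

The flag is an annotation, not a veto. The site table requires fragment
continuity across the modified lysine (below), and matched flanking
fragments pin the residue's mass increment to the fragment tolerance —
20 ppm of a fragment is ~0.01–0.03 Da, two orders of magnitude tighter
than the 0.995 Da carbamyl/acetyl separation — so a continuity-confirmed
site cannot be an acetyl misassignment even when the precursor alone is
ambiguous. Stricter policies are available: `require_distinguishable=True`
gates site rows on the precursor verdict, and
`SearchConfig(reject_ambiguous=True)` hard-rejects flagged PSMs before
FDR filtering.

## Site confidence

"Ion series continuous on both sides of the carbamylated lysine" is
operationalized as the minimal bracketing rule: for a site at peptide
position *i* of an *n*-mer, a single series at any observed charge must
contain both flanking fragments — b(i−1) and b(i), or y(n−i) and
y(n−i+1). A terminal residue has only one flanking fragment in the
informative series (the precursor mass pins the other side), so *i* = 1
requires y(n−1) and *i* = n requires b(n−1). Neutral-loss ions do not
count toward continuity; the isocyanic-acid loss is reported as
corroborating evidence (`neutral_loss_seen`) but is not required, since
its presence is characteristic rather than definitional. On noise-free
synthetic data this rule has sensitivity and specificity 1 by
construction, which the closure test verifies.

## Quantification

The per-site carbamylation frequency in a sample is

  100 × Σ areas of identified forms carbamylated at the site
      ÷ Σ areas of *all* identified forms of peptides covering the site,

pooled over charge states and missed-cleavage contexts. The denominator
deliberately includes every modification state (unmodified, carbamylated,
acetylated, oxidized, …) — "independent of modifications" is read in the
inclusive sense. Only identified forms (accepted PSMs) contribute, so an
unidentified XIC trace never enters the statistic. Per-sample degree of
carbamylation is the mean of the sample's albumin site frequencies
(median available by option).

Protein LFQ sums the areas of peptides unique to one protein and drops
proteins with fewer than 2 unique peptide sequences. iBAQ divides LFQ by
the count of fully tryptic, 0-missed-cleavage peptides of length 6–30
(both bounds configurable). Replicate aggregation takes the median per
condition on the log2 scale, ignoring missing values. The valid-values
filter keeps rows with ≥2 observed values in at least one group.
Imputation draws missing log2 intensities per column from
Normal(m − 1.8·s, (0.3·s)²), where m and s are the column's observed
moments — the convention for proteins near the detection limit; columns
with fewer than 3 observed values are rejected rather than imputed from
unstable moments.

## Statistics

Spearman's rho is the Pearson correlation of mid-ranks (tie-corrected),
with a two-sided p from t = rho·√((n−2)/(1−rho²)). Mann-Whitney U is
computed from rank sums with mid-ranks; p is exact by enumeration of all
group assignments when the pooled size is ≤ 12, otherwise a normal
approximation with tie-corrected variance and 0.5 continuity correction.
Wilcoxon's matched-pairs signed-rank test drops zero differences,
mid-ranks |d|, and uses exact sign enumeration for ≤ 12 non-zero pairs.
Exact two-sided p-values are defined as the null probability of a
statistic at least as far from its null mean as observed. Only
distribution functions (normal, t) are delegated to scipy; ranks,
statistics and enumerations are computed here and cross-checked against
independent enumeration oracles in the tests. The 0.05 significance
threshold is a reporting annotation, never a data filter.

## Synthetic-data generator

The generator emulates the study conditions at desk scale:

* **Proteome.** Albumin (P02768, bundled) in every sample plus 6 random
  240-residue background proteins assigned to fixed group patterns so the
  three-fluid presence/absence partition has populated regions.
* **Sites.** By default the 17 catalogued albumin lysines, with true
  fractions drawn uniformly from 0.1–1.5% — the regime of the observed
  per-site frequencies (highest ≈ 1.4%). For each site the reporting
  peptide is the shortest tryptic peptide holding the lysine at an
  internal position (carbamylation blocks tryptic cleavage, so real
  carbamyl peptides carry the site as a missed cleavage).
* **Cohort.** 20 synovial-fluid samples (the size of the quantification
  cohort) and 12 per plasma group (the size of the functional cohort).
  MPO activity is lognormal (σ_log = 0.4) around group medians of 32.5,
  0.9 and 0.1 ng/mL; neutrophil counts scale with MPO (1.5×10⁶ cells/mL
  per ng/mL, σ_log = 0.3); the degree of carbamylation is α·MPO + ε with
  15% relative noise, normalized so the synovial-fluid mean matches the
  planted mean site frequency. Site fractions are attenuated in plasma
  groups by the deterministic ratio of group median MPO to synovial-fluid
  median MPO.
* **XIC layer.** Area = base abundance × form fraction × noise. Noise has
  two parts: a biological factor shared by all forms of a peptide within
  a sample (σ_log = 0.5 — patient-to-patient spread, which cancels in the
  frequency ratio) and independent analytical integration noise per
  record (σ_log = 0.10, ~10% CV, typical label-free reproducibility).
  Carbamylated forms elute 120 s after their parent (the characteristic
  retention delay), with jitter clipped well below the delay so the
  ordering is invariant.
* **MS2 layer.** One pooled identification run: 3 spectra per form from
  charge-1 b/y ladders, NL peaks at 30% relative intensity for carbamyl
  forms, Gaussian fragment jitter (σ = 5 ppm), 15% peak dropout, 10
  uniform noise peaks per spectrum, 1 ppm precursor jitter, plus 50
  pure-noise spectra. Acetylated confounder forms (0.2% of parent
  abundance) are emitted with their precursor reported on the M+1
  isotopologue half the time, so the carbamyl/¹³C-acetyl trap genuinely
  exists in the data.

All randomness derives from one master seed through named substreams
(truth / run / cohort), so each stage is independently reproducible.

**The planted estimand.** Because two catalogued albumin sites share a
missed-cleavage context (the K249 reporting peptide FPKAEFAEVSK also
spans K257), the forms of one site legitimately enter the other's
denominator, and the true value of the frequency statistic at K257 is
about half its planted fraction. `expected_site_frequencies()` computes
the exact estimand implied by the planted area model; recovery is
asserted against it. For every non-overlapped site it equals 100·f_s.

**What passing tests show — and don't.** The benchmark validates the
machinery: tolerance search, FDR bookkeeping, the continuity rule,
ratio-based quantification and the statistics, under a generative model
whose assumptions are known. It does not model chimeric spectra,
co-eluting isomers, profile peak shapes, charge-state-dependent
fragmentation efficiency, missing-value structure of real LFQ data, or
retention-time drift — so passing here does not certify performance on
raw instrument data.

## Numerical and design choices

* Proton 1.00727646688 Da, water 18.01056469 Da, ¹³C−¹²C 1.0033548 Da;
  isotope envelopes use an averagine carbon estimate of 0.0444 carbons/Da
  with P(¹³C) = 0.0107, normalized to the strongest peak.
* Problem sizes in the test suite (17 sites, ~250–650 spectra, 44-sample
  cohorts, 2000-replicate null calibrations) were chosen to make every
  stage's behavior measurable in seconds while keeping each statistical
  assertion comfortably powered.
* Empty inputs are contract violations, not silent no-ops: unknown
  residues, malformed MGF blocks, negative areas, degenerate rank inputs
  and under-determined imputation columns all raise with the offending
  item named.
* FDR threshold selection takes the most permissive cutoff satisfying the
  decoy/target bound, matching the exhaustive-cutoff definition used as
  the test oracle.

## Known limitations

* Only b/y series; no a/c/x/z ions, internal fragments or immonium ions.
* Site localization is rule-based (continuity); no probabilistic
  localization score, no multi-site isomer deconvolution.
* MGF and TSV are the only interchange formats; an mzML adapter is a
  documented extension point, not implemented.
* The generator's spectra are ladder-based idealizations; intensity
  models are uniform, not learned.
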