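# Methods

This note documents the models and procedures implemented in `antiangio`,
the defaults they ship with, the numerical conventions, and what the
synthetic benchmarks do and do not demonstrate.

## Problem setting

Binary classification of peptides (20-letter alphabet) into anti-angiogenic
(AAP) vs non-AAP.  Curated benchmarks in this area are small (a few hundred
peptides), balanced by construction, and come in two flavours: full-length
sequences (roughly 10–50 residues) and N-terminus sets truncated to the
first 15 residues.  The package's protocol mirrors that setting: an 80/20
stratified development/test split, feature engineering and model selection
on the development set only, and a single final evaluation on the held-out
20%.

## Descriptor registry

The default registry holds 58 descriptor types totalling exactly 4335 values
per peptide.  Twenty-one types are classical families with fixed sizes: AAC
(20), DPC (400), GAAC (5), GDPC (25), CKSAAP with gaps 0–4 (2000), CKSAAGP
with gaps 0–5 over the five physicochemical groups (150), APAAC with λ = 5
and weight w = 0.05 (30), SEP (1), SER (20), CTDC/CTDT/CTDD over 13
properties (39/39/195), CTriad (343), DDE (400), DDR (20), peptide length
(1), and five multidimensional scale autocorrelations — Z3 (3 dims × lags
1–10 = 30), Z5 (5 × 15 = 75), Ez (3 × 10 = 30), Cougar (6 × 5 = 30), ABHPRK
(7 × 15 = 105).  The remaining 37 types are single-scale autocorrelation
descriptors over exact per-residue tables: five Biopython `ProtParamData`
scales (Kyte–Doolittle, Hopp–Woods, Janin, Emini, flexibility), two derived
from the standard genetic code (codon count, mean codon GC), and thirty
RDKit-computed small-molecule descriptors of the free amino acids (logP,
TPSA, molar refractivity, graph indices, atom counts, QED, …; values frozen
into `scales.py` and cross-checked against RDKit by a test).  Each uses lags
1–10 (10 values); the seven classic hydropathy/surface scales additionally
expose the raw sequence-global mean (11 values): 1928 + 2000 + 30 + 7·11 +
30·10 = 4335.

Conventions worth knowing:

* **Autocorrelation.** Scale tables are standardized to mean 0 / population
  SD 1 over the 20 residues; the feature at (dimension d, lag l) is the mean
  product of standardized values at sequence separation l.  The optional
  global mean uses the *raw* table (the classic GRAVY-style average).
* **Short sequences.** Any gap/lag/λ term a sequence cannot support is 0
  with a single logged warning, never a mid-pipeline error — this is what
  lets 15-mer N-terminus data flow through the same 4335-value registry.
  (APAAC still requires L > λ and DDE requires L ≥ 2, which every preset
  satisfies.)
* **CTD.** Seven canonical property groupings (hydrophobicity, van der
  Waals volume, polarity, polarizability, charge, secondary structure,
  solvent accessibility) are entered verbatim; the remaining six properties
  are tertile splits (low 7 / mid 6 / high 7 residues) of exact scales
  shipped with the package.  CTDD reports relative positions (in [0, 1]) of
  the first/25%/50%/75%/last group occurrence; absent groups give 0.
* **Synthetic stand-in tables.**  The Ez, Cougar and ABHPRK tables are
  package-defined composites (documented in `scales.py`) assembled from the
  exact tables above; they fill the corresponding descriptor slots with the
  pinned sizes but are not the originally published parameter sets.
* **DDR** is pinned as the mean gap between consecutive occurrences of a
  residue divided by L (0 for absent/singleton residues).
* **DDE** uses the standard-code codon counts (61 sense codons):
  Tm(ab) = (C_a/61)(C_b/61), Tv = Tm(1−Tm)/(L−1).
* Feature names are `<TYPE>.<feature>`; they are the join key between
  encoding, selection and reporting, and the registry hash in every output
  ties artifacts to the exact layout.

## Normalization

Quartile scaling y = (x − median)/(Q3 − Q1) with linear-interpolation
quantiles, implemented directly over numpy (scikit-learn's RobustScaler is
kept as an independent oracle in the tests).  Zero-IQR features fall back to
divisor 1 (centering only) so matrix widths never change.  The scaler is
re-fit inside every CV training fold and, for the final model, on the full
development set — held-out rows never influence the quartiles.  Whether one
re-fits per fold or once per development set is a genuine design choice; the
per-fold variant was chosen because it is leakage-safe, at the cost of
slightly noisier fold metrics.

## Feature ranking and subset search

Ranking appends a permuted shadow copy of every feature, fits a
random-forest importance model (default 300 trees, depth 7), and scores a
real feature a hit when it beats the best shadow.  After n_iter iterations
(default 30, minimum 10) a two-sided binomial test at α = 0.05 labels
features confirmed/tentative/rejected; the final order is confirmed →
tentative → rejected, by mean importance within class, ties broken by name.
The ranking covers *all* features so any prefix length is defined.

The subset search evaluates prefix sizes N = 50…200 step 10 (16 candidates)
by stratified 5-fold CV, repeated (default 3 repeats with distinct fold
seeds, MCC from pooled fold confusions averaged over repeats), for each of
the six model families at library-default hyperparameters.  Using six
families of different inductive bias keeps the chosen subset from being
tailored to one model.  Best_MCC_N is the per-N max over families; the
selected subset is the smallest N achieving the overall maximum.

## Models and tuning

Families: RBF-kernel SVM, LDA (optionally shrinkage via the lsqr solver),
random forest, extremely randomized trees, LightGBM, and scikit-learn's
histogram gradient boosting — two gradient-boosting implementations with
different tree-growth strategies.  All expose class probabilities; hard
labels are probability ≥ 0.5 (the datasets are balanced by construction, so
no class weighting or threshold shifting is applied).

Hyperparameters are tuned with a tree-structured Parzen estimator
implemented in `antiangio.tpe`: 10 uniform startup trials, then candidates
drawn from a Parzen density over the top-25% trials and scored by the
good/bad density ratio; parameters are treated independently, log-scaled
where declared, integers rounded, categoricals by smoothed frequency ratio.
The objective is mean stratified 10-fold CV MCC; the median rule prunes a
trial after 3 folds when its partial mean falls below the median of earlier
trials' partial means.  Search spaces are declared data
(`modeling.SEARCH_SPACES`), not code constants.  Everything is reproducible
from one seed.

The independent-test protocol retrains the tuned model (and its scaler) on
the complete development matrix before the single held-out evaluation — the
final model sees ~10% more data than any CV fold did.

## Evaluation

Threshold metrics come from confusion counts; in CV they are pooled over
folds (and repeats), while AUC is averaged per fold — pooling probabilities
across folds would mix incomparable score scales.  Zero-denominator metrics
return 0 with an explicit flag rather than NaN.  AUC is the Mann–Whitney
rank statistic with midrank ties.  The calibration analysis bins predicted
probabilities (default width 0.1) and reports the fraction of true positives
per bin; the property analysis stratifies accuracy by the hydrophobic
(VILMFWC), hydrophilic (RNDEQHKST) and charged (EDRKH) residue ratios with
the same default bin width.  Both widths are conventions, recorded in the
outputs and configurable.

## Synthetic data: what it shows and what it does not

The peptide generator draws residues i.i.d. from class-specific
multinomials: a uniform base composition re-weighted by factor 5 on C,P,R,S,W
for positives and on A,E,I,L,V for negatives (both renormalized), lengths
uniform on 10–50 (`fulllength`) or fixed at 15 (`nterm15`), 100 peptides per
class.  These defaults emulate the *structure* of curated AAP benchmarks —
class-biased residue usage in two length regimes — and give every pipeline
stage a known ground truth: enrichment is recovered by the propensity
analysis, planted informative columns by the ranking, and the end-to-end
pipeline reaches CV MCC ≥ 0.9.  They do **not** model motifs, residue
ordering, secondary structure, shared evolutionary history, or redundancy;
i.i.d. composition signal is much easier than real AAP discrimination, so
near-perfect synthetic MCCs say the machinery is correct, not that real
benchmarks would score as high.  On the real curated sets, published
independent-test MCCs for workflows of this family are around 0.67
(full-length) and 0.76 (N-terminus); reproducing those numbers requires
downloading the original datasets and is outside the test suite.

The feature-matrix generator plants `n_informative` columns with a
between-class mean shift (default 3, unit noise) among pure-noise columns —
the standard parameter-recovery setup for the selection module.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale: ranking with
20 shadow iterations of 200 trees, subset search with 1 repeat, tuning with
15 trials over three families (SVM, LDA, LightGBM), and 2×10-fold final CV.
Library defaults are larger (30 iterations, 3 repeats, 100 trials, all six
families); the scaled-down settings change runtimes, not conclusions, on the
strongly separated synthetic benchmarks.

## Known limitations

* The 58-type registry reproduces the documented envelope (type count,
  total size, and the pinned per-type sizes); the identity of descriptor
  types beyond the named families is a reconstruction, recorded in the
  manifest.
* Ez/Cougar/ABHPRK are package-defined stand-in tables (see above).
* The TPE sampler models parameters independently (no joint densities) and
  the LDA family exposes only shrinkage as a tunable.
* Sequence-identity clustering / redundancy reduction is out of scope; real
  benchmark curation is assumed done upstream.
* Class imbalance is not handled (balanced benchmarks by construction).
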