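# Methods

`tadpose` implements a position-effect analysis of chromosomal deletions of
the kind used to dissect genotype–phenotype relations in 22q13 deletion
(Phelan-McDermid) syndrome: a candidate-gene predictor built on TAD and
regulatory-contact disruption, a 2^-ΔΔCt qPCR expression classifier, and a
phenotype-microarray (Biolog PM-M) per-well comparison pipeline, together
with seeded generators that emulate every input so the whole analysis is
testable without access to patient data.

## Coordinate model

Positions are stored 1-based exactly as printed in clinical reports; interval
length is `end − start`, which reproduces every printed deletion size (e.g.
51,244,566 − 42,740,931 = 8,503,635 bp = 8.503635 Mb). All set operations
(overlap, containment, gap) therefore treat intervals as half-open
`[start, end)`; two intervals that merely touch do not overlap and have gap 0.
Zero-length intervals model single positions (breakpoints). BED input is
0-based half-open and is shifted by +1 on read, which preserves lengths.

A gene is classified against a deletion as `deleted` (fully inside),
`partially_deleted` (overlapping a breakpoint — introduced because an
intragenic deletion can remove the major part of a gene; downstream the class
is treated like `deleted`), `within_window` (disjoint, gap ≤ window) or
`distal`. Microarray-derived breakpoints are taken as exact interval
endpoints; probe-level uncertainty is not modeled.

Deletion size classes (`Small` < 5 Mb ≤ `Mid` < 8 Mb ≤ `Large`) are a rough,
deliberately configurable stratification chosen to reproduce the labels of
the five-patient validation panel; they carry no biological meaning.

## Candidate prediction and ranking

For one patient the predictor evaluates every gene with status other than
`distal` on five features:

* **disrupted contacts** — number of the gene's regulatory contacts whose
  element the deletion removes (not counted for deleted genes: losing a
  gene's enhancers is not position-effect evidence when the gene itself is
  gone);
* **disrupted-TAD membership** — the gene overlaps a TAD that contains a
  breakpoint strictly in its interior (a cut exactly on a TAD boundary
  disrupts nothing, consistent with half-open domains);
* **window membership** — status `within_window` for the flanking windows of
  up to 2 Mb on each side of the breakpoints (the distal window is omitted
  for terminal deletions; the proximal window is clipped at position 1);
* **HI flag** — DECIPHER-style %HI ≤ 10. This is a ranking feature, not a
  filter: known candidate lists include genes far above that band. A missing
  HI score is never imputed and never sets the flag;
* **phenotype gate** — Jaccard overlap between the gene's and the patient's
  phenotype-term sets, converted to a percentile within that patient's
  search space (percentile = 100 · #strictly-below / (n − 1); ties share a
  value; a single gene gets 100) and gated at the 75th percentile. Set
  overlap is a documented stand-in for whatever semantic matching the
  clinical coding would support; no ontology traversal is attempted.

The combination rule is an explicit additive score,
`w₁·min(contacts, 5)/5 + w₂·[TAD] + w₃·[window] + w₄·[HI] + w₅·[phenotype]`,
defaults all 1. Published descriptions of such rankings state the criteria
but not a combination rule, so a transparent, auditable score was chosen;
weights, the contact cap and the gates are configurable. Ties are broken by
distance to the nearest breakpoint, then symbol, so output order is
reproducible.

Candidate classes: a deleted (or partially deleted) gene is a `by_deletion`
candidate when it passes a relevance gate (HI flag OR phenotype gate) —
deletion alone is not evidence of phenotypic relevance. A preserved gene is a
`by_position_effect` candidate when it is within the window AND shows
mechanistic evidence (disrupted TAD OR ≥ 1 disrupted contact); whether window
and TAD combine with AND or OR is configurable (`combine="or"`) because the
original criterion is ambiguous, and AND is the default as the stricter
reading. With no TADs and no contacts the position-effect set is empty by
construction.

## qPCR expression pipeline

Replicate Ct values are averaged on the Ct scale within sample × gene (averaging
per-replicate folds instead is exposed as `replicate_scale="fold"`),
normalized to the housekeeping gene TBP (ΔCt), referenced to the mean ΔCt of
the pooled control samples (ΔΔCt), and converted to fold change 2^-ΔΔCt.
This makes the pipeline exactly invariant to a constant Ct shift applied to
one sample (input-amount differences cancel). Folds ≥ 1.5 are `elevated` and
≤ 0.66 `decreased`, both bounds inclusive as the thresholds are printed; no
efficiency correction, standard curves or outlier rejection are applied.
Genes annotated as not expressed in blood are excluded from the pipeline;
genes missing from the annotation are carried with status `unknown` and
excluded from status summaries. The status-stratified summary reports the
arithmetic mean fold per gene within the `not_deleted` / `deleted` /
`within_window` groups (empty group → N/A); printed group averages that
disagree with the mean of their own printed members are not chased.

## Plate (PM-M) pipeline

Per well: relative absorbance A590 − A750 (or a kinetic statistic), minus the
mean of the corresponding empty-plate triplicate, floored at ε = 10⁻⁶ so all
96 wells stay in the analysis (flooring was chosen over dropping wells),
then log10(· + ε). Kinetic statistics are computed on the normalized log
curve: `slope` is the maximum least-squares slope over sliding one-hour
windows, `endpoint` the final reading, `auc` the trapezoid integral in
OD·hours.

Each well is tested with a two-sided Mann-Whitney U against the control
panel: exact distribution when min(n) ≤ 8 and the pooled values are tie-free,
normal approximation with tie correction otherwise; significance at
p ≤ 0.05 by default, with per-plate Benjamini-Hochberg adjustment available
(`adjust="bh"`). Direction (increased / decreased NADH production) is the
sign of the median difference and is reported only for significant wells.
Summary strings render as printed (`43/96 (44.8%)`; the exact-100% case as
`100%`).

The unit of replication is stated loudly because assay descriptions often
leave it implicit: the sample side needs ≥ 2 replicate observations per well
(replicate plate runs or replicate kinetic statistics); single-replicate
input is rejected rather than silently tested. The control side is one value
per control line (a 50-line panel in the emulated design).

## Synthetic-data model

* **Locus** — non-overlapping genes packed with Dirichlet-distributed gaps
  over a ~51 Mb chromosome; HI percentiles uniform with a configurable
  fraction in the 0–10 band and ~5% missing; phenotype terms drawn from a
  fixed 30-term vocabulary; TADs partition the modeled region; contacts link
  each gene to Poisson-many elements within 2 Mb.
* **Cohort** — log-uniform deletion sizes over 0.1–8.5 Mb (the printed
  range); terminal deletions share the chromosome end.
* **Planted truth** — position-effect genes are chosen among genes within
  the window of a deletion (preferring genes in a disrupted TAD, matching
  the mechanism the predictor looks for) and receive extra contacts whose
  elements fall inside the deletion; every deleted gene and each planted
  gene gets a true fold change (default 0.5×, one lost allele without
  compensation). A `compensated` option expresses a gene at 2× in every
  patient regardless of status, emulating dosage compensation of an
  enzyme-coding gene and exercising the classifier's independence from
  deletion status.
* **qPCR** — Ct = gene baseline − log2(expression) + N(0, 0.2 cycles), two
  replicates, two pooled controls, housekeeping constant up to noise.
* **Plates** — per-well logistic curves `A/(1 + e^{−k(t−t₀)}) + baseline`
  sampled every 15 min over 24 h (96 points), A ~ U(0.6, 1.4), k ~ U(0.2,
  0.6)/h, t₀ ~ U(6, 16) h; read noise sd 0.015 OD; empty plates in
  triplicate. Every observation — control line or sample replicate run —
  draws an iid amplitude perturbation N(0, 0.06); planted well effects shift
  the sample amplitude by the stated number of those SD units. Folding
  line-level and run-level variability into one iid per-observation term is
  a deliberate simplification: a shared line effect across a patient's
  replicate runs would make the per-well test anti-conservative, and with it
  the null-calibration property would not be well defined. Real plate data
  also carry edge effects, drift and batch structure that are not modeled,
  so passing tests demonstrate correctness of the machinery under the stated
  model, not robustness to those artifacts.

All generators are pure functions of (parameters, seed) and emit exactly the
CSV/TSV dialects the pipelines read, plus a JSON truth file.

## Numerical and design notes

* Percent strings round half-to-even at one decimal; only exactly 100%
  prints without a decimal, matching the printed style.
* ε-values: 10⁻⁶ for both the normalization floor and the log offset;
  differences far below ε collapse, so the log map is monotone non-strict at
  float precision.
* Degenerate Mann-Whitney input (all values identical in both groups) returns
  p = 1 with no direction rather than an error.
* Problem sizes used by the test suite and the acceptance script — 10,000
  null wells, 100-seed recovery sweeps, 200 recall cohorts, up to 1,000
  oracle loci — were chosen as the smallest sets at which the binomial noise
  of the measured rates is comfortably inside the asserted bands.
* The in-repo validation fixtures carry the printed coordinates of the
  five-patient panel and nine-gene table; the HI percentages stored for the
  two low-HI genes are synthetic stand-ins (only the ≤ 10% flag is public),
  and the three candidate genes without printed coordinates (not
  blood-expressed) are exercised through synthetic loci instead.

## Limitations

The predictor does not re-derive TADs or contacts from Hi-C and implements
no liftover, translocation or ring-chromosome modeling. The qPCR stage
assumes perfect amplification efficiency. The plate stage does not model
dye chemistry or cross-plate batch effects, and the per-well test treats
replicate runs as exchangeable with control lines (see above). Phenotype
matching is raw set overlap over term identifiers.
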