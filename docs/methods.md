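# Methods

## The analysis

`herbnet` implements a prescription-pattern analysis for Chinese herbal
medicine (CHM) claims data. Its object of study is the *co-prescription
structure* of a disease-defined cohort: which reimbursed CHM items — herbal
formulae (HF, fixed multi-herb products) and single herbs (SH) — are
prescribed together, which pairs are combined more often than their
individual popularity explains, and which combination sits at the center of
the resulting network (the *core treatment*). The motivating application is
breast cancer (ICD-9 174.0–174.9) in Taiwan's National Health Insurance
outpatient claims for calendar 2008, where the analysis identifies the
duplex medicinal *Hedyotis diffusa* + *Scutellaria barbata* as the core.

The pipeline has four stages.

**1. Cohort extraction.** From a claims database (patients, visits with up
to three ICD-9 diagnoses and treatment-type flags, prescription line
items), keep visits that (i) fall inside the study window, (ii) carry at
least one diagnosis whose canonical dotless code starts with the index
prefix, (iii) include a CHM prescription, and (iv) are not flagged for
acupuncture, massage or traumatology (these modalities confound CHM
patterns and are excluded). The retained visits' item sets form the
*prescription database*; the funnel counts at each step are reported.

**2. Pair-rule mining.** Over N prescriptions (each a set of items), every
unordered pair {A, B} gets

- support = n_AB / N,
- directional confidences n_AB / n_A and n_AB / n_B,
- one *reported* confidence chosen by policy.

Rules are retained when support ≥ 0.5% and reported confidence ≥ 30%
(configurable), ranked by (support desc, confidence desc, pair id asc).
A retained SH + SH rule is flagged a *duplex medicinal*.

**3. Network.** Retained rules form an undirected simple graph; degree
(number of retained rules incident to an item) is the centrality of
interest. Node attributes carry kind, prevalence and degree; edges carry
support, confidence, n_AB.

**4. Core identification.** The published analysis reads the core off the
drawn network; here it is formalized as a deterministic rule: core nodes =
argmax by (degree, then prevalence, then id), core edge = argmax by
(support, then reported confidence, then pair id). Ties therefore cannot
produce irreproducible output. Alternative centralities (betweenness etc.)
can be computed from the exported GraphML but are not part of the core
criterion.

### The confidence direction

The textbook confidence is directional (P(B | A)), but tabulated CHM
analyses print a single value per pair without fixing the direction. Cross-
checking the published tables shows the only internally consistent cell
divides the pair count by the *rarer* item's count (677 / 2,161 = 31.33%),
so the default policy is `condition_on_rarer`; `condition_on_a` (the
lexicographically first item) and `max_direction` are also available, and
both directional confidences are always stored. Most published confidence
cells imply denominators matching no published item count (plausibly a
sub-cohort denominator in the original processing); those cells are treated
as *not* reproducible from printed numbers, and recomputing them from the
published item counts moves two of the ten published rules below the 30%
threshold. The package documents this rather than trying to reproduce
unexplained cells.

### The support denominator

"Support" is computed over all N prescriptions. Every published support
cell equals n_AB / 37,176 to two decimals, which settles the denominator
choice.

## Synthetic claims generator

The original claims cannot be redistributed, so a seed-reproducible
generator emulates their structure; all downstream stages are tested
against it.

**Sampling model.** Each CHM prescription draws items as independent
Bernoulli variables with configured marginal probabilities, so (a) each
item's empirical frequency converges to its marginal, (b) the expected
prescription size is the sum of the marginals, and (c) every pair's
co-occurrence odds ratio is 1 by construction. *Implanted pairs* are drawn
instead from the 2×2 distribution with the same two marginals and odds
ratio equal to `joint_boost` — the Plackett construction, solving
θ(p_a−p11)(p_b−p11) = p11(1−p_a−p_b+p11) for p11 — which plants dependence
without moving any marginal. Empty draws are redrawn (a prescription has at
least one item); this conditioning inflates every marginal by
1/(1−P(empty)), which is < 0.2% at the default catalog's mean of 6.5 items
and only becomes visible for unrealistically sparse catalogs.
An item may appear in at most one implanted pair; overlapping planted
dependencies would require a joint model over triples and are rejected at
validation.

An earlier design drew a truncated-Poisson prescription size and then
sampled items without replacement; it was abandoned because size-driven
sampling induces spurious positive association between all items and biases
the inclusion probability of high-marginal items, violating the
convergence and independence properties the mining tests rely on. The
Bernoulli scheme satisfies both exactly, at the cost of a
Poisson-binomial (rather than exactly Poisson) size distribution.

**Calibration.** Defaults reproduce the published study conditions:

| parameter | default | source/rationale |
|---|---|---|
| catalog marginals | published per-prescription prevalences of the 20 top items, plus Wen-Dan-Tang (3.86%) and Smilax glabra (3.02%) implied by published pair cells | published tables |
| filler items | 30 synthetic items sharing the remaining probability mass so marginals sum to 6.5 | mean 6.5 items/prescription |
| implanted pairs | (Hedyotis diffusa, Scutellaria barbata) boost 2.84; (Taraxacum mongolicum, Millettia dielsiana) boost 2.50 | lifts joint prevalence from the independent 7.2% / 1.7% to the published 10.9% / 3.2% |
| `p_chm_user` = 0.0725, `p_chm_visit` = 0.69, `p_excluded_treatment` = 0.13 | CHM use is patient-clustered: 7.25% of patients are users; 0.0725 × 0.69 × 0.87 ≈ 4.35% of eligible visits survive as CHM prescriptions | published patient and visit shares; the excluded-modality rate is not published and 0.13 was chosen to close the identity |
| age ~ Normal(52, 9), truncated to [20, 95] | mean age 52 published; sd 9 puts ≈72% of patients in the 40–59 bin as published |
| secondary-diagnosis rates 0.08 / 0.25 | with ~6–8 retained visits per user, per-patient chapter shares land near the published order (top chapter ~11%) |
| `n_patients` = 10,000, 14 visits/patient | ≈1/6 scale of the study population; large enough that the TCM subcohort (~700 users, ~4,500 prescriptions) supports stable mining at the 0.5% support threshold |

**What the generator does not emulate.** Visits are exchangeable within a
patient (no temporal or episode structure); item dependence is limited to
the implanted pairs, so all other items are exactly independent — real
prescriptions carry broad positive and negative correlations (e.g. the most
prevalent formula being *unlinked* to the core herbs, which independence
cannot produce, so the "prevalent but unconnected" list is typically empty
on synthetic data); reimbursement amounts, dosages and outcomes are out of
scope. Passing tests therefore demonstrate the correctness of the
counting, filtering and graph logic and the recoverability of planted
structure — not distributional fidelity to real claims.

## Numerical and formatting conventions

- Percentages are rounded half-up to two decimals (`Decimal`-based), the
  convention of the published tables; all printed-number cross-checks go
  through this one code path.
- Thresholds are inclusive (support ≥ min_support, confidence ≥
  min_confidence).
- ICD-9 codes are canonicalized by trimming, uppercasing and removing the
  decimal point; prefix matching on "174" is then exactly membership in
  {174.0…174.9} for four-digit codes. V/E codes have no numeric chapter and
  are skipped in comorbidity tallies; the index prefix never counts as a
  comorbidity.
- Age bins are half-open ([0,40), [40,60), [60,∞)) in completed years at a
  mid-study reference date (2008-07-01); the published bin labels overlap
  at the boundaries but the printed counts are disjoint, and half-open
  binning reproduces the printed percentages from the printed counts
  either way.
- Pair counting is a sparse X'X product over the binary
  prescription-by-item matrix; a brute-force enumeration oracle holds it
  exact in tests.
- Degenerate inputs: an empty claims database yields an empty cohort with
  zero counts (not an error); an empty rule set yields an empty network
  with a warning, and core identification on an empty network is an error;
  a prevalence over zero prescriptions is undefined and raised, not
  returned as zero.
- Determinism: one integer seed drives a single `numpy` Generator stream;
  equal configs give byte-identical written databases and identical report
  bundles. Multi-seed experiments spawn child seeds below 2^31 from a
  `SeedSequence`.

## Problem sizes used in validation

Oracle-equivalence checks run on ≤ 2,000 prescriptions; implanted-core
recovery uses 100 seeds × 20,000 prescriptions at an 8-fold boost (the
default-calibrated catalog, where the planted pair's joint prevalence
≈13.9% clearly exceeds the strongest independent pair's ≈8.2%); generator
convergence uses 50,000 prescriptions with tolerance 0.02 on marginals and
0.15 on |log OR| of non-implanted pairs. The end-to-end synthetic run uses
the default 10,000-patient configuration (~4,500 retained prescriptions).

## Known limitations

- The generator's independence baseline makes very prevalent items link to
  many partners at the default thresholds; hub degree on synthetic data is
  therefore higher than in the published network, though the core edge and
  core node are unaffected.
- The published confidence cells that are not internally consistent cannot
  be reproduced and are not attempted.
- The rule/network/core path mines pairs (k = 2 itemsets) only, matching
  the analysis this package reimplements; an Apriori frequent-itemset
  helper (`mining.frequent_itemsets`) is available for exploring larger
  combinations but feeds nothing downstream.
- Patient-level counts (comorbidity chapters, age bins) assume one
  diagnosis coding convention per extract; mixed-vintage ICD coding (e.g.
  ICD-10 claims) is out of scope.
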