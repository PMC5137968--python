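# Methods

## The model

Each MMSE administration is a vector of five category scores. Scores are
normalized per category to success rates `r_c = 100 · raw_c / max_c` so that
patients tested under different scoring dialects become comparable; all
downstream geometry is Euclidean in this 0–100% space.

Patient groups are defined by Ward agglomerative clustering of the
first-visit success-rate vectors. We implement Ward on Euclidean input via
`scipy.cluster.hierarchy.linkage(method="ward")`, which is the
"ward.D2"-equivalent criterion — each merge minimises the increase in total
within-cluster variance. This is the variant that matches the stated
objective (within-group variance minimisation); the historical "ward.D"
variant on unsquared distances does not. Tie-breaking follows scipy's
deterministic nearest-neighbour-chain order, so clustering is reproducible
and invariant to input row order up to label permutation.

The classifier is a nearest-centroid rule: per group, the arithmetic mean
success rate over the selected categories; a patient goes to the group with
the smallest Euclidean distance, ties broken by the fixed group order
cognisant → inattentive → forgetful → distant → absent (the better group
wins). Categories are selected by running a tie-corrected Kruskal–Wallis
test per category against the cluster labels and keeping the `n_keep = 3`
smallest p-values. With ~1,900 patients in five well-separated groups the
chi-square tails underflow double precision, so ranking uses log10 tail
probabilities; beyond the subnormal range (H ≳ 1550 at df 4) an asymptotic
expansion of the chi-square survival function takes over
(`centroids.chi2_log10_sf`).

Label agreement is reported as percentage agreement plus Fleiss' κ in its
two-rater form: `κ = (P̄ − P̄ₑ)/(1 − P̄ₑ)` with `P̄` the raw agreement
fraction and `P̄ₑ = Σ_j p_j²` over pooled category proportions. Fleiss'
formula (not Cohen's) is used deliberately; with two raters it reduces to a
Scott's-π-style chance correction.

## Longitudinal transitions

For each patient the *first* visit is the earliest (or the latest visit at
or before an optional per-patient treatment boundary) and the *last* is a
follow-up whose gap lies in a fixed window. "6 months to 4 years" is
concretised as **183–1461 days, both inclusive**; when several follow-ups
qualify the **earliest** is used (minimising the time frame), configurable
to latest. Transition matrices classify both ends with the same centroid
model; row percentages are kept exact internally and displayed as half-up
rounded integers.

## Statistical tests

* **Proportion test** (APOE composition): chi-square test of equal
  proportions over k groups via `scipy.stats.chi2_contingency`, with Yates
  continuity correction in the 2-group case (matching R's `prop.test`).
  The risk set defaults to {ε3/ε4, ε4/ε4}.
* **Medication–transition test**: two-sided binomial test
  (`scipy.stats.binomtest`) of a drug's intake count in a focal
  (from → to) stratum against the intake rate of a comparator stratum.
  Comparator modes: `others` (all other destinations from the same origin,
  the default), `better`/`worse` (destinations ranked above/below the focal
  destination). The outcome ranking is cognisant > inattentive ≈ forgetful
  > distant > absent; inattentive and forgetful are ranked equal because
  they sit at the same total-score level. The direction label is
  "beneficial" when the higher intake rate accompanies the relatively
  better outcome (focal vs mean comparator destination rank) and "adverse"
  otherwise. Raw p-values are reported by default, mirroring the original
  analysis; Benjamini–Hochberg adjustment is available behind a flag.
* **Drug harmonization**: names sharing at least one category tag (after
  case-folding and whitespace normalization) are merged as connected
  components of a name graph; the canonical title is the lexicographically
  smallest member, untagged names stay singletons.

## Dialect inference

The three dialects are (orientation, registration, attention, recall,
language) maxima (10,3,5,3,9)/30, (20,6,10,6,14)/56 and (20,6,5,6,14)/51.
Per trial, candidates are eliminated when any observed category score or
total exceeds their maxima. If several candidates survive, the smallest
(by total) surviving system is chosen **provided** some observed score
attains its maximum in a category whose maxima differ among the survivors —
evidence that the scale tops out there. Otherwise the trial is flagged
ambiguous and excluded by default (a fallback to the standard 30-point
system is available). This is a deterministic, auditable stand-in for the
original distribution-based iterative procedure, whose exact steps are not
public; on trials whose scores span the full range it recovers the
generating dialect essentially always (property-tested).

## The synthetic cohort generator

The generator emulates the published cohort structure; its defaults *are*
the published values wherever those exist:

| parameter | default | source / rationale |
|---|---|---|
| group sizes | 194/261/632/589/182 | published training-set sizes |
| registration/attention/recall centroids | published signature table | verbatim |
| orientation centroids | 75/70/70/62/50 | chosen from the verbal group descriptions; see below |
| language centroids | 88/84/84/78/62 | same |
| noise_sd | 8% | no published dispersion; documented arbitrary default |
| dialect mix | 30pt 0.60 / 56pt 0.25 / 51pt 0.15 | unpublished; standard dialect assumed most common |
| transition matrix | published training-set row proportions | verbatim (one typo corrected, see Limitations) |
| follow-up gap | uniform on [183, 1461] days | the analysis window |
| APOE coverage | 1/3 | "about a third" of patients genotyped |
| APOE frequencies | group-conditional, risk-enriched toward distant; ε2/ε2 absent | qualitative published pattern |
| medication rates | background 4–30% per drug; multivitamins 12% on cognisant→cognisant, citalopram 15% on inattentive→absent, ginkgo 12% on distant→absent | plants the published association directions |

Per-category noise is a **censored (clipped) normal**: draw
`N(centroid, noise_sd)` and clip to [0, 100]. A proper truncated normal was
rejected because it shifts the mean of boundary centroids by ≈ 0.8·sd
(+6.4% at the absent/recall centroid of 0), which would corrupt exactly the
quantities the recovery experiments measure; censoring keeps the mean at
the centroid except for one-sided boundary mass. Rates are then discretised
to the patient's dialect grid (`round(rate · max_c / 100)` integer points),
because real MMSE scores are integers. On the 30-point scale this grid is
coarse (steps of 33.3% in registration/recall, 20% in attention), which is
the dominant source of recovered-centroid error.

The orientation/language centroid defaults deserve a note: the published
signature covers only registration/attention/recall, but the generator needs
all five. The defaults were chosen once to match the verbal group
descriptions *and* to reproduce the published finding that orientation and
language separate the groups far less than the signature categories
(observed H ≈ 930/1610/1280 for registration/attention/recall vs ≈ 640/600
for orientation/language at full scale). They are generator inputs, freely
overridable — not claims about the real cohort.

Determinism: one RNG stream seeded per cohort, consumed in patient order
with a fixed number of draws per patient, so enlarging the cohort leaves
earlier patients' records byte-identical.

### What a green test does and does not establish

The generator draws independent Gaussians per category around sharp group
centroids. Real cognitive data have correlated categories, education and
age effects, irregular visit calendars, dropout, and no latent "true group".
Green pipeline tests therefore establish that the *software* recovers the
structure it was told to plant at realistic sample sizes and noise — they
say nothing about whether five clusters are the right description of real
patients, and the published real-data quantities (92.9%/κ 0.904 agreement,
exact group sizes, p ≈ 10⁻³⁰⁰ tails) are not reproducible without the
restricted data.

## Pipeline conventions

* Train/validation split: patients sorted, permuted by a named seed;
  training gets ⌊n/2⌋ (3717 → 1858/1859, extra patient to validation).
* k is fixed at 5 for the replication; `select_k` (within-cluster variance
  + mean silhouette per k) is diagnostic only and never overrides a
  configured k.
* Anonymous Ward clusters are named by Hungarian matching of their
  registration/attention/recall centroids to the packaged published
  centroids (or to generator truth in the recovery experiments).
* Displayed percentages are rounded half-up to 1 decimal (tables: integer);
  all internal computation keeps full precision.

## Known limitations

* **Cluster-boundary truncation.** Ward partitions cut the overlapping
  tails between adjacent groups, so centroids computed from cluster members
  are pushed away from their neighbours — most visibly between absent and
  distant, where the coarse 30-point registration grid places a fifth of
  absent patients at 66.7% registration, a region the distant cluster can
  annex. At the default noise (8%) this moves individual recovered centroid
  cells past a 3-percentage-point band in roughly a third of cohort draws
  (centroids computed on true labels stay inside it); the corresponding
  acceptance test documents this and is expected to fail at the ≥95%-of-seeds
  level.
* The published validation transition table contains an internally
  inconsistent cell (its row total, percentage and column total jointly
  require 8 where 18 is printed); the packaged counts use the reconstructed
  value.
* Dialect inference resolves multi-survivor trials only when scores attain
  the smallest candidate's maxima; sparse, low-scoring trials stay
  ambiguous by design.
* Medication associations at true cohort scale are underpowered for rare
  transitions (~15 patients on inattentive→absent); the tests demonstrate
  the mechanism at larger simulated scale.
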