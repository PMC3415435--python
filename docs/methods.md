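# Methods

## Scope and shape

`cypddi` implements a translational DDI pipeline as a library: rule-based
literature screening for in vitro CYP substrate/inhibitor evidence, DDI pair
prediction with potency grading, exposure-window cohort construction from
OMOP-CDM-like tables, additive and synergistic logistic-regression tests of
myopathy risk, Bonferroni multiplicity control, CYP enrichment, and power
simulation. A synthetic-data module generates every input with known
generative truth so all stages are testable without clinical data.

## Literature screening

**Retrieval template.** An abstract is retained when at least one term from
each required category is present — drug names, enzyme names, FDA-style
probe reagents, assay-context terms (microsome, hepatocyte, recombinant,
incubation, …), assay-type terms (Ki, Km, IC50, …) — and no prohibited
(oncology) term occurs. Matching is case-folded and token-based; multi-word
terms match on the token stream. The filter is monotone by construction:
adding prohibited terms or removing required terms can only shrink the
retained set.

**Pattern scanner.** Sentences are whitespace/punctuation-tokenised and
case-folded; drug and enzyme dictionaries are applied longest-match-first so
multi-word names occupy one slot. Six patterns over drug (D), enzyme (E) and
operator symbols (O1 inhibit, O2 substrate/metabolise/catalyse, O3 induce,
INT interaction verbs) are matched left-to-right in token order: DEO, DOE,
EOD for drug–enzyme assertions and IDD1 ("interaction between A and B"),
IDD2 ("impact of A on B"), DID ("A interacts with B") for drug–drug
statements; the slot-order permutations OED/ODE/EDO are recognised with the
same operator semantics. Two numerical choices the source text leaves open
are config-exposed rather than inferred: at most `max_gap = 5` intervening
tokens between consecutive slots, and negation scope = a *not*/*no* token
between the first and last slot **or within two tokens before the first
slot** (the lookback is required so that "there is *not* interaction between
A and B" is flagged; a purely between-slot scope would miss the leading
negation these patterns are defined with). Duplicate reports for the same
(pattern, slot set) are suppressed. Sentence segmentation is not
implemented: corpora are sentence-segmented at generation.

**Rule engine (information extraction).** The original curation step was
manual; here it is a deterministic rule engine over structured per-abstract
assay annotations. An assertion is accepted only when the assay system is a
human liver microsome/hepatocyte or recombinant CYP preparation and the
probe used is FDA-listed for the asserted enzyme; O2-operator matches yield
substrate assertions, O1 inhibitor assertions, induction and bare
interaction matches none; negated matches assert nothing.

**In vivo conclusions.** Default rule (`significance_first`): DDI iff
p < 0.05; when no p-value is reported, DDI iff fold-change > 2.0. The
stricter `conjunction` rule (both conditions) is selectable. Studies in
pregnant women or newborns are excluded; both fields missing yields
*indeterminate*, distinct from *no-DDI*.

## DDI prediction

Substrates and inhibitors of the same enzyme are paired (directional,
self-pairs excluded, enzymes merged per pair); for counting and testing,
mirror-role duplicates collapse to unordered pairs. Potency: Ki < 10 µM
strong, 10–100 µM moderate (boundaries inclusive in the moderate bin — the
published bins are open at 10 and 100, so boundary assignment is a
documented choice), > 100 µM weak. Pair potency over shared enzymes and
both drug orderings: major metabolism + strong inhibition → strong;
major+moderate or minor+strong → moderate; else weak. Published pair
classifications are internally inconsistent on minor+strong (one listed pair
is graded strong); `strong_rule="promote_minor"` reproduces that behaviour,
`"strict"` (default) follows the stated rule. The discrepancy is surfaced,
not resolved.

## Cohorts

"One month" is fixed at 30 days everywhere; windows are date-inclusive
closed intervals [anchor − 30 d, anchor], so an exposure exactly 30 days
before the anchor is inside and 31 days is outside. Cases are anchored at
myopathy concept dates (concept set shipped as an editable text file);
window content decides the group. Controls are persons with no myopathy
concept at all: joint when the two drugs were dispensed ≤ 30 days apart
(anchored at the later dispensing so both fall in the window), otherwise
substrate-alone anchored at the first substrate dispensing. Interpretations
where the source design is silent: inhibitor-alone controls are anchored at
the inhibitor dispensing by symmetry; a myopathy-free person with both drugs
but no overlap contributes substrate exposure only; a person whose myopathy
events all lack pair drugs in the look-back window is neither a case nor a
control for that pair and is dropped with a logged count. `first_event` mode
keeps each person's earliest myopathy anchor only. Co-medication count is
the number of distinct drugs dispensed in the window, including the index
pair drugs by default (a config flag excludes them); repeated dispensings of
one drug collapse. Exclusions: persons whose first myopathy event falls
within 183 days of database start are removed (prior history unobservable);
pairs containing a myopathy-treatment drug are excluded pair-level while
their episodes remain valid for other pairs.

## Statistics

**Synergistic model.** Outcome ~ exposure group (3 levels) + covariates by
logistic regression. Adjusted group risks are obtained by covariate
standardisation (g-computation): predicted risks averaged over the pooled
covariate distribution with the group indicator set to each level. This
reduces *exactly* to the raw group proportions with no covariates (the
saturated MLE), which anchors all calibration tests. The synergy statistic
is RR = Risk12/(Risk1+Risk2); H0: RR = 1 is tested by a Wald statistic for
log RR with a delta-method standard error (analytic gradients through the
standardisation; independent binomial variances in the covariate-free case).
A seeded bootstrap of se(log RR) — within-group resampling with refitting,
or binomial resampling in the covariate-free case — is available as
`method="bootstrap"`. Degenerate inputs: zero joint events or a zero
denominator never reject (p = 1).

**Additive model.** Joint vs substrate-alone logistic regression; with no
covariates the closed-form 2×2 Wald estimate (identical to the regression
MLE) is used, with a 0.5 continuity correction flagged when a cell is empty.
Complete separation under covariates is caught and refitted with an L2
penalty; the result is flagged and carries no p-value. Note the additive
null is "joint risk = substrate-alone risk": with a non-inert inhibitor it
is false even without any interaction (joint = Risk1+Risk2 > Risk1), which
is the known weakness of additive DDI testing; its type-I error is therefore
meaningful only in worlds where the inhibitor adds no risk, and that is how
it is calibrated in the tests.

**Significance and multiplicity.** Two-sided p-values throughout; the
pipeline's significance rule additionally requires effect direction > 1.
Consequently the null rejection rate of the directional rule is α/2.
Bonferroni only (α/number of co-medicated pairs tested); no FDR by design.

**Enrichment.** Per enzyme, the 2×2 table (significant × in-enzyme, pairs
counting once per enzyme) is tested one-sided for over-representation with
Fisher's exact test (the exact hypergeometric tail; cross-checked against an
independent hypergeometric oracle in the tests). The original study cites an
external enrichment method; the exact test is this package's disclosed
choice.

**Power.** Monte-Carlo power of the synergistic test: the three cohorts are
drawn as independent binomials with risks (r1, r2, rr_alt·(r1+r2)) and the
covariate-free Wald test (identical to `fit_synergistic`, proven by test) is
applied; rejection = p < α with RR > 1. Reported with its Monte-Carlo
standard error; fully seeded.

## Synthetic data: the stated world

* **Demographics** — sex ~ Bernoulli(0.591 female); age ~ Normal(40.2, 23²)
  truncated to [0, 100]; patient-level idiopathic myopathy probability
  expit(logit(sex risk) + log(1.0015)·(age − 40.2)) with sex risks
  (0.086 female, 0.054 male). With no drug effects this calibrates the
  simulated marginal sex-specific risks to those targets (verified within
  3 Monte-Carlo standard errors at n ≥ 50,000).
* **Exposure** — each patient is assigned at most one index scenario (joint,
  either single of a configured pair, or a standalone risky drug) by
  configured fractions (defaults 4%/4%/2% per pair); joint dispensings are
  ≤ 15 days apart. Single windows carry risk `baseline_window_risk` + drug
  risk, logit-adjusted for sex (OR implied by 0.086/0.054) and age
  (1.0015/year); joint windows carry exactly θ·(Risk1(x)+Risk2(x)), capped
  at 1 with a logged warning — so the synergy parameter is invariant to the
  covariate mix and recoverable by the standardised RR. Events are dated so
  the dispensing(s) fall inside the 30-day look-back window.
* **Co-medication** — every patient has one care episode at which
  Poisson(`comed_rate`, default 2.6) benign drugs are dispensed together: at
  the index anchor for exposed patients, at a random date otherwise.
  Same-visit clustering makes co-medication a genuine confounder; giving
  unexposed patients care episodes too keeps benign drug pairs from being
  perfectly collinear with the risky exposure (an earlier draft without this
  produced a confounding structure no real formulary shows).
* **Background rate** — the unexposed background myopathy rate is not
  reported by the motivating study (a stated limitation), so
  `baseline_window_risk` (default 0.005/window) is a free parameter.
  Idiopathic events dilute all three exposure groups, attenuating end-to-end
  RR estimates below the injected θ — visible in the worked example and
  expected in real data.

What a green end-to-end test establishes: the pipeline recovers injected
synergies, ranks them above benign pairs, and is calibrated under θ = 1.
What it does not establish: realism of prescription dynamics (no drug eras,
dose, days-supply, adherence, seasonality), outcome coding error, care-seeking
bias, or vocabulary mapping — all absent from the generator by design.

**Corpora.** Positive abstracts contain exactly one pattern sentence
(drug/enzyme names from the knowledge base) plus assay-context filler
satisfying every retrieval category; fillers are constructed so they cannot
instantiate a pattern, making scanner recall exactly 1.0 a construction
guarantee, and per-pattern match counts equal to the labels. Negatives are
non-DDI decoys, half carrying a prohibited term.

## Determinism and tolerances

All generators and simulations flow from explicit integer seeds
(`numpy.random.default_rng`); identical seed ⇒ byte-identical files.
Calibration tests use the 95% binomial envelope at the stated replicate
count; θ-recovery uses median relative error ≤ 10% at n12 ≥ 2000 with
single-exposure groups of 20,000 (an order of magnitude larger than the
joint group, matching the shape of published cohort counts). The worked
examples print the numbers the code actually produces.

## Known limitations

* The information-extraction stage consumes structured assay annotations; it
  does not parse assay conditions out of free text.
* Inhibitor-alone control anchoring and the handling of exposed persons with
  out-of-window myopathy are interpretations of an under-specified design
  (documented above).
* The delta-method p-value is asymptotic; with very few joint events it is
  conservative (zero events never reject). The bootstrap alternative agrees
  with it on ≥ 95% of simulated decisions at n12 ≥ 500.
* No propensity scores, matched controls, or case-crossover designs; no
  quantitative exposure (AUC-ratio) prediction.
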