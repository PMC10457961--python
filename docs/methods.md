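# Methods

## Scope and model

`ticksay` analyses adult-immersion-test (AIT) bioassays of an
entomopathogenic fungus against engorged female cattle ticks, and screens a
fungal genome for the gene clusters that determine its toxin profile.  Both
halves operate on plain interchange formats (CSV, FASTA, JSON) and on
synthetic data whose generating process is part of the package, so every
claim the tests make is against a known ground truth.

## Drummond efficacy indices

The experimental unit is a replicate of engorged females (default design:
control + four conidial doses, four replicates of ten ticks, 200 ticks
total).  Per tick we observe initial mass (mg), death at day 15, visible
mycelial growth (morbidity), oviposited egg mass (mg) and hatched/unhatched
counts.  The indices are the classic AIT quantities: mortality %, morbidity
%, EPI % (egg mass over body mass), EC % (hatched over total eggs), and the
control-referenced inhibition indices IO/IH/REI, with RE = (EPI%/100) ×
(EC%/100) × 20000 projecting larvae per female via the standard
larvae-per-gram convention constant.

Averaging semantics are explicit because they change the inhibition
columns:

* **per-replicate** (default, reproduces published AIT tables): every index
  is evaluated on each replicate — EPI as the unweighted mean of per-tick
  EPI, EC from the replicate's pooled egg counts — and IO/IH/REI reference
  the *control group mean* EPI/EC/RE.  The table reports mean ± sample SD
  (n−1) across replicates.  The control row's inhibition mean is then 0 by
  construction, with a nonzero SD.
* **pooled** (diagnostic): IO/IH/REI are computed once per group from
  whole-group tallies (total egg mass over total initial mass; total
  hatched over total eggs).  A mean of per-replicate ratios is not a ratio
  of pooled tallies, so the two modes genuinely disagree on the inhibition
  columns while sharing all base columns.  This is why a published
  per-replicate table's IO/IH/REI generally cannot be recomputed from its
  own printed group means.

Decisions taken where the conventions are genuinely open:

* Morbidity and mortality are independent flags; a dead, overgrown tick
  counts in both.  (Published control rows showing morbidity below
  mortality imply neither flag subsumes the other.)
* EC for a tick — or a replicate — without eggs is **undefined (NaN), not
  zero**; such replicates are excluded from EC/IH/RE/REI means with a
  logged warning.  Scoring non-ovipositers as zero would conflate
  oviposition failure with hatching failure.
* Negative inhibition values (treatment above control) are reported as
  computed, never clamped.

## Group statistics

One-way fixed-effects ANOVA is implemented both from raw values and from
summary triples (mean, sample SD, n) via SSB = Σ nᵢ(x̄ᵢ − x̄)² and
SSW = Σ (nᵢ−1)SDᵢ²; the two routes agree to floating point when the summary
comes from the raw data.  The summary route matters because published
bioassays print only mean ± SD: recomputing a published F from a printed
table inherits the table's rounding.  Concretely, the bundled morbidity
summary (SDs printed as 5 and 11.5) yields F ≈ 232.0 where the source
analysis reported 230.4, and the EPI summary yields F ≈ 2.944 vs a reported
2.922 — agreement within 1%, with the residual entirely attributable to SD
rounding (±0.05 on a printed SD moves F by a few units at these scales).
The package reports what the printed numbers imply and does not force the
published values.  (The same source prints p = 0.569 for that EPI test
where F = 2.922 at df (4,15) corresponds to p ≈ 0.057, and prints a
t(195) critical value of 1.962 — the normal-limit value — where the exact
t quantile is 1.972; both look like typos and are not emulated.)

Tukey's HSD uses the studentized-range quantile computed from first
principles: the CDF P(Q ≤ q) = ∫ f_S(s) · k∫ φ(z)[Φ(z) − Φ(z−qs)]^{k−1} dz ds
with S = √(χ²_ν/ν), evaluated by 240-node Gauss–Legendre quadrature on the
inner integral and adaptive quadrature on the outer, inverted by Brent's
method to 1e-6 on the quantile.  For ν > 10⁴ the scale distribution is
treated as degenerate (normal-limit form), which satisfies the analytic
identity q(2, ∞, α) = √2·z₁₋α/₂.  Unequal group sizes use the Tukey–Kramer
span.  Unadjusted pairwise-t comparisons are provided alongside because
published analyses sometimes quote t critical values even when their tables
footnote Tukey; letters default to Tukey.

The compact letter display uses insert-and-absorb: start with one class
holding all groups, split on each significant pair, absorb subset classes.
The defining iff (sharing a letter ⇔ not significantly different) is
verified before returning; minimality of the letter count is not
guaranteed.

## Synthetic bioassay generator

Per tick: initial mass ~ log-normal (median 250 mg, log-SD 0.15 —
typical engorged-female masses); death and morbidity ~ independent
Bernoullis with per-group probabilities; the egg-mass fraction ~ gamma
around the group EPI target (CV 0.30 per tick, so replicate means spread a
few percentage points, matching published replicate SDs); a configurable
fraction (default 0.5) of dead ticks lay nothing, and the gamma mean is
inflated by the expected zeroing so the *observed* group EPI mean hits the
configured target; eggs ~ Poisson(egg mass × 20 eggs/mg); hatched ~
beta-binomial with intraclass correlation ρ = 0.1, because replicate-level
hatch-rate spread in real assays is far above binomial noise.  The default
per-group vectors (mortality 5/10/15/50/50 %, morbidity 2.5/90/100/100/100
%, EPI 53.4/50.7/53.4/39.8/48.6 %, hatch 85.6/75.7/70.6/67.5/56.3 %) are
the group means of a published AIT of an *A. flavus* isolate against
*R. microplus* — calibration targets of the stochastic model, not fitted
estimates.  Seeding is hierarchical (`SeedSequence(seed, spawn_key=(group,
replicate))`), so enlarging the design never perturbs existing records.

What the generator does **not** emulate: within-host fungal dynamics,
dose–response curve shape between the four doses, correlation between
death and oviposition beyond the zeroing rule, temperature/humidity
effects.  Passing calibration tests therefore shows the analysis machinery
recovers the group structure it was pointed at — not that the biological
model is right.

## Genome screening

The aligner is an exact-word seed-and-extend local aligner: 11-mer exact
seeds (words containing N never seed), grouped by diagonal; ungapped X-drop
extension (match +1, mismatch −2, X = 20) vectorised along the diagonal;
seeds falling inside an already-extended region of their diagonal are
skipped.  A chaining pass merges co-linear hits separated by a small indel
(≤ 30 bp, gap open 2.5 + 0.5/bp) when the combined score improves,
counting gap opens; substitutions and deletions — the mutation types the
generators plant — are handled exactly, while arbitrary gapped alignment is
out of scope.  E-values are Karlin–Altschul, E = K·m·n·e^{−λS}, with λ
solved at import for the scoring scheme (λ ≈ 1.333 for +1/−2) and
K = 0.621, the standard ungapped DNA value; hits above E = 10⁻³ are
dropped.  Coordinates follow the BLAST tabular convention: 1-based
inclusive, minus-strand hits with s_start > s_end.

Per-gene **coverage** is the union of query spans of retained hits over the
gene length (overlapping hits never double-count); **identity** is the
alignment-length-weighted mean of hit identities; a gene is **complete**
when coverage ≥ 90% (configurable; the threshold mirrors the coverage rule
used to call G-type pathway genes defective).  **Synteny** is the Kendall
tau between reference gene order and the genomic order of best-hit
midpoints, ties broken by reference order with a warning; |tau| = 1 is
colinear (negative for a reversed cluster).  **Fragmentation** projects hit
spans back onto the reference gene and reports fragment lengths, pairwise
overlaps, missing prefix/suffix and whether a named site (e.g. an active
site near position 207) is covered; on a full tiling the bookkeeping
conserves length exactly (missing_prefix + Σ lengths − Σ overlaps +
missing_suffix = gene length).  A published fragment set for the aflF gene
is bundled; note its printed numbers (574 + 364 + 221 − 9 = 1150 on a
1149 bp gene) are off by one, so the conservation invariant is only
enforced on synthetic tilings.

**ANI** cuts the query genome into consecutive 3 kb fragments, takes each
fragment's best hit on the reference, keeps fragments whose best-hit
identity reaches 80%, and averages — a deliberately simple, single-aligner
rendition of fragment-mapping ANI, asymmetric in (query, reference) like
the underlying method.  It recovers planted divergence well (99.2% at
μ = 0.008, ~94% at μ = 0.06) but is a didactic instrument, not a
MinHash-based production ANI; published ANI tables are a regime reference,
not a bit-exact target.  End-trimming at the maximal-score point inflates
identity by well under 0.1 point at these divergences.

Phenotype rules: morphotype L requires sclerotia strictly over 400 µm in
mean diameter (the boundary value classifies as S); chemotype is "none" if
a core gene (aflR regulator, aflC polyketide synthase) is incomplete,
"B-only" if the core is complete but a G-type-essential gene (aflU, aflF)
is not, "B+G" otherwise.

## Numerical and interface choices

* Sample SD (n−1) throughout.
* MSW = 0 with MSB > 0 reports F = +∞, p = 0, flagged `degenerate`; an
  all-identical dataset is an error, not a statistic.
* Undefined quantities (EC without eggs, ANI with nothing mapped, identity
  without hits) are NaN and flagged, never silently 0.
* The bundled replicate-level values for the published mortality/morbidity
  columns are reconstructions: any replicate set matching the printed mean
  and sample SD gives the same ANOVA, and integer multiples of 10% (units
  of one tick in ten) were chosen.  Only distribution-level agreement with
  the published table is ever claimed.
* Problem sizes in the test suite and acceptance script (20–100 kb
  genomes, 3 kb ANI fragments, 200 calibration simulations, 10,000 null
  ANOVA replicates) keep stochastic noise at least several times smaller
  than every tolerance asserted.

## Known limitations

* The aligner has no affine-gap DP; long insertions in the subject split
  hits rather than merging them (the fragmentation report is built on
  exactly that behaviour).
* Tukey letters are correct but not guaranteed minimal in letter count.
* The simulator draws morbidity independently of death and dose kinetics;
  it reproduces group-level summaries, not tick-level joint distributions.
* No multiple-testing correction across responses: the analyses mirror the
  field's practice of independent one-way ANOVAs per index.
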