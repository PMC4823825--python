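# Methods

`dipgevo` analyses multi-region sequencing of a single patient's tumor —
the setting of whole-brain autopsy studies of diffuse intrinsic pontine
glioma (DIPG), where many 2 mm punch cores from the pons, brainstem,
cerebellum and cerebrum are sequenced at exome (~70x) and deep-amplicon
(~4,000x) depth.  This note records the models, the defaults and why, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## Generative model of a cohort

A patient is a rooted clone tree: a normal-cell root, a single truncal
tumor clone (tumors are monoclonal in origin), and further clones attached
uniformly at random to existing tumor clones.  Mutations belong to exactly
one clone and are carried by its whole subtree.  Arm-level CNV events
(duplication, deletion, copy-neutral LOH) are assigned to clones at rate
`cnv_rate` per clone (default 0.3 — DIPGs carry a handful of arm-scale
events) and are inherited by descendant clones.

Each region draws a purity uniformly from `purity_range` (default 0.7–0.9),
splits the tumor mass over clones with a symmetric Dirichlet(1) draw, and
assigns the remainder to normal cells.  Non-truncal clones drop out of a
region with probability `dropout_prob` (default 0.2), reproducing the
regional absence of subclones seen in real multi-region data; any clone
dropped everywhere is restored in one region so all clones are observable.
Normal contamination is modeled explicitly even though purity per punch is
rarely known; the analysis side treats purity as 1 unless supplied, which
simply rescales cellular frequencies uniformly per sample.

Expected variant allele fraction is closed-form: mutant copies carried by
the mutation's clade, mixture-weighted, over total locus copies
mixture-weighted, with copy numbers per cell set by the arm's event.  Read
counts are Binomial(depth, VAF) at Poisson depth — no sequencing error
model, no overdispersion — so the binomial standard error is the exact
noise scale and every calibration statement below is analytic.  Germline
het-site B-allele frequencies shift with aneuploidy (a duplication at
clonal fraction f puts the gained allele at (1+f)/(2+f)); the affected
haplotype is random per site, and site depth scales with mean copy number.

Genotype conventions default to: duplication gains the wild-type chromatid
(1 mutant of 3 copies), deletion and CN-LOH retain the mutant haplotype.
Note an asymmetry that follows from the correction formulas themselves
(next section): under the wild-type-gained convention the duplication
correction maps a clonal event to corrected VAF 0.2 rather than back to
the diploid 0.5 — a rank-preserving rescaling, not an exact inverse.  The
exact-inverse convention (mutant chromatid duplicated) is available via
`mutant_on_gained_copy=True`, and `mutant_retained=False` lets robustness
tests violate the retention assumptions.

## CNV-aware count correction

The four corrections are applied exactly as printed, on real-valued
counts:

| event            | Ref'          | Alt'    |
|------------------|---------------|---------|
| duplication      | Ref           | Alt/2   |
| deletion         | Ref + Alt     | Alt     |
| chrX hemizygous  | 2·Ref + Alt   | Alt     |
| copy-neutral LOH | Ref + Alt/2   | Alt/2   |

Counts stay real-valued; rounding to integers for count likelihoods
happens in one place (`estimate_ccf`), avoiding compounded truncation.
The chrX rule applies only to XY individuals and takes precedence over the
arm event.  Corrections are per-sample by default (each region uses its own
arm calls); strict mode refuses observations on arms without a call,
lenient mode assumes neutral with a logged warning.

## Arm-level CNV calling

Per (sample, arm) two signals: the mean folded BAF deviation
mean|BAF−0.5| over germline het sites (computed as |b−a|/2d, exactly
symmetric under allele relabeling), and the median-centered
log2 tumor/normal coverage ratio.  Significance of imbalance comes from a
depth-matched Monte-Carlo null: Binomial(d_i, 1/2) draws at the observed
site depths (default 10,000 replicates; sampled as popcounts of random
bits, which is exact and fast), p = (1+#{null ≥ obs})/(N+1).

The decision table: significant imbalance with coverage ratio above +0.15
is a duplication, below −0.15 a deletion, in between copy-neutral LOH; no
significant imbalance is neutral.  Significance requires p < 0.01 *and* an
effect-size floor.  A fixed floor of 0.05 would sit inside null noise at
exome depth: a balanced arm at depth d has E|BAF−0.5| = sqrt(1/(2πd)),
which is ≈0.048 at 70x.  The effective floor is therefore
max(0.05, 1.5 × mean_i sqrt(1/(2π d_i))) — ≈0.072 at 70x, 0.05 at high
depth — keeping the false-call rate near zero without hurting power: the
weakest target event (duplication at clonal fraction 0.6) sits at folded
deviation ≈0.115, many null standard errors above the floor.  Arms with
fewer than 10 sites of depth ≥ 10 are unevaluable, not neutral.  Matched
normal coverage is required to direction a significant imbalance.

Power at 100 sites × 70x: clonal-fraction ≥ 0.6 events are detected with
the correct type at ≥ 95% sensitivity; clonal fractions around 0.2 are
below the detection floor and deliberately left uncalled (documented
limitation — subclonal CNVs at exome depth are not reliably callable by
arm-level statistics).

## Cellular frequencies, clustering, tree search

CCF = min(1, 2 × corrected VAF / purity), purity defaulting to 1.  Cells
with corrected depth < 10 are missing.  Mutations are clustered by a
k-component binomial mixture (component frequency per sample, shared
across member mutations) fit by EM with 10 seeded restarts, k = 1..k_max
(default 6) selected by BIC with k·S + (k−1) parameters; assignment by
maximum responsibility.  This deliberately replaces the Dirichlet-process
MCMC of tools like PhyloWGS/PyClone with a deterministic, desk-scale
procedure: the quantity of interest here is ground-truth recovery, not a
posterior.

Trees are enumerated exhaustively over clusters: all rooted labeled trees
with the normal root having exactly one (truncal) child — k^(k−1)
candidates, capped at k ≤ 7.  Per sample, raw cluster frequencies are
projected onto the pigeonhole-feasible set {0 ≤ f ≤ 1, f_parent ≥
Σ f_children} by constrained least squares (SLSQP); the candidate score is
the binomial log-likelihood of the member counts at the projected
frequencies minus λ × (summed L1 projection distance), λ = 100.  When some
candidate is feasible outright, all feasible candidates share the
identical unprojected likelihood and strictly dominate the infeasible ones
(the likelihood is maximized at the empirical frequencies), so the QP is
skipped entirely — this makes noiseless analyses exact and fast.

Ties are broken deterministically: fewer constraint-violating nodes, then
smaller total node depth, then lexicographically smaller parent vector;
the size of the tie set is reported (`n_tied`).  The depth rule encodes a
real non-identifiability: when one sibling subtree's frequency dominates
another's in *every* region, the nested and branching topologies fit
equally well and no frequency method can separate them; preferring the
shallower tree asserts the weaker (branching) hypothesis, which under the
generative model is the more frequent source of exact ties.

Mixing proportions per sample: node frequency minus the sum of its
children's, floored at 0; the normal proportion is 1 minus the truncal
frequency; renormalized to sum to 1.  Display trees collapse nodes whose
mixing stays below 0.05 in every sample into their parent (the fitted tree
is untouched; the truncal node is never collapsed).  Export formats:
lossless JSON, Graphviz DOT with per-sample mixing labels, topology-only
Newick.

## Temporal ordering and classification

For two mutations sharing ≥ 2 evaluable regions: A precedes B when
CCF(A) ≥ CCF(B) − tol everywhere and exceeds it by tol somewhere; equal
within tolerance everywhere is unresolved; mutual excess is incomparable
(distinct branches).  The tolerance defaults to 2 × the pooled binomial SE
of the CCF difference per sample, so exome and amplicon data are judged on
their own noise scales.  All directed pairs are transitively reduced;
tolerance-induced cycles (possible because the dominance test is not
transitive at finite tolerance) are demoted to unresolved.  Roots of the
order are the candidate initial events.

On noiseless input the inferred order equals the true ancestor relation
*given an identifiability condition*: no clone's frequency dominates a
non-descendant clone's in every region.  The noiseless test instances are
drawn under that condition (rejection sampling on the mixtures) because
without it the true relation is not recoverable from frequencies by any
method — this is a statement about the data, not a tuning of the method.

Spatial classes over tumor samples (default: samples with ≥ 1 present
driver-gene mutation): ubiquitous = present in all evaluable tumor
samples, shared = in ≥ 2 but not all, private = exactly 1.  Driver
categories: main driver = listed gene, truncal cluster, ubiquitous;
accessory driver = listed gene but subclonal or non-ubiquitous; passenger
otherwise.  The driver-gene list is configuration data (defaults: H3F3A,
HIST1H3B, HIST2H3C, TP53, PPM1D, ACVR1, PIK3R1, PIK3CA, ATRX, PTEN).
Obligate partnership: every evaluable tumor sample carrying the
oncohistone mutation also carries ≥ 1 partner-gene mutation; the
partnership is *complementary* when no single partner covers all samples
by itself (two subclones with distinct partners jointly covering the
tumor).  Early-vs-late spread is reported descriptively (which subclonal
mutations each site carries), not labeled.

## ddPCR quantification

Occupancy λ = −ln(1 − positive/total) per channel; concentration
λ / droplet volume (0.85 nl per droplet by default — an assumption, the
instrument chemistry's commonly published value, not a measurement);
mutant fraction 100 × c_m/(c_m + c_w) with a delta-method 95% interval
from per-channel variances Var(λ̂) = p/((1−p)N).  Saturated assays (all
droplets positive) raise rather than extrapolate.

## Presence calling

Exome mode: present iff depth ≥ 10 and alt fraction ≥ 10%, boundary
inclusive; depth < 10 is unevaluable.  Deep-amplicon mode has no published
rule for this assay; the declared choice is alt ≥ 5 reads and a one-sided
binomial test against a per-read error rate e0 = 0.002 at α = 1e−3 — a
flat 10% cut would erase exactly the low-frequency subclones deep
sequencing exists to find.  All parameters sit on `PresenceParams`.

## Problem sizes and verification

The studies in `dipgevo.studies` (also run by `scripts/acceptance.py`)
use: 100 cohorts of 4 clones × 6 regions × 50 mutations/clone at 4,000x
for topology/mixing recovery; 200 noiseless identifiable instances of 2–5
clones for exhaustive-search equivalence; 120 event arms and 500 null arms
at 100 sites × 70x for CNV power/specificity; 20 seeds of the branching
partner fixture; 1,000 Monte-Carlo partitions for ddPCR calibration.
All randomness flows from explicit integer seeds; identical seeds give
byte-identical cohorts and bit-identical trees.

## Known limitations

* Binomial read noise only — no sequencing error, mapping bias, FFPE
  artifacts or overdispersion; real-data error bars are wider than the
  simulated ones, so recovery rates here are upper bounds.
* Arm-level CNV only; no sub-arm breakpoints, whole-genome doubling, or
  joint purity/ploidy estimation; locus-level integer copy number and
  mutation multiplicity are out of scope (the four printed corrections
  are the model).
* Per-sample all-or-nothing correction: a subclonal CNV corrects all
  cells of a sample as if clonal — inherited from the correction formulas
  themselves.
* Exhaustive tree search is capped at 7 clusters; larger problems need
  the clustering to stay coarse.
* The tie-break cannot create information: dominated sibling topologies
  remain ambiguous and are reported as such via `n_tied`.
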