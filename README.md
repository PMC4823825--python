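# dipgevo

Clonal-evolution analysis of multi-region tumor sequencing, built around
the study design used for diffuse intrinsic pontine glioma (DIPG) autopsy
brains: many spatially distinct punch cores of one patient's tumor,
sequenced at exome (~70x) and deep-amplicon (~4,000x) depth, analysed
jointly to reconstruct how the tumor evolved and spread.

It is a library for bioinformaticians working on tumor heterogeneity:
the public face is the importable API plus `examples/` (one short script
per capability); a thin `dipgevo` CLI wraps cohort simulation and tree
reconstruction.

## What it computes

Given per-sample somatic allele counts, germline het-site B-allele counts
and per-arm coverage for one patient:

1. **Arm-level CNV calls** from allelic imbalance + coverage.  Per arm the
   mean folded B-allele-frequency deviation mean|BAF − 1/2| is tested
   against a depth-matched Monte-Carlo binomial null; significant
   imbalance with raised / lowered / flat log2 tumor-normal coverage is a
   duplication / deletion / copy-neutral LOH.
2. **CNV-aware count correction**, the exact printed formulas
   (duplication Ref′=Ref, Alt′=Alt/2; deletion Ref′=Ref+Alt, Alt′=Alt;
   chrX hemizygous Ref′=2Ref+Alt, Alt′=Alt; CN-LOH Ref′=Ref+Alt/2,
   Alt′=Alt/2), making allele frequencies comparable across copy states.
3. **Clone-tree reconstruction**: cellular frequencies
   CCF = min(1, 2·VAF′/purity), binomial-mixture EM clustering with BIC
   model selection, then exhaustive search over all rooted clone trees
   (single truncal clone; k^(k−1) candidates) scored by a penalized
   binomial likelihood under the pigeonhole condition — in every sample a
   parent's frequency must cover the sum of its children's.  Output
   includes per-region clonal mixing proportions and a display tree with
   trajectories of contribution ≥ 0.05.
4. **Temporal ordering and classification**: mutation order from relative
   frequencies across regions (earlier events dominate everywhere),
   ubiquitous/shared/private spatial classes, main/accessory/passenger
   driver categories, and detection of obligate oncohistone partnerships —
   including the case where two complementary subclones carry distinct
   partners.
5. **ddPCR quantification**: Poisson occupancy λ = −ln(1 − positive
   fraction), copies/µl, and mutant percentage with a delta-method CI.

A first-class synthetic-cohort generator (`dipgevo.simulate`) produces
patients with known clone trees, mixtures, CNV assignments and
binomially sampled reads, so every stage is verifiable against ground
truth without any data download.  `dipgevo.studies` packages the seeded
recovery studies.  The tree search deliberately replaces MCMC machinery
(PhyloWGS-style Dirichlet-process + stick-breaking posteriors) with a
deterministic EM + exhaustive penalized-ML search; see `docs/methods.md`.

## Worked example

```bash
python examples/04_reconstruct_tree.py
```

prints (seed 23, 4 clones, 6 regions, 50 mutations/clone at 4,000x):

```
selected k = 4 clusters (BIC over k=1..6)
fitted parent map (0 = normal root): {1: 0, 2: 1, 3: 1, 4: 2}
true parent map:                     {1: 0, 2: 1, 3: 1, 4: 3}
cluster -> true clone: {1: 1, 2: 3, 3: 2, 4: 4}
tie set size: 1 (1 = topology unambiguous)

per-region mixing proportions (rows: clones + normal):
           R1     R2     R3     R4     R5     R6
1       0.810  0.304  0.051  0.021  0.003  0.385
2       0.049  0.594  0.132  0.185  0.200  0.091
3       0.000  0.000  0.393  0.459  0.463  0.039
4       0.003  0.000  0.299  0.072  0.176  0.333
normal  0.138  0.102  0.125  0.263  0.158  0.153

Newick: (((clone4)clone2,clone3)clone1)normal;
```

Cluster labels are ordered by mean frequency, so cluster 2 is true clone
3 and vice versa — under that mapping the fitted topology equals the true
one (fitted clone-4 parent = cluster 2 = true clone 3).  The mixing rows
are the fraction of each region's cells per clone; the `normal` row is
the non-tumor content of each punch.  `examples/05_order_and_classify.py`
shows the ordering output on a patient with a truncal oncohistone-like
mutation and complementary TP53-like / PPM1D-like sibling subclones:

```
ordered pairs (earlier -> later): [('H3F3A', 'PPM1D'), ('H3F3A', 'TP53')]
incomparable (distinct branches): [('TP53', 'PPM1D')]
roots (candidate initial events): ['H3F3A']
obligate partnership: True (complementary subclones: True)
```

## Layout

```
src/dipgevo/
  simulate.py    synthetic cohorts with ground truth
  io.py          count-table / VCF ingestion, presence calling
  cnv.py         arm-level CNV calls (BAF + coverage)
  correction.py  CNV-aware count correction
  clonetree.py   CCF, clustering, exhaustive tree search, export
  ordering.py    temporal order, spatial/driver classes, partnerships
  ddpcr.py       Poisson droplet quantification
  studies.py     seeded recovery/calibration studies
  cli.py         `dipgevo simulate`, `dipgevo reconstruct`
```
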