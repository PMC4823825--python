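"""Synthetic multi-region tumor sequencing cohorts with known clonal structure.

A cohort is one patient: a rooted clone tree (normal cells at the root, a
single truncal tumor clone below it), mutations assigned to clones, arm-level
CNV events assigned to clones, and per-region clonal mixing proportions.
From that ground truth the generator produces the three tables the analysis
pipeline consumes:

* somatic variant read counts per (mutation, region) — binomial sampling at a
  configurable mean depth (``70`` emulates whole-exome data, ``4000`` deep
  amplicon sequencing);
* germline heterozygous-site B-allele counts per arm, whose expected BAF is
  shifted away from 0.5 by any aneuploidy present in the mixture;
* per-arm mean coverage for tumor and matched normal, scaled by mean copy
  number.

By default the genotype conventions are the exact inverse of the read-count
correction formulas applied downstream: a duplication gains the wild-type
chromatid (1 mutant of 3 copies), a deletion removes the wild-type chromatid
(1 of 1), and copy-neutral LOH retains the mutant haplotype (2 of 2).  Flags
on :class:`SimulationConfig` flip these assumptions for robustness testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TrueTumor",
    "SimulatedCohort",
    "simulate_clone_tree",
    "assign_mutations",
    "simulate_region_mixtures",
    "expected_vaf",
    "simulate_read_counts",
    "simulate_baf_sites",
    "simulate_cohort",
    "write_cohort",
    "read_truth_json",
    "DEFAULT_DRIVER_TEMPLATE",
]

NORMAL = 0  #: clone id of the normal-cell root

#: canonical arm names used when the config asks for ``n_arms`` arms
_ARM_POOL = [
    "1p", "1q", "2p", "2q", "3p", "3q", "4p", "4q", "5p", "5q",
    "6p", "6q", "7p", "7q", "8p", "8q", "9p", "9q", "10p", "10q",
    "11p", "11q", "12p", "12q", "13q", "14q", "15q", "16p", "16q",
    "17p", "17q", "18p", "18q", "19p", "19q", "20p", "20q", "21q", "22q",
]

EVENTS = ("duplication", "deletion", "cn_loh")

#: an oncohistone-like truncal driver with an obligate truncal partner
DEFAULT_DRIVER_TEMPLATE = [("H3F3A", "truncal"), ("TP53", "truncal")]


class InvalidConfigError(ValueError):
    pass


class UndefinedVAFError(ValueError):
    """Raised when the mixture-weighted locus copy number is zero."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic patient cohort.

    ``mean_depth`` applies to the somatic variant counts; ``baf_depth`` to
    the germline het sites and arm coverage (exome-like by default even when
    the variants are deep-amplicon).
    """

    n_clones: int = 4
    n_regions: int = 6
    mutations_per_clone: int = 10
    mean_depth: float = 70.0
    baf_depth: float = 70.0
    purity_range: Tuple[float, float] = (0.7, 0.9)
    n_arms: int = 10
    cnv_rate: float = 0.3
    het_sites_per_arm: int = 100
    dropout_prob: float = 0.2
    dirichlet_alpha: float = 1.0
    mutant_on_gained_copy: bool = False
    mutant_retained: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1:
            raise InvalidConfigError("n_clones must be >= 1")
        if self.n_regions < 1:
            raise InvalidConfigError("n_regions must be >= 1")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidConfigError("purity_range must satisfy 0 <= low <= high <= 1")
        if self.mean_depth <= 0 or self.baf_depth <= 0:
            raise InvalidConfigError("depths must be > 0")
        if self.n_arms < 1 or self.n_arms > len(_ARM_POOL):
            raise InvalidConfigError(f"n_arms must be in [1, {len(_ARM_POOL)}]")
        if self.mutations_per_clone < 0:
            raise InvalidConfigError("mutations_per_clone must be >= 0")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise InvalidConfigError("dropout_prob must be in [0, 1]")

    @property
    def arms(self) -> List[str]:
        return _ARM_POOL[: self.n_arms]


@dataclass
class TrueTumor:
    """Ground truth of a simulated patient.

    ``parent`` maps each tumor clone id to its parent (clone 1, the truncal
    clone, has parent 0 = normal).  ``region_mixtures`` maps region name to
    ``{clone_id: fraction}`` including the normal component under key 0; the
    fractions of each region sum to 1.
    """

    parent: Dict[int, int]
    mutation_clone: Dict[str, int] = field(default_factory=dict)
    mutation_arm: Dict[str, str] = field(default_factory=dict)
    mutation_gene: Dict[str, str] = field(default_factory=dict)
    driver_labels: Dict[str, str] = field(default_factory=dict)
    region_mixtures: Dict[str, Dict[int, float]] = field(default_factory=dict)
    cnv_assignment: Dict[Tuple[int, str], str] = field(default_factory=dict)
    mutant_on_gained_copy: bool = False
    mutant_retained: bool = True

    @property
    def clones(self) -> List[int]:
        return sorted(self.parent)

    @property
    def regions(self) -> List[str]:
        return list(self.region_mixtures)

    def children(self, clone: int) -> List[int]:
        return [c for c, p in self.parent.items() if p == clone]

    def subtree(self, clone: int) -> set:
        out, stack = set(), [clone]
        while stack:
            c = stack.pop()
            out.add(c)
            stack.extend(self.children(c))
        return out

    def ancestors(self, clone: int) -> List[int]:
        """Path from ``clone`` up to (excluding) the normal root."""
        path = []
        while clone != NORMAL:
            path.append(clone)
            clone = self.parent[clone]
        return path

    def effective_event(self, clone: int, arm: str) -> str:
        """CNV state of ``arm`` in cells of ``clone``: the event carried by the
        nearest ancestor (including itself) with an assignment, else neutral."""
        for c in self.ancestors(clone):
            ev = self.cnv_assignment.get((c, arm))
            if ev is not None:
                return ev
        return "neutral"


def simulate_clone_tree(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None) -> TrueTumor:
    """Rooted clone tree: normal root, one truncal clone, remaining clones
    attached uniformly at random among existing tumor clones."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    parent = {1: NORMAL}
    for c in range(2, config.n_clones + 1):
        parent[c] = int(rng.integers(1, c))
    return TrueTumor(parent=parent,
                     mutant_on_gained_copy=config.mutant_on_gained_copy,
                     mutant_retained=config.mutant_retained)


def assign_mutations(tumor: TrueTumor, config: SimulationConfig,
                     driver_template: Sequence[Tuple[str, object]] = (),
                     rng: Optional[np.random.Generator] = None) -> None:
    """Give each clone its anonymous passenger mutations plus template drivers.

    Template entries are ``(gene_label, role)`` where role is ``"truncal"``,
    ``"subclone"`` (a random non-truncal clone) or an explicit clone id.
    Truncal template drivers are labelled main drivers; subclonal ones
    accessory drivers; everything else passenger.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    arms = config.arms
    clones = tumor.clones
    mid = 0
    for clone in clones:
        for _ in range(config.mutations_per_clone):
            mid += 1
            m = f"m{mid:04d}"
            tumor.mutation_clone[m] = clone
            tumor.mutation_arm[m] = arms[int(rng.integers(len(arms)))]
            tumor.mutation_gene[m] = f"GENE{mid:04d}"
            tumor.driver_labels[m] = "passenger"
    subclones = [c for c in clones if c != 1]
    for gene, role in driver_template:
        if role == "truncal":
            clone = 1
        elif role == "subclone":
            if not subclones:
                raise InvalidConfigError("driver template asks for a subclone "
                                         "but the tree has only the truncal clone")
            clone = int(subclones[int(rng.integers(len(subclones)))])
        else:
            clone = int(role)  # type: ignore[arg-type]
            if clone not in tumor.parent:
                raise InvalidConfigError(f"driver template references absent clone {clone}")
        tumor.mutation_clone[gene] = clone
        tumor.mutation_arm[gene] = arms[int(rng.integers(len(arms)))]
        tumor.mutation_gene[gene] = gene
        tumor.driver_labels[gene] = "main_driver" if clone == 1 else "accessory_driver"


def assign_cnv_events(tumor: TrueTumor, config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None) -> None:
    """Assign Poisson(cnv_rate) arm-level events per clone, one event per
    (clone, arm) at most, event types uniform over dup/del/CN-LOH."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    arms = config.arms
    for clone in tumor.clones:
        n_events = int(rng.poisson(config.cnv_rate))
        n_events = min(n_events, len(arms))
        if n_events == 0:
            continue
        chosen = rng.choice(len(arms), size=n_events, replace=False)
        for idx in np.atleast_1d(chosen):
            arm = arms[int(idx)]
            if (clone, arm) in tumor.cnv_assignment:
                continue
            tumor.cnv_assignment[(clone, arm)] = EVENTS[int(rng.integers(len(EVENTS)))]


def simulate_region_mixtures(tumor: TrueTumor, config: SimulationConfig,
                             rng: Optional[np.random.Generator] = None) -> None:
    """Per region: purity ~ U(purity_range), tumor mass split over clones by a
    symmetric Dirichlet draw, normal cells take the remainder.

    Each non-truncal clone is zeroed ("dropped out") of a region with
    probability ``dropout_prob`` to create spatial heterogeneity; a clone
    dropped from every region is restored in one random region so that every
    clone is observable somewhere in the patient.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    clones = tumor.clones
    k = len(clones)
    regions = [f"R{i + 1}" for i in range(config.n_regions)]

    keep = np.ones((config.n_regions, k), dtype=bool)
    for j, clone in enumerate(clones):
        if clone == 1:
            continue  # the truncal clone is never dropped
        keep[:, j] = rng.random(config.n_regions) >= config.dropout_prob
        if not keep[:, j].any():
            keep[int(rng.integers(config.n_regions)), j] = True

    lo, hi = config.purity_range
    for i, region in enumerate(regions):
        purity = float(rng.uniform(lo, hi))
        w = rng.dirichlet(np.full(k, config.dirichlet_alpha))
        w = w * keep[i]
        if w.sum() == 0:  # only possible if truncal weight drawn exactly 0
            w[clones.index(1)] = 1.0
        w = w / w.sum() * purity
        mix = {clone: float(w[j]) for j, clone in enumerate(clones)}
        mix[NORMAL] = 1.0 - purity
        tumor.region_mixtures[region] = mix


def _copies(event: str, carrier: bool, mutant_on_gained_copy: bool,
            mutant_retained: bool) -> Tuple[int, int]:
    """(total copies, mutant copies) of the locus in one cell."""
    if event == "neutral":
        return 2, 1 if carrier else 0
    if event == "duplication":
        if not carrier:
            return 3, 0
        return 3, 2 if mutant_on_gained_copy else 1
    if event == "deletion":
        if not carrier:
            return 1, 0
        return 1, 1 if mutant_retained else 0
    if event == "cn_loh":
        if not carrier:
            return 2, 0
        return 2, 2 if mutant_retained else 0
    raise ValueError(f"unknown CNV event {event!r}")


def expected_vaf(mutation_id: str, region: str, tumor: TrueTumor) -> float:
    """Closed-form expected variant allele fraction of a mutation in a region.

    Mutant copies carried by clones at/below the mutation's clone, weighted by
    the region mixture, divided by total locus copies weighted the same way.
    """
    clone = tumor.mutation_clone[mutation_id]
    arm = tumor.mutation_arm[mutation_id]
    carriers = tumor.subtree(clone)
    mix = tumor.region_mixtures[region]
    total = 2.0 * mix.get(NORMAL, 0.0)
    mutant = 0.0
    for c in tumor.clones:
        w = mix.get(c, 0.0)
        if w == 0.0:
            continue
        tot, mut = _copies(tumor.effective_event(c, arm), c in carriers,
                           tumor.mutant_on_gained_copy, tumor.mutant_retained)
        total += w * tot
        mutant += w * mut
    if total <= 0:
        raise UndefinedVAFError(f"zero mixture-weighted copy number for "
                                f"{mutation_id} in {region}")
    return mutant / total


def simulate_read_counts(exp_vaf: float, mean_depth: float,
                         rng: np.random.Generator) -> Tuple[int, int]:
    """Depth ~ Poisson(mean_depth); alt ~ Binomial(depth, expected VAF)."""
    if mean_depth <= 0:
        raise InvalidConfigError("mean_depth must be > 0")
    if not (0.0 <= exp_vaf <= 1.0):
        raise ValueError("expected VAF must lie in [0, 1]")
    depth = int(rng.poisson(mean_depth))
    alt = int(rng.binomial(depth, exp_vaf)) if depth > 0 else 0
    return depth - alt, alt


#: copies of (altered haplotype, other haplotype) per germline het site
_HAP_COPIES = {"neutral": (1, 1), "duplication": (2, 1),
               "deletion": (0, 1), "cn_loh": (0, 2)}


def arm_clonal_state(region: str, arm: str, tumor: TrueTumor) -> Tuple[float, float]:
    """(expected BAF of the allele on the altered haplotype, mean copy number)
    of an arm in one region, mixing over clones and normal cells."""
    mix = tumor.region_mixtures[region]
    alt_c = 1.0 * mix.get(NORMAL, 0.0)
    tot_c = 2.0 * mix.get(NORMAL, 0.0)
    for c in tumor.clones:
        w = mix.get(c, 0.0)
        if w == 0.0:
            continue
        a, b = _HAP_COPIES[tumor.effective_event(c, arm)]
        alt_c += w * a
        tot_c += w * (a + b)
    return alt_c / tot_c, tot_c


def simulate_baf_sites(region: str, tumor: TrueTumor, config: SimulationConfig,
                       rng: np.random.Generator):
    """Germline het-site allele counts and arm coverage for one region.

    Returns ``(het_rows, coverage_rows)`` where het rows are
    ``(arm, chrom, pos, a_count, b_count)`` and coverage rows
    ``(arm, tumor_mean, normal_mean)``.  Each site's B allele lies on the
    CNV-altered haplotype with probability 1/2; site depth is Poisson with
    mean scaled by the arm's mean copy number over 2.
    """
    het_rows, cov_rows = [], []
    for arm in config.arms:
        baf_alt, cn = arm_clonal_state(region, arm, tumor)
        n = config.het_sites_per_arm
        on_altered = rng.random(n) < 0.5
        baf = np.where(on_altered, baf_alt, 1.0 - baf_alt)
        depth = rng.poisson(config.baf_depth * cn / 2.0, size=n)
        b = rng.binomial(depth, baf)
        chrom = arm.rstrip("pq")
        start = 1 if arm.endswith("p") else 10_000_001
        for j in range(n):
            het_rows.append((arm, chrom, start + j * 1000,
                             int(depth[j] - b[j]), int(b[j])))
        normal_depth = rng.poisson(config.baf_depth, size=n)
        cov_rows.append((arm, float(depth.mean()), float(normal_depth.mean())))
    return het_rows, cov_rows


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    tumor: TrueTumor
    variants: pd.DataFrame      # mutation_id gene chrom pos arm sample_id ref_count alt_count
    het_sites: pd.DataFrame     # sample_id arm chrom pos a_count b_count
    arm_coverage: pd.DataFrame  # sample_id arm tumor_mean normal_mean


def simulate_cohort(config: SimulationConfig,
                    driver_template: Optional[Sequence[Tuple[str, object]]] = None,
                    tree: Optional[Mapping[int, int]] = None,
                    region_mixtures: Optional[Mapping[str, Mapping[int, float]]] = None,
                    ) -> SimulatedCohort:
    """End-to-end generation of one patient cohort.

    ``tree`` and ``region_mixtures`` override the random draws with explicit
    ground truth (used to build fixed textbook fixtures such as the branching
    two-subclone pattern).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if driver_template is None:
        driver_template = DEFAULT_DRIVER_TEMPLATE

    if tree is not None:
        tumor = TrueTumor(parent=dict(tree),
                          mutant_on_gained_copy=config.mutant_on_gained_copy,
                          mutant_retained=config.mutant_retained)
        if sorted(tumor.parent) != list(range(1, len(tumor.parent) + 1)) or tumor.parent[1] != NORMAL:
            raise InvalidConfigError("explicit tree must label clones 1..k with clone 1 truncal")
    else:
        tumor = simulate_clone_tree(config, rng)
    assign_mutations(tumor, config, driver_template, rng)
    assign_cnv_events(tumor, config, rng)
    if region_mixtures is not None:
        for region, mix in region_mixtures.items():
            mix = {int(k): float(v) for k, v in mix.items()}
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9 or min(mix.values()) < 0:
                raise InvalidConfigError(f"mixture of {region} must be nonnegative and sum to 1")
            tumor.region_mixtures[region] = mix
    else:
        simulate_region_mixtures(tumor, config, rng)

    mutations = list(tumor.mutation_clone)
    arms = config.arms
    pos_of = {m: 1_000_000 + i * 137 for i, m in enumerate(mutations)}
    var_rows = []
    for region in tumor.regions:
        for m in mutations:
            v = expected_vaf(m, region, tumor)
            ref, alt = simulate_read_counts(v, config.mean_depth, rng)
            arm = tumor.mutation_arm[m]
            var_rows.append((m, tumor.mutation_gene[m], arm.rstrip("pq"),
                             pos_of[m], arm, region, ref, alt))
    variants = pd.DataFrame(var_rows, columns=[
        "mutation_id", "gene", "chrom", "pos", "arm", "sample_id",
        "ref_count", "alt_count"])

    het_rows, cov_rows = [], []
    for region in tumor.regions:
        hets, covs = simulate_baf_sites(region, tumor, config, rng)
        het_rows += [(region,) + r for r in hets]
        cov_rows += [(region,) + r for r in covs]
    het_sites = pd.DataFrame(het_rows, columns=[
        "sample_id", "arm", "chrom", "pos", "a_count", "b_count"])
    arm_coverage = pd.DataFrame(cov_rows, columns=[
        "sample_id", "arm", "tumor_mean", "normal_mean"])
    return SimulatedCohort(config, tumor, variants, het_sites, arm_coverage)


def write_cohort(cohort: SimulatedCohort, directory) -> Dict[str, Path]:
    """Write the three input tables plus the ground-truth JSON; lossless."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": directory / "variants.tsv",
        "het_sites": directory / "het_sites.tsv",
        "arm_coverage": directory / "arm_coverage.tsv",
        "truth": directory / "truth.json",
    }
    cohort.variants.to_csv(paths["variants"], sep="\t", index=False)
    cohort.het_sites.to_csv(paths["het_sites"], sep="\t", index=False)
    cohort.arm_coverage.to_csv(paths["arm_coverage"], sep="\t",
                               index=False, float_format="%.6f")
    t = cohort.tumor
    truth = {
        "parent": {str(k): v for k, v in t.parent.items()},
        "mutation_clone": t.mutation_clone,
        "mutation_arm": t.mutation_arm,
        "mutation_gene": t.mutation_gene,
        "driver_labels": t.driver_labels,
        "region_mixtures": {r: {str(c): f for c, f in mix.items()}
                            for r, mix in t.region_mixtures.items()},
        "cnv_assignment": [{"clone": c, "arm": a, "event": e}
                           for (c, a), e in sorted(t.cnv_assignment.items())],
        "mutant_on_gained_copy": t.mutant_on_gained_copy,
        "mutant_retained": t.mutant_retained,
        "config": asdict(cohort.config),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def read_truth_json(path) -> TrueTumor:
    d = json.loads(Path(path).read_text())
    return TrueTumor(
        parent={int(k): v for k, v in d["parent"].items()},
        mutation_clone=d["mutation_clone"],
        mutation_arm=d["mutation_arm"],
        mutation_gene=d["mutation_gene"],
        driver_labels=d["driver_labels"],
        region_mixtures={r: {int(c): f for c, f in mix.items()}
                         for r, mix in d["region_mixtures"].items()},
        cnv_assignment={(e["clone"], e["arm"]): e["event"]
                        for e in d["cnv_assignment"]},
        mutant_on_gained_copy=d["mutant_on_gained_copy"],
        mutant_retained=d["mutant_retained"],
    )
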