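"""Seeded simulation studies quantifying pipeline performance.

Each function generates cohorts with the synthetic-data module, runs the
relevant pipeline stage end to end, and measures recovery against the known
ground truth.  They back both the test suite and ``scripts/acceptance.py``.

Problem sizes are desk-scale by design: tree recovery uses 4-clone,
6-region cohorts at deep-amplicon depth; the CNV study uses 100 het sites
per arm at exome depth; the noiseless study covers trees of up to 5 clones.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .simulate import (SimulationConfig, TrueTumor, simulate_cohort,
                       simulate_baf_sites, simulate_clone_tree, NORMAL)
from .io import observations_from_frame, build_presence_matrix
from .cnv import call_cnv_profile, CNVThresholds, NEUTRAL, UNEVALUABLE
from .correction import apply_corrections, CorrectedCounts
from .clonetree import (estimate_ccf, cluster_mutations,
                        clusters_from_assignment, fit_tree, CloneTree)
from .ordering import build_partial_order, detect_obligate_partners

__all__ = [
    "tree_recovery_study", "branching_pattern_study", "noiseless_instances",
    "noiseless_equivalence_study", "cnv_detection_study",
    "ddpcr_calibration_study", "match_clusters_to_clones",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent sub-seeds below 2^31 derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def match_clusters_to_clones(tree: CloneTree, tumor: TrueTumor
                             ) -> Optional[Dict[int, int]]:
    """Majority-vote map cluster id -> true clone id; None unless bijective."""
    mapping: Dict[int, int] = {}
    for c in tree.clusters:
        votes: Dict[int, int] = {}
        for m in c.members:
            clone = tumor.mutation_clone.get(m)
            if clone is not None:
                votes[clone] = votes.get(clone, 0) + 1
        if not votes:
            return None
        mapping[c.cluster_id] = max(votes, key=lambda k: (votes[k], -k))
    if len(set(mapping.values())) != len(mapping):
        return None
    return mapping


def _topology_matches(tree: CloneTree, tumor: TrueTumor,
                      mapping: Dict[int, int]) -> bool:
    if len(mapping) != len(tumor.parent):
        return False
    for cluster, parent in tree.parent.items():
        true_parent = NORMAL if parent == 0 else mapping[parent]
        if tumor.parent[mapping[cluster]] != true_parent:
            return False
    return True


def _mixing_mae(tree: CloneTree, tumor: TrueTumor,
                mapping: Dict[int, int]) -> float:
    errs = []
    for region in tumor.regions:
        true_mix = tumor.region_mixtures[region]
        for cluster, clone in mapping.items():
            errs.append(abs(float(tree.mixing.at[cluster, region])
                            - true_mix.get(clone, 0.0)))
        errs.append(abs(float(tree.mixing.at["normal", region])
                        - true_mix.get(NORMAL, 0.0)))
    return float(np.mean(errs))


def run_cohort_pipeline(cohort, seed: int = 0, k_max: int = 6,
                        call_cnv: bool = True):
    """Counts -> CNV calls -> corrected counts -> CCF -> clusters -> tree."""
    obs = observations_from_frame(cohort.variants)
    calls = (call_cnv_profile(cohort.het_sites, cohort.arm_coverage, seed=seed)
             if call_cnv else None)
    corrected = apply_corrections(obs, calls, strict=False)
    ccf = estimate_ccf(corrected)
    clustering = cluster_mutations(ccf, k_max=k_max, seed=seed)
    tree = fit_tree(ccf, clustering.clusters)
    return ccf, clustering, tree, calls


def tree_recovery_study(n_cohorts: int = 100, seed: int = 0,
                        n_clones: int = 4, n_regions: int = 6,
                        mutations_per_clone: int = 50,
                        depth: float = 4000.0,
                        purity_range: Tuple[float, float] = (0.7, 0.9),
                        k_max: int = 6) -> Dict[str, float]:
    """Exact-topology recovery and mixing-proportion error over seeded
    multi-region cohorts run through the full pipeline."""
    seeds = _child_seeds(seed, n_cohorts)
    n_recovered = 0
    maes: List[float] = []
    for si in seeds:
        cfg = SimulationConfig(n_clones=n_clones, n_regions=n_regions,
                               mutations_per_clone=mutations_per_clone,
                               mean_depth=depth, purity_range=purity_range,
                               cnv_rate=0.0, seed=int(si))
        cohort = simulate_cohort(cfg)
        _, clustering, tree, _ = run_cohort_pipeline(cohort, seed=int(si),
                                                     k_max=k_max)
        mapping = match_clusters_to_clones(tree, cohort.tumor)
        if mapping is not None and _topology_matches(tree, cohort.tumor, mapping):
            n_recovered += 1
            maes.append(_mixing_mae(tree, cohort.tumor, mapping))
    return {
        "n_cohorts": n_cohorts,
        "n_recovered": n_recovered,
        "recovery_rate": n_recovered / n_cohorts,
        "mixing_mae": float(np.mean(maes)) if maes else float("nan"),
    }


# ---------------------------------------------------------------------------
# branching oncohistone-partner fixture (truncal histone mutation, two
# complementary sibling subclones carrying distinct partner drivers)

_BRANCH_TREE = {1: 0, 2: 1, 3: 1}
_BRANCH_TEMPLATE = [("H3F3A", "truncal"), ("TP53", 2), ("PPM1D", 3)]


def _branch_mixtures(n_regions: int = 6) -> Dict[str, Dict[int, float]]:
    mix = {}
    for i in range(n_regions):
        if i < n_regions // 2:
            mix[f"R{i + 1}"] = {NORMAL: 0.2, 1: 0.2, 2: 0.6, 3: 0.0}
        else:
            mix[f"R{i + 1}"] = {NORMAL: 0.2, 1: 0.2, 2: 0.0, 3: 0.6}
    return mix


def simulate_branching_fixture(seed: int, depth: float = 4000.0,
                               n_regions: int = 6):
    """A patient with a truncal oncohistone-like mutation and two sibling
    subclones carrying complementary partner drivers."""
    cfg = SimulationConfig(n_clones=3, n_regions=n_regions,
                           mutations_per_clone=10, mean_depth=depth,
                           cnv_rate=0.0, seed=seed)
    return simulate_cohort(cfg, driver_template=_BRANCH_TEMPLATE,
                           tree=_BRANCH_TREE,
                           region_mixtures=_branch_mixtures(n_regions))


def branching_pattern_study(n_seeds: int = 20, seed: int = 0,
                            depth: float = 4000.0) -> Dict[str, float]:
    """Does the pipeline report the oncohistone as sole root, the partner
    pair as incomparable sibling events, and the partnership as obligate via
    complementary subclones?"""
    seeds = _child_seeds(seed, n_seeds)
    n_root = n_incomp = n_obligate = n_all = 0
    drivers = ["H3F3A", "TP53", "PPM1D"]
    for si in seeds:
        cohort = simulate_branching_fixture(int(si), depth=depth)
        obs = observations_from_frame(cohort.variants)
        corrected = apply_corrections(obs, None)
        ccf = estimate_ccf(corrected)
        order = build_partial_order(ccf, drivers)
        presence = build_presence_matrix(obs, mode="amplicon")
        report = detect_obligate_partners(presence, "H3F3A",
                                          partner_genes=("TP53", "PPM1D"),
                                          tumor_samples=list(cohort.tumor.regions))
        ok_root = order.roots == ["H3F3A"]
        ok_incomp = ("TP53", "PPM1D") in order.incomparable
        ok_partner = report.obligate and report.complementary
        n_root += ok_root
        n_incomp += ok_incomp
        n_obligate += ok_partner
        n_all += ok_root and ok_incomp and ok_partner
    return {"n_seeds": n_seeds, "n_root_correct": n_root,
            "n_incomparable": n_incomp, "n_obligate_complementary": n_obligate,
            "n_all_correct": n_all}


# ---------------------------------------------------------------------------
# noiseless exhaustive-equivalence instances

def _clone_freqs(tumor: TrueTumor, clones: List[int],
                 regions: List[str]) -> np.ndarray:
    F = np.zeros((len(clones), len(regions)))
    for i, c in enumerate(clones):
        sub = tumor.subtree(c)
        for j, r in enumerate(regions):
            F[i, j] = sum(tumor.region_mixtures[r].get(s, 0.0) for s in sub)
    return F


def _identifiable(tumor: TrueTumor, eps: float = 1e-3) -> bool:
    """Mixtures allow frequency-based order recovery: every non-nested clone
    pair out-dominates each other somewhere; every strict ancestor has a
    strict margin somewhere."""
    clones = tumor.clones
    regions = tumor.regions
    F = _clone_freqs(tumor, clones, regions)
    for i, j in itertools.combinations(range(len(clones)), 2):
        ci, cj = clones[i], clones[j]
        i_anc = ci in set(tumor.ancestors(cj))
        j_anc = cj in set(tumor.ancestors(ci))
        d = F[i] - F[j]
        if i_anc:
            if not np.any(d > eps):
                return False
        elif j_anc:
            if not np.any(-d > eps):
                return False
        else:
            if not (np.any(d > eps) and np.any(-d > eps)):
                return False
    return True


def noiseless_instances(n_instances: int, seed: int = 0, max_clones: int = 5,
                        n_regions: int = 6, muts_per_clone: int = 3,
                        pseudo_depth: float = 10_000.0,
                        max_tries: int = 1000) -> Iterator[dict]:
    """Random noiseless multi-region instances with identifiable mixtures.

    Yields dicts with the true parent map, the exact CCF matrix (real-valued
    counts, no sampling noise), ground-truth clusters, the cluster -> clone
    map and the true ancestor relation over mutations.
    """
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        k = int(rng.integers(2, max_clones + 1))
        cfg = SimulationConfig(n_clones=k, n_regions=n_regions,
                               mutations_per_clone=muts_per_clone,
                               cnv_rate=0.0, dropout_prob=0.0,
                               purity_range=(0.6, 0.95),
                               seed=int(rng.integers(2 ** 31)))
        for _ in range(max_tries):
            tumor = simulate_clone_tree(cfg, rng)
            from .simulate import assign_mutations, simulate_region_mixtures
            assign_mutations(tumor, cfg, driver_template=(), rng=rng)
            simulate_region_mixtures(tumor, cfg, rng=rng)
            if _identifiable(tumor):
                break
        else:
            raise RuntimeError("could not draw identifiable mixtures")
        regions = tumor.regions
        clones = tumor.clones
        F = _clone_freqs(tumor, clones, regions)
        corrected = []
        for m, clone in tumor.mutation_clone.items():
            f = F[clones.index(clone)]
            for j, r in enumerate(regions):
                vaf = f[j] / 2.0
                corrected.append(CorrectedCounts(
                    m, r, ref_prime=(1 - vaf) * pseudo_depth,
                    alt_prime=vaf * pseudo_depth,
                    event_applied="none", corrected_vaf=vaf))
        ccf = estimate_ccf(corrected, round_counts=False)
        clusters = clusters_from_assignment(ccf, tumor.mutation_clone)
        clone_of_cluster = {c.cluster_id: tumor.mutation_clone[c.members[0]]
                            for c in clusters}
        anc_pairs = set()
        for a, ca in tumor.mutation_clone.items():
            for b, cb in tumor.mutation_clone.items():
                if a != b and ca != cb and ca in set(tumor.ancestors(cb)):
                    anc_pairs.add((a, b))
        yield {"tumor": tumor, "ccf": ccf, "clusters": clusters,
               "clone_of_cluster": clone_of_cluster,
               "true_ancestor_pairs": anc_pairs, "k": k}


def noiseless_equivalence_study(n_instances: int = 200, seed: int = 0,
                                max_clones: int = 5) -> Dict[str, float]:
    """On noiseless identifiable input: does the fitted tree reproduce the
    true topology and the inferred partial order the true ancestor relation?"""
    n_topo = n_order = 0
    for inst in noiseless_instances(n_instances, seed, max_clones):
        tumor = inst["tumor"]
        tree = fit_tree(inst["ccf"], inst["clusters"])
        mapping = inst["clone_of_cluster"]
        if _topology_matches(tree, tumor, mapping):
            n_topo += 1
        order = build_partial_order(inst["ccf"], list(tumor.mutation_clone),
                                    tolerance=1e-9)
        closure = order.ancestors_closure()
        if closure == inst["true_ancestor_pairs"]:
            n_order += 1
    return {"n_instances": n_instances, "n_topology_match": n_topo,
            "n_order_match": n_order,
            "order_match_rate": n_order / n_instances}


# ---------------------------------------------------------------------------
# arm-level CNV calling power / specificity

def simulate_arm_batch(event: Optional[str], fraction: float, seed: int,
                       n_sites: int = 100, depth: float = 70.0,
                       n_arms: int = 10):
    """One sample with ``n_arms`` arms, the first carrying ``event`` at the
    given clonal fraction (None = all neutral); returns het + coverage frames."""
    cfg = SimulationConfig(n_clones=1, n_regions=1, mutations_per_clone=0,
                           baf_depth=depth, het_sites_per_arm=n_sites,
                           n_arms=n_arms, cnv_rate=0.0, dropout_prob=0.0,
                           purity_range=(fraction, fraction), seed=seed)
    tumor = TrueTumor(parent={1: 0})
    tumor.region_mixtures["R1"] = {1: fraction, NORMAL: 1.0 - fraction}
    if event is not None:
        tumor.cnv_assignment[(1, cfg.arms[0])] = event
    rng = np.random.default_rng(seed)
    het_rows, cov_rows = simulate_baf_sites("R1", tumor, cfg, rng)
    sample = f"S{seed}"
    het = pd.DataFrame([(sample,) + r for r in het_rows],
                       columns=["sample_id", "arm", "chrom", "pos",
                                "a_count", "b_count"])
    cov = pd.DataFrame([(sample,) + r for r in cov_rows],
                       columns=["sample_id", "arm", "tumor_mean", "normal_mean"])
    return het, cov


def cnv_detection_study(seed: int = 0, n_event: int = 120, n_null: int = 500,
                        n_sites: int = 100, depth: float = 70.0,
                        fraction_range: Tuple[float, float] = (0.6, 1.0),
                        thresholds: CNVThresholds = CNVThresholds()
                        ) -> Dict[str, float]:
    """Sensitivity on clonal-fraction >= 0.6 events, false-positive rate on
    balanced diploid arms, and duplication/deletion type confusion when the
    coverage signal is strong (|log2 ratio| >= 2 x threshold)."""
    rng = np.random.default_rng(seed)
    events = ["duplication", "deletion", "cn_loh"]
    n_correct = n_detected = 0
    confusions = 0
    n_strong = 0
    for i in range(n_event):
        ev = events[i % 3]
        frac = float(rng.uniform(*fraction_range))
        s = int(rng.integers(2 ** 31))
        het, cov = simulate_arm_batch(ev, frac, s, n_sites, depth)
        calls = call_cnv_profile(het, cov, thresholds, seed=s)
        call = next(c for c in calls if c.arm == het["arm"].iloc[0])
        if call.event not in (NEUTRAL, UNEVALUABLE):
            n_detected += 1
        if call.event == ev:
            n_correct += 1
        if ev in ("duplication", "deletion") and \
                abs(call.stats.log2_coverage_ratio) >= 2 * thresholds.t_cov:
            n_strong += 1
            if (ev == "duplication" and call.event == "deletion") or \
               (ev == "deletion" and call.event == "duplication"):
                confusions += 1
    n_fp = 0
    n_null_arms = 0
    batches = (n_null + 9) // 10
    for _ in range(batches):
        s = int(rng.integers(2 ** 31))
        het, cov = simulate_arm_batch(None, 0.8, s, n_sites, depth)
        calls = call_cnv_profile(het, cov, thresholds, seed=s)
        for c in calls:
            if n_null_arms >= n_null:
                break
            n_null_arms += 1
            if c.event not in (NEUTRAL, UNEVALUABLE):
                n_fp += 1
    return {"n_event_arms": n_event,
            "sensitivity": n_correct / n_event,
            "detection_rate": n_detected / n_event,
            "n_null_arms": n_null_arms,
            "false_positive_rate": n_fp / n_null_arms,
            "n_strong_coverage": n_strong,
            "dup_del_confusions": confusions}


# ---------------------------------------------------------------------------
# ddPCR calibration

def ddpcr_calibration_study(seed: int = 0, n_reps: int = 1000,
                            lam: float = 0.5, n_droplets: int = 15_000,
                            mutant_frac: float = 0.30,
                            lam_total: float = 0.8) -> Dict[str, float]:
    """Monte-Carlo partitioning: bias of the occupancy estimate and coverage
    of the delta-method mutant-fraction interval."""
    from .ddpcr import DropletAssay, mutant_fraction

    rng = np.random.default_rng(seed)
    p = 1.0 - np.exp(-lam)
    pos = rng.binomial(n_droplets, p, size=n_reps)
    lam_hat = -np.log1p(-pos / n_droplets)
    mean_lambda = float(lam_hat.mean())

    lam_m = mutant_frac * lam_total
    lam_w = (1.0 - mutant_frac) * lam_total
    pm = 1.0 - np.exp(-lam_m)
    pw = 1.0 - np.exp(-lam_w)
    pos_m = rng.binomial(n_droplets, pm, size=n_reps)
    pos_w = rng.binomial(n_droplets, pw, size=n_reps)
    covered = 0
    target = 100.0 * mutant_frac
    for m, w in zip(pos_m, pos_w):
        _, (lo, hi) = mutant_fraction(DropletAssay(int(m), n_droplets),
                                      DropletAssay(int(w), n_droplets,
                                                   channel="wildtype"))
        covered += lo <= target <= hi
    return {"true_lambda": lam, "mean_lambda_hat": mean_lambda,
            "lambda_relative_bias": abs(mean_lambda - lam) / lam,
            "n_reps": n_reps,
            "ci_coverage": covered / n_reps}
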