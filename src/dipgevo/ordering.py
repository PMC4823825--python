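"""Temporal ordering of mutations and spatial/driver classification.

Ordering uses the pigeonhole logic of multi-region frequencies: a mutation
whose cellular frequency is at least that of another in *every* shared
region, and strictly greater in at least one, is the earlier event; two
mutations that exceed each other in different regions must live on distinct
branches (incomparable); frequencies equal everywhere leave the order
unresolved.  The comparison tolerance defaults to twice the pooled binomial
standard error of the frequency difference, so deep-amplicon and exome data
are compared on their own noise scales.

Spatial classes follow the ubiquitous / shared / private trichotomy
(present in all evaluable tumor samples / in at least two but not all /
in exactly one), and driver categories the three-way split into main
drivers (truncal, ubiquitous, in the driver-gene list), accessory drivers
(listed gene, subclonal or non-ubiquitous) and passengers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .clonetree import CCFMatrix, CloneTree
from .io import PresenceMatrix, PRESENT, UNEVALUABLE

__all__ = [
    "A_FIRST", "B_FIRST", "UNRESOLVED", "INCOMPARABLE", "UNEVALUABLE_PAIR",
    "PartialOrder", "MutationClassification", "PartnershipReport",
    "DEFAULT_DRIVER_GENES",
    "pairwise_order", "build_partial_order", "classify_spatial",
    "classify_driver", "classify_mutations", "detect_obligate_partners",
    "infer_tumor_samples",
]

A_FIRST = "A_first"
B_FIRST = "B_first"
UNRESOLVED = "unresolved"
INCOMPARABLE = "incomparable"
UNEVALUABLE_PAIR = "unevaluable"

UBIQUITOUS = "ubiquitous"
SHARED = "shared"
PRIVATE = "private"

MAIN_DRIVER = "main_driver"
ACCESSORY_DRIVER = "accessory_driver"
PASSENGER = "passenger"

#: recurrent driver genes of H3K27M gliomas (configurable; data, not code)
DEFAULT_DRIVER_GENES = ("H3F3A", "HIST1H3B", "HIST2H3C", "TP53", "PPM1D",
                        "ACVR1", "PIK3R1", "PIK3CA", "ATRX", "PTEN")

ONCOHISTONE_GENES = ("H3F3A", "HIST1H3B", "HIST2H3C")


def _pair_tolerance(ccf: CCFMatrix, a: str, b: str, samples) -> np.ndarray:
    """2 x pooled binomial SE of the CCF difference, per shared sample."""
    tol = np.empty(len(samples))
    for j, s in enumerate(samples):
        var = 0.0
        for m in (a, b):
            d = float(ccf.depth.at[m, s])
            v = float(ccf.alt.at[m, s]) / d if d > 0 else 0.0
            var += v * (1 - v) / max(d, 1.0)
        # CCF = 2 * vaf / purity
        scale = 2.0 / float(ccf.purity[s])
        tol[j] = 2.0 * scale * math.sqrt(var)
    return tol


def pairwise_order(a: str, b: str, ccf: CCFMatrix,
                   tolerance: Optional[float] = None) -> str:
    """Temporal relation of two mutations from their CCFs across regions."""
    shared = [s for s in ccf.samples
              if not ccf.missing.at[a, s] and not ccf.missing.at[b, s]]
    if len(shared) < 2:
        return UNEVALUABLE_PAIR
    fa = ccf.ccf.loc[a, shared].to_numpy(dtype=float)
    fb = ccf.ccf.loc[b, shared].to_numpy(dtype=float)
    tol = (np.full(len(shared), float(tolerance)) if tolerance is not None
           else _pair_tolerance(ccf, a, b, shared))
    diff = fa - fb
    a_above = bool(np.any(diff > tol))
    b_above = bool(np.any(diff < -tol))
    if not a_above and not b_above:
        return UNRESOLVED
    if a_above and b_above:
        return INCOMPARABLE
    return A_FIRST if a_above else B_FIRST


@dataclass
class PartialOrder:
    """Acyclic temporal order over mutations.

    ``edges`` is the transitive reduction of all (earlier, later) pairs;
    ``evidence`` keeps the per-sample CCF differences behind each directed
    pair; ``roots`` are the earliest candidates (no incoming edge, at least
    one outgoing one among the compared set).
    """

    edges: Set[Tuple[str, str]]
    unresolved: Set[Tuple[str, str]]
    incomparable: Set[Tuple[str, str]]
    unevaluable: Set[Tuple[str, str]]
    evidence: Dict[Tuple[str, str], Dict[str, float]]
    roots: List[str]
    demoted_cycles: List[List[str]] = field(default_factory=list)

    def ancestors_closure(self) -> Set[Tuple[str, str]]:
        g = nx.DiGraph(self.edges)
        out = set()
        for n in g.nodes:
            for d in nx.descendants(g, n):
                out.add((n, d))
        return out


def build_partial_order(ccf: CCFMatrix, mutations: Sequence[str],
                        tolerance: Optional[float] = None) -> PartialOrder:
    """All-pairs ordering, cycle demotion, transitive reduction."""
    mutations = list(mutations)
    directed: Set[Tuple[str, str]] = set()
    unresolved, incomparable, unevaluable = set(), set(), set()
    evidence: Dict[Tuple[str, str], Dict[str, float]] = {}
    for a, b in itertools.combinations(mutations, 2):
        rel = pairwise_order(a, b, ccf, tolerance)
        pair = (a, b)
        if rel == A_FIRST:
            directed.add((a, b))
        elif rel == B_FIRST:
            directed.add((b, a))
        elif rel == UNRESOLVED:
            unresolved.add(pair)
        elif rel == INCOMPARABLE:
            incomparable.add(pair)
        else:
            unevaluable.add(pair)
        if rel in (A_FIRST, B_FIRST):
            shared = [s for s in ccf.samples
                      if not ccf.missing.at[a, s] and not ccf.missing.at[b, s]]
            key = (a, b) if rel == A_FIRST else (b, a)
            sign = 1.0 if rel == A_FIRST else -1.0
            evidence[key] = {s: sign * float(ccf.ccf.at[a, s] - ccf.ccf.at[b, s])
                             for s in shared}

    g = nx.DiGraph()
    g.add_nodes_from(mutations)
    g.add_edges_from(directed)
    demoted: List[List[str]] = []
    while not nx.is_directed_acyclic_graph(g):
        cycle = [u for u, _ in nx.find_cycle(g)]
        demoted.append(cycle)
        for u, v in itertools.combinations(sorted(cycle), 2):
            for e in [(u, v), (v, u)]:
                if g.has_edge(*e):
                    g.remove_edge(*e)
                    evidence.pop(e, None)
                    unresolved.add((u, v))
    reduced = nx.transitive_reduction(g)
    edges = set(reduced.edges)
    evidence = {e: ev for e, ev in evidence.items() if e in set(g.edges)}
    roots = [n for n in g.nodes
             if g.in_degree(n) == 0 and g.out_degree(n) > 0]
    return PartialOrder(edges=edges, unresolved=unresolved,
                        incomparable=incomparable, unevaluable=unevaluable,
                        evidence=evidence, roots=sorted(roots),
                        demoted_cycles=demoted)


def infer_tumor_samples(presence: PresenceMatrix,
                        driver_genes: Sequence[str] = DEFAULT_DRIVER_GENES,
                        gene_of: Optional[Mapping[str, str]] = None) -> List[str]:
    """Samples with oncogenic content: >= 1 present driver-gene mutation.

    ``gene_of`` maps mutation id -> gene; by default the mutation id itself
    is matched against the driver list.
    """
    gene_of = gene_of or {}
    tumor = []
    for s in presence.samples:
        for m in presence.mutations:
            gene = gene_of.get(m, m)
            if gene in driver_genes and presence.calls.at[m, s] == PRESENT:
                tumor.append(s)
                break
    return tumor


def classify_spatial(presence: PresenceMatrix,
                     tumor_samples: Sequence[str]) -> Dict[str, Optional[str]]:
    """Ubiquitous / shared / private per mutation over the tumor samples;
    mutations present nowhere map to None (excluded)."""
    out: Dict[str, Optional[str]] = {}
    for m in presence.mutations:
        calls = [presence.calls.at[m, s] for s in tumor_samples]
        evaluable = [c for c in calls if c != UNEVALUABLE]
        n_present = sum(c == PRESENT for c in evaluable)
        if not evaluable or n_present == 0:
            out[m] = None
        elif n_present == len(evaluable):
            out[m] = UBIQUITOUS
        elif n_present >= 2:
            out[m] = SHARED
        else:
            out[m] = PRIVATE
    return out


def classify_driver(mutation_id: str, spatial_class: Optional[str],
                    tree: CloneTree,
                    driver_genes: Sequence[str] = DEFAULT_DRIVER_GENES,
                    gene_of: Optional[Mapping[str, str]] = None) -> str:
    """Main driver: listed gene, truncal cluster, ubiquitous.  Accessory:
    listed gene but subclonal or non-ubiquitous.  Otherwise passenger."""
    gene = (gene_of or {}).get(mutation_id, mutation_id)
    if gene not in driver_genes:
        return PASSENGER
    cluster = tree.assignment.get(mutation_id)
    truncal = cluster == tree.trunk
    if truncal and spatial_class == UBIQUITOUS:
        return MAIN_DRIVER
    return ACCESSORY_DRIVER


@dataclass
class MutationClassification:
    mutation_id: str
    spatial_class: Optional[str]
    driver_category: str
    partner_group: Optional[str] = None


def classify_mutations(presence: PresenceMatrix, tree: CloneTree,
                       tumor_samples: Optional[Sequence[str]] = None,
                       driver_genes: Sequence[str] = DEFAULT_DRIVER_GENES,
                       gene_of: Optional[Mapping[str, str]] = None,
                       ) -> List[MutationClassification]:
    if tumor_samples is None:
        tumor_samples = infer_tumor_samples(presence, driver_genes, gene_of)
    spatial = classify_spatial(presence, tumor_samples)
    out = []
    for m in presence.mutations:
        cat = classify_driver(m, spatial[m], tree, driver_genes, gene_of)
        out.append(MutationClassification(m, spatial[m], cat))
    return out


@dataclass
class PartnershipReport:
    """Co-occurrence of the oncohistone mutation with partner drivers."""

    applicable: bool
    obligate: bool = False
    complementary: bool = False
    per_sample_partners: Dict[str, List[str]] = field(default_factory=dict)
    failing_samples: List[str] = field(default_factory=list)
    partners_seen: List[str] = field(default_factory=list)


def detect_obligate_partners(presence: PresenceMatrix,
                             oncohistone: str,
                             partner_genes: Sequence[str],
                             tumor_samples: Optional[Sequence[str]] = None,
                             gene_of: Optional[Mapping[str, str]] = None,
                             ) -> PartnershipReport:
    """Is the oncohistone always accompanied by >= 1 partner driver?

    The partnership is *obligate* when every evaluable tumor sample carrying
    the oncohistone also carries some partner mutation, and *complementary*
    when no single partner gene covers all samples by itself (distinct
    partners in distinct subclones jointly covering the tumor).
    """
    gene_of = gene_of or {}
    if oncohistone not in presence.mutations:
        return PartnershipReport(applicable=False)
    if tumor_samples is None:
        tumor_samples = [s for s in presence.samples
                         if presence.calls.at[oncohistone, s] == PRESENT]
    partner_muts = [m for m in presence.mutations
                    if m != oncohistone and gene_of.get(m, m) in partner_genes]
    per_sample: Dict[str, List[str]] = {}
    failing = []
    for s in tumor_samples:
        if presence.calls.at[oncohistone, s] != PRESENT:
            continue
        partners = [m for m in partner_muts if presence.calls.at[m, s] == PRESENT]
        per_sample[s] = partners
        if not partners:
            failing.append(s)
    obligate = bool(per_sample) and not failing
    complementary = False
    if obligate:
        covering = [m for m in partner_muts
                    if all(presence.calls.at[m, s] == PRESENT for s in per_sample)]
        complementary = not covering
    seen = sorted({m for ps in per_sample.values() for m in ps})
    return PartnershipReport(applicable=True, obligate=obligate,
                             complementary=complementary,
                             per_sample_partners=per_sample,
                             failing_samples=failing, partners_seen=seen)


def classifications_to_frame(classifications: Sequence[MutationClassification]
                             ) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in classifications])
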