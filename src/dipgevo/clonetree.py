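"""Mutation clustering and clone-tree reconstruction across tumor regions.

All regions of one patient are fit jointly.  Corrected allele counts become
cellular-frequency (CCF) estimates (``2 x corrected VAF / purity``, capped at
1).  Mutations are clustered by a finite binomial-mixture EM with shared
per-sample component frequencies and BIC model selection, and the clone tree
is found by exhaustive search over all rooted labeled trees with a single
truncal clone, scoring each candidate by a penalized binomial likelihood.

The biological constraint is the pigeonhole ("sum") condition: in every
sample a parent clone's cellular frequency must be at least the sum of its
children's.  Candidate trees whose raw cluster frequencies violate it are
projected onto the feasible set by constrained least squares and pay a
penalty proportional to the projection distance.

This is a deterministic, desk-scale stand-in for the MCMC machinery of
subclonal-reconstruction tools such as PhyloWGS or PyClone: no Dirichlet
process, no posterior sampling — a fixed-seed EM plus an exhaustive
penalized-ML tree search whose output is reproducible bit for bit.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .correction import CorrectedCounts

__all__ = [
    "CCFMatrix", "MutationCluster", "ClusteringResult", "CloneTree",
    "estimate_ccf", "cluster_mutations", "clusters_from_assignment",
    "enumerate_trees", "score_tree", "fit_tree", "prune_tree",
    "export_tree", "load_tree_json", "reconstruct",
]

NORMAL_LABEL = "normal"
_QCLIP = 1e-9


@dataclass
class CCFMatrix:
    """Cellular-frequency estimates plus the integer counts behind them.

    ``ccf``, ``alt``, ``depth`` and ``missing`` are mutations x samples
    DataFrames; ``alt``/``depth`` are the corrected counts rounded to the
    nearest integer (the single place rounding happens), except that exact
    real-valued counts may be injected for noiseless analyses.
    """

    ccf: pd.DataFrame
    alt: pd.DataFrame
    depth: pd.DataFrame
    missing: pd.DataFrame
    purity: pd.Series

    @property
    def mutations(self) -> List[str]:
        return list(self.ccf.index)

    @property
    def samples(self) -> List[str]:
        return list(self.ccf.columns)


def estimate_ccf(corrected: Sequence[CorrectedCounts],
                 purity: Optional[Mapping[str, float]] = None,
                 min_depth: int = 10,
                 round_counts: bool = True) -> CCFMatrix:
    """CCF = min(1, 2 x corrected VAF / purity); purity defaults to 1.

    Cells with corrected depth below ``min_depth`` are flagged missing.
    """
    df = pd.DataFrame([vars(c) for c in corrected])
    if df.empty:
        raise ValueError("no corrected counts supplied")
    dup = df.duplicated(["mutation_id", "sample_id"])
    if dup.any():
        raise ValueError("duplicate (mutation, sample) entries in corrected counts")
    mut_order = list(dict.fromkeys(df["mutation_id"]))
    sample_order = list(dict.fromkeys(df["sample_id"]))

    def pivot(col):
        return (df.pivot(index="mutation_id", columns="sample_id", values=col)
                  .reindex(index=mut_order, columns=sample_order))

    alt = pivot("alt_prime")
    depth = alt + pivot("ref_prime")
    if round_counts:
        alt = alt.round()
        depth = depth.round()
    missing = depth.isna() | (depth < min_depth)
    alt = alt.fillna(0.0)
    depth = depth.fillna(0.0)

    pur = pd.Series(1.0, index=sample_order, dtype=float)
    if purity is not None:
        for s, p in purity.items():
            if p <= 0:
                raise ValueError(f"purity of sample {s} must be > 0")
            if s in pur.index:
                pur[s] = float(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = alt.to_numpy() / np.where(depth.to_numpy() > 0, depth.to_numpy(), np.nan)
    ccf = np.minimum(1.0, 2.0 * vaf / pur.to_numpy()[None, :])
    ccf = pd.DataFrame(ccf, index=mut_order, columns=sample_order)
    return CCFMatrix(ccf=ccf, alt=alt, depth=depth, missing=missing, purity=pur)


@dataclass
class MutationCluster:
    cluster_id: int
    members: List[str]
    freq: pd.Series  # per-sample cellular frequency (weighted mean), CCF scale

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusteringResult:
    clusters: List[MutationCluster]
    k: int
    bic: Dict[int, float]
    log_likelihood: float
    assignment: Dict[str, int]  # mutation id -> cluster id
    excluded: List[str] = field(default_factory=list)


def _cluster_freq(ccf: CCFMatrix, members: Sequence[str]) -> pd.Series:
    a = ccf.alt.loc[list(members)].sum(axis=0)
    d = ccf.depth.loc[list(members)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 2.0 * (a / d) / ccf.purity
    return f.clip(upper=1.0).fillna(0.0)


def clusters_from_assignment(ccf: CCFMatrix,
                             assignment: Mapping[str, int]) -> List[MutationCluster]:
    """Build clusters from a known mutation -> group mapping (e.g. simulation
    ground truth), ordered by descending mean frequency, ids 1..K."""
    groups: Dict[int, List[str]] = {}
    for m, g in assignment.items():
        groups.setdefault(g, []).append(m)
    prelim = [(tuple(members), _cluster_freq(ccf, members))
              for members in groups.values()]
    prelim.sort(key=lambda t: (-float(t[1].mean()), t[0]))
    return [MutationCluster(i + 1, list(mem), fr)
            for i, (mem, fr) in enumerate(prelim)]


def _em_binomial_mixture(A: np.ndarray, D: np.ndarray, k: int,
                         rng: np.random.Generator, n_restarts: int,
                         max_iter: int, tol: float) -> Tuple[float, np.ndarray]:
    """Fit a k-component binomial mixture with per-sample component means.

    Returns (log-likelihood up to a constant, responsibilities N x k).
    Cells with D == 0 are treated as missing.
    """
    n, s = A.shape
    valid = D > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        V = np.where(valid, A / np.where(valid, D, 1.0), np.nan)

    def loglik_parts(theta):
        q = np.clip(theta, _QCLIP, 1 - _QCLIP)  # k x s
        ll = (A[:, None, :] * np.log(q)[None, :, :]
              + (D - A)[:, None, :] * np.log1p(-q)[None, :, :])
        return np.where(valid[:, None, :], ll, 0.0).sum(axis=2)  # n x k

    best = (-np.inf, None)
    for _ in range(n_restarts):
        rows = rng.choice(n, size=k, replace=n < k)
        theta = np.vstack([np.where(np.isnan(V[r]), 0.25, V[r]) for r in rows])
        theta = np.clip(theta + rng.normal(0, 0.01, theta.shape), 1e-4, 1 - 1e-4)
        pi = np.full(k, 1.0 / k)
        prev = -np.inf
        for _ in range(max_iter):
            lp = loglik_parts(theta) + np.log(pi)[None, :]
            norm = logsumexp(lp, axis=1)
            ll_total = float(norm.sum())
            r = np.exp(lp - norm[:, None])
            pi = np.clip(r.mean(axis=0), 1e-12, None)
            pi = pi / pi.sum()
            num = r.T @ np.where(valid, A, 0.0)
            den = r.T @ np.where(valid, D, 0.0)
            theta = np.clip(num / np.clip(den, 1e-12, None), 1e-6, 1 - 1e-6)
            if ll_total - prev < tol and np.isfinite(prev):
                break
            prev = ll_total
        if ll_total > best[0]:
            best = (ll_total, r)
    return best


def cluster_mutations(ccf: CCFMatrix, k_max: int = 6, n_restarts: int = 10,
                      seed: int = 0, max_iter: int = 300,
                      tol: float = 1e-6) -> ClusteringResult:
    """Cluster mutations by cellular frequency profile across samples.

    For k = 1..k_max a k-component binomial mixture is fit by EM (restarts
    seeded, hence deterministic); k is chosen by BIC; assignments are maximum
    responsibility.  Mutations missing in every sample are excluded.
    """
    usable = [m for m in ccf.mutations if not ccf.missing.loc[m].all()]
    excluded = [m for m in ccf.mutations if m not in usable]
    if not usable:
        raise ValueError("no mutation has evaluable depth in any sample")
    A = ccf.alt.loc[usable].to_numpy(dtype=float)
    D = ccf.depth.loc[usable].to_numpy(dtype=float)
    D = np.where(ccf.missing.loc[usable].to_numpy(), 0.0, D)
    A = np.where(D > 0, A, 0.0)
    n, s = A.shape
    rng = np.random.default_rng(seed)
    bic: Dict[int, float] = {}
    best: Tuple[float, int, np.ndarray] = (np.inf, 0, None)
    for k in range(1, min(k_max, n) + 1):
        ll, resp = _em_binomial_mixture(A, D, k, rng, n_restarts, max_iter, tol)
        n_params = k * s + (k - 1)
        b = -2.0 * ll + n_params * math.log(n)
        bic[k] = b
        if b < best[0]:
            best = (b, k, resp)
    _, k_sel, resp = best
    labels = resp.argmax(axis=1)
    assignment_raw = {m: int(l) for m, l in zip(usable, labels)}
    clusters = clusters_from_assignment(ccf, assignment_raw)
    assignment = {m: c.cluster_id for c in clusters for m in c.members}
    ll_sel = -0.5 * (bic[k_sel] - (k_sel * s + k_sel - 1) * math.log(n))
    return ClusteringResult(clusters=clusters, k=len(clusters), bic=bic,
                            log_likelihood=float(ll_sel),
                            assignment=assignment, excluded=excluded)


# ---------------------------------------------------------------------------
# tree search


def enumerate_trees(k: int, k_tree_max: int = 7) -> List[Tuple[int, ...]]:
    """All rooted labeled trees over clusters 1..k with a normal root that has
    exactly one (truncal) child; returned as parent vectors ``p[i-1] = parent
    of cluster i`` (0 denotes the normal root), sorted lexicographically.

    There are k^(k-1) such trees (k choices of trunk times Cayley's k^(k-2)
    rooted trees on the tumor clusters).
    """
    if k < 1:
        raise ValueError("need at least one cluster")
    if k > k_tree_max:
        raise ValueError(f"exhaustive enumeration limited to {k_tree_max} clusters; "
                         "reduce k_max or merge clusters")
    if k == 1:
        return [(0,)]
    out = []
    nodes = list(range(1, k + 1))
    for trunk in nodes:
        others = [i for i in nodes if i != trunk]
        for choice in itertools.product(nodes, repeat=k - 1):
            if any(choice[j] == others[j] for j in range(k - 1)):
                continue
            parent = {trunk: 0}
            parent.update({o: c for o, c in zip(others, choice)})
            ok = True
            for start in others:
                seen = set()
                cur = start
                while cur != 0:
                    if cur in seen:
                        ok = False
                        break
                    seen.add(cur)
                    cur = parent[cur]
                if not ok:
                    break
            if ok:
                out.append(tuple(parent[i] for i in nodes))
    out.sort()
    return out


def _freq_matrix(clusters: Sequence[MutationCluster],
                 samples: Sequence[str]) -> np.ndarray:
    return np.vstack([c.freq.reindex(samples).to_numpy() for c in clusters])


def _aggregate_counts(ccf: CCFMatrix, clusters: Sequence[MutationCluster]):
    A = np.vstack([ccf.alt.loc[c.members].sum(axis=0).to_numpy() for c in clusters])
    D = np.vstack([ccf.depth.loc[c.members].sum(axis=0).to_numpy() for c in clusters])
    return A, D


def _children_lists(parent_vec: Sequence[int]) -> List[List[int]]:
    k = len(parent_vec)
    ch: List[List[int]] = [[] for _ in range(k + 1)]
    for i, p in enumerate(parent_vec, start=1):
        ch[p].append(i)
    return ch


def _is_feasible(parent_vec, F, tol=1e-9) -> bool:
    ch = _children_lists(parent_vec)
    for v in range(1, len(parent_vec) + 1):
        if not ch[v]:
            continue
        child_sum = F[[c - 1 for c in ch[v]], :].sum(axis=0)
        if np.any(F[v - 1, :] + tol < child_sum):
            return False
    return True


def _project_sample(f_raw: np.ndarray, parent_vec: Sequence[int]) -> np.ndarray:
    """Euclidean projection of one sample's cluster frequencies onto
    {0 <= f <= 1, f_parent >= sum(children)} by SLSQP."""
    k = len(parent_vec)
    ch = _children_lists(parent_vec)
    rows = []
    for v in range(1, k + 1):
        if ch[v]:
            row = np.zeros(k)
            row[v - 1] = 1.0
            for c in ch[v]:
                row[c - 1] -= 1.0
            rows.append(row)
    if not rows:
        return np.clip(f_raw, 0.0, 1.0)
    C = np.vstack(rows)
    res = minimize(
        lambda x: 0.5 * np.sum((x - f_raw) ** 2), np.clip(f_raw, 0.0, 1.0),
        jac=lambda x: x - f_raw,
        constraints=[{"type": "ineq", "fun": lambda x: C @ x, "jac": lambda x: C}],
        bounds=[(0.0, 1.0)] * k, method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12})
    x = np.clip(res.x, 0.0, 1.0)
    # enforce exact feasibility against numeric slack
    slack = C @ x
    if slack.min() < -1e-8:
        x = np.clip(x + 0.0, 0.0, 1.0)
    return x


def _candidate_score(parent_vec, F, A, D, purity, lam):
    """(logL, violation, projected F) of one candidate tree."""
    k, s = F.shape
    proj = np.empty_like(F)
    violation = 0.0
    for j in range(s):
        f = F[:, j]
        if _is_feasible(parent_vec, f[:, None]):
            proj[:, j] = f
        else:
            proj[:, j] = _project_sample(f, parent_vec)
            violation += float(np.abs(proj[:, j] - f).sum())
    q = np.clip(proj * purity[None, :] / 2.0, _QCLIP, 1 - _QCLIP)
    logL = float(np.sum(A * np.log(q) + (D - A) * np.log1p(-q)))
    return logL, violation, proj


def score_tree(parent_vec: Sequence[int], ccf: CCFMatrix,
               clusters: Sequence[MutationCluster],
               lam: float = 100.0) -> Tuple[float, float]:
    """Penalized likelihood of one candidate tree: per sample the cluster
    frequencies are projected onto the pigeonhole-feasible set, the binomial
    likelihood is evaluated at the projection, and the summed projection
    distance is penalized with weight ``lam``.  Returns
    (log_likelihood, violation_total)."""
    samples = ccf.samples
    F = _freq_matrix(clusters, samples)
    A, D = _aggregate_counts(ccf, clusters)
    purity = ccf.purity.reindex(samples).to_numpy()
    logL, violation, _ = _candidate_score(tuple(parent_vec), F, A, D, purity, lam)
    return logL, violation


def _n_violating_nodes(parent_vec, F) -> int:
    ch = _children_lists(parent_vec)
    n = 0
    for v in range(1, len(parent_vec) + 1):
        if not ch[v]:
            continue
        child_sum = F[[c - 1 for c in ch[v]], :].sum(axis=0)
        if np.any(F[v - 1, :] + 1e-9 < child_sum):
            n += 1
    return n


def _depth_sum(parent_vec) -> int:
    total = 0
    for i in range(1, len(parent_vec) + 1):
        d, cur = 0, i
        while cur != 0:
            cur = parent_vec[cur - 1]
            d += 1
        total += d
    return total


@dataclass
class CloneTree:
    """Fitted clonal tree: clusters plus a normal root.

    ``freq`` holds the projected per-sample cellular frequency of each node;
    ``mixing`` the per-sample mixing proportions including a ``"normal"``
    row; both sum-constrained as documented.  ``n_tied`` reports how many
    candidate trees were within the score tie tolerance (1 = unambiguous).
    """

    parent: Dict[int, int]
    clusters: List[MutationCluster]
    freq: pd.DataFrame
    mixing: pd.DataFrame
    log_likelihood: float
    violation_total: float
    score: float
    n_tied: int = 1

    @property
    def samples(self) -> List[str]:
        return list(self.freq.columns)

    @property
    def trunk(self) -> int:
        return next(c for c, p in self.parent.items() if p == 0)

    @property
    def parent_vector(self) -> Tuple[int, ...]:
        return tuple(self.parent[i] for i in sorted(self.parent))

    def children(self, node: int) -> List[int]:
        return [c for c, p in self.parent.items() if p == node]

    def members_of(self, node: int) -> List[str]:
        return next(c.members for c in self.clusters if c.cluster_id == node)

    @property
    def assignment(self) -> Dict[str, int]:
        return {m: c.cluster_id for c in self.clusters for m in c.members}


def _mixing_from_freq(parent_vec, proj: np.ndarray, samples,
                      node_ids) -> pd.DataFrame:
    k, s = proj.shape
    ch = _children_lists(parent_vec)
    trunk = parent_vec.index(0) + 1
    mix = np.zeros((k + 1, s))
    for v in range(1, k + 1):
        child_sum = (proj[[c - 1 for c in ch[v]], :].sum(axis=0)
                     if ch[v] else np.zeros(s))
        mix[v - 1] = np.clip(proj[v - 1] - child_sum, 0.0, None)
    mix[k] = np.clip(1.0 - proj[trunk - 1], 0.0, None)
    total = mix.sum(axis=0)
    total = np.where(total > 0, total, 1.0)
    mix = mix / total[None, :]
    return pd.DataFrame(mix, index=list(node_ids) + [NORMAL_LABEL], columns=samples)


def fit_tree(ccf: CCFMatrix, clusters: Sequence[MutationCluster],
             lam: float = 100.0, k_tree_max: int = 7,
             tie_tol: float = 1e-7) -> CloneTree:
    """Best tree over the exhaustive enumeration.

    When at least one candidate satisfies the pigeonhole condition outright,
    all feasible candidates share the identical (unprojected) likelihood and
    strictly dominate every infeasible one, so only they are compared.
    Ties are broken deterministically: fewer constraint-violating nodes,
    then smaller total node depth (prefer branching over unsupported
    nesting), then lexicographically smaller parent vector.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("empty cluster set")
    k = len(clusters)
    samples = ccf.samples
    F = _freq_matrix(clusters, samples)
    A, D = _aggregate_counts(ccf, clusters)
    purity = ccf.purity.reindex(samples).to_numpy()
    candidates = enumerate_trees(k, k_tree_max)

    feasible = [c for c in candidates if _is_feasible(c, F)]
    if feasible:
        q = np.clip(F * purity[None, :] / 2.0, _QCLIP, 1 - _QCLIP)
        logL = float(np.sum(A * np.log(q) + (D - A) * np.log1p(-q)))
        pool = [(c, logL, 0.0, F) for c in feasible]
        n_tied = len(feasible)
    else:
        scored = []
        best_score = -np.inf
        for c in candidates:
            logL, viol, proj = _candidate_score(c, F, A, D, purity, lam)
            s = logL - lam * viol
            scored.append((c, logL, viol, proj, s))
            best_score = max(best_score, s)
        pool = [(c, logL, viol, proj) for c, logL, viol, proj, s in scored
                if s >= best_score - tie_tol]
        n_tied = len(pool)

    def key(entry):
        c = entry[0]
        return (_n_violating_nodes(c, F), _depth_sum(c), c)

    best_vec, logL, violation, proj = min(pool, key=key)
    node_ids = [c.cluster_id for c in clusters]
    freq = pd.DataFrame(proj, index=node_ids, columns=samples)
    mixing = _mixing_from_freq(best_vec, proj, samples, node_ids)
    parent = {i: best_vec[i - 1] for i in range(1, k + 1)}
    return CloneTree(parent=parent, clusters=clusters, freq=freq,
                     mixing=mixing, log_likelihood=logL,
                     violation_total=violation,
                     score=logL - lam * violation, n_tied=n_tied)


def prune_tree(tree: CloneTree, threshold: float = 0.05) -> CloneTree:
    """Display tree: nodes whose mixing proportion stays below ``threshold``
    in every sample are collapsed into their parent (mutations re-annotated
    to the parent trajectory); the truncal node is never collapsed.  The
    fitted tree is left untouched."""
    parent = dict(tree.parent)
    members = {c.cluster_id: list(c.members) for c in tree.clusters}
    mixing = tree.mixing.copy()
    freq = tree.freq.copy()
    changed = True
    while changed:
        changed = False
        by_depth = sorted(parent, key=lambda v: -_node_depth(parent, v))
        for v in by_depth:
            if parent[v] == 0:
                continue
            if float(mixing.loc[v].max()) < threshold:
                p = parent[v]
                mixing.loc[p] += mixing.loc[v]
                members[p].extend(members.pop(v))
                for c in list(parent):
                    if parent.get(c) == v:
                        parent[c] = p
                del parent[v]
                mixing = mixing.drop(index=v)
                freq = freq.drop(index=v)
                changed = True
                break
    clusters = []
    for c in tree.clusters:
        if c.cluster_id in parent:
            clusters.append(MutationCluster(c.cluster_id,
                                            members[c.cluster_id], c.freq))
    return replace(tree, parent=parent, clusters=clusters,
                   freq=freq, mixing=mixing)


def _node_depth(parent: Mapping[int, int], v: int) -> int:
    d = 0
    while v != 0:
        v = parent[v]
        d += 1
    return d


def export_tree(tree: CloneTree, format: str = "json") -> str:
    """Serialize a tree: lossless JSON, Graphviz DOT with per-sample mixing
    labels, or topology-only Newick with cluster labels."""
    if format == "json":
        doc = {
            "parent": {str(k): v for k, v in tree.parent.items()},
            "clusters": [{"cluster_id": c.cluster_id, "members": c.members,
                          "freq": {s: float(c.freq[s]) for s in tree.samples}}
                         for c in tree.clusters],
            "freq": {str(i): {s: float(tree.freq.at[i, s]) for s in tree.samples}
                     for i in tree.freq.index},
            "mixing": {str(i): {s: float(tree.mixing.at[i, s]) for s in tree.samples}
                       for i in tree.mixing.index},
            "log_likelihood": tree.log_likelihood,
            "violation_total": tree.violation_total,
            "score": tree.score,
            "n_tied": tree.n_tied,
        }
        return json.dumps(doc, indent=1, sort_keys=True)
    if format == "dot":
        lines = ["digraph clonetree {", '  normal [shape=box, label="normal"];']
        for c in tree.clusters:
            label = f"clone {c.cluster_id} ({c.size} mut)"
            named = [m for m in c.members if not m.startswith("m")]
            if named:
                label += "\\n" + ",".join(named[:4])
            mix = " ".join(f"{s}:{tree.mixing.at[c.cluster_id, s]:.2f}"
                           for s in tree.samples)
            lines.append(f'  c{c.cluster_id} [label="{label}\\n{mix}"];')
        for child, par in sorted(tree.parent.items()):
            src = "normal" if par == 0 else f"c{par}"
            lines.append(f"  {src} -> c{child};")
        lines.append("}")
        return "\n".join(lines)
    if format == "newick":
        def nw(node: int) -> str:
            kids = sorted(tree.children(node))
            label = NORMAL_LABEL if node == 0 else f"clone{node}"
            if not kids:
                return label
            return "(" + ",".join(nw(c) for c in kids) + ")" + label
        return nw(0) + ";"
    raise ValueError(f"unknown export format {format!r}")


def load_tree_json(text: str) -> CloneTree:
    d = json.loads(text)
    samples = list(next(iter(d["freq"].values())).keys())
    clusters = [MutationCluster(c["cluster_id"], list(c["members"]),
                                pd.Series(c["freq"]).reindex(samples))
                for c in d["clusters"]]
    node_ids = [c.cluster_id for c in clusters]
    freq = pd.DataFrame({s: [d["freq"][str(i)][s] for i in node_ids]
                         for s in samples}, index=node_ids)
    mix_index = node_ids + [NORMAL_LABEL]
    mixing = pd.DataFrame({s: [d["mixing"][str(i)][s] for i in mix_index]
                           for s in samples}, index=mix_index)
    return CloneTree(parent={int(k): v for k, v in d["parent"].items()},
                     clusters=clusters, freq=freq, mixing=mixing,
                     log_likelihood=d["log_likelihood"],
                     violation_total=d["violation_total"],
                     score=d["score"], n_tied=d["n_tied"])


def reconstruct(corrected: Sequence[CorrectedCounts],
                purity: Optional[Mapping[str, float]] = None,
                k_max: int = 6, seed: int = 0, lam: float = 100.0,
                min_depth: int = 10):
    """Convenience pipeline: corrected counts -> CCF -> clusters -> tree.

    Returns ``(ccf, clustering, tree)``.
    """
    ccf = estimate_ccf(corrected, purity=purity, min_depth=min_depth)
    clustering = cluster_mutations(ccf, k_max=k_max, seed=seed)
    tree = fit_tree(ccf, clustering.clusters, lam=lam)
    return ccf, clustering, tree
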