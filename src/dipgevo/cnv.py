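"""Arm-level CNV calling from allelic imbalance and tumor/normal coverage.

For each (sample, chromosome arm) two orthogonal signals are summarised:

* **B-allele frequency deviation** at germline heterozygous sites — per-site
  BAF folded as |BAF - 0.5|, averaged over the arm.  Significance is assessed
  against a depth-matched Monte-Carlo null (balanced binomial draws at the
  observed site depths), so no normality assumption is made.
* **Normalized coverage** — log2(tumor mean / normal mean), median-centered
  across arms so that the bulk of the genome sits at 0.

The decision table: significant imbalance with raised coverage is a
duplication, with lowered coverage a deletion, with unchanged coverage a
copy-neutral LOH; no significant imbalance is neutral.

Significance requires both a small Monte-Carlo p-value and an effect size
above a depth-aware floor: the folded deviation of a *balanced* arm has null
mean sqrt(1/(2*pi*d)) at depth d (~0.048 at 70x), so the floor is
``max(dev_min, null_dev_multiplier * mean_i sqrt(1/(2*pi*d_i)))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ArmStats",
    "ArmCNVCall",
    "CNVThresholds",
    "folded_baf_deviation",
    "normalized_arm_coverage",
    "classify_arm",
    "call_cnv_profile",
    "write_calls_tsv",
]

DUPLICATION = "duplication"
DELETION = "deletion"
CN_LOH = "cn_loh"
NEUTRAL = "neutral"
UNEVALUABLE = "unevaluable"


@dataclass(frozen=True)
class CNVThresholds:
    alpha: float = 0.01          # Monte-Carlo p-value cut for imbalance
    dev_min: float = 0.05        # floor on mean folded BAF deviation
    t_cov: float = 0.15          # |log2 ratio| band for "unchanged" coverage
    min_depth: int = 10          # per-site depth floor
    min_sites: int = 10          # minimum evaluable het sites per arm
    n_null: int = 10_000         # Monte-Carlo replicates
    null_dev_multiplier: float = 1.5  # depth-aware effect-size floor factor


@dataclass
class ArmStats:
    sample_id: str
    arm: str
    n_het_sites: int
    mean_folded_baf_dev: float
    baf_p_value: float
    log2_coverage_ratio: float

    @property
    def evaluable(self) -> bool:
        return self.n_het_sites > 0 and not math.isnan(self.mean_folded_baf_dev)


@dataclass
class ArmCNVCall:
    sample_id: str
    arm: str
    event: str
    stats: ArmStats


def folded_baf_deviation(het_counts: Sequence[Tuple[int, int]],
                         min_depth: int = 10, min_sites: int = 10,
                         n_null: int = 10_000,
                         rng: Optional[np.random.Generator] = None,
                         seed: int = 0) -> Tuple[float, float]:
    """Mean folded BAF deviation of an arm and its Monte-Carlo p-value.

    The null distribution is the mean of |Binomial(d_i, 1/2)/d_i - 1/2| at
    the same site depths; p = (1 + #{null >= observed}) / (n_null + 1).
    Returns ``(nan, nan)`` when fewer than ``min_sites`` sites pass the
    depth floor.
    """
    counts = np.asarray(het_counts, dtype=float)
    if counts.size == 0:
        return float("nan"), float("nan")
    depth = counts.sum(axis=1)
    keep = depth >= min_depth
    if keep.sum() < min_sites:
        return float("nan"), float("nan")
    depth = depth[keep]
    a = counts[keep, 0]
    b = counts[keep, 1]
    # |b/d - 1/2| computed as |b - a| / 2d: exactly symmetric under A/B swap
    obs = float(np.mean(np.abs(b - a) / (2.0 * depth)))
    rng = np.random.default_rng(seed) if rng is None else rng
    null_stat = _null_mean_dev_draws(depth.astype(np.int64), n_null, rng)
    p = (1.0 + np.count_nonzero(null_stat >= obs)) / (n_null + 1.0)
    return obs, float(p)


def _binomial_half(depths: np.ndarray, n_null: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Exact Binomial(d_i, 1/2) draws, shape (n_null, len(depths)).

    A Binomial(d, 1/2) variate is the popcount of d independent random bits,
    which vectorizes far better than the generic binomial sampler.
    """
    out = np.zeros((n_null, depths.size), dtype=np.int64)
    remaining = depths.copy()
    while (remaining > 0).any():
        bits = np.minimum(remaining, 64)
        words = rng.integers(0, 2 ** 64, size=out.shape, dtype=np.uint64)
        # keep only `bits` low-order bits per column
        safe_bits = np.minimum(bits, 63).astype(np.uint64)  # avoid UB shift by 64
        mask = np.where(bits >= 64, np.uint64(0xFFFFFFFFFFFFFFFF),
                        (np.uint64(1) << safe_bits) - np.uint64(1))
        out += np.bitwise_count(words & mask[None, :]).astype(np.int64)
        remaining = remaining - bits
    return out


def _null_mean_dev_draws(depths: np.ndarray, n_null: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null of the mean folded BAF deviation at given depths."""
    b = _binomial_half(depths, n_null, rng)
    return np.mean(np.abs(2 * b - depths[None, :]) / (2.0 * depths[None, :]),
                   axis=1)


def null_mean_folded_dev(depths: Sequence[float]) -> float:
    """Expected mean folded deviation of a balanced arm: the half-normal
    approximation E|BAF - 0.5| = sqrt(1/(2*pi*d)) averaged over sites."""
    d = np.asarray(depths, dtype=float)
    d = d[d > 0]
    if d.size == 0:
        return float("nan")
    return float(np.mean(np.sqrt(1.0 / (2.0 * np.pi * d))))


def normalized_arm_coverage(tumor_arm_means: pd.Series,
                            normal_arm_means: pd.Series) -> pd.Series:
    """Median-centered log2 tumor/normal coverage ratio per arm."""
    t = tumor_arm_means.astype(float)
    n = normal_arm_means.reindex(t.index).astype(float)
    if (t <= 0).any() or (n <= 0).any() or n.isna().any():
        raise ValueError("arm coverage means must be positive and matched between "
                         "tumor and normal")
    ratio = np.log2(t / n)
    return ratio - ratio.median()


def classify_arm(stats: ArmStats,
                 thresholds: CNVThresholds = CNVThresholds(),
                 dev_floor: Optional[float] = None) -> ArmCNVCall:
    """Apply the imbalance x coverage decision table to one arm.

    ``dev_floor`` is the effective effect-size floor; when omitted the plain
    ``thresholds.dev_min`` is used (callers with access to site depths pass
    the depth-aware value).
    """
    if not stats.evaluable:
        return ArmCNVCall(stats.sample_id, stats.arm, UNEVALUABLE, stats)
    floor = thresholds.dev_min if dev_floor is None else dev_floor
    significant = (stats.baf_p_value < thresholds.alpha
                   and stats.mean_folded_baf_dev >= floor)
    if not significant:
        return ArmCNVCall(stats.sample_id, stats.arm, NEUTRAL, stats)
    if math.isnan(stats.log2_coverage_ratio):
        raise ValueError("coverage ratio required to direction a significant "
                         "imbalance; matched-normal coverage missing")
    if stats.log2_coverage_ratio > thresholds.t_cov:
        event = DUPLICATION
    elif stats.log2_coverage_ratio < -thresholds.t_cov:
        event = DELETION
    else:
        event = CN_LOH
    return ArmCNVCall(stats.sample_id, stats.arm, event, stats)


def call_cnv_profile(het_sites: pd.DataFrame, arm_coverage: pd.DataFrame,
                     thresholds: CNVThresholds = CNVThresholds(),
                     seed: int = 0) -> List[ArmCNVCall]:
    """One call per (sample, arm) from a het-site table
    (sample_id, arm, a_count, b_count) and an arm-coverage table
    (sample_id, arm, tumor_mean, normal_mean)."""
    required_het = {"sample_id", "arm", "a_count", "b_count"}
    required_cov = {"sample_id", "arm", "tumor_mean", "normal_mean"}
    if not required_het.issubset(het_sites.columns):
        raise ValueError(f"het-site table needs columns {sorted(required_het)}")
    if not required_cov.issubset(arm_coverage.columns):
        raise ValueError(f"coverage table needs columns {sorted(required_cov)}")

    calls: List[ArmCNVCall] = []
    rng = np.random.default_rng(seed)
    for sample_id, cov in arm_coverage.groupby("sample_id", sort=False):
        cov = cov.set_index("arm")
        hets = het_sites[het_sites["sample_id"] == sample_id]
        het_arms = set(hets["arm"])
        if not het_arms.issubset(set(cov.index)):
            raise ValueError(f"sample {sample_id}: het-site arms "
                             f"{sorted(het_arms - set(cov.index))} missing from coverage table")
        log2 = normalized_arm_coverage(cov["tumor_mean"], cov["normal_mean"])
        for arm in cov.index:
            sub = hets[hets["arm"] == arm]
            pairs = sub[["a_count", "b_count"]].to_numpy()
            dev, p = folded_baf_deviation(pairs, thresholds.min_depth,
                                          thresholds.min_sites,
                                          thresholds.n_null, rng=rng)
            stats_ = ArmStats(sample_id, arm, len(sub), dev, p, float(log2[arm]))
            depths = pairs.sum(axis=1) if len(pairs) else []
            floor = max(thresholds.dev_min,
                        thresholds.null_dev_multiplier * null_mean_folded_dev(depths)) \
                if len(pairs) else thresholds.dev_min
            calls.append(classify_arm(stats_, thresholds, dev_floor=floor))
    return calls


def write_calls_tsv(calls: Sequence[ArmCNVCall], path) -> None:
    """BED-like per-arm segment output (1-based inclusive coordinates are not
    tracked here; arms are named segments)."""
    rows = [{"sample_id": c.sample_id, "arm": c.arm, "event": c.event,
             "n_het_sites": c.stats.n_het_sites,
             "mean_folded_baf_dev": c.stats.mean_folded_baf_dev,
             "baf_p_value": c.stats.baf_p_value,
             "log2_coverage_ratio": c.stats.log2_coverage_ratio}
            for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
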