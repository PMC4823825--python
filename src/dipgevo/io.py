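"""Count-table / VCF ingestion and per-sample mutation presence calling.

Presence rules
--------------
Whole-exome mode mirrors the variant-support quality filter used at ~70x:
a mutation is *present* in a sample when the site has at least ``min_depth``
reads (default 10, matching a ">=10 reads" coverage QC floor) and at least
10% of them support the variant; sites below the depth floor are
*unevaluable*.

Deep-amplicon data (~4,000x) needs a different rule — a flat 10% cut would
discard genuine low-frequency subclones that deep sequencing exists to
detect.  Here a mutation is present when ``alt_count >= min_alt`` and a
one-sided binomial test of the alt fraction against a background error rate
``e0`` rejects at level ``alpha``.  All parameters live on
:class:`PresenceParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "VariantObservation",
    "PresenceParams",
    "PresenceMatrix",
    "SchemaError",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_vcf_allele_depths",
    "call_presence",
    "build_presence_matrix",
]

PRESENT = "present"
ABSENT = "absent"
UNEVALUABLE = "unevaluable"

_COUNT_COLUMNS = ["mutation_id", "gene", "chrom", "pos", "arm",
                  "sample_id", "ref_count", "alt_count"]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class VariantObservation:
    """One mutation's read counts in one sample."""

    mutation_id: str
    gene: str
    chrom: str
    pos: int
    arm: str
    sample_id: str
    ref_count: int
    alt_count: int

    def __post_init__(self):
        if self.ref_count < 0 or self.alt_count < 0:
            raise SchemaError(f"negative read count for {self.mutation_id}/{self.sample_id}")
        if self.pos < 1:
            raise SchemaError(f"position must be 1-based (>=1), got {self.pos}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else float("nan")


@dataclass(frozen=True)
class PresenceParams:
    min_depth: int = 10        # below this a cell is unevaluable (both modes)
    min_vaf: float = 0.10      # WES: "at least 10% of reads", boundary inclusive
    min_alt: int = 5           # amplicon: minimum supporting reads
    error_rate: float = 0.002  # amplicon: per-read background error rate e0
    alpha: float = 1e-3        # amplicon: one-sided binomial test level


def read_counts_tsv(path) -> List[VariantObservation]:
    """Parse a variant-count TSV; malformed rows are rejected with their
    1-based data row number."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(VariantObservation(
                mutation_id=str(row.mutation_id), gene=str(row.gene),
                chrom=str(row.chrom), pos=int(row.pos), arm=str(row.arm),
                sample_id=str(row.sample_id),
                ref_count=int(row.ref_count), alt_count=int(row.alt_count)))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return out


def write_counts_tsv(observations: Iterable[VariantObservation], path) -> None:
    df = pd.DataFrame([vars(o) for o in observations], columns=_COUNT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def observations_from_frame(df: pd.DataFrame) -> List[VariantObservation]:
    """Typed observations from an in-memory count table (simulator output)."""
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"count table missing column(s) {missing}")
    return [VariantObservation(
        mutation_id=str(r.mutation_id), gene=str(r.gene), chrom=str(r.chrom),
        pos=int(r.pos), arm=str(r.arm), sample_id=str(r.sample_id),
        ref_count=int(r.ref_count), alt_count=int(r.alt_count))
        for r in df.itertuples(index=False)]


def _arm_of(chrom: str, pos: int) -> str:
    # Without a cytoband table the arm is left as the chromosome name; callers
    # supplying TSV input carry explicit arm labels instead.
    return chrom.removeprefix("chr")


def read_vcf_allele_depths(path) -> List[VariantObservation]:
    """One observation per (variant, sample) from a VCF with per-sample AD;
    multi-allelic records are split per alternate allele."""
    import pysam

    vf = pysam.VariantFile(str(path))
    if not list(vf.header.samples):
        raise SchemaError(f"{path}: VCF has no genotype columns")
    if "AD" not in vf.header.formats:
        raise SchemaError(f"{path}: VCF lacks a per-sample AD (allele depth) FORMAT field")
    out = []
    for rec in vf:
        alts = rec.alts or ()
        for sample_id, call in rec.samples.items():
            ad = call.get("AD")
            if ad is None or ad[0] is None:
                continue
            for ai, alt in enumerate(alts, start=1):
                if ai >= len(ad) or ad[ai] is None:
                    continue
                mutation_id = f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}"
                gene = rec.info.get("GENE", mutation_id) if "GENE" in rec.header.info else mutation_id
                out.append(VariantObservation(
                    mutation_id=mutation_id, gene=str(gene),
                    chrom=rec.chrom.removeprefix("chr"), pos=rec.pos,
                    arm=_arm_of(rec.chrom, rec.pos), sample_id=sample_id,
                    ref_count=int(ad[0]), alt_count=int(ad[ai])))
    return out


def call_presence(obs: VariantObservation, mode: str = "wes",
                  params: PresenceParams = PresenceParams()) -> str:
    """Classify one (mutation, sample) cell as present/absent/unevaluable."""
    depth = obs.depth
    if depth < params.min_depth:
        return UNEVALUABLE
    if mode == "wes":
        return PRESENT if obs.alt_count / depth >= params.min_vaf else ABSENT
    if mode == "amplicon":
        if obs.alt_count < params.min_alt:
            return ABSENT
        # one-sided tail P(X >= alt | depth, e0)
        p = stats.binom.sf(obs.alt_count - 1, depth, params.error_rate)
        return PRESENT if p < params.alpha else ABSENT
    raise ValueError(f"unknown presence mode {mode!r}")


@dataclass
class PresenceMatrix:
    """Mutations x samples grid of presence calls."""

    calls: pd.DataFrame  # cells in {present, absent, unevaluable}

    @property
    def mutations(self) -> List[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> List[str]:
        return list(self.calls.columns)

    def is_present(self, mutation_id: str, sample_id: str) -> bool:
        return self.calls.at[mutation_id, sample_id] == PRESENT

    def to_tsv(self, path) -> None:
        coded = self.calls.replace({PRESENT: "1", ABSENT: "0", UNEVALUABLE: "NA"})
        coded.to_csv(path, sep="\t", index_label="mutation_id")


def build_presence_matrix(observations: Sequence[VariantObservation],
                          mode: str = "wes",
                          params: PresenceParams = PresenceParams()) -> PresenceMatrix:
    """Presence matrix over the (mutation, sample) grid; missing cells are
    unevaluable; row/column order follows first appearance in the input."""
    mutations: List[str] = []
    samples: List[str] = []
    seen = {}
    for o in observations:
        key = (o.mutation_id, o.sample_id)
        if key in seen:
            prev = seen[key]
            if (prev.ref_count, prev.alt_count) != (o.ref_count, o.alt_count):
                raise SchemaError(f"conflicting counts for {key}")
            continue
        seen[key] = o
        if o.mutation_id not in mutations:
            mutations.append(o.mutation_id)
        if o.sample_id not in samples:
            samples.append(o.sample_id)
    calls = pd.DataFrame(UNEVALUABLE, index=mutations, columns=samples)
    for (m, s), o in seen.items():
        calls.at[m, s] = call_presence(o, mode, params)
    return PresenceMatrix(calls=calls)
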