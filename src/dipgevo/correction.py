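"""CNV-aware correction of somatic allele counts.

Read counts at a mutated site are rescaled so that allele frequencies are
comparable across copy-number states before feeding them to clone-tree
reconstruction.  The four corrections (Ref, Alt -> Ref', Alt'):

==================  =====================  ==============
event               Ref'                   Alt'
==================  =====================  ==============
duplication         Ref                    Alt / 2
deletion            Ref + Alt              Alt
chrX hemizygous     Ref * 2 + Alt          Alt
copy-neutral LOH    Ref + Alt / 2          Alt / 2
==================  =====================  ==============

Each formula maps a clonal event back onto the diploid-heterozygous scale
(expected corrected VAF 0.5 for a clonal mutation at purity 1) under the
assumptions that a duplication gains the wild-type chromatid and that
deletion / CN-LOH retain the mutant haplotype.  Corrected counts are kept
real-valued; rounding to integers for count likelihoods happens in one place
downstream (:func:`dipgevo.clonetree.estimate_ccf`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .io import VariantObservation
from .cnv import ArmCNVCall

__all__ = ["CorrectedCounts", "correct_counts", "apply_corrections",
           "write_corrected_tsv", "EVENT_LABELS"]

logger = logging.getLogger(__name__)

EVENT_LABELS = ("duplication", "deletion", "cn_loh", "chrX_hemizygous", "none")


@dataclass(frozen=True)
class CorrectedCounts:
    mutation_id: str
    sample_id: str
    ref_prime: float
    alt_prime: float
    event_applied: str
    corrected_vaf: float


def correct_counts(ref: float, alt: float, event: str) -> Tuple[float, float]:
    """Apply one correction formula; ``"none"``/``"neutral"`` is the identity."""
    if ref < 0 or alt < 0:
        raise ValueError("read counts must be nonnegative")
    if event in ("none", "neutral"):
        return float(ref), float(alt)
    if event == "duplication":
        return float(ref), alt / 2.0
    if event == "deletion":
        return float(ref + alt), float(alt)
    if event == "chrX_hemizygous":
        return float(ref * 2 + alt), float(alt)
    if event == "cn_loh":
        return ref + alt / 2.0, alt / 2.0
    raise ValueError(f"unknown CNV event label {event!r}")


def _calls_to_map(cnv_calls) -> Dict[Tuple[str, str], str]:
    if cnv_calls is None:
        return {}
    if isinstance(cnv_calls, Mapping):
        return dict(cnv_calls)
    if isinstance(cnv_calls, pd.DataFrame):
        return {(r.sample_id, r.arm): r.event for r in cnv_calls.itertuples()}
    out = {}
    for c in cnv_calls:
        if isinstance(c, ArmCNVCall):
            out[(c.sample_id, c.arm)] = c.event
        else:
            raise TypeError(f"cannot interpret CNV call {c!r}")
    return out


def apply_corrections(observations: Sequence[VariantObservation],
                      cnv_calls=None,
                      sex: str = "XX",
                      strict: bool = True) -> List[CorrectedCounts]:
    """Join observations to per-(sample, arm) CNV calls and correct counts.

    ``cnv_calls`` may be a list of :class:`~dipgevo.cnv.ArmCNVCall`, a
    DataFrame with columns (sample_id, arm, event), or a mapping
    ``{(sample_id, arm): event}``.  For XY individuals any chromosome-X
    mutation gets the hemizygous correction, taking precedence over the arm
    event.  In strict mode an observation whose arm has no call raises;
    in lenient mode neutral is assumed with a logged warning.  Unevaluable
    arm calls are treated as absent calls.
    """
    if sex not in ("XX", "XY"):
        raise ValueError("sex must be 'XX' or 'XY'")
    call_map = _calls_to_map(cnv_calls)
    out = []
    for obs in observations:
        chrom = obs.chrom.removeprefix("chr")
        if sex == "XY" and chrom == "X":
            event = "chrX_hemizygous"
        else:
            event = call_map.get((obs.sample_id, obs.arm))
            if event in (None, "unevaluable"):
                if strict and cnv_calls is not None:
                    raise KeyError(f"no CNV call for ({obs.sample_id}, {obs.arm}); "
                                   "pass strict=False to assume neutral")
                if cnv_calls is not None:
                    logger.warning("no CNV call for (%s, %s); assuming neutral",
                                   obs.sample_id, obs.arm)
                event = "none"
            elif event == "neutral":
                event = "none"
        ref_p, alt_p = correct_counts(obs.ref_count, obs.alt_count, event)
        total = ref_p + alt_p
        vaf = alt_p / total if total > 0 else float("nan")
        out.append(CorrectedCounts(obs.mutation_id, obs.sample_id,
                                   ref_p, alt_p, event, vaf))
    return out


def write_corrected_tsv(corrected: Iterable[CorrectedCounts], path) -> None:
    pd.DataFrame([vars(c) for c in corrected]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
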