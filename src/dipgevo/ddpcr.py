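"""Poisson quantification of droplet digital PCR assays.

A reaction partitioned into ~12,000-16,000 droplets yields a count of
fluorescence-positive droplets per channel.  Under random partitioning the
number of target molecules per droplet is Poisson, so the mean occupancy is
recovered from the *negative* fraction: lambda = -ln(1 - positive/total).
Concentration is lambda over droplet volume, and the mutant allele fraction
is the mutant concentration as a percentage of total, with a delta-method
95% interval propagated from the per-channel Poisson uncertainty.

The droplet volume (0.85 nl by default, a commonly published value for this
droplet chemistry) is an explicit assumption, not a measured quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

__all__ = ["DropletAssay", "SaturationError", "poisson_lambda",
           "lambda_variance", "concentration", "mutant_fraction",
           "DEFAULT_DROPLET_VOLUME_UL"]

DEFAULT_DROPLET_VOLUME_UL = 0.00085  # 0.85 nl per droplet, in microliters


class SaturationError(ValueError):
    """All droplets positive: concentration unbounded."""


@dataclass(frozen=True)
class DropletAssay:
    positive_droplets: int
    total_droplets: int
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL  # microliters
    channel: str = "mutant"

    def __post_init__(self):
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be > 0")
        if not (0 <= self.positive_droplets <= self.total_droplets):
            raise ValueError("positive_droplets must lie in [0, total_droplets]")
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be > 0")


def poisson_lambda(positive: int, total: int) -> float:
    """Mean molecules per droplet: lambda = -ln(1 - positive/total)."""
    if total <= 0 or positive < 0 or positive > total:
        raise ValueError("need 0 <= positive <= total with total > 0")
    if positive == total:
        raise SaturationError("every droplet positive; concentration unbounded")
    return -math.log1p(-positive / total)


def lambda_variance(positive: int, total: int) -> float:
    """Delta-method variance of the lambda estimate: p / ((1-p) N)."""
    p = positive / total
    if p >= 1.0:
        raise SaturationError("saturated assay has no finite variance")
    return p / ((1.0 - p) * total)


def concentration(assay: DropletAssay) -> float:
    """Copies per microliter: lambda / droplet volume."""
    lam = poisson_lambda(assay.positive_droplets, assay.total_droplets)
    return lam / assay.droplet_volume


def mutant_fraction(mutant: DropletAssay, wildtype: DropletAssay,
                    z: float = 1.959963984540054
                    ) -> Tuple[float, Tuple[float, float]]:
    """Mutant percentage of total gene copies with a delta-method 95% CI.

    The droplet volume cancels when both channels share it; concentrations
    are compared on the lambda scale per droplet-volume.
    """
    cm = concentration(mutant)
    cw = concentration(wildtype)
    total = cm + cw
    if total <= 0:
        raise ValueError("both channels empty; mutant fraction undefined")
    frac = cm / total

    lm = poisson_lambda(mutant.positive_droplets, mutant.total_droplets)
    lw = poisson_lambda(wildtype.positive_droplets, wildtype.total_droplets)
    vm = lambda_variance(mutant.positive_droplets, mutant.total_droplets)
    vw = lambda_variance(wildtype.positive_droplets, wildtype.total_droplets)
    # F = lm / (lm + lw), channels independent
    s = lm / mutant.droplet_volume + lw / wildtype.droplet_volume
    dfm = (lw / wildtype.droplet_volume) / (mutant.droplet_volume * s * s)
    dfw = -(lm / mutant.droplet_volume) / (wildtype.droplet_volume * s * s)
    var = dfm * dfm * vm + dfw * dfw * vw
    half = z * math.sqrt(var)
    lo = max(0.0, frac - half)
    hi = min(1.0, frac + half)
    return 100.0 * frac, (100.0 * lo, 100.0 * hi)
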