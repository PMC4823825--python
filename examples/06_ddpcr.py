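"""Quantify a droplet digital PCR assay with Poisson statistics.

A reaction partitioned into ~15,000 droplets: the mean target molecules per
droplet is lambda = -ln(1 - positive fraction), concentration is lambda per
droplet volume, and the mutant allele fraction is reported as a percentage
of total gene copies with a delta-method 95% interval.
"""

from dipgevo import DropletAssay, concentration, mutant_fraction

mutant = DropletAssay(positive_droplets=2100, total_droplets=15000,
                      channel="mutant")
wildtype = DropletAssay(positive_droplets=5600, total_droplets=15000,
                        channel="wildtype")

print(f"mutant:   {concentration(mutant):8.1f} copies/uL")
print(f"wildtype: {concentration(wildtype):8.1f} copies/uL")

pct, (lo, hi) = mutant_fraction(mutant, wildtype)
print(f"mutant fraction: {pct:.1f}% of total gene copies "
      f"(95% CI {lo:.1f}-{hi:.1f}%)")
# With 14% and 37% positive droplets the occupancies are ~0.151 and ~0.465
# molecules/droplet; the mutant allele is ~25% of total copies, typical of a
# heterozygous somatic mutation in a punch with substantial normal tissue.
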