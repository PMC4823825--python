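"""Apply the CNV-aware read-count corrections.

The four printed formulas rescale ref/alt counts so allele frequencies are
comparable across copy-number states before tree building: duplication
Ref'=Ref, Alt'=Alt/2; deletion Ref'=Ref+Alt, Alt'=Alt; chrX hemizygous (XY)
Ref'=2*Ref+Alt, Alt'=Alt; copy-neutral LOH Ref'=Ref+Alt/2, Alt'=Alt/2.
"""

from dipgevo import correct_counts

cases = [
    (100, 50, "duplication"),
    (60, 40, "deletion"),
    (30, 30, "chrX_hemizygous"),
    (50, 40, "cn_loh"),
    (70, 30, "none"),
]

print(f"{'event':>16} {'ref':>5} {'alt':>4} {'ref_prime':>10} {'alt_prime':>10} "
      f"{'raw VAF':>8} {'corr VAF':>9}")
for ref, alt, event in cases:
    rp, ap = correct_counts(ref, alt, event)
    print(f"{event:>16} {ref:>5} {alt:>4} {rp:>10.1f} {ap:>10.1f} "
          f"{alt/(ref+alt):>8.3f} {ap/(rp+ap):>9.3f}")
# Corrected VAFs feed cellular-frequency estimation (CCF = 2 x VAF / purity);
# the corrections keep clones comparable across arms with different events.
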