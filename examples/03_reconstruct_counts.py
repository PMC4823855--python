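"""Recover exact 2x2 counts from printed rounded statistics.

A published accuracy row (Sn/Sp/PPV/NPV at one decimal plus the cohort
marginals) usually determines the underlying 2x2 table uniquely; the oracle
finds it by brute force over the true-positive count.
"""

from akicode import published_rows, reconstruct_counts

for row in published_rows():
    t = reconstruct_counts(row)
    print(
        f"{row.algorithm:>20} vs {row.reference}:  "
        f"TP={t.tp:3d} FP={t.fp:3d} FN={t.fn:3d} TN={t.tn:3d}  "
        f"(from Sn {row.sn}, Sp {row.sp}, PPV {row.ppv}, NPV {row.npv})"
    )
# Each of the eight unsuppressed published rows yields exactly one consistent
# table; these integer counts are what the planted replication cohort embeds.
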