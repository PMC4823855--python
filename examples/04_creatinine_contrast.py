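"""Contrast creatinine changes between code-positive and code-negative cases.

Does the N17x code separate patients with large creatinine excursions from
those with stable grafts? Summarises the change distributions per code group
and tests the difference with the Mann-Whitney test.
"""

from akicode import RunConfig, SimulationParams, run_pipeline

config = RunConfig(simulation=SimulationParams(n_patients=2000, seed=21), seed=21)
bundle = run_pipeline(config)

report = bundle.contrast
for algorithm, block in report.groupby("algorithm"):
    print(f"\n{algorithm}")
    for _, row in block.iterrows():
        print(
            f"  {row['group']:>13}: n={row['n']:4d}  "
            f"abs change {row['abs_median']:7.1f} ({row['abs_q1']:.1f} to {row['abs_q3']:.1f}) umol/L  "
            f"rel change {row['rel_median']:6.1f} %"
        )
    print(f"  Mann-Whitney two-sided p (absolute change): {block['p_abs'].iloc[0]:.2e}")
# Code-positive patients show a far larger median creatinine rise than
# code-negative ones; the rank test rejects equality of the distributions.
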