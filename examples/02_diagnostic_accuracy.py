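"""Measure coding accuracy on a simulated cohort.

Classifies N17x positivity under the three coding algorithms, cross-tabulates
against the creatinine reference standard, and prints the accuracy report
with Wilson intervals and small-cell suppression applied.
"""

from akicode import RunConfig, SimulationParams, run_pipeline
from akicode.performance import render_performance_text

config = RunConfig(simulation=SimulationParams(n_patients=2000, seed=11), seed=11)
bundle = run_pipeline(config)

print(render_performance_text(bundle.performance))
# Sensitivity sits near the stage-conditional coding rates the generator was
# calibrated with (~28 % against stage >= 1) while specificity stays high;
# rows containing a nonzero cell below the suppression threshold print as
# suppressed instead of leaking small counts.
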