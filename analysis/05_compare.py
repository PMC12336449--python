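"""Step 5: compare ATR/CHK1-axis inhibitor cells against the DMSO control.

Writes results/comparison.json: second-pulse amplitude fold change, median
second-peak advance, and median first-cytokinesis advance with Welch t tests.
The example contrasts the CHK1 inhibitor Rabusertib; change --group-b to any
drug name or condition key (drug@dose) to compare others.
"""

from foxmdyn.cli import main

main(["compare", "--traces", "results/traces.csv",
      "--group-a", "DMSO@0", "--group-b", "Rabusertib",
      "--outdir", "results", "--verbose"])
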