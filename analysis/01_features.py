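"""Step 1: normalize traces and extract per-cell pulse features.

Writes results/features.csv.
"""

from foxmdyn.cli import main

main(["features", "--traces", "results/traces.csv", "--outdir", "results",
      "--verbose"])
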