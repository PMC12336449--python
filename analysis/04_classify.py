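"""Step 4: classify every cell into one of the six fates.

Writes results/fates.csv and results/fate_fractions.csv. Delay rules are
anchored at the DMSO@0 control medians.
"""

from foxmdyn.cli import main

main(["classify", "--traces", "results/traces.csv", "--outdir", "results",
      "--verbose"])
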