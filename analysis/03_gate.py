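"""Step 3: fit DAPI/EdU cutoffs and gate the endpoint stain population.

Writes results/gates.json, results/phases.csv and results/phase_fractions.csv.
"""

from foxmdyn.cli import main

main(["gate", "--stains", "results/stains.csv", "--outdir", "results",
      "--verbose"])
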