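"""Step 0: simulate the default inhibitor panel and endpoint stain population.

Writes results/traces.csv and results/stains.csv. All downstream steps read
from results/, so run the steps in numeric order.
"""

from foxmdyn.cli import main

main(["simulate", "--seed", "1", "--outdir", "results", "--verbose"])
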