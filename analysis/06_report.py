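"""Step 6: produce the single summary document.

Writes results/report.json: cluster assignments, variance-explained table,
per-condition fate fractions and phase fractions.
"""

from foxmdyn.cli import main

main(["report", "--traces", "results/traces.csv",
      "--stains", "results/stains.csv", "--outdir", "results", "--verbose"])
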