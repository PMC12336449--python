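"""Step 2: batch-correct, fit condition-level fPCA, and cluster the drugs.

Writes results/fpca_model.json, results/scores.csv, results/clusters.csv and
results/cluster_summary.json.
"""

from foxmdyn.cli import main

try:
    main(["fpca", "--traces", "results/traces.csv", "--outdir", "results",
          "--verbose"])
except SystemExit as exc:
    if exc.code:
        raise

main(["cluster", "--traces", "results/traces.csv", "--outdir", "results",
      "--verbose"])
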