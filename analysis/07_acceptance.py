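"""Step 7: recompute the acceptance-target metrics from scratch.

Writes results/acceptance.json.
"""

import subprocess
import sys

subprocess.run(
    [sys.executable, "scripts/acceptance.py", "--seed", "1",
     "--out", "results/acceptance.json"],
    check=True,
)
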