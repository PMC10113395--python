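#!/usr/bin/env python
"""Score every analysis stage against the planted truth ledger.

Reports substitution sensitivity and decoy removal, pause-ratio recovery
and control-codon specificity, accessibility effect-size recovery, and the
sign of the usage-abundance correlation, each as pass/fail.
"""

import argparse
import json
from pathlib import Path

from misphe.pipeline import evaluate_recovery

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
args = parser.parse_args()

report = evaluate_recovery(args.run_dir)
print(json.dumps(report, indent=2, sort_keys=True))
print("overall:", "PASS" if report["passed"] else "FAIL")
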