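#!/usr/bin/env python
"""Codon-aligned metagenes of footprint 5'-ends and pause calls.

Profiles UUU (the codon read by the deleted tRNA), UUC (synonymous control)
and AUC (unrelated control).  Stalling appears as an elevated knockout/
control ratio at the A/P/E-site offsets upstream of UUU codons only.
"""

import argparse
from pathlib import Path

import pandas as pd

from misphe.pipeline import stage_ribo

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
args = parser.parse_args()

dataset = args.run_dir / "dataset"
outdir = args.run_dir / "results" / "ribo"
stage_ribo(
    dataset / "cds.fasta",
    dataset / "ribo_counts.tsv",
    dataset / "ribo_design.tsv",
    outdir,
)

calls = pd.read_csv(outdir / "pause_calls.tsv", sep="\t")
print("knockout/control ratios at ribosome-site offsets:")
print(calls.to_string(index=False))
flagged = calls[calls["flagged"]]
if len(flagged):
    print("stalling flagged at:",
          ", ".join(f"{r.codon} {r.site}-site ({r.ko_ctrl_ratio:.2f}x)"
                    for r in flagged.itertuples()))
else:
    print("no stalling flagged")
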