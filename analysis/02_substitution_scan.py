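#!/usr/bin/env python
"""Detect phenylalanine-misincorporation peptides in the DIA report.

Screens identified peptides against the in-silico tryptic digest of the
canonical proteome and of every single-position Phe-substitution variant,
aggregates peptidoform intensities, tests knockout vs control, and removes
near-isobaric artifacts (F->ox-M; F->V plus three ox-Met).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from misphe.pipeline import stage_subscan

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
args = parser.parse_args()

dataset = args.run_dir / "dataset"
outdir = args.run_dir / "results" / "subscan"
stage_subscan(
    dataset / "proteome.fasta",
    dataset / "peptide_report.tsv",
    dataset / "dia_design.tsv",
    outdir,
)

kept = pd.read_csv(outdir / "substitution_report.tsv", sep="\t")
removed = pd.read_csv(outdir / "removed_candidates.tsv", sep="\t")
truth = json.loads((dataset / "truth.json").read_text())
planted = {e["peptide"] for e in truth["planted_substitutions"]}

print(f"substitution candidates kept: {len(kept)} "
      f"(planted: {len(planted)}, recovered: "
      f"{len(planted & set(kept['peptide_sequence']))})")
print(f"near-isobaric candidates removed: {len(removed)}")
print("top candidates by p-value:")
cols = ["peptide_sequence", "substituted", "ratio_knockout", "p_value"]
print(kept[cols].head(5).to_string(index=False))
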