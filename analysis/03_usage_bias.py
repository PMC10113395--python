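#!/usr/bin/env python
"""Relate per-protein amino-acid usage to abundance change.

Computes %Phe per protein, its Spearman correlation with the log2 abundance
ratio (down-sloping when Phe-rich proteins are depleted), and per-residue
usage enrichment between down- and up-regulated protein sets.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from misphe.pipeline import stage_usage

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
args = parser.parse_args()

dataset = args.run_dir / "dataset"
outdir = args.run_dir / "results" / "usage"
stage_usage(dataset / "proteome.fasta", dataset / "abundance_changes.tsv", outdir)

corr = json.loads((outdir / "usage_correlation.json").read_text())
print(f"Spearman rho(%Phe, log2 ratio) = {corr['spearman_rho']:.3f} "
      f"(p = {corr['p_value']:.2e})")
enr_path = outdir / "usage_enrichment.tsv"
if enr_path.exists():
    enr = pd.read_csv(enr_path, sep="\t")
    top = enr.sort_values("p_value").head(5)
    print("residues most different between down- and up-regulated proteins:")
    print(top[["residue", "mean_difference", "direction", "p_value"]]
          .to_string(index=False))
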