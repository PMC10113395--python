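#!/usr/bin/env python
"""Count significant GWAS hits near the tRNA genes.

Applies the p < 0.05 filter and counts hits whose distance to the nearest
tRNA gene boundary falls within windows of 50/100/250/500/1000 bp.
"""

import argparse
from pathlib import Path

import pandas as pd

from misphe.pipeline import stage_gwaswin

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--run-dir", type=Path, default=Path("results/run"))
parser.add_argument("--exclude", default="",
                    help="comma-separated locus ids to drop before counting")
args = parser.parse_args()

dataset = args.run_dir / "dataset"
outdir = args.run_dir / "results" / "gwaswin"
stage_gwaswin(
    dataset / "gwas_hits.tsv",
    dataset / "trna_loci.bed",
    outdir,
    exclude=tuple(x for x in args.exclude.split(",") if x),
)

table = pd.read_csv(outdir / "gwas_window_counts.tsv", sep="\t")
wide = table.pivot(index="category", columns="window", values="n_hits")
print("significant GWAS hits per window (bp):")
print(wide.to_string())
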