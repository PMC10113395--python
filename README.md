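# misphe

Analyses for studying what happens when a cell loses part of its tRNA-Phe
gene family: detection of phenylalanine-misincorporation (mistranslation)
peptides in DIA proteomics, amino-acid-usage bias versus protein abundance
change, codon-aligned ribosome-stalling metagenes, tRNA-locus ATAC-seq
nucleosome-state accessibility, and GWAS-proximity counting — each
exercisable end-to-end on synthetic data with planted ground truth.

## Who this is for

Researchers working with multi-copy tRNA gene families (isodecoders) who
need the downstream consequences of a tRNA gene deletion quantified from
standard assay exports: a peptide-level DIA report, ribosome-footprint
5′-end counts, an ATAC fragment file, and a GWAS hit table. Every stage is
a library function plus a CLI subcommand, and a simulator generates all
inputs with known truth so each detector's sensitivity and false-positive
behaviour can be measured before touching real data.

## The core methods

**Substitution scan.** Every Phe position *i* in each canonical protein *P*
is substituted with each of the other 19 amino acids, giving a variant
library of 19 × ΣF sequences. Identified peptides absent from the tryptic
digest of *every* canonical protein but present in the digest of ≥ 1
variant are substitution candidates, annotated (protein, position,
substituted residue). Peptidoform intensities are summed per bare sequence,
knockout and control replicates compared with a two-sided pooled-variance
*t*-test, and the ratio to the canonical counterpart reported per group.
Candidates whose mass can be matched by the canonical peptide within
0.04 Da under some number *k* ∈ {0..#Met} of methionine oxidations are
removed as near-isobaric artifacts — this always removes F→ox-M
(Δ = −0.0330 Da) and F→V + 3×ox-Met (Δ = −0.0153 Da).

**Usage bias.** Per-protein usage u(a) = count(a)/length; %Phe = 100·u(F).
Spearman's ρ of %Phe against the abundance log₂ ratio over all detected
proteins; per-residue two-sided *t*-tests of usage between down- and
up-regulated protein sets.

**Ribosome stalling.** Footprint 5′-end counts, normalized per transcript,
are averaged across all in-frame occurrences of a query codon (window
−30..+30 nt). A codon the ribosome decodes slowly shows an elevated
knockout/control ratio at the A-site offset (−15 nt; P −12, E −9).
Poly-Phe runs are profiled with the run start as anchor.

**ATAC accessibility.** Fragment lengths are segmented into
nucleosome-free/mono/di/tri states from the smoothed length histogram's
peak periodicity (defaults NF < 100, mono 180–247, di 315–473, tri
558–615 nt when minima are unresolvable). Tn5 cut sites (+4/−5 end shift)
are counted per tRNA gene ±50 nt, and tested per locus × state with
median-of-ratios size factors, a floored method-of-moments
negative-binomial dispersion, a Wald test and BH adjustment.

**GWAS windows.** Hits with p < 0.05 are counted when their distance to
the nearest (non-excluded) tRNA gene boundary is within 50/100/250/500/
1000 bp.

## Worked example

```sh
python analysis/01_simulate.py --seed 1 --run-dir results/run
python analysis/02_substitution_scan.py --run-dir results/run
python analysis/04_ribosome_stalling.py --run-dir results/run
python analysis/05_atac_accessibility.py --run-dir results/run
python analysis/07_recovery_report.py --run-dir results/run
```

The scan reports (seed 1):

```
substitution candidates kept: 100 (planted: 100, recovered: 100)
near-isobaric candidates removed: 20
```

meaning all 100 planted substitution events were recovered, nothing
spurious was reported, and all 20 planted F→ox-M / F→V+3ox decoys were
removed. The ribosome stage prints

```
stalling flagged at: UUU A-site (3.15x)
```

— the planted 3× pause at the UUU A-site offset, recovered as a 3.15-fold
knockout/control ratio, with UUC and AUC profiles flat. The ATAC stage
finds exactly the planted lesion:

```
    locus_id           state  log2_fold_change   p_adjusted
tRNA-Phe-1-1 nucleosome_free         -1.977869 5.217225e-59
```

an estimated log₂ fold change of −1.98 against a planted −2 (a 4-fold
nucleosome-free accessibility loss at one of seven tRNA-Phe loci), with no
off-target locus called. The same stages are available as `misphe`
subcommands (`misphe simulate|subscan|usage|ribo|atac|gwaswin|run|evaluate`)
for running on your own files.

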