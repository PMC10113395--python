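# Methods

This note documents the models, parameter choices and known limitations of
each stage, and what the synthetic-data generator does and does not
emulate.

## Substitution scan

**Model.** Mistranslation at a limiting codon produces peptides whose
sequence matches no tryptic peptide of any canonical protein but does
match a peptide of a single-residue substitution variant. The scan is
sequence-level: a peptide is a candidate iff it is (a) absent from the
digest of every canonical protein — this also excludes candidates that
happen to be canonical peptides of a *different* protein — and (b) present
in the digest of at least one variant. Peptides matching several variants
retain all annotations; an unexplained remainder (non-canonical, matching
no variant) is reported separately rather than silently dropped.

**Digestion.** Trypsin: cleavage C-terminal to K/R except before P, up to
2 missed cleavages, peptide length 7–52 residues. These are conventional
DIA search settings, exposed as parameters; variant digestion uses a fast
path (substitutions outside {K, R, P} cannot alter cleavage sites, so the
canonical digest is reused with the covering peptides letter-swapped),
verified in tests against direct digestion of every variant.

**Statistics.** Peptidoform rows (modification variants of one bare
sequence) are summed per sample before testing — modifications are
bookkeeping, not evidence, at this stage. The group comparison is a
two-sided pooled-variance Student's t-test on per-replicate summed
intensities (Welch by flag); zero variance in both groups with equal means
is defined as p = 1. Ratios are substituted/canonical group means; when
the canonical counterpart is undetected the ratio is NaN and the candidate
is kept. BH-adjusted p-values are reported alongside raw ones.

**Near-isobaric exclusion.** A candidate is removed when
|mass(substituted) + k·15.994915 − mass(canonical)| ≤ 0.04 Da for some
k ∈ {0..#Met(substituted peptide)}. The 0.04 Da default is the smallest
round tolerance covering both phenylalanine patterns (F→ox-M, Δ −0.0330;
F→V + 3×ox-Met, Δ −0.0153) while keeping every other F substitution
(nearest competitor |Δ| ≈ 0.9 Da after oxidation compensation) untouched.
Only Met oxidation is considered compensating mass; oxidation on the
*canonical* side (which would pair with F→Y, Δ +15.9949) is not modelled,
matching the two-pattern exclusion the scan targets. F→L and F→I are mass
identical; candidates with either are annotated "L/I" ambiguous rather
than duplicated. Residue and modification monoisotopic masses are
hard-coded standard values, validated in tests against atomic-composition
arithmetic to 1e-4 Da.

## Usage bias

Usage is computed on the longest isoform per protein id; proportions are
exact counts over length, so rows sum to 1 and repeat-duplication leaves
them invariant. Non-standard residues are dropped with a warning. The
correlation stage uses all paired proteins; the enrichment stage uses only
the up/down sets, mirroring the difference between an all-detected-protein
scatter and a changed-set comparison. No multiple-testing correction is
applied across the 20 residues by default (a BH column is emitted); one
residue's test is the quantity of interest, the rest are context.

## Ribosome stalling

Counts are footprint 5′ ends per nt, the quantity codon-level metagenes
consume. Per transcript, each sample's track is divided by its mean
count/nt (so library depth and transcript expression cancel; scaling any
sample leaves its profile unchanged). Windows of −30..+30 nt around each
in-frame occurrence are extracted; occurrences truncated by transcript
ends are dropped, not padded. Per transcript the occurrence windows are
averaged (default) or summed ("cumulative" mode); transcripts are then
averaged with equal weight, then samples within each group. The mean
default makes a uniform track give a flat profile of exactly 1, which is
the natural normalization for ratio-based pause calling; cumulative mode
is retained for summed-score comparisons.

Site offsets follow the 5′-end convention for ~29–31 nt footprints:
A −15, P −12, E −9 nt from the codon's first base, configurable. An offset
is flagged when the knockout/control ratio exceeds 1.5; zero control
signal with non-zero knockout signal is flagged as infinite and noted.
Transcripts below 0.1 mean counts/nt are excluded. Poly-codon runs
(≥ 2 consecutive query codons) are anchored at the run start.

## ATAC accessibility

Lengths are histogrammed per nt, smoothed with a Gaussian (σ = 10 nt), and
peaks (prominence ≥ 2% of max, ≥ 60 nt apart) located. The period is the
median spacing of the first four peaks; boundaries sit at the histogram
minima between successive peaks, the last interval extending half a period
past the last peak. With fewer than four peaks the conventional defaults
(NF < 100, mono 180–247, di 315–473, tri 558–615 nt) are substituted with
a warning. Intervals are inclusive; lengths outside all intervals are
"unclassified", so states always partition the input.

Cut sites are fragment ends shifted +4 (5′) and −5 (3′) for the Tn5
transposition offset; both ends are counted (flag available) in each
half-open window (gene ± 50 nt). Differential testing is a deliberately
simplified count model — median-of-ratios size factors, per-feature
method-of-moments NB dispersion pooled across groups and floored at 0.01
(a minimal 1% squared biological CV that keeps near-Poisson features from
yielding overconfident calls at n = 3), a Wald test on the log ratio of
group means, BH across loci × states. It is not a reimplementation of any
specific differential-expression package; its null behaviour and
effect-size recovery are established by the simulation tests rather than
by equivalence to external software. Family sums inherit size factors
from the per-locus matrix — estimating them on the summed table would
absorb a genuine family-wide change into the normalization.

GWAS distance is to the nearest boundary of the nearest included gene
(0 inside a gene), so counts are monotone in window size by construction;
excluded loci are removed before distances are computed.

## Synthetic data

The generator emulates the statistical structure each detector assumes,
not the raw assays. DIA intensities are log-normal (between-peptide
σ = 1.0, replicate σ = 0.25 on the natural-log scale) with no missingness
by default; planted substituted peptides appear only in knockout samples
at 0.05 × the canonical intensity; a configurable fraction of Met-bearing
peptides is split into oxidised/unmodified peptidoform rows that conserve
the total. Decoys are planted as F→M rows carrying an oxidation at the
substituted position and as F→V rows with three oxidations on engineered
peptides containing one F and three M (the engineering is part of the
canonical sequences, so the decoys have genuine canonical counterparts).
True planted events avoid F→M and avoid F→V on ≥3-Met peptides: those
patterns are mass-indistinguishable from modified canonical peptidoforms
and therefore unrecoverable by any mass-respecting detector — planting
them as "true" would only measure the simulator, not the scan. Footprint
counts are Poisson with per-gene log-normal rates (σ = 0.3) around a
2 counts/nt background; knockout samples multiply the rate at occurrence
+ offset by 3 (a further ×2 at poly-Phe run anchors). ATAC fragments draw
lengths from a 60/200/400/600 ± 20/25/35/45 nt mixture (weights
0.45/0.3/0.15/0.1), midpoints near the gene body, ~5500 fragments per
locus per sample (≈ 5000 nucleosome-free cuts per locus, the order of
magnitude of deep tRNA-focused ATAC), per-sample log-normal depth factors
(σ = 0.1) for the size factors to absorb, and a 2^−2 scaling of the
nucleosome-free component at the planted locus in knockouts. Defaults
describe the reference study conditions used throughout the tests: 100
proteins of 150–400 residues at 4% Phe, 100 planted events, 5 + 5 DIA
replicates, 50 transcripts of 150–250 codons with 3 + 3 replicates, seven
tRNA-Phe loci with 3 + 3 samples.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: chimeric/ambiguous peptide
identifications and spectrum-level FDR, intensity missingness and
batch structure, ribosome-footprint length heterogeneity and biased
digestion, ATAC sequence bias and peak structure outside the tRNA
windows, and LD structure in GWAS hits. Determinism is part of the
contract: a `SimConfig` (including seed) fixes every output byte, with
independent substreams per modality.

## Problem sizes in the test suite

Recovery tests run at the reference conditions above. Repetition-based
calibration checks scale cohort counts, not the per-unit signal: the
usage null uses 200 permuted 100 vs 100 splits of one 500-protein
proteome; the ribosome null uses 200 cohorts of 15 transcripts at 3 + 3
replicates (smaller cohorts at reduced replication push Poisson noise
into the flag band and would measure the scale-down, not the detector);
the accessibility recovery uses 50 seeds at full per-locus depth. The
acceptance script regenerates everything at the reference conditions from
a single seed.

## Known limitations

- Sequence-level screening cannot see substitutions whose variant peptide
  collides with a canonical peptide elsewhere in the proteome; such events
  are excluded by design and reported in the unexplained set only when
  they match no variant at all.
- The isobaric filter is pattern-limited (Met oxidation as the only
  compensating modification); a full modification-aware open search is out
  of scope.
- The NB Wald test with n = 3 and floored MoM dispersion is conservative
  for near-Poisson counts; strongly overdispersed real data would warrant
  an exact dispersion-shrinkage framework instead.
- Genomic windows ignore strand (they are symmetric) and the cut-site
  counter assumes fragments and windows share one assembly.
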