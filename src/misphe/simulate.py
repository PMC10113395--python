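"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the data modalities of a single-tRNA-gene knockout
experiment: a toy proteome with controllable phenylalanine content, a DIA
peptide report carrying planted misincorporation events and near-isobaric
decoys, ribosome-footprint 5'-end tracks with planted pausing at chosen
codons, ATAC fragment files with nucleosomal length periodicity and a
planted locus-specific accessibility loss, and a GWAS hit table with hits
at controlled distances from tRNA genes.

Every dataset is accompanied by a machine-readable truth ledger (JSON)
listing the planted events, so downstream detection stages can be scored
for sensitivity and specificity.  A fixed :class:`SimConfig` (including its
seed) determines every output byte; independent random streams are derived
per modality so generators can be called in any order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import tryptic_digest
from .io import (
    format_modifications,
    write_counts_tsv,
    write_fasta,
    write_fragments_bed,
    write_loci_bed,
    write_truth,
)

__all__ = [
    "SimConfig",
    "generate_proteome",
    "generate_dia_report",
    "generate_cds",
    "generate_ribo_profile",
    "default_trna_loci",
    "generate_atac_fragments",
    "generate_gwas_table",
    "simulate_dataset",
    "verify_truth",
]

SENSE_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

#: Residues eligible as misincorporation targets by default: amino acids whose
#: codons are near-cognate to UUU/UUC.  Methionine is excluded because an
#: F→M peptide plus one Met oxidation is mass-identical to the canonical
#: peptidoform and therefore unrecoverable by design.
DEFAULT_SUBSTITUTION_TARGETS = {"Y": 0.35, "L": 0.25, "S": 0.20, "C": 0.10, "V": 0.10}

#: ATAC fragment-length mixture: (mean nt, sd nt, weight) for the
#: nucleosome-free, mono-, di- and tri-nucleosome populations.
DEFAULT_FRAGMENT_MIXTURE = [
    (60.0, 20.0, 0.45),
    (200.0, 25.0, 0.30),
    (400.0, 35.0, 0.15),
    (600.0, 45.0, 0.10),
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions exercised throughout the test
    suite: five DIA replicates per genotype, a 5% substituted/canonical
    intensity ratio, a threefold UUU-codon pause at the A-site offset in
    knockouts only, and a 4-fold (log2FC −2) nucleosome-free accessibility
    loss at one of seven tRNA-Phe loci.
    """

    seed: int = 0

    # -- proteome -----------------------------------------------------------
    n_proteins: int = 100
    protein_length_range: tuple[int, int] = (150, 400)
    phe_frequency: float = 0.04

    # -- DIA report ---------------------------------------------------------
    substitution_rate: float = 0.1
    n_substitutions: int | None = 100
    substitution_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_TARGETS)
    )
    substitution_ratio: float = 0.05
    n_oxmet_decoys: int = 10
    n_val3ox_decoys: int = 10
    n_replicates_per_group: int = 5
    intensity_log_mean: float = 14.0
    intensity_log_sd: float = 0.25
    peptide_log_sd: float = 1.0
    mod_split_fraction: float = 0.2

    # -- usage vs abundance -------------------------------------------------
    usage_slope: float = -0.05
    usage_noise_sd: float = 0.2
    usage_direction_threshold: float = 0.2

    # -- ribosome profiling -------------------------------------------------
    n_transcripts: int = 50
    cds_length_codons: tuple[int, int] = (150, 250)
    pause_codons: tuple[str, ...] = ("TTT",)
    pause_multiplier: float = 3.0
    pause_offset: int = -15
    pause_run_multiplier: float = 2.0
    n_polyphe_runs: int = 5
    ribo_background_rate: float = 2.0
    ribo_replicates: int = 3

    # -- ATAC ----------------------------------------------------------------
    fragment_length_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_FRAGMENT_MIXTURE)
    )
    fragments_per_locus: float = 5500.0
    accessibility_fold_change: dict[str, float] = field(
        default_factory=lambda: {"tRNA-Phe-1-1": -2.0}
    )
    accessibility_state: str = "nucleosome_free"
    atac_replicates: int = 3
    atac_depth_log_sd: float = 0.1

    # -- GWAS ----------------------------------------------------------------
    gwas_hit_distances: tuple[int, ...] = (0, 40, 80, 200, 400, 600, 1500)
    gwas_hit_pvalues: tuple[float, ...] = (0.01, 0.01, 0.2, 0.03, 0.04, 0.02, 0.001)
    gwas_categories: tuple[str, ...] = ("neurological", "metabolic", "cardiovascular")

    def __post_init__(self) -> None:
        for name in ("phe_frequency", "substitution_rate", "mod_split_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.substitution_targets:
            w = sum(self.substitution_targets.values())
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"substitution target weights must sum to 1, got {w}")
            bad = set(self.substitution_targets) - set("ACDEGHIKLNQSTVWY")
            if bad:
                raise ValueError(
                    f"invalid substitution targets {sorted(bad)}: must be standard "
                    "residues other than F/M/P/R (which break detectability or cleavage)"
                )
        if any(d < 0 for d in self.gwas_hit_distances):
            raise ValueError("GWAS hit distances must be non-negative")
        mix_w = sum(w for _, _, w in self.fragment_length_mixture)
        if abs(mix_w - 1.0) > 1e-9:
            raise ValueError("fragment mixture weights must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one modality, fully determined by seed."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

# Background residue frequencies (excluding F, whose frequency is configured).
# K and R are kept near their natural ~5.5% so tryptic peptides have
# realistic lengths; the remaining mass is spread evenly.
_BACKGROUND_RESIDUES = "ACDEGHIKLMNPQRSTVWY"


def _residue_probabilities(phe_frequency: float) -> tuple[list[str], np.ndarray]:
    letters = list(_BACKGROUND_RESIDUES) + ["F"]
    probs = np.empty(len(letters))
    kr = 0.055
    rest = (1.0 - phe_frequency - 2 * kr) / (len(_BACKGROUND_RESIDUES) - 2)
    for i, aa in enumerate(_BACKGROUND_RESIDUES):
        probs[i] = kr if aa in "KR" else rest
    probs[-1] = phe_frequency
    return letters, probs


def generate_proteome(config: SimConfig) -> dict[str, str]:
    """Random proteome over the 20 standard amino acids.

    Phenylalanine appears at the configured frequency.  When valine+3-oxMet
    decoys are requested, tryptic peptides containing one F and three M are
    engineered into randomly chosen proteins so the decoy pattern has
    somewhere to live; these motifs are part of the canonical sequences.
    """
    rng = config.rng(1)
    lo, hi = config.protein_length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid protein length range: {config.protein_length_range}")
    letters, probs = _residue_probabilities(config.phe_frequency)
    proteome: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        proteome[f"SYN{i:04d}"] = seq

    if config.n_val3ox_decoys > 0 and config.n_proteins > 0:
        _plant_phe_met_motifs(proteome, config, rng)
    return proteome


def _plant_phe_met_motifs(
    proteome: dict[str, str], config: SimConfig, rng: np.random.Generator
) -> None:
    """Overwrite slices with K-delimited peptides containing one F and 3 M."""
    ids = sorted(proteome)
    filler = np.array(list("AGSTNQHEDV"))
    for _ in range(config.n_val3ox_decoys):
        pid = ids[int(rng.integers(len(ids)))]
        seq = proteome[pid]
        body_len = int(rng.integers(9, 13))  # peptide length incl. terminal K
        body = list(rng.choice(filler, size=body_len - 1)) + ["K"]
        pos = rng.choice(body_len - 1, size=4, replace=False)
        body[pos[0]] = "F"
        for p in pos[1:]:
            body[p] = "M"
        insert = "K" + "".join(body) + "A"
        start = int(rng.integers(1, len(seq) - len(insert) - 1))
        proteome[pid] = seq[:start] + insert + seq[start + len(insert) :]


# ---------------------------------------------------------------------------
# DIA peptide report
# ---------------------------------------------------------------------------


def _canonical_peptides(
    proteome: dict[str, str],
    missed_cleavages: int = 2,
    length_range: tuple[int, int] = (7, 52),
) -> pd.DataFrame:
    rows = []
    for pid, seq in proteome.items():
        for pep in tryptic_digest(seq, missed_cleavages, length_range):
            rows.append((pep.sequence, pid, pep.start, pep.end, pep.missed_cleavages))
    return pd.DataFrame(
        rows, columns=["sequence", "protein_id", "start", "end", "missed"]
    )


def sample_names(n_per_group: int) -> tuple[list[str], list[str]]:
    ctrl = [f"control_{i + 1}" for i in range(n_per_group)]
    ko = [f"knockout_{i + 1}" for i in range(n_per_group)]
    return ctrl, ko


def generate_dia_report(
    proteome: dict[str, str], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """DIA-style peptide report with planted substitutions and decoys.

    Returns ``(report, design, truth)``.  The report holds canonical tryptic
    peptides with log-normal intensities in every sample; each planted
    substitution adds the substituted peptide at ``substitution_ratio`` times
    its canonical intensity in the knockout group only.  Near-isobaric decoys
    are emitted as F→M peptides carrying an oxidation on the substituted
    methionine, and as F→V peptides (on engineered 3-Met peptides) carrying
    three methionine oxidations.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    rng = config.rng(2)
    ctrl, ko = sample_names(config.n_replicates_per_group)
    samples = ctrl + ko
    design = pd.DataFrame(
        {"sample": samples, "group": ["control"] * len(ctrl) + ["knockout"] * len(ko)}
    )

    # Base report: fully cleaved canonical peptides, one protein each.
    digest = _canonical_peptides(proteome, missed_cleavages=0)
    digest = digest.drop_duplicates("sequence", keep=False).reset_index(drop=True)
    # Sequence-level index over the permissive digest (<=2 missed cleavages),
    # used to guarantee planted variant peptides are genuinely non-canonical.
    canonical_any = set(_canonical_peptides(proteome, missed_cleavages=2)["sequence"])

    base_log = rng.normal(config.intensity_log_mean, config.peptide_log_sd, len(digest))
    noise = rng.normal(0.0, config.intensity_log_sd, (len(digest), len(samples)))
    intensities = np.exp(base_log[:, None] + noise)

    rows: list[dict] = []

    def emit(seq: str, mods: str, pid: str, values: np.ndarray) -> None:
        row = {"peptide_sequence": seq, "modifications": mods, "protein_id": pid}
        row.update({s: float(v) for s, v in zip(samples, values)})
        rows.append(row)

    for i, rec in digest.iterrows():
        vals = intensities[i]
        met_pos = [j + 1 for j, aa in enumerate(rec.sequence) if aa == "M"]
        if met_pos and rng.random() < config.mod_split_fraction:
            frac = rng.uniform(0.15, 0.45)
            emit(rec.sequence, "", rec.protein_id, vals * (1 - frac))
            pos = int(met_pos[int(rng.integers(len(met_pos)))])
            emit(rec.sequence, f"Oxidation@{pos}", rec.protein_id, vals * frac)
        else:
            emit(rec.sequence, "", rec.protein_id, vals)

    # -- plant true substitution events -------------------------------------
    phe_sites = []
    for i, rec in digest.iterrows():
        for j, aa in enumerate(rec.sequence):
            if aa == "F":
                phe_sites.append((i, j))
    n_events = (
        config.n_substitutions
        if config.n_substitutions is not None
        else int(round(config.substitution_rate * len(phe_sites)))
    )
    if n_events > 0 and not phe_sites:
        raise ValueError(
            "substitutions requested but the proteome contains no Phe site "
            "inside a quantifiable tryptic peptide (is phe_frequency zero?)"
        )

    targets = sorted(config.substitution_targets)
    target_w = np.array([config.substitution_targets[t] for t in targets])
    order = rng.permutation(len(phe_sites))
    planted_subs: list[dict] = []
    used_sequences: set[str] = set()
    ko_idx = np.array([samples.index(s) for s in ko])

    for k in order:
        if len(planted_subs) >= n_events:
            break
        i, j = phe_sites[k]
        rec = digest.iloc[i]
        target = str(rng.choice(targets, p=target_w))
        if target == "V" and rec.sequence.count("M") >= 3:
            # indistinguishable from the canonical peptidoform by mass
            continue
        variant = rec.sequence[:j] + target + rec.sequence[j + 1 :]
        if variant in canonical_any or variant in used_sequences:
            continue
        used_sequences.add(variant)
        vals = np.zeros(len(samples))
        jitter = np.exp(rng.normal(0.0, config.intensity_log_sd, len(ko_idx)))
        vals[ko_idx] = config.substitution_ratio * intensities[i, ko_idx] * jitter
        emit(variant, "", rec.protein_id, vals)
        planted_subs.append(
            {
                "protein_id": rec.protein_id,
                "position": int(rec.start + j),
                "original": "F",
                "substituted": target,
                "peptide": variant,
                "canonical_peptide": rec.sequence,
                "ratio": config.substitution_ratio,
                "group": "knockout",
            }
        )
    if len(planted_subs) < n_events:
        raise ValueError(
            f"could only plant {len(planted_subs)} of {n_events} requested "
            "substitution events; enlarge the proteome or raise phe_frequency"
        )

    # -- plant near-isobaric decoys ------------------------------------------
    planted_decoys: list[dict] = []
    used_sites = {(d["protein_id"], d["position"]) for d in planted_subs}

    # F -> oxidised M on ordinary F-containing canonical peptides.
    for k in order[::-1]:
        if len(planted_decoys) >= config.n_oxmet_decoys:
            break
        i, j = phe_sites[k]
        rec = digest.iloc[i]
        if (rec.protein_id, int(rec.start + j)) in used_sites:
            continue
        variant = rec.sequence[:j] + "M" + rec.sequence[j + 1 :]
        if variant in canonical_any or variant in used_sequences:
            continue
        used_sequences.add(variant)
        used_sites.add((rec.protein_id, int(rec.start + j)))
        vals = np.zeros(len(samples))
        vals[ko_idx] = config.substitution_ratio * intensities[i, ko_idx]
        emit(variant, f"Oxidation@{j + 1}", rec.protein_id, vals)
        planted_decoys.append(
            {
                "protein_id": rec.protein_id,
                "position": int(rec.start + j),
                "type": "F>ox-M",
                "peptide": variant,
                "canonical_peptide": rec.sequence,
            }
        )
    if len(planted_decoys) < config.n_oxmet_decoys:
        raise ValueError("not enough free Phe peptides to plant ox-Met decoys")

    # F -> V with three oxidised methionines, on the engineered motifs.
    n_planted_v = 0
    motif = digest[
        digest["sequence"].str.count("M").ge(3) & digest["sequence"].str.contains("F")
    ]
    for i, rec in motif.iterrows():
        if n_planted_v >= config.n_val3ox_decoys:
            break
        j = rec.sequence.index("F")
        variant = rec.sequence[:j] + "V" + rec.sequence[j + 1 :]
        if variant in canonical_any or variant in used_sequences:
            continue
        used_sequences.add(variant)
        mods = format_modifications(
            ("Oxidation", p + 1)
            for p, aa in enumerate(variant)
            if aa == "M"
        )
        vals = np.zeros(len(samples))
        vals[ko_idx] = config.substitution_ratio * intensities[i, ko_idx]
        emit(variant, mods, rec.protein_id, vals)
        planted_decoys.append(
            {
                "protein_id": rec.protein_id,
                "position": int(rec.start + j),
                "type": "F>V+3ox",
                "peptide": variant,
                "canonical_peptide": rec.sequence,
            }
        )
        n_planted_v += 1
    if n_planted_v < config.n_val3ox_decoys:
        raise ValueError("not enough engineered 3-Met peptides for F>V decoys")

    report = pd.DataFrame(rows).sort_values(
        ["peptide_sequence", "modifications", "protein_id"], ignore_index=True
    )
    truth = {
        "planted_substitutions": planted_subs,
        "planted_isobaric_decoys": planted_decoys,
        "substitution_ratio": config.substitution_ratio,
    }
    return report, design, truth


def generate_abundance_changes(
    proteome: dict[str, str], config: SimConfig
) -> pd.DataFrame:
    """Protein abundance log2 fold changes with a planted %Phe dependence.

    log2_ratio = usage_slope * percent_phe + N(0, usage_noise_sd).  A
    protein is called ``up``/``down`` when its log2 ratio clears the
    direction threshold, else ``unchanged``.
    """
    from .usage import compute_usage, simulate_usage_abundance

    usage = compute_usage(proteome)
    changes = simulate_usage_abundance(
        usage, config.usage_slope, config.usage_noise_sd, config.rng(6)
    )
    thr = config.usage_direction_threshold
    changes["direction"] = np.select(
        [changes["log2_ratio"] > thr, changes["log2_ratio"] < -thr],
        ["up", "down"],
        default="unchanged",
    )
    return changes


# ---------------------------------------------------------------------------
# Ribosome profiling
# ---------------------------------------------------------------------------


def generate_cds(config: SimConfig) -> dict[str, str]:
    """Random coding sequences: ATG + sense codons + TAA, with a few planted
    poly-phenylalanine runs so run-anchored pausing can be exercised."""
    rng = config.rng(3)
    lo, hi = config.cds_length_codons
    cds: dict[str, str] = {}
    for i in range(config.n_transcripts):
        n_codons = int(rng.integers(lo, hi + 1))
        body = list(rng.choice(SENSE_CODONS, size=n_codons))
        cds[f"TX{i:04d}"] = "ATG" + "".join(body) + "TAA"
    # plant poly-Phe runs (>=2 consecutive UUU codons) at interior positions
    ids = sorted(cds)
    for _ in range(config.n_polyphe_runs):
        tid = ids[int(rng.integers(len(ids)))]
        seq = cds[tid]
        n_codons = len(seq) // 3
        run_len = int(rng.integers(2, 4))
        start_codon = int(rng.integers(15, n_codons - run_len - 2))
        s = start_codon * 3
        cds[tid] = seq[:s] + "TTT" * run_len + seq[s + 3 * run_len :]
    return cds


def _pause_positions(seq: str, codon: str) -> list[int]:
    codon = codon.upper().replace("U", "T")
    return [
        i
        for i in range(0, len(seq) - 2, 3)
        if seq[i : i + 3] == codon
    ]


def generate_ribo_profile(
    cds: dict[str, str], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-nt footprint 5'-end counts for control and knockout samples.

    Background counts are Poisson with a gene-specific rate.  In knockout
    samples only, the rate at position ``occurrence_start + pause_offset`` of
    each pause-codon occurrence is multiplied by ``pause_multiplier``; run
    anchors (>=2 consecutive pause codons) receive a further
    ``pause_run_multiplier``.  Events whose offset falls outside the
    transcript are skipped.

    Returns ``(counts, design, truth)`` with counts in long format
    (transcript_id, position, sample, count).
    """
    rng = config.rng(4)
    ctrl, ko = sample_names(config.ribo_replicates)
    samples = ctrl + ko
    design = pd.DataFrame(
        {"sample": samples, "group": ["control"] * len(ctrl) + ["knockout"] * len(ko)}
    )

    planted = []
    frames = []
    for tid in sorted(cds):
        seq = cds[tid].upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"CDS length of {tid} not divisible by 3")
        n = len(seq)
        gene_rate = config.ribo_background_rate * float(np.exp(rng.normal(0.0, 0.3)))
        rate_ctrl = np.full(n, gene_rate)
        rate_ko = np.full(n, gene_rate)
        for codon in config.pause_codons:
            occ = _pause_positions(seq, codon)
            runs = _run_starts(occ)
            for p in occ:
                at = p + config.pause_offset
                if not 0 <= at < n:
                    continue
                rate_ko[at] *= config.pause_multiplier
                mult = config.pause_multiplier
                if p in runs:
                    rate_ko[at] *= config.pause_run_multiplier
                    mult *= config.pause_run_multiplier
                planted.append(
                    {
                        "transcript_id": tid,
                        "codon": codon.replace("T", "U"),
                        "codon_start": p,
                        "offset": config.pause_offset,
                        "multiplier": mult,
                        "run_anchor": p in runs,
                    }
                )
        counts = np.empty((n, len(samples)), dtype=np.int64)
        for s_i, sample in enumerate(samples):
            rates = rate_ko if sample in ko else rate_ctrl
            counts[:, s_i] = rng.poisson(rates)
        frame = pd.DataFrame(counts, columns=samples)
        frame.insert(0, "position", np.arange(n))
        frame.insert(0, "transcript_id", tid)
        frames.append(frame)

    wide = pd.concat(frames, ignore_index=True)
    counts = wide.melt(
        id_vars=["transcript_id", "position"],
        var_name="sample",
        value_name="count",
    )
    truth = {
        "planted_pauses": planted,
        "pause_multiplier": config.pause_multiplier,
        "pause_offset": config.pause_offset,
        "pause_codons": [c.replace("T", "U") for c in config.pause_codons],
    }
    return counts, design, truth


def _run_starts(occurrences: list[int], min_run: int = 2) -> set[int]:
    """First codon start of each maximal run of consecutive occurrences."""
    starts: set[int] = set()
    occ = set(occurrences)
    for p in occurrences:
        if p - 3 in occ:
            continue
        length = 1
        while p + 3 * length in occ:
            length += 1
        if length >= min_run:
            starts.add(p)
    return starts


# ---------------------------------------------------------------------------
# ATAC fragments
# ---------------------------------------------------------------------------

TRNA_PHE_LOCI = [
    "tRNA-Phe-1-1",
    "tRNA-Phe-1-2",
    "tRNA-Phe-1-3",
    "tRNA-Phe-1-4",
    "tRNA-Phe-1-5",
    "tRNA-Phe-2-1",
    "tRNA-Phe-3-1",
]


def default_trna_loci(gene_width: int = 72, spacing: int = 10_000) -> pd.DataFrame:
    """Seven synthetic tRNA-Phe gene loci on one chromosome, well separated."""
    rows = []
    for i, name in enumerate(TRNA_PHE_LOCI):
        start = 100_000 + i * spacing
        rows.append(("chr13", start, start + gene_width, name, 0, "+"))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "locus_id", "score", "strand"]
    )


STATE_NAMES = ["nucleosome_free", "mono", "di", "tri"]


def generate_atac_fragments(
    trna_loci: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """ATAC fragment intervals per sample with planted accessibility loss.

    Fragment lengths follow the configured nucleosomal mixture; midpoints
    cluster on the gene bodies.  For each planted locus the fragment count
    of the configured nucleosome state is scaled by ``2**log2fc`` in
    knockout samples.  Per-sample sequencing-depth factors (log-normal)
    are applied to all loci, to be absorbed by size-factor normalization.
    """
    if trna_loci.empty:
        raise ValueError("locus set is empty")
    rng = config.rng(5)
    ctrl, ko = sample_names(config.atac_replicates)
    samples = ctrl + ko
    design = pd.DataFrame(
        {"sample": samples, "group": ["control"] * len(ctrl) + ["knockout"] * len(ko)}
    )
    unknown = set(config.accessibility_fold_change) - set(trna_loci["locus_id"])
    if unknown:
        raise ValueError(f"planted accessibility loci not in locus set: {unknown}")
    if config.accessibility_state not in STATE_NAMES:
        raise ValueError(f"unknown nucleosome state: {config.accessibility_state}")

    means = np.array([m for m, _, _ in config.fragment_length_mixture])
    sds = np.array([s for _, s, _ in config.fragment_length_mixture])
    weights = np.array([w for _, _, w in config.fragment_length_mixture])
    state_of_component = STATE_NAMES[: len(means)]

    depth = {s: float(np.exp(rng.normal(0.0, config.atac_depth_log_sd))) for s in samples}

    chroms, starts, ends, samp_col = [], [], [], []
    for _, locus in trna_loci.iterrows():
        center = 0.5 * (locus.start + locus.end)
        span = locus.end - locus.start
        planted_fc = config.accessibility_fold_change.get(locus.locus_id)
        for sample in samples:
            for comp, (m, sd, w) in enumerate(zip(means, sds, weights)):
                lam = config.fragments_per_locus * w * depth[sample]
                if (
                    planted_fc is not None
                    and sample in ko
                    and state_of_component[comp] == config.accessibility_state
                ):
                    lam *= 2.0**planted_fc
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                lengths = np.maximum(20, rng.normal(m, sd, n)).astype(int)
                mids = rng.uniform(center - span / 2 - 30, center + span / 2 + 30, n)
                frag_start = np.maximum(0, (mids - lengths / 2).astype(int))
                chroms.extend([locus.chrom] * n)
                starts.append(frag_start)
                ends.append(frag_start + lengths)
                samp_col.extend([sample] * n)

    fragments = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts) if starts else np.array([], dtype=int),
            "end": np.concatenate(ends) if ends else np.array([], dtype=int),
            "sample": samp_col,
        }
    ).sort_values(["chrom", "start", "end", "sample"], ignore_index=True)

    truth = {
        "planted_accessibility_changes": [
            {
                "locus_id": locus,
                "state": config.accessibility_state,
                "log2_fold_change": fc,
            }
            for locus, fc in sorted(config.accessibility_fold_change.items())
        ],
        "depth_factors": depth,
    }
    return fragments, design, truth


# ---------------------------------------------------------------------------
# GWAS table
# ---------------------------------------------------------------------------


def generate_gwas_table(trna_loci: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """GWAS hits at exact configured distances from the tRNA loci.

    Hits alternate between upstream and downstream placement; distance 0
    places the hit inside the gene body.  p-values and trait categories are
    cycled from the configured lists.
    """
    if not len(config.gwas_hit_distances):
        return pd.DataFrame(columns=["chrom", "pos", "pvalue", "category"])
    loci = trna_loci.reset_index(drop=True)
    rows = []
    for i, dist in enumerate(config.gwas_hit_distances):
        locus = loci.iloc[i % len(loci)]
        if dist == 0:
            pos = int((locus.start + locus.end) // 2)
        elif i % 2 == 0:
            pos = int(locus.start - dist)
        else:
            pos = int(locus.end - 1 + dist)
        rows.append(
            {
                "chrom": locus.chrom,
                "pos": pos,
                "pvalue": config.gwas_hit_pvalues[i % len(config.gwas_hit_pvalues)],
                "category": config.gwas_categories[i % len(config.gwas_categories)],
                "distance": int(dist),
                "locus_id": locus.locus_id,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dataset assembly and truth verification
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every modality and write it under ``outdir``.

    Emits: ``proteome.fasta``, ``peptide_report.tsv``, ``dia_design.tsv``,
    ``cds.fasta``, ``ribo_counts.tsv``, ``ribo_design.tsv``,
    ``fragments.bed``, ``atac_design.tsv``, ``trna_loci.bed``,
    ``gwas_hits.tsv`` and ``truth.json``.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    proteome = generate_proteome(config)
    report, dia_design, dia_truth = generate_dia_report(proteome, config)
    changes = generate_abundance_changes(proteome, config)
    cds = generate_cds(config)
    ribo_counts, ribo_design, ribo_truth = generate_ribo_profile(cds, config)
    loci = default_trna_loci()
    fragments, atac_design, atac_truth = generate_atac_fragments(loci, config)
    gwas = generate_gwas_table(loci, config)

    def save(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        paths[name] = path

    save("proteome.fasta", write_fasta, proteome)
    save("peptide_report.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), report)
    save("dia_design.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), dia_design)
    save(
        "abundance_changes.tsv",
        lambda df, p: df.to_csv(p, sep="\t", index=False),
        changes,
    )
    save("cds.fasta", write_fasta, cds)
    save("ribo_counts.tsv", write_counts_tsv, ribo_counts)
    save("ribo_design.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), ribo_design)
    save("fragments.bed", write_fragments_bed, fragments)
    save("atac_design.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), atac_design)
    save("trna_loci.bed", write_loci_bed, loci)
    save("gwas_hits.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), gwas)

    truth = {
        "seed": config.seed,
        "config": _config_as_json(config),
        "planted_usage_effect": {
            "slope": config.usage_slope,
            "noise_sd": config.usage_noise_sd,
        },
        **dia_truth,
        **ribo_truth,
        **atac_truth,
        "gwas_hits": gwas.to_dict(orient="records"),
    }
    write_truth(truth, outdir / "truth.json")
    paths["truth.json"] = outdir / "truth.json"
    return paths


def _config_as_json(config: SimConfig) -> dict:
    out = dataclasses.asdict(config)
    out["fragment_length_mixture"] = [list(c) for c in config.fragment_length_mixture]
    return out


def verify_truth(truth: dict, report: pd.DataFrame, cds: dict[str, str]) -> None:
    """Assert that every planted event is represented in the emitted records.

    Raises ``AssertionError`` naming the first missing event.
    """
    observed = set(report["peptide_sequence"])
    for ev in truth.get("planted_substitutions", []):
        assert ev["peptide"] in observed, f"planted substitution missing: {ev}"
    for ev in truth.get("planted_isobaric_decoys", []):
        assert ev["peptide"] in observed, f"planted decoy missing: {ev}"
    for ev in truth.get("planted_pauses", []):
        tid = ev["transcript_id"]
        assert tid in cds, f"planted pause on unknown transcript: {ev}"
        codon = ev["codon"].replace("U", "T")
        seq = cds[tid].upper().replace("U", "T")
        start = ev["codon_start"]
        assert seq[start : start + 3] == codon, f"planted pause codon mismatch: {ev}"
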