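"""Detection of amino-acid misincorporation events from a DIA peptide report.

The strategy: every phenylalanine position in the canonical proteome is
substituted with each of the other 19 amino acids to form a variant
library.  Identified peptides that match no canonical tryptic peptide of
any protein, but do match a tryptic peptide of a substitution variant, are
substitution candidates.  Candidate intensities are summed across
peptidoforms, compared between genotypes with a two-sided Student's t-test,
expressed as a ratio to the canonical peptide, and finally screened to
remove candidates whose mass is indistinguishable from a modified canonical
peptidoform (phenylalanine to oxidised methionine, or phenylalanine to
valine plus three oxidised methionines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .digest import tryptic_digest, validate_protein_sequence
from .masses import DEFAULT_MASS_MODEL, MassModel, peptide_mass

__all__ = [
    "SubstitutionVariant",
    "ScanParams",
    "ScanResult",
    "build_substitution_library",
    "variant_peptide_index",
    "canonical_peptide_set",
    "screen_candidates",
    "aggregate_peptidoforms",
    "test_candidates",
    "isobaric_filter",
    "substitution_report",
    "scan_peptide_report",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SubstitutionVariant:
    """One full-length protein sequence with a single residue substituted."""

    protein_id: str
    position: int  # 1-based residue index of the original target residue
    original: str
    substituted: str
    variant_sequence: str


@dataclass
class ScanParams:
    """Tunable parameters of the substitution scan."""

    target_residue: str = "F"
    missed_cleavages: int = 2
    length_range: tuple[int, int] = (7, 52)
    isobaric_tolerance_da: float = 0.04
    welch: bool = False
    mass_model: MassModel = field(default_factory=lambda: DEFAULT_MASS_MODEL)


def build_substitution_library(
    proteome: dict[str, str], target_residue: str = "F"
) -> list[SubstitutionVariant]:
    """All single-position substitutions of ``target_residue``.

    For every occurrence of the target residue there are exactly 19
    variants; the self-substitution equals the canonical sequence and is
    not emitted.
    """
    if target_residue not in AMINO_ACIDS:
        raise ValueError(f"invalid target residue: {target_residue!r}")
    variants: list[SubstitutionVariant] = []
    for pid, seq in proteome.items():
        validate_protein_sequence(seq, pid)
        for i, aa in enumerate(seq):
            if aa != target_residue:
                continue
            for sub in AMINO_ACIDS:
                if sub == target_residue:
                    continue
                variants.append(
                    SubstitutionVariant(
                        protein_id=pid,
                        position=i + 1,
                        original=target_residue,
                        substituted=sub,
                        variant_sequence=seq[:i] + sub + seq[i + 1 :],
                    )
                )
    return variants


def canonical_peptide_set(proteome: dict[str, str], params: ScanParams) -> set[str]:
    """Sequences of all tryptic peptides of all proteins."""
    peptides: set[str] = set()
    for seq in proteome.values():
        peptides.update(
            p.sequence
            for p in tryptic_digest(seq, params.missed_cleavages, params.length_range)
        )
    return peptides


def variant_peptide_index(
    variants: list[SubstitutionVariant], params: ScanParams
) -> dict[str, list[dict]]:
    """Map variant-specific tryptic peptides to their source annotations.

    Only peptides covering the substituted position are variant-specific;
    all others equal canonical peptides.  Each annotation records the
    protein, the substituted position, the replacement residue and the
    canonical counterpart peptide (the same span with the original residue
    restored), which is what intensity ratios are computed against.
    """
    index: dict[str, list[dict]] = {}
    # Substituting a residue by anything outside {K, R, P} cannot create,
    # destroy or unsuppress a trypsin cleavage site (the original residue is
    # never K/R/P itself, being the substitution target), so the variant
    # digest equals the canonical digest with the covering peptides letter-
    # swapped.  Only K/R/P substitutions need a fresh digest.
    canonical_cache: dict[str, list] = {}

    def canonical_digest(var: SubstitutionVariant) -> list:
        if var.protein_id not in canonical_cache:
            canonical_seq = (
                var.variant_sequence[: var.position - 1]
                + var.original
                + var.variant_sequence[var.position :]
            )
            canonical_cache[var.protein_id] = tryptic_digest(
                canonical_seq, params.missed_cleavages, params.length_range
            )
        return canonical_cache[var.protein_id]

    for var in variants:
        if var.substituted in "KRP" or var.original in "KRP":
            peptides = tryptic_digest(
                var.variant_sequence, params.missed_cleavages, params.length_range
            )
            covering = [
                (p.sequence, p.start, p.end)
                for p in peptides
                if p.start <= var.position <= p.end
            ]
        else:
            covering = []
            for p in canonical_digest(var):
                if p.start <= var.position <= p.end:
                    off = var.position - p.start
                    covering.append(
                        (
                            p.sequence[:off] + var.substituted + p.sequence[off + 1 :],
                            p.start,
                            p.end,
                        )
                    )
        for seq, start, _end in covering:
            offset = var.position - start  # 0-based within peptide
            canonical = seq[:offset] + var.original + seq[offset + 1 :]
            index.setdefault(seq, []).append(
                {
                    "protein_id": var.protein_id,
                    "position": var.position,
                    "original": var.original,
                    "substituted": var.substituted,
                    "peptide_position": offset + 1,
                    "canonical_peptide": canonical,
                }
            )
    return index


def aggregate_peptidoforms(
    report: pd.DataFrame, sample_columns: list[str]
) -> pd.DataFrame:
    """Sum intensities across all modification forms of each peptide.

    Returns one row per bare sequence with summed per-sample intensities,
    the (majority) protein assignment, and the number of contributing
    peptidoform rows.  Conflicting protein assignments trigger a warning.
    """
    def majority_protein(group: pd.Series) -> str:
        counts = group.value_counts()
        if len(counts) > 1:
            warnings.warn(
                f"conflicting protein assignments for a peptide: {list(counts.index)}; "
                "keeping the majority assignment",
                stacklevel=2,
            )
        return counts.index[0]

    grouped = report.groupby("peptide_sequence", sort=True)
    agg = grouped[sample_columns].sum()
    agg["protein_id"] = grouped["protein_id"].agg(majority_protein)
    agg["n_peptidoforms"] = grouped.size()
    return agg.reset_index()


def screen_candidates(
    aggregated: pd.DataFrame,
    canonical_set: set[str],
    variant_index: dict[str, list[dict]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split identified peptides into substitution candidates and leftovers.

    A peptide is a candidate iff its sequence is absent from the canonical
    digest of every protein and present in the digest of at least one
    substitution variant.  Returns ``(candidates, unexplained)``;
    candidates carry one row per matching variant annotation.
    """
    cand_rows = []
    unexplained = []
    for _, row in aggregated.iterrows():
        seq = row["peptide_sequence"]
        if seq in canonical_set:
            continue
        annotations = variant_index.get(seq)
        if annotations is None:
            unexplained.append(row)
            continue
        for ann in annotations:
            out = dict(row)
            out.update(ann)
            out["ambiguity"] = "L/I" if ann["substituted"] in "LI" else ""
            cand_rows.append(out)
    candidates = pd.DataFrame(cand_rows)
    unexplained_df = pd.DataFrame(unexplained)
    return candidates, unexplained_df


def _ttest(ko: np.ndarray, ctrl: np.ndarray, welch: bool) -> float:
    """Two-sided t-test p-value with degenerate cases pinned down."""
    if len(ko) < 2 or len(ctrl) < 2:
        return float("nan")
    if np.var(ko) == 0 and np.var(ctrl) == 0:
        return 1.0 if np.mean(ko) == np.mean(ctrl) else 0.0
    res = stats.ttest_ind(ko, ctrl, equal_var=not welch)
    return float(res.pvalue)


def test_candidates(
    candidates: pd.DataFrame,
    aggregated: pd.DataFrame,
    design: pd.DataFrame,
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Attach group means, t-test p-values and canonical-relative ratios.

    The test compares the candidate's per-replicate summed intensities
    between the two groups (two-sided, pooled variance by default).  The
    ratio per group is mean(substituted) / mean(canonical counterpart);
    when the canonical peptide was not detected the ratio is NaN and the
    candidate is retained.
    """
    params = params or ScanParams()
    if candidates.empty:
        return candidates.assign(
            mean_control=[], mean_knockout=[], p_value=[],
            ratio_control=[], ratio_knockout=[], canonical_detected=[],
        )
    groups = design.groupby("group")["sample"].agg(list)
    ctrl_samples, ko_samples = groups.get("control", []), groups.get("knockout", [])
    canon_lookup = aggregated.set_index("peptide_sequence")

    out = candidates.copy()
    stats_rows = []
    for _, row in candidates.iterrows():
        ko = np.asarray([row[s] for s in ko_samples], dtype=float)
        ctrl = np.asarray([row[s] for s in ctrl_samples], dtype=float)
        rec = {
            "mean_control": float(ctrl.mean()) if len(ctrl) else np.nan,
            "mean_knockout": float(ko.mean()) if len(ko) else np.nan,
            "p_value": _ttest(ko, ctrl, params.welch),
        }
        canonical = row["canonical_peptide"]
        if canonical in canon_lookup.index:
            canon = canon_lookup.loc[canonical]
            c_ctrl = float(np.mean([canon[s] for s in ctrl_samples]))
            c_ko = float(np.mean([canon[s] for s in ko_samples]))
            rec["ratio_control"] = rec["mean_control"] / c_ctrl if c_ctrl > 0 else np.nan
            rec["ratio_knockout"] = rec["mean_knockout"] / c_ko if c_ko > 0 else np.nan
            rec["canonical_detected"] = True
        else:
            rec["ratio_control"] = np.nan
            rec["ratio_knockout"] = np.nan
            rec["canonical_detected"] = False
        stats_rows.append(rec)
    return pd.concat([out.reset_index(drop=True), pd.DataFrame(stats_rows)], axis=1)


test_candidates.__test__ = False  # statistical op, not a pytest case


def isobaric_match(
    substituted_peptide: str,
    canonical_peptide: str,
    mass_model: MassModel,
    tolerance_da: float,
) -> tuple[bool, str]:
    """Can any 0..k Met-oxidation assignment make the masses identical?

    ``k`` is the methionine count of the substituted peptide.  Returns
    ``(matched, reason)``; the reason names the matching combination and
    the residual mass difference.
    """
    base_delta = peptide_mass(substituted_peptide, mass_model=mass_model) - peptide_mass(
        canonical_peptide, mass_model=mass_model
    )
    ox = mass_model.modification("Oxidation")
    n_met = substituted_peptide.count("M")
    sub_residues = [
        b for a, b in zip(canonical_peptide, substituted_peptide) if a != b
    ]
    sub = sub_residues[0] if sub_residues else "?"
    for n_ox in range(n_met + 1):
        delta = base_delta + n_ox * ox
        if abs(delta) <= tolerance_da:
            if sub == "M" and n_ox == 1:
                label = "F→ox-M"
            elif n_ox == 0:
                label = f"F→{sub}"
            else:
                label = f"F→{sub} + {n_ox}×ox-Met"
            return True, f"{label}, Δ={delta:+.4f} Da"
    return False, ""


def isobaric_filter(
    candidates: pd.DataFrame, params: ScanParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition candidates into kept and removed (near-isobaric) sets.

    A candidate is removed when some number of methionine oxidations on the
    substituted peptide brings its mass within tolerance of the canonical
    counterpart — this always removes F→ox-M and F→V+3×ox-Met patterns at
    the default 0.04 Da tolerance.
    """
    params = params or ScanParams()
    if candidates.empty:
        return candidates.assign(isobaric_reason=[]).iloc[:0], candidates.assign(
            isobaric_reason=[]
        ).iloc[:0]
    flags, reasons = [], []
    for _, row in candidates.iterrows():
        matched, reason = isobaric_match(
            row["peptide_sequence"],
            row["canonical_peptide"],
            params.mass_model,
            params.isobaric_tolerance_da,
        )
        flags.append(matched)
        reasons.append(reason)
    out = candidates.copy()
    out["isobaric_reason"] = reasons
    mask = np.asarray(flags)
    return out[~mask].reset_index(drop=True), out[mask].reset_index(drop=True)


def substitution_report(kept: pd.DataFrame, sample_columns: list[str]) -> pd.DataFrame:
    """Final candidate table: sorted by p-value, with a BH-adjusted column."""
    columns = [
        "peptide_sequence", "protein_id", "position", "original", "substituted",
        "ambiguity", "canonical_peptide", "canonical_detected",
        "mean_control", "mean_knockout", "ratio_control", "ratio_knockout",
        "p_value", "p_adjusted",
    ]
    if kept.empty:
        return pd.DataFrame(columns=columns)
    out = kept.copy()
    pvals = out["p_value"].to_numpy(dtype=float)
    adjusted = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        adjusted[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    out["p_adjusted"] = adjusted
    out = out.sort_values(
        ["p_value", "peptide_sequence", "substituted"], na_position="last",
        ignore_index=True,
    )
    return out[columns]


@dataclass
class ScanResult:
    """Everything the substitution scan produces."""

    report: pd.DataFrame       # kept candidates, tested and sorted
    removed: pd.DataFrame      # near-isobaric candidates with reasons
    unexplained: pd.DataFrame  # non-canonical peptides matching no variant
    n_variants: int
    n_canonical_peptides: int


def scan_peptide_report(
    proteome: dict[str, str],
    report: pd.DataFrame,
    design: pd.DataFrame,
    params: ScanParams | None = None,
) -> ScanResult:
    """Run the full substitution scan on one peptide report."""
    params = params or ScanParams()
    sample_columns = [c for c in design["sample"] if c in report.columns]
    missing = set(design["sample"]) - set(sample_columns)
    if missing:
        raise ValueError(f"design samples missing from report: {sorted(missing)}")

    variants = build_substitution_library(proteome, params.target_residue)
    canonical = canonical_peptide_set(proteome, params)
    index = variant_peptide_index(variants, params)

    aggregated = aggregate_peptidoforms(report, sample_columns)
    candidates, unexplained = screen_candidates(aggregated, canonical, index)
    tested = test_candidates(candidates, aggregated, design, params)
    kept, removed = isobaric_filter(tested, params)
    final = substitution_report(kept, sample_columns)
    return ScanResult(
        report=final,
        removed=removed,
        unexplained=unexplained,
        n_variants=len(variants),
        n_canonical_peptides=len(canonical),
    )
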