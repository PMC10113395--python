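"""Amino-acid usage versus protein abundance change.

When a tRNA becomes limiting, proteins rich in the corresponding amino acid
are translated less efficiently.  This module computes per-protein
amino-acid usage (occurrence / length), correlates phenylalanine content
with abundance log2 fold change (Spearman), and compares per-residue usage
between down- and up-regulated protein sets with two-sided t-tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_usage",
    "phe_abundance_correlation",
    "usage_enrichment",
    "simulate_usage_abundance",
]

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")


def compute_usage(
    proteome: dict[str, str | list[str]], isoform_policy: str = "longest"
) -> pd.DataFrame:
    """Per-protein residue usage proportions.

    ``proteome`` maps protein id to a sequence or a list of isoform
    sequences; with the default policy the longest isoform is used.
    Non-standard residues (U, X, ...) are dropped from the counts with a
    warning.  Returns a DataFrame indexed by protein id with one column per
    residue (proportions summing to 1), plus ``length`` and ``percent_phe``.
    """
    if isoform_policy != "longest":
        raise ValueError(f"unknown isoform policy: {isoform_policy!r}")
    rows = {}
    warned = False
    for pid, seqs in proteome.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        if not seqs or not max(seqs, key=len):
            raise ValueError(f"protein {pid}: empty sequence")
        seq = max(seqs, key=len).upper()
        counts = pd.Series(list(seq)).value_counts()
        nonstandard = set(counts.index) - set(AMINO_ACIDS)
        if nonstandard and not warned:
            warnings.warn(
                f"dropping non-standard residues {sorted(nonstandard)} from usage counts",
                stacklevel=2,
            )
            warned = True
        counts = counts.reindex(AMINO_ACIDS, fill_value=0)
        total = int(counts.sum())
        if total == 0:
            raise ValueError(f"protein {pid}: no standard residues")
        rows[pid] = counts / total
    usage = pd.DataFrame.from_dict(rows, orient="index")
    usage.index.name = "protein_id"
    usage["length"] = [
        len(max([s] if isinstance(s, str) else s, key=len))
        for s in proteome.values()
    ]
    usage["percent_phe"] = 100.0 * usage["F"]
    return usage


def phe_abundance_correlation(
    usage: pd.DataFrame, changes: pd.DataFrame
) -> tuple[float, float]:
    """Spearman rank correlation of %Phe against abundance log2 ratio.

    ``changes`` must carry columns ``protein_id`` and ``log2_ratio``; the
    correlation is computed over the id intersection.  Ties receive average
    ranks.  Requires at least 3 paired proteins.
    """
    merged = changes.merge(
        usage[["percent_phe"]], left_on="protein_id", right_index=True
    )
    if len(merged) < 3:
        raise ValueError(f"need >= 3 paired proteins, got {len(merged)}")
    rho, p = stats.spearmanr(merged["percent_phe"], merged["log2_ratio"])
    return float(rho), float(p)


def usage_enrichment(
    up_ids: list[str], down_ids: list[str], usage: pd.DataFrame, welch: bool = False
) -> pd.DataFrame:
    """Per-residue usage difference between down- and up-regulated proteins.

    For each of the 20 residues, a two-sided pooled-variance t-test of the
    usage proportions between the down and up sets.  Positive
    ``mean_difference`` means higher usage in the down-regulated set.  Raw
    p-values are reported (one test per residue); a BH-adjusted column is
    added alongside.
    """
    if not len(up_ids) or not len(down_ids):
        raise ValueError("both protein sets must be non-empty")
    up = usage.loc[[i for i in up_ids if i in usage.index], AMINO_ACIDS]
    down = usage.loc[[i for i in down_ids if i in usage.index], AMINO_ACIDS]
    rows = []
    for aa in AMINO_ACIDS:
        u, d = up[aa].to_numpy(), down[aa].to_numpy()
        diff = float(d.mean() - u.mean())
        if len(u) < 2 or len(d) < 2:
            p = np.nan
        elif np.var(u) == 0 and np.var(d) == 0:
            p = 1.0 if d.mean() == u.mean() else 0.0
        else:
            p = float(stats.ttest_ind(d, u, equal_var=not welch).pvalue)
        rows.append(
            {
                "residue": aa,
                "mean_up": float(u.mean()),
                "mean_down": float(d.mean()),
                "mean_difference": diff,
                "direction": "higher_in_down" if diff > 0 else (
                    "higher_in_up" if diff < 0 else "equal"
                ),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(
            out.loc[ok, "p_value"], method="fdr_bh"
        )[1]
    return out


def simulate_usage_abundance(
    usage: pd.DataFrame,
    slope: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Abundance changes with a planted linear dependence on %Phe.

    log2_ratio = slope * percent_phe + N(0, noise_sd), one draw per
    protein.  Used by the simulator and the calibration tests.
    """
    log2 = slope * usage["percent_phe"].to_numpy() + rng.normal(
        0.0, noise_sd, len(usage)
    )
    return pd.DataFrame({"protein_id": usage.index, "log2_ratio": log2})
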