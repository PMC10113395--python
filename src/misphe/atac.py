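"""ATAC fragment-length segmentation, tRNA-locus accessibility and GWAS windows.

Tn5 preferentially inserts into open chromatin, so ATAC fragment lengths
form a mixture: short fragments (< ~100 nt) from nucleosome-free DNA and
~190 nt-periodic populations protected by one, two or three nucleosomes.
This module estimates that periodicity, segments fragments into nucleosome
states, counts Tn5 cut sites in tRNA-gene windows (gene span ±50 nt), and
tests differential accessibility between genotypes with a simplified
count-model test (median-of-ratios size factors, method-of-moments
negative-binomial dispersion, Wald test, BH adjustment).  A separate
routine counts GWAS hits falling within fixed windows of tRNA genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from statsmodels.stats.multitest import multipletests

__all__ = [
    "STATE_NAMES",
    "DEFAULT_BOUNDARIES",
    "LengthSegmentation",
    "estimate_segmentation",
    "classify_fragments",
    "make_locus_windows",
    "count_cut_sites",
    "state_coverage_bedgraph",
    "differential_accessibility",
    "family_sum",
    "gwas_window_counts",
]

STATE_NAMES = ["nucleosome_free", "mono", "di", "tri"]

#: Fallback length intervals (inclusive), used when histogram minima cannot
#: be resolved: nucleosome-free < 100 nt, mono 180-247, di 315-473,
#: tri 558-615.
DEFAULT_BOUNDARIES: list[tuple[int, int]] = [(0, 99), (180, 247), (315, 473), (558, 615)]


@dataclass
class LengthSegmentation:
    """Fragment-length histogram with nucleosome-state boundaries."""

    histogram: np.ndarray          # count per length (index = length, nt)
    period: float                  # nt between successive nucleosomal peaks
    boundaries: list[tuple[int, int]]  # four inclusive (lo, hi) intervals
    resolved: bool                 # False when defaults were substituted

    def __post_init__(self) -> None:
        for (lo1, hi1), (lo2, _) in zip(self.boundaries, self.boundaries[1:]):
            if not (lo1 <= hi1 < lo2):
                raise ValueError("state intervals must be disjoint and increasing")


def estimate_segmentation(
    fragments: pd.DataFrame,
    smoothing_sd: float = 10.0,
    min_fragments: int = 1000,
) -> LengthSegmentation:
    """Estimate nucleosome periodicity and state boundaries from lengths.

    The length histogram is Gaussian-smoothed; the period is the median
    spacing of successive peaks, and state boundaries are placed at the
    histogram minima between them.  If fewer than four peaks are resolved
    the conventional default boundaries are used instead (with a warning).
    """
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    if len(lengths) < min_fragments:
        raise ValueError(
            f"need >= {min_fragments} fragments to estimate segmentation "
            f"(got {len(lengths)}); consider the default boundaries"
        )
    max_len = int(lengths.max()) + 1
    hist = np.bincount(lengths, minlength=max_len).astype(float)
    smooth = gaussian_filter1d(hist, smoothing_sd)
    peaks, _ = find_peaks(smooth, prominence=0.02 * smooth.max(), distance=60)
    if len(peaks) < 4:
        warnings.warn(
            f"only {len(peaks)} length-histogram peaks resolved; "
            "falling back to default state boundaries",
            stacklevel=2,
        )
        return LengthSegmentation(
            histogram=hist, period=float("nan"),
            boundaries=list(DEFAULT_BOUNDARIES), resolved=False,
        )
    peaks = peaks[:4]
    spacings = np.diff(peaks)
    period = float(np.median(spacings))
    minima = [
        int(p1 + np.argmin(smooth[p1 : p2 + 1])) for p1, p2 in zip(peaks, peaks[1:])
    ]
    upper = min(max_len - 1, int(peaks[-1] + period / 2))
    boundaries = [
        (0, minima[0] - 1),
        (minima[0], minima[1] - 1),
        (minima[1], minima[2] - 1),
        (minima[2], upper),
    ]
    return LengthSegmentation(
        histogram=hist, period=period, boundaries=boundaries, resolved=True
    )


def classify_fragments(
    fragments: pd.DataFrame, segmentation: LengthSegmentation
) -> pd.DataFrame:
    """Assign each fragment a nucleosome state by its length interval.

    Lengths outside every interval are labelled ``unclassified``.
    """
    out = fragments.copy()
    lengths = (out["end"] - out["start"]).to_numpy()
    out["length"] = lengths
    conditions = [
        (lengths >= lo) & (lengths <= hi) for lo, hi in segmentation.boundaries
    ]
    out["state"] = np.select(conditions, STATE_NAMES, default="unclassified")
    return out


def make_locus_windows(trna_loci: pd.DataFrame, flank: int = 50) -> pd.DataFrame:
    """Extend each gene span by ``flank`` nt on both sides (clipped at 0)."""
    windows = trna_loci.copy()
    windows["window_start"] = (windows["start"] - flank).clip(lower=0)
    windows["window_end"] = windows["end"] + flank
    return windows


def count_cut_sites(
    fragments: pd.DataFrame,
    windows: pd.DataFrame,
    samples: list[str] | None = None,
    shift: tuple[int, int] = (4, -5),
    count_both_ends: bool = True,
) -> pd.DataFrame:
    """Tn5 cut sites per locus window, nucleosome state and sample.

    Each fragment contributes its 5' cut (start + shift[0]) and, when
    ``count_both_ends``, its 3' cut (end + shift[1]); a cut is counted for
    every half-open window containing it.  Fragments must already carry a
    ``state`` column.  Returns a complete long-format table
    (locus_id x state x sample), including zero rows.
    """
    if "state" not in fragments.columns:
        raise ValueError("fragments must be classified before counting (no 'state')")
    if (windows["window_end"] <= windows["window_start"]).any():
        raise ValueError("degenerate locus window (end <= start)")
    if samples is None:
        samples = sorted(fragments["sample"].unique())
    states = STATE_NAMES + ["unclassified"]

    cut_frames = []
    five = fragments.assign(cut=fragments["start"] + shift[0])
    cut_frames.append(five)
    if count_both_ends:
        cut_frames.append(fragments.assign(cut=fragments["end"] + shift[1]))
    cuts = pd.concat(cut_frames, ignore_index=True)

    rows = []
    for _, w in windows.iterrows():
        inside = cuts[
            (cuts["chrom"] == w["chrom"])
            & (cuts["cut"] >= w["window_start"])
            & (cuts["cut"] < w["window_end"])
        ]
        tally = inside.groupby(["state", "sample"]).size()
        for state in states:
            for sample in samples:
                rows.append(
                    {
                        "locus_id": w["locus_id"],
                        "state": state,
                        "sample": sample,
                        "count": int(tally.get((state, sample), 0)),
                    }
                )
    return pd.DataFrame(rows)


def state_coverage_bedgraph(
    fragments: pd.DataFrame, path, state: str, samples: list[str] | None = None
) -> None:
    """Write per-nt cut-site coverage of one nucleosome state as bedGraph.

    Coverage is summed over ``samples`` (default: all).  Runs of equal
    coverage are merged into single intervals.
    """
    sub = fragments[fragments["state"] == state]
    if samples is not None:
        sub = sub[sub["sample"].isin(samples)]
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{state}"\n')
        for chrom, group in sub.groupby("chrom", sort=True):
            cuts = np.sort(
                np.concatenate([group["start"] + 4, group["end"] - 5])
            )
            positions, counts = np.unique(cuts, return_counts=True)
            for pos, n in zip(positions, counts):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{n}\n")


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (columns = samples)."""
    logs = np.log(matrix.where(matrix > 0))
    log_geo = logs.mean(axis=1)
    usable = np.isfinite(log_geo) & matrix.gt(0).all(axis=1)
    if not usable.any():
        return pd.Series(1.0, index=matrix.columns)
    ratios = np.log(matrix.loc[usable]).sub(log_geo[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def differential_accessibility(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    dispersion_floor: float = 0.01,
    ko_group: str = "knockout",
    ctrl_group: str = "control",
    sf: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-(locus, state) differential accessibility between genotypes.

    Counts are normalized with median-of-ratios size factors; per feature,
    a negative-binomial Wald test on the log ratio of group means with a
    method-of-moments dispersion estimate floored at ``dispersion_floor``
    (a minimal 1% squared biological CV keeps near-Poisson features from
    producing overconfident calls at this replication level).  p-values are
    BH-adjusted across all testable features.  Features with an all-zero
    group are marked untestable.
    """
    for group in (ko_group, ctrl_group):
        if (design["group"] == group).sum() < 2:
            raise ValueError(f"need >= 2 samples in group {group!r}")
    matrix = counts.pivot_table(
        index=["locus_id", "state"], columns="sample", values="count", fill_value=0
    )
    if sf is None:
        sf = size_factors(matrix)
    norm = matrix.div(sf, axis=1)
    group_of = design.set_index("sample")["group"]
    ko_cols = [s for s in matrix.columns if group_of.get(s) == ko_group]
    ctrl_cols = [s for s in matrix.columns if group_of.get(s) == ctrl_group]

    rows = []
    for (locus, state), row in norm.iterrows():
        ko = row[ko_cols].to_numpy(dtype=float)
        ctrl = row[ctrl_cols].to_numpy(dtype=float)
        mu_k, mu_c = ko.mean(), ctrl.mean()
        rec = {
            "locus_id": locus,
            "state": state,
            "base_mean": float(row.mean()),
            "mean_control": float(mu_c),
            "mean_knockout": float(mu_k),
        }
        if mu_k <= 0 or mu_c <= 0:
            rec.update(
                log2_fold_change=np.nan, p_value=np.nan, testable=False,
                dispersion=np.nan,
            )
            rows.append(rec)
            continue
        alphas = []
        for vals in (ko, ctrl):
            m, v = vals.mean(), vals.var(ddof=1)
            alphas.append(max(0.0, (v - m) / m**2))
        alpha = max(dispersion_floor, float(np.mean(alphas)))
        se = np.sqrt(
            (1.0 / mu_k + alpha) / len(ko) + (1.0 / mu_c + alpha) / len(ctrl)
        )
        z = np.log(mu_k / mu_c) / se
        rec.update(
            log2_fold_change=float(np.log2(mu_k / mu_c)),
            p_value=float(2.0 * stats.norm.sf(abs(z))),
            testable=True,
            dispersion=alpha,
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    ok = out["p_value"].notna()
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(
            out.loc[ok, "p_value"], method="fdr_bh"
        )[1]
    # normalized counts per sample, for reporting
    norm_cols = norm.reset_index()
    return out.merge(norm_cols, on=["locus_id", "state"]), sf


def family_sum(
    counts: pd.DataFrame, family_map: dict[str, str], design: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Sum counts across the loci of each family and test group differences.

    ``family_map`` maps locus_id -> family name and must cover every
    counted locus.  Size factors are estimated on the per-locus matrix
    (summing first would let a genuine family-wide change be absorbed into
    the normalization) and the summed table is then tested exactly like
    per-locus counts.  Returns ``(results, size_factors)``.
    """
    missing = set(counts["locus_id"]) - set(family_map)
    if missing:
        raise ValueError(f"family map does not cover loci: {sorted(missing)}")
    if "sf" not in kwargs or kwargs["sf"] is None:
        matrix = counts.pivot_table(
            index=["locus_id", "state"], columns="sample", values="count",
            fill_value=0,
        )
        kwargs["sf"] = size_factors(matrix)
    summed = (
        counts.assign(locus_id=counts["locus_id"].map(family_map))
        .groupby(["locus_id", "state", "sample"], as_index=False)["count"]
        .sum()
    )
    return differential_accessibility(summed, design, **kwargs)


def gwas_window_counts(
    hits: pd.DataFrame,
    trna_loci: pd.DataFrame,
    windows: tuple[int, ...] = (50, 100, 250, 500, 1000),
    p_threshold: float = 0.05,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Count significant GWAS hits within fixed windows of tRNA genes.

    A hit counts for window ``w`` when its p-value is below ``p_threshold``
    and its distance to the nearest included tRNA gene boundary is <= ``w``
    (hits inside a gene count for every window).  Loci named in ``exclude``
    are removed before distances are computed.  Returns a long table
    (window, category, n_hits) over all observed categories; counts are
    monotone in window size by construction.
    """
    loci = trna_loci[~trna_loci["locus_id"].isin(exclude)]
    categories = sorted(hits["category"].unique()) if len(hits) else []
    sig = hits[hits["pvalue"] < p_threshold]

    distances = []
    for _, hit in sig.iterrows():
        same = loci[loci["chrom"] == hit["chrom"]]
        if same.empty:
            distances.append(np.inf)
            continue
        pos = hit["pos"]
        inside = (same["start"] <= pos) & (pos < same["end"])
        if inside.any():
            distances.append(0)
            continue
        d = np.minimum(
            np.abs(same["start"] - pos), np.abs(pos - (same["end"] - 1))
        ).min()
        distances.append(int(d))
    sig = sig.assign(distance_to_gene=distances)

    rows = []
    for w in sorted(windows):
        for cat in categories:
            n = int(
                (
                    (sig["category"] == cat) & (sig["distance_to_gene"] <= w)
                ).sum()
            )
            rows.append({"window": w, "category": cat, "n_hits": n})
        rows.append(
            {
                "window": w,
                "category": "all",
                "n_hits": int((sig["distance_to_gene"] <= w).sum()),
            }
        )
    return pd.DataFrame(rows)
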