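"""Fragment segmentation, cut-site counting, differential accessibility, GWAS windows."""

import numpy as np
import pandas as pd
import pytest

from misphe.atac import (
    DEFAULT_BOUNDARIES,
    STATE_NAMES,
    LengthSegmentation,
    classify_fragments,
    count_cut_sites,
    differential_accessibility,
    estimate_segmentation,
    family_sum,
    gwas_window_counts,
    make_locus_windows,
    size_factors,
)
from misphe.simulate import SimConfig, generate_atac_fragments

RNG = np.random.default_rng(13)


def _fragments_of_lengths(lengths, chrom="chr1", sample="s1"):
    starts = np.arange(len(lengths)) * 1000
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + np.asarray(lengths),
            "sample": sample,
        }
    )


def default_segmentation():
    return LengthSegmentation(
        histogram=np.zeros(1), period=float("nan"),
        boundaries=list(DEFAULT_BOUNDARIES), resolved=False,
    )


# ---------------------------------------------------------------------------
# Segmentation and classification
# ---------------------------------------------------------------------------


def test_nucleosomal_mixture_resolves_four_states():
    comp_means = [60, 200, 400, 600]
    comp_sds = [20, 25, 35, 45]
    weights = [0.45, 0.3, 0.15, 0.1]
    comp = RNG.choice(4, p=weights, size=40_000)
    lengths = np.maximum(
        20,
        RNG.normal(np.take(comp_means, comp), np.take(comp_sds, comp)),
    ).astype(int)
    seg = estimate_segmentation(_fragments_of_lengths(lengths))
    assert seg.resolved
    assert 190 <= seg.period <= 210
    for mode, (lo, hi) in zip(comp_means, seg.boundaries):
        assert lo <= mode <= hi


def test_single_component_falls_back_to_defaults():
    lengths = RNG.normal(200, 10, 5000).astype(int)
    with pytest.warns(UserWarning, match="falling back"):
        seg = estimate_segmentation(_fragments_of_lengths(lengths))
    assert not seg.resolved
    assert seg.boundaries == DEFAULT_BOUNDARIES


def test_too_few_fragments_rejected():
    with pytest.raises(ValueError, match="1000"):
        estimate_segmentation(_fragments_of_lengths([100, 200]))


def test_segmentation_deterministic_under_fixed_input():
    lengths = RNG.normal(200, 40, 3000).astype(int).clip(min=20)
    frags = _fragments_of_lengths(lengths)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = estimate_segmentation(frags)
        b = estimate_segmentation(frags)
    assert a.boundaries == b.boundaries and (
        a.period == b.period or (np.isnan(a.period) and np.isnan(b.period))
    )


def test_default_boundary_classification():
    frags = _fragments_of_lengths([80, 200, 999])
    out = classify_fragments(frags, default_segmentation())
    assert list(out["state"]) == ["nucleosome_free", "mono", "unclassified"]


def test_classification_matches_interval_oracle_and_partitions():
    lengths = RNG.integers(20, 800, size=10_000)
    frags = _fragments_of_lengths(lengths)
    out = classify_fragments(frags, default_segmentation())
    for (lo, hi), state in zip(DEFAULT_BOUNDARIES, STATE_NAMES):
        oracle = ((lengths >= lo) & (lengths <= hi)).sum()
        assert (out["state"] == state).sum() == oracle
    # every fragment maps to exactly one state; counts sum to total
    assert out["state"].notna().all()
    assert out["state"].value_counts().sum() == len(frags)


# ---------------------------------------------------------------------------
# Cut-site counting
# ---------------------------------------------------------------------------


def _windows(start, end, locus="L1", chrom="chr1"):
    loci = pd.DataFrame(
        {"chrom": [chrom], "start": [start + 50], "end": [end - 50],
         "locus_id": [locus], "score": [0], "strand": ["+"]}
    )
    w = make_locus_windows(loci)
    assert w.iloc[0]["window_start"] == start and w.iloc[0]["window_end"] == end
    return w


def test_both_cut_sites_inside_window():
    frags = pd.DataFrame(
        {"chrom": ["chr1"], "start": [100], "end": [200], "sample": ["s1"]}
    )
    frags = classify_fragments(frags, default_segmentation())
    counts = count_cut_sites(frags, _windows(50, 222), samples=["s1"])
    assert counts["count"].sum() == 2


def test_three_prime_cut_outside_window():
    # fragment [100, 300): 5' cut at 104 inside [50, 222); 3' cut at 295 outside
    frags = pd.DataFrame(
        {"chrom": ["chr1"], "start": [100], "end": [300], "sample": ["s1"]}
    )
    frags = classify_fragments(frags, default_segmentation())
    counts = count_cut_sites(frags, _windows(50, 222), samples=["s1"])
    assert counts["count"].sum() == 1


def test_empty_fragments_give_all_zero_matrix():
    frags = classify_fragments(
        pd.DataFrame(columns=["chrom", "start", "end", "sample"]).astype(
            {"start": int, "end": int}
        ),
        default_segmentation(),
    )
    counts = count_cut_sites(frags, _windows(0, 200), samples=["s1", "s2"])
    assert (counts["count"] == 0).all()
    assert len(counts) == len(STATE_NAMES + ["unclassified"]) * 2


def test_state_coverage_bedgraph_written(tmp_path):
    from misphe.atac import state_coverage_bedgraph

    frags = classify_fragments(
        pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 100], "end": [180, 180],
             "sample": ["s1", "s2"]}
        ),
        default_segmentation(),
    )
    path = tmp_path / "nf.bedGraph"
    state_coverage_bedgraph(frags, path, "nucleosome_free")
    lines = path.read_text().splitlines()
    assert lines[0].startswith("track type=bedGraph")
    # two fragments share both shifted cut sites: coverage 2 at 104 and 175
    assert "chr1\t104\t105\t2" in lines
    assert "chr1\t175\t176\t2" in lines


def test_single_end_counting_flag():
    frags = pd.DataFrame(
        {"chrom": ["chr1"], "start": [100], "end": [200], "sample": ["s1"]}
    )
    frags = classify_fragments(frags, default_segmentation())
    counts = count_cut_sites(
        frags, _windows(50, 222), samples=["s1"], count_both_ends=False
    )
    assert counts["count"].sum() == 1


# ---------------------------------------------------------------------------
# Differential accessibility
# ---------------------------------------------------------------------------


def _counts_table(matrix: dict, samples):
    rows = []
    for (locus, state), values in matrix.items():
        for sample, value in zip(samples, values):
            rows.append(
                {"locus_id": locus, "state": state, "sample": sample, "count": value}
            )
    return pd.DataFrame(rows)


def _design(n=3):
    return pd.DataFrame(
        {
            "sample": [f"c{i}" for i in range(n)] + [f"k{i}" for i in range(n)],
            "group": ["control"] * n + ["knockout"] * n,
        }
    )


def test_size_factor_tracks_depth_scaling():
    base = RNG.poisson(1000, size=(20, 6)).astype(float)
    matrix = pd.DataFrame(base, columns=list("abcdef"))
    matrix["b"] *= 2.0
    sf = size_factors(matrix)
    assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=0.05)
    # normalized counts are unchanged by the scaling
    norm = matrix.div(sf, axis=1)
    assert np.allclose(norm["a"], norm["b"], rtol=0.2)


def test_identical_group_size_factors_near_one():
    matrix = pd.DataFrame(RNG.poisson(2000, size=(30, 6)).astype(float),
                          columns=list("abcdef"))
    assert np.allclose(size_factors(matrix), 1.0, atol=0.05)


def test_planted_fold_change_recovered():
    samples = ["c0", "c1", "c2", "k0", "k1", "k2"]
    matrix = {}
    for locus in range(7):
        mean = 5000
        vals = RNG.poisson(mean, 6).astype(float)
        if locus == 0:
            vals[3:] = RNG.poisson(mean / 4, 3)
        matrix[(f"L{locus}", "nucleosome_free")] = vals
    res, _ = differential_accessibility(_counts_table(matrix, samples), _design())
    hit = res[res["locus_id"] == "L0"].iloc[0]
    assert hit["log2_fold_change"] == pytest.approx(-2.0, abs=0.3)
    assert hit["p_adjusted"] < 0.05
    others = res[res["locus_id"] != "L0"]
    assert (others["p_adjusted"] > 0.05).all()


def test_all_zero_locus_marked_untestable():
    samples = ["c0", "c1", "k0", "k1"]
    design = _design(2)
    matrix = {("L0", "mono"): [0, 0, 0, 0], ("L1", "mono"): [50, 60, 55, 52]}
    res, _ = differential_accessibility(_counts_table(matrix, samples), design)
    assert not res.set_index("locus_id").loc["L0", "testable"]
    assert np.isnan(res.set_index("locus_id").loc["L0", "p_value"])


def test_fewer_than_two_replicates_rejected():
    design = pd.DataFrame({"sample": ["c0", "k0"], "group": ["control", "knockout"]})
    with pytest.raises(ValueError, match=">= 2"):
        differential_accessibility(
            _counts_table({("L", "mono"): [1, 2]}, ["c0", "k0"]), design
        )


def test_null_counts_rarely_significant():
    # no planted difference: BH-adjusted calls should be absent in most runs
    n_sig = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        samples = ["c0", "c1", "c2", "k0", "k1", "k2"]
        matrix = {
            (f"L{i}", "nucleosome_free"): rng.poisson(4000, 6).astype(float)
            for i in range(7)
        }
        res, _ = differential_accessibility(_counts_table(matrix, samples), _design())
        n_sig += int((res["p_adjusted"] < 0.05).any())
    assert n_sig <= 1


def test_family_sum_identity_and_arithmetic():
    samples = ["c0", "c1", "k0", "k1"]
    design = _design(2)
    matrix = {
        ("L0", "mono"): [300.0, 310.0, 305.0, 295.0],
        ("L1", "mono"): [700.0, 690.0, 700.0, 710.0],
    }
    counts = _counts_table(matrix, samples)
    # one-locus family equals the locus itself
    solo, _ = family_sum(counts, {"L0": "A", "L1": "B"}, design)
    per_locus, _ = differential_accessibility(counts, design)
    merged = solo.set_index("locus_id")["mean_control"]
    assert merged["A"] == pytest.approx(
        per_locus.set_index("locus_id").loc["L0", "mean_control"]
    )
    # deleting a locus contributing ~30% of family counts: log2FC ~ log2(0.7)
    deleted = {
        ("L0", "mono"): [300.0, 310.0, 0.0, 0.0],
        ("L1", "mono"): [700.0, 690.0, 700.0, 710.0],
    }
    fam, _ = family_sum(_counts_table(deleted, samples), {"L0": "F", "L1": "F"}, design)
    assert fam.iloc[0]["log2_fold_change"] == pytest.approx(np.log2(0.7), abs=0.1)
    with pytest.raises(ValueError, match="cover"):
        family_sum(counts, {"L0": "F"}, design)


def test_family_sum_is_order_invariant():
    samples = ["c0", "c1", "k0", "k1"]
    design = _design(2)
    matrix = {
        ("L0", "mono"): [300.0, 310.0, 100.0, 95.0],
        ("L1", "mono"): [700.0, 690.0, 700.0, 710.0],
    }
    counts = _counts_table(matrix, samples)
    fam1, _ = family_sum(counts, {"L0": "F", "L1": "F"}, design)
    fam2, _ = family_sum(
        counts.iloc[::-1].reset_index(drop=True), {"L0": "F", "L1": "F"}, design
    )
    pd.testing.assert_frame_equal(fam1, fam2)


# ---------------------------------------------------------------------------
# GWAS windows
# ---------------------------------------------------------------------------


def _loci():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 50_000],
            "end": [10_072, 50_072],
            "locus_id": ["geneA", "geneB"],
            "score": [0, 0],
            "strand": ["+", "+"],
        }
    )


def _hits(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "pvalue", "category"])


def test_close_significant_hit_counts_in_all_windows():
    hits = _hits([("chr1", 10_000 - 40, 0.01, "neuro")])
    out = gwas_window_counts(hits, _loci()).set_index(["window", "category"])
    for w in (50, 100, 250, 500, 1000):
        assert out.loc[(w, "all"), "n_hits"] == 1


def test_distant_hit_counts_only_in_largest_window():
    hits = _hits([("chr1", 10_072 - 1 + 600, 0.01, "neuro")])
    out = gwas_window_counts(hits, _loci()).set_index(["window", "category"])
    assert out.loc[(500, "all"), "n_hits"] == 0
    assert out.loc[(1000, "all"), "n_hits"] == 1


def test_nonsignificant_hit_excluded():
    hits = _hits([("chr1", 10_010, 0.2, "neuro")])
    out = gwas_window_counts(hits, _loci())
    assert (out["n_hits"] == 0).all()


def test_excluded_gene_removed_before_distance():
    hits = _hits([("chr1", 50_010, 0.001, "neuro")])  # inside geneB
    out = gwas_window_counts(hits, _loci(), exclude=("geneB",))
    assert (out["n_hits"] == 0).all()


def test_toy_table_matches_exhaustive_enumeration():
    loci = _loci()
    distances = [0, 40, 80, 200, 400, 600, 1500]
    pvalues = [0.01, 0.01, 0.2, 0.03, 0.04, 0.02, 0.001]
    rows = []
    for i, (d, p) in enumerate(zip(distances, pvalues)):
        locus = loci.iloc[i % 2]
        pos = locus["start"] + 10 if d == 0 else (
            locus["start"] - d if i % 2 == 0 else locus["end"] - 1 + d
        )
        rows.append(("chr1", pos, p, "cat"))
    hits = _hits(rows)
    out = gwas_window_counts(hits, loci).set_index(["window", "category"])

    for w in (50, 100, 250, 500, 1000):
        expected = sum(
            1 for d, p in zip(distances, pvalues) if p < 0.05 and d <= w
        )
        assert out.loc[(w, "all"), "n_hits"] == expected

    # monotone in window size
    all_counts = [out.loc[(w, "all"), "n_hits"] for w in (50, 100, 250, 500, 1000)]
    assert all_counts == sorted(all_counts)


def test_planted_atac_dataset_recovers_only_planted_locus(trna_loci):
    cfg = SimConfig(seed=21, fragments_per_locus=3000)
    frags, design, truth = generate_atac_fragments(trna_loci, cfg)
    seg = estimate_segmentation(frags)
    classified = classify_fragments(frags, seg)
    counts = count_cut_sites(
        classified, make_locus_windows(trna_loci), samples=list(design["sample"])
    )
    res, _ = differential_accessibility(counts, design)
    ev = truth["planted_accessibility_changes"][0]
    hit = res[(res["locus_id"] == ev["locus_id"]) & (res["state"] == ev["state"])]
    assert hit.iloc[0]["log2_fold_change"] == pytest.approx(
        ev["log2_fold_change"], abs=0.3
    )
    assert hit.iloc[0]["p_adjusted"] < 0.05
    others = res[
        res["p_adjusted"].notna()
        & ~((res["locus_id"] == ev["locus_id"]) & (res["state"] == ev["state"]))
    ]
    assert (others["p_adjusted"] > 0.05).all()
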