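"""Substitution library, screening, aggregation, testing and isobaric filter."""

import numpy as np
import pandas as pd
import pytest

from misphe.digest import tryptic_digest
from misphe.simulate import SimConfig, generate_dia_report, generate_proteome
from misphe.subscan import (
    ScanParams,
    aggregate_peptidoforms,
    build_substitution_library,
    canonical_peptide_set,
    isobaric_filter,
    isobaric_match,
    scan_peptide_report,
    screen_candidates,
    substitution_report,
    test_candidates,
    variant_peptide_index,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------


def test_single_phe_site_yields_19_variants():
    variants = build_substitution_library({"P1": "MFKR"})
    assert len(variants) == 19
    assert {v.variant_sequence for v in variants} == {
        "M" + aa + "KR" for aa in AA if aa != "F"
    }


def test_no_phe_no_variants():
    assert build_substitution_library({"P1": "AAKR"}) == []


def test_two_phe_sites_exhaustive_enumeration():
    variants = build_substitution_library({"P1": "FFK"})
    assert len(variants) == 38
    for v in variants:
        diffs = [i for i, (a, b) in enumerate(zip("FFK", v.variant_sequence)) if a != b]
        assert diffs == [v.position - 1]
        assert v.position in (1, 2)


def test_library_count_is_19_per_phe_on_random_proteins(rng):
    for _ in range(20):
        seq = "".join(rng.choice(list(AA), size=int(rng.integers(20, 120))))
        variants = build_substitution_library({"P": seq})
        assert len(variants) == 19 * seq.count("F")
        for v in variants:
            assert seq[v.position - 1] == "F"
            assert v.variant_sequence[v.position - 1] == v.substituted
            # differs at exactly one position
            assert (
                sum(a != b for a, b in zip(seq, v.variant_sequence)) == 1
            )


def test_nonstandard_residue_rejected_with_location():
    with pytest.raises(ValueError, match="position 2"):
        build_substitution_library({"BAD": "AZF"})


# ---------------------------------------------------------------------------
# Variant peptide index (fast path vs direct digestion)
# ---------------------------------------------------------------------------


def naive_variant_index(variants, params):
    index = {}
    for var in variants:
        for pep in tryptic_digest(
            var.variant_sequence, params.missed_cleavages, params.length_range
        ):
            if pep.start <= var.position <= pep.end:
                index.setdefault(pep.sequence, set()).add(
                    (var.protein_id, var.position, var.substituted)
                )
    return index


def test_variant_index_matches_direct_digestion_including_krp(rng):
    # K/R/P substitutions change cleavage sites; the index must follow suit.
    for _ in range(5):
        seq = "".join(rng.choice(list(AA), size=80))
        variants = build_substitution_library({"P": seq})
        params = ScanParams(missed_cleavages=2, length_range=(4, 40))
        fast = variant_peptide_index(variants, params)
        naive = naive_variant_index(variants, params)
        assert set(fast) == set(naive)
        for seq_key, annotations in fast.items():
            got = {(a["protein_id"], a["position"], a["substituted"]) for a in annotations}
            assert got == naive[seq_key]


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def _aggregated(rows, samples):
    df = pd.DataFrame(rows)
    for s in samples:
        if s not in df:
            df[s] = 0.0
    return df


def test_screening_contract():
    proteome = {"P1": "AAAKAFKLLLK"}
    params = ScanParams(missed_cleavages=0, length_range=(2, 50))
    canonical = canonical_peptide_set(proteome, params)
    index = variant_peptide_index(build_substitution_library(proteome), params)
    agg = _aggregated(
        [
            {"peptide_sequence": "AVK", "protein_id": "P1", "n_peptidoforms": 1},
            {"peptide_sequence": "AFK", "protein_id": "P1", "n_peptidoforms": 1},
            {"peptide_sequence": "WWWWK", "protein_id": "P1", "n_peptidoforms": 1},
        ],
        ["s1"],
    )
    candidates, unexplained = screen_candidates(agg, canonical, index)
    # AVK is absent from the canonical digest but present in the F->V variant
    assert list(candidates["peptide_sequence"]) == ["AVK"]
    assert candidates.iloc[0]["substituted"] == "V"
    assert candidates.iloc[0]["canonical_peptide"] == "AFK"
    # canonical peptide is never a candidate; unmatched peptides are reported
    assert list(unexplained["peptide_sequence"]) == ["WWWWK"]


# ---------------------------------------------------------------------------
# Aggregation and testing
# ---------------------------------------------------------------------------


def test_peptidoform_intensities_sum_per_sample():
    report = pd.DataFrame(
        {
            "peptide_sequence": ["AMK", "AMK", "CCK"],
            "modifications": ["", "Oxidation@2", ""],
            "protein_id": ["P1", "P1", "P2"],
            "s1": [100.0, 200.0, 7.0],
            "s2": [10.0, 20.0, 5.0],
        }
    )
    agg = aggregate_peptidoforms(report, ["s1", "s2"]).set_index("peptide_sequence")
    assert agg.loc["AMK", "s1"] == 300.0
    assert agg.loc["AMK", "s2"] == 30.0
    assert agg.loc["AMK", "n_peptidoforms"] == 2
    # single rows pass through unchanged
    assert agg.loc["CCK", "s1"] == 7.0


def test_conflicting_protein_assignment_warns_and_keeps_majority():
    report = pd.DataFrame(
        {
            "peptide_sequence": ["AMK"] * 3,
            "modifications": ["", "Oxidation@2", "Acetyl@0"],
            "protein_id": ["P1", "P1", "P2"],
            "s1": [1.0, 2.0, 3.0],
        }
    )
    with pytest.warns(UserWarning, match="conflicting protein"):
        agg = aggregate_peptidoforms(report, ["s1"])
    assert agg.iloc[0]["protein_id"] == "P1"


def _candidate_frame(ko_vals, ctrl_vals, canonical="AFK", sequence="AYK"):
    samples = {f"knockout_{i}": v for i, v in enumerate(ko_vals)}
    samples |= {f"control_{i}": v for i, v in enumerate(ctrl_vals)}
    design = pd.DataFrame(
        {
            "sample": list(samples),
            "group": ["knockout"] * len(ko_vals) + ["control"] * len(ctrl_vals),
        }
    )
    cand = pd.DataFrame([{
        "peptide_sequence": sequence, "protein_id": "P1", "position": 2,
        "original": "F", "substituted": "Y", "canonical_peptide": canonical,
        **samples,
    }])
    agg = pd.DataFrame([{ "peptide_sequence": sequence, **samples }])
    return cand, agg, design


def test_identical_groups_give_p_one_and_unit_ratio():
    cand, agg, design = _candidate_frame([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    # make the canonical counterpart detected with equal means in both groups
    canon = agg.copy()
    canon["peptide_sequence"] = "AFK"
    tested = test_candidates(cand, pd.concat([agg, canon]), design)
    assert tested.iloc[0]["p_value"] == 1.0
    assert tested.iloc[0]["ratio_knockout"] == tested.iloc[0]["ratio_control"] == 1.0


def test_separated_groups_give_tiny_p():
    cand, agg, design = _candidate_frame(
        [10.0, 10.001, 9.999], [0.0, 0.001, -0.001]
    )
    tested = test_candidates(cand, agg, design)
    assert tested.iloc[0]["p_value"] < 1e-6


def test_missing_canonical_keeps_candidate_with_nan_ratio():
    cand, agg, design = _candidate_frame([1.0, 2.0], [0.0, 0.0])
    tested = test_candidates(cand, agg, design)
    assert not tested.iloc[0]["canonical_detected"]
    assert np.isnan(tested.iloc[0]["ratio_knockout"])
    assert len(tested) == 1


# ---------------------------------------------------------------------------
# Isobaric filter
# ---------------------------------------------------------------------------


def test_phe_to_oxidised_met_removed_with_reason():
    matched, reason = isobaric_match("AMK", "AFK", ScanParams().mass_model, 0.04)
    assert matched
    assert "F→ox-M" in reason
    assert "0.0330" in reason


def test_phe_to_val_with_three_met_removed():
    matched, reason = isobaric_match("VMMMK", "FMMMK", ScanParams().mass_model, 0.04)
    assert matched
    assert "F→V + 3×ox-Met" in reason
    assert "0.0153" in reason


def test_phe_to_val_without_three_met_kept():
    matched, _ = isobaric_match("AVK", "AFK", ScanParams().mass_model, 0.04)
    assert not matched


def test_phe_to_gly_kept():
    matched, _ = isobaric_match("AGK", "AFK", ScanParams().mass_model, 0.04)
    assert not matched


def test_isobaric_filter_partitions_candidates():
    rows = pd.DataFrame(
        [
            {"peptide_sequence": "AMK", "canonical_peptide": "AFK"},
            {"peptide_sequence": "AYK", "canonical_peptide": "AFK"},
        ]
    )
    kept, removed = isobaric_filter(rows)
    assert list(kept["peptide_sequence"]) == ["AYK"]
    assert list(removed["peptide_sequence"]) == ["AMK"]
    assert removed.iloc[0]["isobaric_reason"].startswith("F→ox-M")


# ---------------------------------------------------------------------------
# Report and end-to-end contracts
# ---------------------------------------------------------------------------


def test_empty_input_produces_header_only_report():
    out = substitution_report(pd.DataFrame(), ["s1"])
    assert out.empty
    assert "p_adjusted" in out.columns


def test_null_dataset_yields_no_candidates(small_config, small_proteome):
    import dataclasses

    cfg = dataclasses.replace(
        small_config, n_substitutions=0, n_oxmet_decoys=0, n_val3ox_decoys=0
    )
    report, design, truth = generate_dia_report(small_proteome, cfg)
    assert truth["planted_substitutions"] == []
    result = scan_peptide_report(small_proteome, report, design)
    assert result.report.empty
    assert result.removed.empty


def test_planted_events_recovered_and_decoys_removed(small_config, small_proteome):
    report, design, truth = generate_dia_report(small_proteome, small_config)
    result = scan_peptide_report(small_proteome, report, design)
    planted = {e["peptide"] for e in truth["planted_substitutions"]}
    decoys = {e["peptide"] for e in truth["planted_isobaric_decoys"]}
    kept = set(result.report["peptide_sequence"])
    removed = set(result.removed["peptide_sequence"])
    assert kept == planted          # all recovered, nothing spurious
    assert decoys <= removed
    # knockout-only planting: substituted intensity absent in controls
    assert (result.report["mean_control"] == 0).all()
    # ratio estimates recover the planted 5% within simulation error
    ratios = result.report["ratio_knockout"].dropna()
    assert ratios.between(0.01, 0.25).all()
    assert np.median(ratios) == pytest.approx(
        small_config.substitution_ratio, rel=0.5
    )


def test_scan_is_deterministic(small_config, small_proteome):
    report, design, _ = generate_dia_report(small_proteome, small_config)
    a = scan_peptide_report(small_proteome, report, design).report
    b = scan_peptide_report(small_proteome, report, design).report
    pd.testing.assert_frame_equal(a, b)
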