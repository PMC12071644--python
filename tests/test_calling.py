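"""Per-sample calls: paired rule, Fisher test, reversal calling, refinement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reodeg import (
    SimulationSpec,
    build_background,
    call_paired,
    call_sample_reo,
    cohort_calls,
    fisher_two_sided,
    generate_normal_cohort,
    generate_paired_cohort,
    generate_tumor_cohort,
    refine_calls,
)
from conftest import background_as_dict
from reference import brute_call_sample, brute_refine, enum_fisher, gene_tables


# ---------------------------------------------------------------- paired calls

def test_paired_direct_comparison():
    tumor = pd.DataFrame({"P1": [5.0, 1.0, 2.0]}, index=["GA", "GB", "GC"])
    adjacent = pd.DataFrame({"P1": [3.0, 4.0, 2.0]}, index=["GA", "GB", "GC"])
    call = call_paired(tumor, adjacent)[0]
    assert call.status.to_dict() == {"GA": "up", "GB": "down", "GC": "stable"}
    assert call.p_value["GA"] == 0.0 and call.q_value["GA"] == 0.0
    assert call.p_value["GC"] == 1.0


def test_paired_misalignment_names_first_mismatch():
    tumor = pd.DataFrame({"P1": [1.0], "P2": [2.0]}, index=["GA"])
    adjacent = pd.DataFrame({"P1": [1.0], "P3": [2.0]}, index=["GA"])
    with pytest.raises(ValueError, match="P2.*P3"):
        call_paired(tumor, adjacent)


def test_saturated_paired_plant_called_up_in_every_pair():
    spec = SimulationSpec(n_genes=30, n_pairs=20, seed=5, planted_up=[("G0003", 1.0, 50.0)])
    tumor, adjacent, _ = generate_paired_cohort(spec)
    calls = call_paired(tumor, adjacent)
    assert all(c.status["G0003"] == "up" for c in calls)


# ----------------------------------------------------------------- Fisher test

@pytest.mark.parametrize(
    "table, expected",
    [
        ([[5, 5], [5, 5]], 1.0),
        ([[0, 0], [3, 7]], 1.0),   # degenerate margin carries no information
        ([[0, 3], [0, 5]], 1.0),
        ([[10, 0], [0, 0]], 1.0),
    ],
)
def test_fisher_trivial_tables(table, expected):
    assert fisher_two_sided(table) == expected


def test_fisher_extreme_reversal_matches_enumeration():
    assert fisher_two_sided([[0, 20], [20, 0]]) == pytest.approx(enum_fisher(0, 20, 20, 0), abs=1e-12)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.tuples(*[st.integers(0, 40)] * 4))
def test_fisher_matches_enumeration_oracle(counts):
    a, b, c, d = counts
    assert fisher_two_sided([[a, b], [c, d]]) == pytest.approx(enum_fisher(a, b, c, d), abs=1e-9)


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_two_sided([[-1, 2], [3, 4]])


# ----------------------------------------------------------- reversal calling

def test_concordant_sample_is_all_stable(tiny_normal):
    background = build_background(tiny_normal, 0.9)
    # the cohort median profile follows the background orderings almost surely
    sample = tiny_normal.median(axis=1)
    sample.name = "S"
    call = call_sample_reo(sample, background)
    assert (call.status == "stable").all()
    assert (call.p_value > 0.2).all()


def test_total_reversal_of_bottom_gene_is_called_up():
    # noise-free ladder: the bottom gene is below all 20 partners in the
    # background, then jumps above all of them in the disease sample
    genes = [f"G{i:02d}" for i in range(21)]
    normal = pd.DataFrame(
        np.exp(np.arange(21))[:, None] * np.ones((21, 10)), index=genes,
        columns=[f"N{i}" for i in range(10)],
    )
    background = build_background(normal, 0.9)
    sample = pd.Series(np.exp(np.arange(21, dtype=float)), index=genes, name="S")
    sample["G00"] = np.exp(25.0)
    call = call_sample_reo(sample, background)
    tables, _ = gene_tables(sample, background_as_dict(background))
    assert tables["G00"] == (0, 20, 20, 0)
    assert call.p_value["G00"] == pytest.approx(enum_fisher(0, 20, 20, 0), abs=1e-12)
    assert call.status["G00"] == "up"


def test_planted_frequency_recovered_in_cohort_calls():
    spec = SimulationSpec(
        n_genes=100, n_normal=80, n_tumor=40, noise_sd=0.15, seed=23,
        planted_up=[("G0010", 0.9, 20.0)], planted_down=[("G0090", 0.9, 20.0)],
    )
    normal = generate_normal_cohort(spec)
    tumor, truth = generate_tumor_cohort(spec, normal)
    calls = cohort_calls(tumor, build_background(normal, 0.9))
    up_frac = np.mean([c.status["G0010"] == "up" for c in calls])
    down_frac = np.mean([c.status["G0090"] == "down" for c in calls])
    assert abs(up_frac - 0.9) <= 0.05
    assert abs(down_frac - 0.9) <= 0.05


def test_empty_background_calls_everything_stable(tiny_normal):
    empty = build_background(
        pd.DataFrame(np.ones((2, 6)), index=["GA", "GB"], columns=list("abcdef")), 0.9
    )
    sample = pd.Series([1.0, 2.0], index=["GA", "GB"], name="S")
    call = call_sample_reo(sample, empty)
    assert (call.status == "stable").all()
    assert (call.n_partners_used == 0).all()


def test_calls_invariant_under_monotone_transform_of_sample(tiny_normal):
    background = build_background(tiny_normal, 0.9)
    spec = SimulationSpec(n_genes=20, n_normal=30, n_tumor=3, noise_sd=0.2, seed=41,
                          planted_up=[("G0002", 1.0, 10.0)])
    tumor, _ = generate_tumor_cohort(spec, tiny_normal)
    for col in tumor.columns:
        sample = tumor[col]
        base = refine_calls(call_sample_reo(sample, background), sample, background)
        for transform in (np.log, np.cbrt, lambda v: 7.0 * v + 3.0):
            t = pd.Series(transform(sample.to_numpy()), index=sample.index, name=col)
            other = refine_calls(call_sample_reo(t, background), t, background)
            pd.testing.assert_frame_equal(base.table, other.table)


def test_refinement_is_noop_without_calls(tiny_normal):
    background = build_background(tiny_normal, 0.9)
    sample = tiny_normal.median(axis=1)
    sample.name = "S"
    first = call_sample_reo(sample, background)
    refined = refine_calls(first, sample, background)
    assert refined.n_iterations == 1 and refined.converged
    pd.testing.assert_series_equal(first.status, refined.status)


def test_refinement_is_a_fixed_point():
    spec = SimulationSpec(n_genes=40, n_normal=60, n_tumor=4, noise_sd=0.25, seed=3,
                          planted_down=[(f"G00{i:02d}", 1.0, 8.0) for i in range(20, 28)])
    normal = generate_normal_cohort(spec)
    background = build_background(normal, 0.9)
    tumor, _ = generate_tumor_cohort(spec, normal)
    for col in tumor.columns:
        sample = tumor[col]
        refined = refine_calls(call_sample_reo(sample, background), sample, background)
        again = refine_calls(refined, sample, background)
        pd.testing.assert_series_equal(refined.status, again.status)


def test_fabricated_up_calls_are_revoked_by_refinement():
    """Genes crashing to the bottom fabricate up-evidence for the genes they
    fall past; excluding the down-called partners must revoke those calls."""
    spec = SimulationSpec(n_genes=40, n_normal=60, n_tumor=6, noise_sd=0.25, seed=3,
                          planted_down=[(f"G00{i:02d}", 1.0, 8.0) for i in range(20, 28)])
    normal = generate_normal_cohort(spec)
    background = build_background(normal, 0.9)
    tumor, truth = generate_tumor_cohort(spec, normal)
    planted = set(truth.direction)
    n_fabricated = 0
    for col in tumor.columns:
        sample = tumor[col]
        first = call_sample_reo(sample, background)
        refined = refine_calls(first, sample, background)
        fabricated = [g for g in first.genes_called("up") if g not in planted]
        n_fabricated += len(fabricated)
        assert all(refined.status[g] == "stable" for g in fabricated)
        assert refined.genes_called("up") == []
        assert set(refined.genes_called("down")) == planted
    assert n_fabricated > 0  # the fixture does exercise the exclusion clause


def test_calls_and_refinement_match_brute_force_oracle():
    spec = SimulationSpec(n_genes=25, n_normal=30, n_tumor=5, noise_sd=0.3, seed=19,
                          planted_up=[("G0005", 1.0, 5.0)],
                          planted_down=[("G0020", 1.0, 5.0)])
    normal = generate_normal_cohort(spec)
    background = build_background(normal, 0.9)
    oracle_background = background_as_dict(background)
    tumor, _ = generate_tumor_cohort(spec, normal)
    for col in tumor.columns:
        sample = tumor[col]
        first = call_sample_reo(sample, background)
        status, p, _ = brute_call_sample(sample, oracle_background)
        assert first.status.to_dict() == status
        for g in sample.index:
            assert first.p_value[g] == pytest.approx(p[g], abs=1e-9)
        refined = refine_calls(first, sample, background)
        r_status, r_p, _ = brute_refine(sample, oracle_background)
        assert refined.status.to_dict() == r_status
        for g in sample.index:
            assert refined.p_value[g] == pytest.approx(r_p[g], abs=1e-9)


def test_margin_conservation_in_contingency_tables(tiny_normal):
    background = background_as_dict(build_background(tiny_normal, 0.9))
    spec = SimulationSpec(n_genes=20, n_normal=30, n_tumor=4, noise_sd=0.4, seed=31)
    tumor, _ = generate_tumor_cohort(spec, tiny_normal)
    for col in tumor.columns:
        tables, _ = gene_tables(tumor[col], background)
        for a, b, c, d in tables.values():
            assert a + b == c + d


def test_null_cohort_false_call_rate_is_controlled():
    rates = []
    for seed in (101, 102):
        spec = SimulationSpec(n_genes=300, n_normal=100, n_tumor=10, seed=seed)
        normal = generate_normal_cohort(spec)
        background = build_background(normal, 0.9)
        tumor, _ = generate_tumor_cohort(spec, normal)
        for call in cohort_calls(tumor, background):
            rates.append(np.mean(call.status != "stable"))
    assert np.mean(rates) <= 0.07
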