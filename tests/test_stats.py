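import numpy as np
import pandas as pd
import pytest

from spinemri.cohort import CohortParams, generate_cohort
from spinemri.grading import grade_cohort
from spinemri.stats import (
    ConstantInputError,
    ContingencyTable,
    build_report,
    chi2_test,
    format_count_percent,
    spearman,
    spearman_from_table,
    summarize_percentages,
)

# the published grouped counts of facet grade (rows 0-3) by herniation
# category (LDH, bulging, none); column totals 52 / 69 / 6 of 127
TABLE1_COUNTS = np.array([[14, 20, 2], [21, 31, 4], [10, 11, 0], [7, 7, 0]])


def midrank_oracle(x, y):
    """Brute-force Spearman: explicit midranks, then textbook Pearson."""

    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


# -- spearman --------------------------------------------------------------


def test_perfect_monotone_and_antitone():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).rho == pytest.approx(-1.0)


def test_spearman_matches_brute_force_oracle_on_tied_vectors():
    rng = np.random.default_rng(0)
    for _ in range(500):
        n = rng.integers(5, 40)
        x = rng.integers(0, 5, n).astype(float)
        y = rng.integers(0, 4, n).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        assert spearman(x, y).rho == pytest.approx(midrank_oracle(x, y), abs=1e-12)


def test_constant_vector_rejected():
    with pytest.raises(ConstantInputError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


def test_exact_permutation_p_for_tiny_n():
    res = spearman([1, 2, 3, 4], [10, 20, 30, 40], p_method="exact")
    # only the identity and the reversal reach |rho| = 1 among 4! orders
    assert res.p_value == pytest.approx(2 / 24)


def test_grouped_table_expansion_of_published_counts():
    """Expanding the printed grouped counts with severity encodings gives a
    weak negative association (about -0.09), not the strong value claimed
    alongside the table — the grouped data simply does not support it."""
    table = ContingencyTable(
        row_labels=(0, 1, 2, 3),
        col_labels=("LDH", "bulging", "none"),
        counts=TABLE1_COUNTS,
        row_scores=(0, 1, 2, 3),
        col_scores=(1, 2, 3),
    )
    xs, ys = table.expand()
    assert len(xs) == 127
    res = spearman(xs, ys)
    assert res.rho == pytest.approx(-0.0918663, abs=1e-6)
    assert res.rho == pytest.approx(midrank_oracle(xs, ys), abs=1e-12)


# -- spearman_from_table ---------------------------------------------------


def test_diagonal_and_antidiagonal_tables():
    diag = ContingencyTable((0, 1), (0, 1), np.array([[10, 0], [0, 10]]))
    anti = ContingencyTable((0, 1), (0, 1), np.array([[0, 10], [10, 0]]))
    assert spearman_from_table(diag).rho == pytest.approx(1.0)
    assert spearman_from_table(anti).rho == pytest.approx(-1.0)


def test_table_route_equals_expansion_route():
    rng = np.random.default_rng(1)
    for _ in range(50):
        r, c = rng.integers(2, 7), rng.integers(2, 7)
        counts = rng.integers(0, 30, (r, c))
        if counts.sum() == 0:
            continue
        table = ContingencyTable(tuple(range(r)), tuple(range(c)), counts)
        try:
            grouped = spearman_from_table(table)
        except ConstantInputError:
            continue
        xs, ys = table.expand()
        assert grouped.rho == pytest.approx(spearman(xs, ys).rho, abs=1e-12)
        assert grouped.n == len(xs)


def test_single_cell_table_rejected():
    with pytest.raises(ConstantInputError):
        spearman_from_table(ContingencyTable((0, 1), (0, 1), np.array([[5, 0], [0, 0]])))


# -- chi-square ------------------------------------------------------------


def test_chi2_independence_and_perfect_association():
    flat = ContingencyTable((0, 1), (0, 1), np.array([[10, 10], [10, 10]]))
    stat, dof, p = chi2_test(flat)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    diag = ContingencyTable((0, 1), (0, 1), np.array([[20, 0], [0, 20]]))
    stat, dof, p = chi2_test(diag)
    assert stat == pytest.approx(40.0)  # equals n for a perfect 2x2 association
    assert dof == 1


def test_chi2_on_published_counts_matches_cell_oracle():
    table = ContingencyTable((0, 1, 2, 3), ("LDH", "bulging", "none"), TABLE1_COUNTS)
    stat, dof, _ = chi2_test(table)
    expected = np.outer(TABLE1_COUNTS.sum(1), TABLE1_COUNTS.sum(0)) / TABLE1_COUNTS.sum()
    oracle = float(((TABLE1_COUNTS - expected) ** 2 / expected).sum())
    assert stat == pytest.approx(oracle, rel=1e-12)
    assert dof == 6


def test_chi2_invariant_under_permutations():
    rng = np.random.default_rng(2)
    counts = rng.integers(1, 20, (3, 4))
    base = chi2_test(ContingencyTable((0, 1, 2), (0, 1, 2, 3), counts))[0]
    perm = counts[[2, 0, 1]][:, [3, 1, 0, 2]]
    assert chi2_test(ContingencyTable((0, 1, 2), (0, 1, 2, 3), perm))[0] == pytest.approx(base)


def test_chi2_zero_margin_names_the_category():
    table = ContingencyTable(("a", "b"), ("x", "y"), np.array([[5, 0], [7, 0]]))
    with pytest.raises(ValueError, match="'y'"):
        chi2_test(table)


# -- percentages -----------------------------------------------------------


@pytest.mark.parametrize(
    "count,denom,expected",
    [
        (18, 81, "18 (22.22%)"),
        (15, 81, "15 (18.52%)"),
        (21, 52, "21 (40.38%)"),
        (0, 50, "0 (0.00%)"),
        (81, 127, "81 (63.78%)"),
    ],
)
def test_count_percent_rendering(count, denom, expected):
    assert format_count_percent(count, denom) == expected


def test_percentages_sum_to_hundred_over_a_partition():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 40, 7)
    df = summarize_percentages(list(counts))
    assert abs(df["percent"].sum() - 100.0) <= 0.02
    assert (df["denominator"] == counts.sum()).all()


def test_zero_denominator_rejected():
    with pytest.raises(ValueError, match="denominator"):
        format_count_percent(1, 0)


# -- report bundle ---------------------------------------------------------


@pytest.fixture(scope="module")
def graded_cohort():
    df = generate_cohort(CohortParams(n_patients=127, fixed_margins=True, seed=3))
    return grade_cohort(df)


def test_report_column_totals_match_fixed_margins(graded_cohort):
    bundle = build_report(graded_cohort)
    counts = bundle.facet_by_category.map(lambda s: int(s.split(" ")[0]))
    assert counts["LDH"].sum() == 52
    assert counts["bulging"].sum() == 69
    assert counts["none"].sum() == 6
    assert bundle.n_patients == 127
    assert bundle.n_records == 381


def test_report_is_deterministic(graded_cohort):
    a = build_report(graded_cohort)
    b = build_report(graded_cohort)
    assert a.to_json() == b.to_json()
    pd.testing.assert_frame_equal(a.facet_by_category, b.facet_by_category)
    pd.testing.assert_frame_equal(a.symptom_frequencies, b.symptom_frequencies)


def test_report_age_sex_rows_cover_all_symptomatic_patients(graded_cohort):
    df = graded_cohort.copy()
    df["residual_symptoms"] = True
    df.loc[df["symptom_codes"] == "", "symptom_codes"] = "A"
    bundle = build_report(df)
    assert bundle.residual_age_sex.to_numpy().sum() == bundle.n_patients


def test_report_correlations_present_and_bounded(graded_cohort):
    bundle = build_report(graded_cohort)
    assert "disc_grade_vs_facet_grade" in bundle.correlations
    assert "facet_grade_vs_ldh_category" in bundle.correlations
    for res in bundle.correlations.values():
        assert -1.0 <= res.rho <= 1.0
        assert 0.0 <= res.p_value <= 1.0
    # the generator couples disc and facet degeneration strongly
    assert bundle.correlations["disc_grade_vs_facet_grade"].rho > 0.5


def test_empty_cohort_rejected():
    with pytest.raises(ValueError, match="empty"):
        build_report(pd.DataFrame())
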