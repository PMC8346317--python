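"""Rank statistics and report building for the cohort analysis.

The clinical variables here are ordinal (facet grade 0-3, disc grade I-V,
herniation category) with heavy ties, so association is measured by
Spearman's rank correlation computed on midranks, and category tables are
tested with Pearson's chi-square.  Per the analysis protocol, rank
correlations carry alpha = 0.005 and chi-square tests alpha = 0.05 as
metadata; no multiplicity correction is applied.

Grouped data (a contingency table of two ordinal variables) admits a closed
form: the midrank of every subject in row i is determined by the row
margins alone, so Spearman's rho can be computed directly from the counts
without expanding to subject-level pairs.  ``spearman_from_table`` uses that
closed form; its equivalence to expansion + ``spearman`` is part of the test
suite.

Category encodings default to severity-decreasing order LDH = 1, bulging =
2, none = 3; the *sign* of any rho involving the herniation category depends
on this choice, which is why it is explicit and configurable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import LDH_CATEGORIES, LEVELS, SYMPTOM_CODES, SYMPTOM_LABELS

ALPHA_RANK = 0.005
ALPHA_CHI2 = 0.05

#: default numeric encoding of the herniation category (decreasing severity)
LDH_CATEGORY_SCORES = {"LDH": 1, "bulging": 2, "none": 3}


class ConstantInputError(ValueError):
    """Correlation is undefined when one variable never varies."""


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman rank correlation with its test metadata."""

    rho: float
    n: int
    p_value: float
    method: str = "spearman"
    alpha: float = ALPHA_RANK

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class ContingencyTable:
    """An ordered ordinal x categorical count matrix with numeric scores."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray
    row_scores: tuple | None = None
    col_scores: tuple | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(counts < 0) or counts.sum() == 0:
            raise ValueError("counts must be nonnegative with positive total")
        object.__setattr__(self, "counts", counts)
        for name, scores, labels in (
            ("row_scores", self.row_scores, self.row_labels),
            ("col_scores", self.col_scores, self.col_labels),
        ):
            if scores is not None:
                s = np.asarray(scores, float)
                if len(s) != len(labels) or np.any(np.diff(s) <= 0):
                    raise ValueError(f"{name} must be strictly increasing per label")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Subject-level (row_score, col_score) pairs, one per count."""
        rs = np.asarray(self.row_scores if self.row_scores is not None else range(len(self.row_labels)), float)
        cs = np.asarray(self.col_scores if self.col_scores is not None else range(len(self.col_labels)), float)
        xs, ys = [], []
        for i in range(len(self.row_labels)):
            for j in range(len(self.col_labels)):
                k = int(self.counts[i, j])
                xs.extend([rs[i]] * k)
                ys.extend([cs[j]] * k)
        return np.asarray(xs), np.asarray(ys)


def spearman(x, y, alpha: float = ALPHA_RANK, p_method: str = "t") -> CorrelationResult:
    """Spearman's rho with midranks for ties.

    ``p_method='t'`` uses the large-sample t approximation; ``'exact'``
    enumerates all permutations (only sensible for n < 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if p_method == "t":
        p = float(res.pvalue)
    elif p_method == "exact":
        if len(x) >= 10:
            raise ValueError("exact permutation p-value is limited to n < 10")
        rx = sps.rankdata(x)
        count = 0
        total = 0
        ry = sps.rankdata(y)
        for perm in itertools.permutations(range(len(y))):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CorrelationResult(rho=rho, n=len(x), p_value=p, alpha=alpha)


def _grouped_midranks(margins: np.ndarray) -> np.ndarray:
    """Midrank shared by all subjects in each ordered category."""
    cum = np.concatenate([[0], np.cumsum(margins)])
    return cum[:-1] + (margins + 1) / 2.0


def spearman_from_table(table: ContingencyTable, alpha: float = ALPHA_RANK) -> CorrelationResult:
    """Spearman's rho of grouped ordinal data, directly from the counts.

    Every subject in row *i* has the same midrank (a function of the row
    margins), so rho is the weighted Pearson correlation of row and column
    midranks with the cell counts as weights — no expansion needed.
    """
    counts = table.counts.astype(float)
    n = counts.sum()
    rmarg = counts.sum(axis=1)
    cmarg = counts.sum(axis=0)
    if np.count_nonzero(rmarg) < 2 or np.count_nonzero(cmarg) < 2:
        raise ConstantInputError("correlation undefined: a margin is concentrated in one category")
    rr = _grouped_midranks(rmarg)
    cr = _grouped_midranks(cmarg)
    mean_rank = (n + 1) / 2.0
    dr = rr - mean_rank
    dc = cr - mean_rank
    cov = float(dr @ counts @ dc)
    vr = float(rmarg @ dr**2)
    vc = float(cmarg @ dc**2)
    rho = cov / np.sqrt(vr * vc)
    n_int = int(n)
    # large-sample t approximation, as in the vector path
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n_int - 2) / (1.0 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df=n_int - 2))
    return CorrelationResult(rho=float(rho), n=n_int, p_value=p, alpha=alpha)


def chi2_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns ``(statistic, dof, p_value)``.  Zero row/column margins are
    rejected with the degenerate margin named.
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi-square needs at least a 2x2 table")
    rmarg = counts.sum(axis=1)
    cmarg = counts.sum(axis=0)
    for name, marg, labels in (("row", rmarg, table.row_labels), ("column", cmarg, table.col_labels)):
        zero = np.where(marg == 0)[0]
        if len(zero):
            raise ValueError(f"degenerate {name} margin: {labels[zero[0]]!r} has zero total")
    res = sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# -- percentage rendering --------------------------------------------------


def format_count_percent(count: int, denominator: int) -> str:
    """Render ``"count (percent%)"`` with two half-even decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return f"{count} ({100.0 * count / denominator:.2f}%)"


def summarize_percentages(counts, denominator: int | None = None, labels=None) -> pd.DataFrame:
    """Tabulate counts as ``count (percent)`` rows with an explicit denominator.

    *counts* may be a mapping, a pandas Series, or a sequence (paired with
    *labels*).  The denominator defaults to the total of the counts.
    """
    if isinstance(counts, dict):
        labels = list(counts.keys())
        values = list(counts.values())
    elif isinstance(counts, pd.Series):
        labels = list(counts.index)
        values = list(counts.values)
    else:
        values = list(counts)
        labels = list(labels) if labels is not None else list(range(len(values)))
    denom = int(denominator) if denominator is not None else int(sum(values))
    if denom <= 0:
        raise ValueError("denominator must be > 0")
    return pd.DataFrame(
        {
            "label": labels,
            "count": values,
            "denominator": denom,
            "percent": [round(100.0 * v / denom, 2) for v in values],
            "rendered": [format_count_percent(int(v), denom) for v in values],
        }
    )


# -- the report bundle -----------------------------------------------------


@dataclass
class ReportBundle:
    """All cohort summary tables plus their association statistics."""

    facet_by_category: pd.DataFrame
    asymmetry_by_level: pd.DataFrame
    disc_grade_distribution: pd.DataFrame
    residual_age_sex: pd.DataFrame
    symptom_frequencies: pd.DataFrame
    correlations: dict[str, CorrelationResult]
    chi2: dict[str, tuple[float, int, float]]
    n_patients: int
    n_records: int

    def to_json(self) -> str:
        payload = {
            "n_patients": self.n_patients,
            "n_records": self.n_records,
            "correlations": {
                k: {"rho": v.rho, "n": v.n, "p_value": v.p_value, "alpha": v.alpha}
                for k, v in self.correlations.items()
            },
            "chi2": {
                k: {"statistic": s, "dof": d, "p_value": p}
                for k, (s, d, p) in self.chi2.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.facet_by_category.to_csv(out / "facet_by_category.csv")
        self.asymmetry_by_level.to_csv(out / "asymmetry_by_level.csv")
        self.disc_grade_distribution.to_csv(out / "disc_grade_distribution.csv", index=False)
        self.residual_age_sex.to_csv(out / "residual_age_sex.csv")
        self.symptom_frequencies.to_csv(out / "symptom_frequencies.csv", index=False)
        (out / "associations.json").write_text(self.to_json())


def plot_report(bundle: ReportBundle, outdir) -> None:
    """Bar charts of the distribution tables (PNG): disc-grade
    distribution, residual-symptom age/sex breakdown, symptom frequencies."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(5, 3))
    dist = bundle.disc_grade_distribution
    ax.bar(dist["label"], dist["percent"], color="tab:blue")
    ax.set_ylabel("patients (%)")
    ax.set_title("disc degeneration grade distribution")
    fig.tight_layout()
    fig.savefig(out / "disc_grade_distribution.png", dpi=120)
    plt.close(fig)

    if not bundle.residual_age_sex.empty:
        ax = bundle.residual_age_sex.plot.bar(figsize=(6, 3))
        ax.set_ylabel("patients")
        ax.set_title("residual-symptom patients by age decade and sex")
        ax.figure.tight_layout()
        ax.figure.savefig(out / "residual_age_sex.png", dpi=120)
        plt.close(ax.figure)

    if not bundle.symptom_frequencies.empty:
        fig, ax = plt.subplots(figsize=(6, 3))
        freq = bundle.symptom_frequencies
        ax.bar(freq["label"], freq["percent"], color="tab:orange")
        ax.set_ylabel("patients (%)")
        ax.set_title("residual neurological symptom frequencies")
        fig.tight_layout()
        fig.savefig(out / "symptom_frequencies.png", dpi=120)
        plt.close(fig)


def index_level_view(records: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: the level with the worst disc grade.

    Ties break toward the more cranial level (L3/4 before L4/5 before
    L5/S1), following the stable level ordering of the cohort schema.
    """
    df = records.copy()
    df["_lvl_order"] = df["level"].map({lv: i for i, lv in enumerate(LEVELS)})
    df = df.sort_values(["patient_id", "disc_grade", "_lvl_order"], ascending=[True, False, True])
    return df.groupby("patient_id", sort=True).head(1).drop(columns="_lvl_order")


def _category_table(rows: pd.Series, cats: pd.Series, row_order, row_scores) -> ContingencyTable:
    counts = pd.crosstab(rows, cats).reindex(
        index=list(row_order), columns=list(LDH_CATEGORIES), fill_value=0
    )
    return ContingencyTable(
        row_labels=tuple(counts.index),
        col_labels=tuple(counts.columns),
        counts=counts.to_numpy(),
        row_scores=tuple(row_scores),
        col_scores=tuple(LDH_CATEGORY_SCORES[c] for c in LDH_CATEGORIES),
    )


def _drop_zero_margins(table: ContingencyTable) -> ContingencyTable:
    counts = table.counts
    rkeep = counts.sum(axis=1) > 0
    ckeep = counts.sum(axis=0) > 0
    return ContingencyTable(
        row_labels=tuple(np.asarray(table.row_labels, dtype=object)[rkeep]),
        col_labels=tuple(np.asarray(table.col_labels, dtype=object)[ckeep]),
        counts=counts[np.ix_(rkeep, ckeep)],
    )


def build_report(graded: pd.DataFrame) -> ReportBundle:
    """Assemble the full cohort report from a graded record table.

    Emits (a) per-patient facet grade x herniation category, (b) asymmetric
    records by level x category, (c) the disc-grade distribution, (d) the
    age/sex breakdown of residual-symptom patients, and (e) symptom-code
    frequencies, together with the Spearman and chi-square statistics each
    table supports.  Deterministic: no randomness is consumed.
    """
    if graded.empty:
        raise ValueError("empty cohort")
    required = {"facet_grade", "disc_grade", "ldh_category", "asymmetric"}
    missing = required - set(graded.columns)
    if missing:
        raise ValueError(f"graded cohort missing columns: {sorted(missing)}")

    patients = index_level_view(graded)
    n_patients = len(patients)
    correlations: dict[str, CorrelationResult] = {}
    chi2: dict[str, tuple[float, int, float]] = {}

    # (a) facet grade x herniation category, per patient
    tab_a = _category_table(
        patients["facet_grade"], patients["ldh_category"], row_order=range(4), row_scores=range(4)
    )
    facet_df = pd.DataFrame(tab_a.counts, index=[f"grade {g}" for g in tab_a.row_labels], columns=tab_a.col_labels)
    col_tot = facet_df.sum(axis=0)
    rendered = facet_df.copy().astype(object)
    for c in facet_df.columns:  # per-column denominators
        denom = int(col_tot[c])
        for r in facet_df.index:
            rendered.loc[r, c] = format_count_percent(int(facet_df.loc[r, c]), denom) if denom else "0"
    correlations["facet_grade_vs_ldh_category"] = spearman_from_table(_with_scores(tab_a))
    chi2["facet_grade_vs_ldh_category"] = chi2_test(_drop_zero_margins(tab_a))

    # (b) asymmetric records by level x category (record level)
    asym = graded[graded["asymmetric"] == 1]
    tab_b_df = pd.crosstab(asym["level"], asym["ldh_category"]).reindex(
        index=list(LEVELS), columns=list(LDH_CATEGORIES), fill_value=0
    )
    cat_codes = graded["ldh_category"].map(LDH_CATEGORY_SCORES)
    try:
        correlations["asymmetry_vs_ldh_category"] = spearman(
            graded["asymmetric"].to_numpy(), cat_codes.to_numpy()
        )
    except ConstantInputError:
        pass
    try:
        chi2["asymmetry_by_level"] = chi2_test(
            _drop_zero_margins(
                ContingencyTable(
                    row_labels=tuple(tab_b_df.index),
                    col_labels=tuple(tab_b_df.columns),
                    counts=tab_b_df.to_numpy(),
                )
            )
        )
    except ValueError:
        pass

    # (c) disc-grade distribution per patient + ordinal correlations
    disc_counts = patients["disc_grade"].value_counts().reindex(range(1, 6), fill_value=0)
    disc_dist = summarize_percentages(
        disc_counts.to_list(),
        denominator=n_patients,
        labels=[f"grade {r}" for r in ("I", "II", "III", "IV", "V")],
    )
    correlations["disc_grade_vs_facet_grade"] = spearman(
        graded["disc_grade"].to_numpy(), graded["facet_grade"].to_numpy()
    )
    if patients["age"].nunique() > 1:
        correlations["facet_grade_vs_age"] = spearman(
            patients["facet_grade"].to_numpy(), patients["age"].to_numpy()
        )

    # (d) residual-symptom patients by age decade x sex
    res = patients[patients["residual_symptoms"]]
    if len(res):
        bins = pd.cut(res["age"], bins=[20, 30, 40, 50, 60, 70, 80], right=True)
        age_sex = pd.crosstab(bins, res["sex"], dropna=False)
    else:
        age_sex = pd.DataFrame()
    n_res = len(res)
    if not age_sex.empty and age_sex.shape[1] >= 2:
        nonzero = age_sex.loc[age_sex.sum(axis=1) > 0]
        if len(nonzero) >= 2:
            chi2["residual_age_by_sex"] = chi2_test(
                ContingencyTable(
                    row_labels=tuple(str(i) for i in nonzero.index),
                    col_labels=tuple(nonzero.columns),
                    counts=nonzero.to_numpy(),
                )
            )

    # (e) symptom-code frequencies among residual-symptom patients
    if n_res:
        freq = {
            code: int(res["symptom_codes"].str.contains(code).sum()) for code in SYMPTOM_CODES
        }
        symptom_df = summarize_percentages(list(freq.values()), denominator=n_res, labels=list(SYMPTOM_CODES))
        symptom_df["meaning"] = [SYMPTOM_LABELS[c] for c in SYMPTOM_CODES]
    else:
        symptom_df = pd.DataFrame(columns=["label", "count", "denominator", "percent", "rendered", "meaning"])

    return ReportBundle(
        facet_by_category=rendered,
        asymmetry_by_level=tab_b_df,
        disc_grade_distribution=disc_dist,
        residual_age_sex=age_sex,
        symptom_frequencies=symptom_df,
        correlations=correlations,
        chi2=chi2,
        n_patients=n_patients,
        n_records=len(graded),
    )


def _with_scores(table: ContingencyTable) -> ContingencyTable:
    """Keep only rows/cols with nonzero margins, preserving scores."""
    counts = table.counts
    rkeep = counts.sum(axis=1) > 0
    ckeep = counts.sum(axis=0) > 0
    rs = np.asarray(table.row_scores, float)[rkeep] if table.row_scores is not None else None
    cs = np.asarray(table.col_scores, float)[ckeep] if table.col_scores is not None else None
    return ContingencyTable(
        row_labels=tuple(np.asarray(table.row_labels, dtype=object)[rkeep]),
        col_labels=tuple(np.asarray(table.col_labels, dtype=object)[ckeep]),
        counts=counts[np.ix_(rkeep, ckeep)],
        row_scores=tuple(rs) if rs is not None else None,
        col_scores=tuple(cs) if cs is not None else None,
    )
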