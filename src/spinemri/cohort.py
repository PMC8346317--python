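"""Synthetic lumbar-spine patient cohorts.

Each simulated patient contributes one record per lumbar level (L3/4, L4/5,
L5/S1).  A record carries the quantities the downstream grading and
correlation analyses consume: bilateral facet-joint angles, an ordinal facet
degeneration grade (0-3), disc height and an ordinal disc degeneration grade
(I-V), the patient's herniation category (LDH / bulging / none), and
residual-symptom information.

The statistical backbone is a Gaussian copula.  Every patient-level record
has a latent "degeneration severity" factor; the disc and facet latents load
on it equally, and ordinal grades arise by cutting each latent at the
quantiles of the target marginal frequencies.  The latent correlation is
calibrated so that the *population* Spearman correlation of the two
discretized grades matches the requested target exactly — the population
value is computed in closed form from bivariate-normal rectangle
probabilities, so no Monte-Carlo tuning is involved and the empirical
Spearman at large n converges to the target.

The herniation category loads on the same severity factor (more degenerate
spines are more likely to be herniated), and the left-right facet angle
difference is drawn with a mean shift for LDH patients, so asymmetry and
herniation are positively associated.  A fixed-margin mode assigns the exact
category multiset (e.g. 52 / 69 / 6 of 127) to patients ranked by their
herniation propensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

LEVELS = ("L3/4", "L4/5", "L5/S1")
LDH_CATEGORIES = ("LDH", "bulging", "none")
SYMPTOM_CODES = tuple("ABCDEFGHI")

#: symptom-code meanings (axial legend of the residual-symptom analysis)
SYMPTOM_LABELS = {
    "A": "waist pain",
    "B": "hip pain",
    "C": "lower extremity radiating pain",
    "D": "lower extremity pain",
    "E": "waist movement limitation",
    "F": "lower extremity weakness",
    "G": "lower extremity paresthesia",
    "H": "intermittent claudication",
    "I": "severe urinary excretion disorder",
}

# default marginal frequencies -------------------------------------------------

#: disc degeneration grade I..V marginals; grade IV is the modal grade.
DISC_GRADE_PROBS = (0.07, 0.17, 0.26, 0.32, 0.18)

#: facet degeneration grade 0..3 marginals (row totals 36/56/21/14 of 127).
FACET_GRADE_PROBS = (36 / 127, 56 / 127, 21 / 127, 14 / 127)

#: herniation category marginals (LDH, bulging, none) = (52, 69, 6) of 127.
LDH_CATEGORY_PROBS = (52 / 127, 69 / 127, 6 / 127)

#: age-decade bins and weights, peaked at 61-70 years.
AGE_BINS = ((21, 30), (31, 40), (41, 50), (51, 60), (61, 70), (71, 80))
AGE_BIN_PROBS = (0.06, 0.10, 0.16, 0.20, 0.33, 0.15)

#: per-symptom probabilities among residual-symptom patients; severe urinary
#: excretion disorder (I) dominates.
SYMPTOM_PROBS = {
    "A": 0.55, "B": 0.30, "C": 0.45, "D": 0.35, "E": 0.40,
    "F": 0.28, "G": 0.33, "H": 0.20, "I": 0.7196,
}

#: fraction of patients with postoperative residual neurological symptoms.
RESIDUAL_SYMPTOM_PROB = 81 / 127

#: mean facet-joint angle (degrees from sagittal) per level; facet joints
#: become more coronally oriented caudally.
LEVEL_ANGLE_MEANS = {"L3/4": 32.0, "L4/5": 38.0, "L5/S1": 44.0}
ANGLE_SD = 6.0

#: half-normal scale of the left-right angle difference (degrees) and the
#: additional mean shift applied to LDH patients.
ASYMMETRY_SCALE = 4.0
DEFAULT_ASYMMETRY_EFFECT = 3.5

#: mid-range normal disc heights (cm) per level; mean height ratio per disc
#: grade I..V with Gaussian scatter.
LEVEL_HEIGHT_REF = {"L3/4": 1.160, "L4/5": 1.226, "L5/S1": 1.030}
GRADE_HEIGHT_RATIO = (1.00, 0.92, 0.84, 0.72, 0.55)
HEIGHT_RATIO_SD = 0.05


class CalibrationError(ValueError):
    """Requested association is unreachable under the latent model."""


@dataclass(frozen=True)
class CohortParams:
    """Configuration for one synthetic cohort draw."""

    n_patients: int
    target_rho_disc_facet: float = 0.753
    ldh_category_probs: tuple[float, float, float] = LDH_CATEGORY_PROBS
    age_distribution: tuple[float, ...] = AGE_BIN_PROBS
    asymmetry_effect: float = DEFAULT_ASYMMETRY_EFFECT
    fixed_margins: bool = False
    seed: int = 0
    disc_grade_probs: tuple[float, ...] = DISC_GRADE_PROBS
    facet_grade_probs: tuple[float, ...] = FACET_GRADE_PROBS
    ldh_severity_loading: float = 0.6

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not -1.0 <= self.target_rho_disc_facet <= 1.0:
            raise ValueError("target_rho_disc_facet must lie in [-1, 1]")
        for name, probs in (
            ("ldh_category_probs", self.ldh_category_probs),
            ("age_distribution", self.age_distribution),
            ("disc_grade_probs", self.disc_grade_probs),
            ("facet_grade_probs", self.facet_grade_probs),
        ):
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be nonnegative and sum to 1")


# ---------------------------------------------------------------------------
# copula calibration


def _midrank_scores(probs: np.ndarray) -> np.ndarray:
    """Population midranks (on the [0, 1] scale) of an ordinal marginal."""
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    return cum[:-1] + probs / 2.0


def _cell_probs(row_probs: np.ndarray, col_probs: np.ndarray, r: float) -> np.ndarray:
    """Joint cell probabilities of two ordinals cut from a BVN(r) latent."""
    urow = norm.ppf(np.cumsum(row_probs))[:-1]
    ucol = norm.ppf(np.cumsum(col_probs))[:-1]
    hi = 12.0  # effectively +inf for the standard normal
    redges = np.concatenate([[-hi], urow, [hi]])
    cedges = np.concatenate([[-hi], ucol, [hi]])
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    grid = np.array(
        [[mvn.cdf([redges[i], cedges[j]]) for j in range(len(cedges))]
         for i in range(len(redges))]
    )
    cells = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(cells, 0.0, 1.0)


def population_spearman(row_probs, col_probs, latent_r: float) -> float:
    """Population Spearman rho of two ordinals sharing a BVN(latent_r) copula.

    This is the large-n limit of the midrank sample Spearman when each
    ordinal is produced by quantile-thresholding one margin of a bivariate
    normal with correlation *latent_r*.
    """
    rp = np.asarray(row_probs, float)
    cp = np.asarray(col_probs, float)
    a = _midrank_scores(rp)
    b = _midrank_scores(cp)
    cells = _cell_probs(rp, cp, latent_r)
    ea, eb = float(rp @ a), float(cp @ b)
    va = float(rp @ a**2) - ea**2
    vb = float(cp @ b**2) - eb**2
    cov = float(a @ cells @ b) - ea * eb
    return cov / np.sqrt(va * vb)


def calibrate_latent_correlation(
    target_rho: float,
    row_probs=DISC_GRADE_PROBS,
    col_probs=FACET_GRADE_PROBS,
    tol: float = 1e-6,
) -> float:
    """Solve for the latent BVN correlation whose discretized Spearman is
    *target_rho*, by bisection on the monotone map ``population_spearman``.

    Raises
    ------
    CalibrationError
        If |target_rho| exceeds the maximum attainable under the given
        marginals (the value at latent correlation -> 1).
    """
    if target_rho == 0.0:
        return 0.0
    sign = 1.0 if target_rho > 0 else -1.0
    target = abs(target_rho)
    rho_max = population_spearman(row_probs, col_probs, 0.999999)
    if target > rho_max + 1e-9:
        raise CalibrationError(
            f"target Spearman {target_rho:+.3f} exceeds the attainable maximum "
            f"{sign * rho_max:+.3f} under the configured grade marginals"
        )
    lo, hi = 0.0, 0.999999
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if population_spearman(row_probs, col_probs, mid) < target:
            lo = mid
        else:
            hi = mid
    return sign * 0.5 * (lo + hi)


def _discretize(z: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Map standard-normal draws to ordinal codes 0..K-1 by quantile cuts."""
    edges = norm.ppf(np.cumsum(probs))[:-1]
    return np.searchsorted(edges, z, side="left")


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a cohort; one row per patient per lumbar level.

    Columns follow the patient-record schema: ``patient_id, age, sex, level,
    facet_angle_left, facet_angle_right, facet_grade, disc_height,
    disc_grade, ldh_category, residual_symptoms, symptom_codes``.
    ``disc_grade`` uses integer codes 1..5 (clinical grades I-V) and
    ``facet_grade`` 0..3.  ``symptom_codes`` is a string such as ``"ACI"``.

    Deterministic given ``params.seed``; all randomness flows from that one
    integer.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    n_rec = n * len(LEVELS)

    latent_r = calibrate_latent_correlation(
        params.target_rho_disc_facet,
        params.disc_grade_probs,
        params.facet_grade_probs,
    )

    # one-factor Gaussian copula: shared severity s, equal loadings sqrt(|r|)
    lam = np.sqrt(abs(latent_r))
    s = rng.standard_normal(n_rec)
    e_disc = rng.standard_normal(n_rec)
    e_facet = rng.standard_normal(n_rec)
    z_disc = lam * s + np.sqrt(1 - lam**2) * e_disc
    z_facet = np.sign(latent_r) * lam * s + np.sqrt(1 - lam**2) * e_facet

    disc_grade = _discretize(z_disc, np.asarray(params.disc_grade_probs)) + 1
    facet_grade = _discretize(z_facet, np.asarray(params.facet_grade_probs))

    # herniation propensity per patient: mean record severity + noise
    lam_l = params.ldh_severity_loading
    sev_patient = s.reshape(n, len(LEVELS)).mean(axis=1) * np.sqrt(len(LEVELS))
    z_ldh = lam_l * sev_patient + np.sqrt(1 - lam_l**2) * rng.standard_normal(n)

    cat_probs = np.asarray(params.ldh_category_probs, float)
    if params.fixed_margins:
        counts = _apportion_counts(cat_probs, n)
        # draw-without-replacement: patients ranked by propensity take the
        # category multiset from most severe (LDH) to least (none)
        order = np.argsort(-z_ldh, kind="stable")
        cat_idx = np.empty(n, dtype=int)
        bounds = np.concatenate([[0], np.cumsum(counts)])
        for k in range(3):
            cat_idx[order[bounds[k]:bounds[k + 1]]] = k
    else:
        # severity-ordered categories: high propensity -> LDH, low -> none
        edges = norm.ppf(np.cumsum(cat_probs[::-1]))[:-1]
        cat_idx = 2 - np.searchsorted(edges, z_ldh, side="left")
    ldh_category = np.array(LDH_CATEGORIES)[cat_idx]

    # facet angles: per-level base orientation plus left-right asymmetry with
    # an extra mean shift for LDH patients
    level_col = np.tile(np.array(LEVELS), n)
    base = np.array([LEVEL_ANGLE_MEANS[lv] for lv in level_col])
    mean_angle = np.clip(base + rng.normal(0, ANGLE_SD, n_rec), 8.0, 82.0)
    shift = np.where(np.repeat(cat_idx == 0, len(LEVELS)), params.asymmetry_effect, 0.0)
    diff = np.abs(rng.normal(0, ASYMMETRY_SCALE, n_rec)) + shift * np.abs(
        rng.normal(0.6, 0.4, n_rec)
    )
    side = rng.choice([-1.0, 1.0], n_rec)
    left = np.clip(mean_angle + side * diff / 2, 1.0, 89.0)
    right = np.clip(mean_angle - side * diff / 2, 1.0, 89.0)

    # disc height follows disc grade: more degenerate -> lower height ratio
    ref = np.array([LEVEL_HEIGHT_REF[lv] for lv in level_col])
    ratio = np.array(GRADE_HEIGHT_RATIO)[disc_grade - 1] + rng.normal(
        0, HEIGHT_RATIO_SD, n_rec
    )
    disc_height = np.round(np.maximum(ref * ratio, 0.05), 4)

    # demographics and residual symptoms (per patient)
    age_bin = rng.choice(len(AGE_BINS), size=n, p=np.asarray(params.age_distribution))
    lo = np.array([b[0] for b in AGE_BINS])[age_bin]
    hi = np.array([b[1] for b in AGE_BINS])[age_bin]
    age = rng.integers(lo, hi + 1)
    sex = rng.choice(["M", "F"], size=n, p=[0.55, 0.45])
    residual = rng.random(n) < RESIDUAL_SYMPTOM_PROB
    probs = np.array([SYMPTOM_PROBS[c] for c in SYMPTOM_CODES])
    draws = rng.random((n, len(SYMPTOM_CODES))) < probs[None, :]
    codes = []
    for i in range(n):
        if not residual[i]:
            codes.append("")
            continue
        picked = "".join(c for c, hit in zip(SYMPTOM_CODES, draws[i]) if hit)
        codes.append(picked if picked else "I")

    df = pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(1, n + 1), len(LEVELS)),
            "age": np.repeat(age, len(LEVELS)),
            "sex": np.repeat(sex, len(LEVELS)),
            "level": level_col,
            "facet_angle_left": np.round(left, 2),
            "facet_angle_right": np.round(right, 2),
            "facet_grade": facet_grade.astype(int),
            "disc_height": disc_height,
            "disc_grade": disc_grade.astype(int),
            "ldh_category": np.repeat(ldh_category, len(LEVELS)),
            "residual_symptoms": np.repeat(residual, len(LEVELS)),
            "symptom_codes": np.repeat(np.array(codes, dtype=object), len(LEVELS)),
        }
    )
    return df


def _apportion_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n into integer category counts."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def cohort_to_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (stable column order, no index)."""
    df.to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`cohort_to_csv`."""
    df = pd.read_csv(path, keep_default_na=False, dtype={"symptom_codes": str})
    df["residual_symptoms"] = df["residual_symptoms"].astype(str).isin(("True", "1"))
    return df
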