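"""Growth trajectories, quadratic fits and five-pattern classification.

Each (person, phenotype) time series is expressed on *relative age*
(photo age minus the person's current age, so the current photo sits at
0 and all past photos at negative ages), fitted with an ordinary
least-squares quadratic, and classified by the signs of the fitted
endpoint slopes into one of five growth patterns:

======  ====  ==========================
label   code  meaning
======  ====  ==========================
DD      1     continued decrease
DI      2     decrease then increase
CC      3     constant
ID      4     increase then decrease
II      5     continued increase
======  ====  ==========================

A slope counts as flat when the change it implies over the whole age
span is below ``eps_rel`` times the magnitude of the fitted curve, so
classification is invariant to uniform positive scaling of the values
and to adding a constant offset changes only through the scale term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PATTERN_LABELS",
    "LABEL_TO_CODE",
    "CODE_TO_LABEL",
    "Trajectory",
    "GrowthFit",
    "Pattern",
    "build_trajectories",
    "fit_growth",
    "classify_pattern",
    "classify_cohort",
    "pattern_table",
]

PATTERN_LABELS = ("DD", "DI", "CC", "ID", "II")
LABEL_TO_CODE = {lab: i + 1 for i, lab in enumerate(PATTERN_LABELS)}
CODE_TO_LABEL = {i + 1: lab for i, lab in enumerate(PATTERN_LABELS)}

MIN_OBS = 3


@dataclass(frozen=True)
class Trajectory:
    person_id: str
    phenotype: str
    relative_ages: np.ndarray  # strictly increasing, max == 0
    values: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.relative_ages)


@dataclass(frozen=True)
class Pattern:
    label: str
    code: int


@dataclass(frozen=True)
class GrowthFit:
    """Quadratic fit value = a + b1*t + b2*t**2 over relative age t."""

    a: float
    b1: float
    b2: float
    residual_sd: float
    t_min: float
    t_max: float

    def value_at(self, t):
        return self.a + self.b1 * t + self.b2 * t * t

    def slope_at(self, t: float) -> float:
        return self.b1 + 2.0 * self.b2 * t

    @property
    def s_start(self) -> float:
        return self.slope_at(self.t_min)

    @property
    def s_end(self) -> float:
        return self.slope_at(self.t_max)

    @property
    def total_change(self) -> float:
        return self.value_at(self.t_max) - self.value_at(self.t_min)


def build_trajectories(
    phenotypes: pd.DataFrame,
    *,
    min_obs: int = MIN_OBS,
    require_current: bool = True,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Group QC-passed phenotype records into per-(person, phenotype) series.

    Same-age duplicate photos are averaged.  Series with fewer than
    ``min_obs`` surviving observations, or whose current photo (relative
    age 0) was removed by QC, are reported in the returned unclassifiable
    table rather than raised.  A person with no current photo at all in
    the input is a data error when ``require_current`` is set.
    """
    df = phenotypes.copy()
    df["relative_age"] = df["age"] - df["current_age"]
    if (df["relative_age"] > 0).any():
        raise ValueError("photo age exceeds current age")

    if require_current:
        has_current = df.groupby("person_id")["relative_age"].max()
        lacking = has_current[has_current < 0].index.tolist()
        if lacking:
            raise ValueError(f"person(s) lacking a current photo: {lacking}")

    trajectories: list[Trajectory] = []
    unclassifiable: list[tuple[str, str, int, str]] = []
    for (person, pheno), grp in df.groupby(["person_id", "phenotype"], sort=True):
        # average duplicate same-age observations
        series = grp.groupby("relative_age")["value"].mean().sort_index()
        t = series.index.to_numpy(dtype=float)
        v = series.to_numpy(dtype=float)
        if len(t) < min_obs:
            unclassifiable.append((person, pheno, len(t), "too_few_observations"))
            continue
        if t[-1] != 0.0:
            unclassifiable.append((person, pheno, len(t), "no_current_photo"))
            continue
        trajectories.append(Trajectory(person, pheno, t, v))

    unc = pd.DataFrame(
        unclassifiable, columns=["person_id", "phenotype", "n_obs", "reason"]
    )
    return trajectories, unc


def fit_growth(traj: Trajectory, degree: int = 2) -> GrowthFit:
    """OLS polynomial fit of the trajectory on relative age.

    With exactly three points the quadratic interpolates them.  Degree 1
    is accepted for a linear fit (b2 = 0).
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    t, v = traj.relative_ages, traj.values
    if traj.n_obs < MIN_OBS:
        raise ValueError(f"need >= {MIN_OBS} observations, got {traj.n_obs}")
    assert len(np.unique(t)) == traj.n_obs, "duplicate ages must be averaged first"

    coeffs = np.polynomial.polynomial.polyfit(t, v, degree)
    a, b1 = float(coeffs[0]), float(coeffs[1])
    b2 = float(coeffs[2]) if degree == 2 else 0.0
    resid = v - (a + b1 * t + b2 * t * t)
    dof = traj.n_obs - (degree + 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return GrowthFit(a, b1, b2, residual_sd, float(t[0]), float(t[-1]))


def classify_pattern(fit: GrowthFit, eps_rel: float = 0.02, scale_floor: float = 1e-9) -> Pattern:
    """Assign a growth-pattern label from the fitted endpoint slopes.

    A slope ``s`` is flat iff ``|s| * span < eps_rel * scale`` where
    ``scale`` is the largest magnitude of the fitted curve over the span
    (floored to avoid a zero scale on all-zero data).  Both slopes
    non-flat gives the four signed patterns; both flat gives CC; with
    one flat slope the sign of the fitted total change decides between
    DD, CC and II.
    """
    if not (fit.t_min < fit.t_max):
        raise ValueError("degenerate age span")
    span = fit.t_max - fit.t_min
    # extremum of the quadratic may exceed both endpoint values
    ts = [fit.t_min, fit.t_max]
    if fit.b2 != 0.0:
        t_vertex = -fit.b1 / (2.0 * fit.b2)
        if fit.t_min < t_vertex < fit.t_max:
            ts.append(t_vertex)
    scale = max(max(abs(fit.value_at(t)) for t in ts), scale_floor)
    tol = eps_rel * scale

    def flat(s: float) -> bool:
        return abs(s) * span < tol

    s0, s1 = fit.s_start, fit.s_end
    if not flat(s0) and not flat(s1):
        if s0 < 0 and s1 < 0:
            label = "DD"
        elif s0 < 0 and s1 > 0:
            label = "DI"
        elif s0 > 0 and s1 < 0:
            label = "ID"
        else:
            label = "II"
    elif flat(s0) and flat(s1):
        label = "CC"
    else:
        # one flat slope: direction of the net fitted change decides
        tc = fit.total_change
        if abs(tc) < tol:
            label = "CC"
        else:
            label = "DD" if tc < 0 else "II"
    return Pattern(label, LABEL_TO_CODE[label])


def classify_cohort(
    trajectories: list[Trajectory],
    eps_rel: float = 0.02,
    degree: int = 2,
) -> pd.DataFrame:
    """Fit and classify every trajectory; one row per (person, phenotype)."""
    rows = []
    for traj in trajectories:
        fit = fit_growth(traj, degree=degree)
        pat = classify_pattern(fit, eps_rel=eps_rel)
        rows.append(
            (traj.person_id, traj.phenotype, pat.label, pat.code, traj.n_obs,
             fit.a, fit.b1, fit.b2, fit.residual_sd, fit.total_change)
        )
    return pd.DataFrame(
        rows,
        columns=["person_id", "phenotype", "label", "code", "n_obs",
                 "a", "b1", "b2", "residual_sd", "total_change"],
    )


def pattern_table(classified: pd.DataFrame, phenotypes: list[str] | None = None) -> pd.DataFrame:
    """Per-phenotype frequency table over the five pattern codes.

    Columns: counts ``n1..n5``, proportions ``p1..p5``, total ``n`` and
    ``modal`` (the most frequent code; ties broken toward the lower code;
    0 marks an empty phenotype).
    """
    if phenotypes is None:
        phenotypes = sorted(classified["phenotype"].unique())
    rows = []
    for pheno in phenotypes:
        codes = classified.loc[classified["phenotype"] == pheno, "code"]
        counts = np.array([(codes == c).sum() for c in range(1, 6)], dtype=int)
        total = int(counts.sum())
        props = counts / total if total else np.zeros(5)
        modal = int(np.argmax(counts)) + 1 if total else 0  # argmax ties -> lower code
        rows.append((pheno, *counts, *props, total, modal))
    return pd.DataFrame(
        rows,
        columns=["phenotype", "n1", "n2", "n3", "n4", "n5",
                 "p1", "p2", "p3", "p4", "p5", "n", "modal"],
    )
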