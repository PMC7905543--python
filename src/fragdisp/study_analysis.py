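"""Inter-rater study pipeline.

Per-fragment deviations from the gold-standard plan are averaged per rater
and case, then aggregated to one mean and one standard deviation per rater
(performance and consistency).  Profession groups are compared by one-way
fixed-effects ANOVA with Bonferroni-corrected pairwise post hoc t tests,
run separately on the rater means and on the rater standard deviations, and
separately for the shift (TFS) and angle (TFA) outcomes.  The influence of
experience is assessed by univariate ordinary least squares of the rater
means on years of 3D planning experience (all raters) and on years of
clinical experience (raters possessing one; biomedical engineers have
none).  The gold-standard rater is excluded from every analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .displacement import DisplacementResult, displacement_between
from .errors import (
    DegenerateVarianceError,
    TableValidationError,
    UndefinedStatisticError,
)
from .geometry import compute_obb
from .mesh_io import PlanTable, RaterProfile, RigidTransform, TriangleMesh

logger = logging.getLogger("fragdisp")

__all__ = [
    "CaseSummary",
    "RaterSummary",
    "AnovaResult",
    "PosthocResult",
    "RegressionResult",
    "StudyResult",
    "aggregate_case",
    "aggregate_rater",
    "oneway_anova",
    "bonferroni_posthoc",
    "regress_experience",
    "run_study",
]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseSummary:
    """Per-fragment deviations of one rater on one case, averaged."""

    rater_id: str
    case_id: str
    mean_tfs: float
    mean_tfa: float
    n_fragments: int


@dataclass(frozen=True)
class RaterSummary:
    """One rater's performance (mean over case means) and consistency
    (sample standard deviation thereof), for TFS and TFA."""

    rater_id: str
    profession: str
    mean_tfs: float
    sd_tfs: float
    mean_tfa: float
    sd_tfa: float
    n_cases: int


def aggregate_case(
    rater_id: str, case_id: str, deviations: Sequence[DisplacementResult]
) -> CaseSummary:
    """Arithmetic mean of the per-fragment TFS and TFA of one rater+case."""
    if not deviations:
        raise UndefinedStatisticError(
            f"rater {rater_id!r}, case {case_id!r}: no fragment deviations"
        )
    return CaseSummary(
        rater_id=rater_id,
        case_id=case_id,
        mean_tfs=float(np.mean([d.tfs for d in deviations])),
        mean_tfa=float(np.mean([d.tfa for d in deviations])),
        n_fragments=len(deviations),
    )


def aggregate_rater(
    case_summaries: Sequence[CaseSummary], profession: str
) -> RaterSummary:
    """Mean and sample standard deviation (n-1 denominator) over the
    case-level means of one rater."""
    if len(case_summaries) < 2:
        raise UndefinedStatisticError(
            "at least 2 cases are required for a per-rater standard deviation"
            f" (got {len(case_summaries)})"
        )
    rater_ids = {c.rater_id for c in case_summaries}
    if len(rater_ids) != 1:
        raise UndefinedStatisticError(
            f"case summaries mix raters: {sorted(rater_ids)}"
        )
    tfs = np.array([c.mean_tfs for c in case_summaries])
    tfa = np.array([c.mean_tfa for c in case_summaries])
    return RaterSummary(
        rater_id=case_summaries[0].rater_id,
        profession=profession,
        mean_tfs=float(tfs.mean()),
        sd_tfs=float(tfs.std(ddof=1)),
        mean_tfa=float(tfa.mean()),
        sd_tfa=float(tfa.std(ddof=1)),
        n_cases=len(case_summaries),
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class PosthocResult:
    group_a: str
    group_b: str
    t: float
    df: int
    p_raw: float
    p_adjusted: float


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from sums of squares; handles
    unbalanced groups; p from the F distribution."""
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    if len(values) < 2 or any(len(v) == 0 for v in values):
        raise UndefinedStatisticError(
            "need >= 2 non-empty groups for a one-way ANOVA"
        )
    n_total = sum(len(v) for v in values)
    df_between = len(values) - 1
    df_within = n_total - len(values)
    if df_within < 1:
        raise UndefinedStatisticError(
            "at least one group must contribute >= 2 values"
        )
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    if ss_within <= 0:
        raise DegenerateVarianceError(
            "zero within-group variance in every group; F is undefined"
        )
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), df_between, df_within, p)


def bonferroni_posthoc(
    groups: Mapping[str, Sequence[float]]
) -> list[PosthocResult]:
    """All pairwise pooled-variance two-sample t tests with Bonferroni
    adjustment ``p_adj = min(1, k * p_raw)``, k = number of pairs."""
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    k = len(pairs)
    out: list[PosthocResult] = []
    for a, b in pairs:
        va = np.asarray(groups[a], dtype=float)
        vb = np.asarray(groups[b], dtype=float)
        df = len(va) + len(vb) - 2
        if df < 1:
            raise UndefinedStatisticError(
                f"groups {a!r} and {b!r} leave no degrees of freedom for a "
                "pooled t test"
            )
        t, p_raw = stats.ttest_ind(va, vb, equal_var=True)
        out.append(
            PosthocResult(
                group_a=a,
                group_b=b,
                t=float(t),
                df=df,
                p_raw=float(p_raw),
                p_adjusted=float(min(1.0, k * p_raw)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Experience regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    """Univariate OLS ``y = intercept + slope * x``.

    A negative slope means improvement with experience; the "improvement
    per year" magnitude is ``abs(slope)``.  ``F = t**2`` with
    ``df = (1, n - 2)``.
    """

    slope: float
    intercept: float
    r_squared: float
    F: float
    df: tuple[int, int]
    p: float
    n: int


def regress_experience(
    x: Sequence[float | None], y: Sequence[float]
) -> RegressionResult:
    """OLS of an outcome on years of experience.  Raters lacking the
    experience variable (``None``/NaN) are dropped, shrinking the degrees of
    freedom accordingly."""
    pairs = [
        (float(xi), float(yi))
        for xi, yi in zip(x, y, strict=True)
        if xi is not None and np.isfinite(xi)
    ]
    if len(pairs) < 3:
        raise UndefinedStatisticError(
            f"need >= 3 raters with both values, got {len(pairs)}"
        )
    xv = np.array([p[0] for p in pairs])
    yv = np.array([p[1] for p in pairs])
    if np.ptp(xv) == 0:
        raise UndefinedStatisticError(
            "zero variance in the experience variable; slope undefined"
        )
    if np.ptp(yv) == 0:
        # constant outcome: flat line, nothing explained
        return RegressionResult(
            slope=0.0,
            intercept=float(yv[0]),
            r_squared=0.0,
            F=0.0,
            df=(1, len(pairs) - 2),
            p=1.0,
            n=len(pairs),
        )
    fit = sm.OLS(yv, sm.add_constant(xv)).fit()
    t = float(fit.tvalues[1])
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        F=t * t,
        df=(1, len(pairs) - 2),
        p=float(fit.pvalues[1]),
        n=len(pairs),
    )


# ---------------------------------------------------------------------------
# End-to-end study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyResult:
    """Everything the inter-rater comparison produces."""

    rater_summaries: tuple[RaterSummary, ...]
    case_summaries: tuple[CaseSummary, ...]
    anova: dict[str, AnovaResult | None]
    posthoc: dict[str, list[PosthocResult]]
    regressions: dict[str, RegressionResult | None]
    alpha: float = 0.05
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        import dataclasses

        def conv(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return dataclasses.asdict(v)
            return v

        return {
            "alpha": self.alpha,
            "rater_summaries": [conv(s) for s in self.rater_summaries],
            "case_summaries": [conv(s) for s in self.case_summaries],
            "anova": {k: conv(v) for k, v in self.anova.items()},
            "posthoc": {k: [conv(x) for x in v] for k, v in self.posthoc.items()},
            "regressions": {k: conv(v) for k, v in self.regressions.items()},
            "notes": list(self.notes),
        }


#: outcome keys used in StudyResult.anova / .posthoc
ANOVA_OUTCOMES = ("tfs_mean", "tfs_sd", "tfa_mean", "tfa_sd")

#: (outcome, experience) keys used in StudyResult.regressions
REGRESSION_KEYS = ("tfs_planning", "tfs_clinical", "tfa_planning", "tfa_clinical")


def run_study(
    plans: PlanTable,
    raters: Sequence[RaterProfile],
    meshes: Mapping[tuple[str, str], TriangleMesh],
    poses: Mapping[str, RigidTransform],
    alpha: float = 0.05,
) -> StudyResult:
    """Run the full inter-rater pipeline.

    Parameters
    ----------
    plans
        The (rater, case, fragment) -> pose assignment with a designated
        gold-standard rater.
    raters
        Profiles for every rater appearing in ``plans``.
    meshes
        Fragment surfaces keyed by ``(case_id, fragment_id)``.
    poses
        Rigid transforms keyed by the plan table's ``pose_ref``.
    """
    profile_by_id = {p.rater_id: p for p in raters}
    for rid in plans.rater_ids:
        if rid not in profile_by_id:
            raise TableValidationError(f"rater {rid!r} in plans has no profile")
    gold = plans.gold_rater_id
    if gold not in profile_by_id:
        raise TableValidationError(f"gold rater {gold!r} has no profile")

    gold_pose: dict[tuple[str, str], RigidTransform] = {}
    for row in plans.rows_for(gold):
        gold_pose[(row.case_id, row.fragment_id)] = poses[row.pose_ref]

    # fragment centers in the gold pose, computed once per fragment
    center_cache: dict[tuple[str, str], np.ndarray] = {}

    def _deviation(row) -> DisplacementResult:
        key = (row.case_id, row.fragment_id)
        if key not in meshes:
            raise TableValidationError(
                f"no mesh for fragment {key} (rater {row.rater_id!r})"
            )
        mesh = meshes[key]
        pg = gold_pose[key]
        pr = poses[row.pose_ref]
        Vg = pg.apply(mesh.vertices)
        Vr = pr.apply(mesh.vertices)
        if key not in center_cache:
            center_cache[key] = compute_obb(Vg).center
        result, _ = displacement_between(
            Vg,
            Vr,
            center_cache[key],
            fragment_id=row.fragment_id,
            diameter=mesh.diameter,
        )
        return result

    # per rater+case aggregation (gold excluded: its deviation is zero by
    # construction and the study reports the other raters' performance)
    by_rater_case: dict[tuple[str, str], list[DisplacementResult]] = {}
    for row in plans.rows:
        if row.rater_id == gold:
            continue
        try:
            dev = _deviation(row)
        except Exception as exc:
            raise type(exc)(
                f"rater {row.rater_id!r}, case {row.case_id!r}, fragment "
                f"{row.fragment_id!r}: {exc}"
            ) from exc
        by_rater_case.setdefault((row.rater_id, row.case_id), []).append(dev)

    case_summaries = tuple(
        aggregate_case(rid, cid, devs)
        for (rid, cid), devs in sorted(by_rater_case.items())
    )
    rater_ids = sorted({c.rater_id for c in case_summaries})
    rater_summaries = tuple(
        aggregate_rater(
            [c for c in case_summaries if c.rater_id == rid],
            profile_by_id[rid].profession,
        )
        for rid in rater_ids
    )

    # group structure: profession -> rater-level values
    notes: list[str] = []

    def groups_of(attr: str) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for s in rater_summaries:
            out.setdefault(s.profession, []).append(getattr(s, attr))
        return out

    anova: dict[str, AnovaResult | None] = {}
    posthoc: dict[str, list[PosthocResult]] = {}
    for outcome, attr in zip(
        ANOVA_OUTCOMES, ("mean_tfs", "sd_tfs", "mean_tfa", "sd_tfa")
    ):
        grp = groups_of(attr)
        try:
            anova[outcome] = oneway_anova(grp)
            posthoc[outcome] = bonferroni_posthoc(grp)
        except (DegenerateVarianceError, UndefinedStatisticError) as exc:
            anova[outcome] = None
            posthoc[outcome] = []
            notes.append(f"{outcome}: no variability — {exc}")

    regressions: dict[str, RegressionResult | None] = {}
    planning = [profile_by_id[s.rater_id].planning_years for s in rater_summaries]
    clinical = [profile_by_id[s.rater_id].clinical_years for s in rater_summaries]
    for key, xs, attr in (
        ("tfs_planning", planning, "mean_tfs"),
        ("tfs_clinical", clinical, "mean_tfs"),
        ("tfa_planning", planning, "mean_tfa"),
        ("tfa_clinical", clinical, "mean_tfa"),
    ):
        ys = [getattr(s, attr) for s in rater_summaries]
        try:
            regressions[key] = regress_experience(xs, ys)
        except UndefinedStatisticError as exc:
            regressions[key] = None
            notes.append(f"regression {key}: {exc}")

    return StudyResult(
        rater_summaries=rater_summaries,
        case_summaries=case_summaries,
        anova=anova,
        posthoc=posthoc,
        regressions=regressions,
        alpha=alpha,
        notes=tuple(notes),
    )
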