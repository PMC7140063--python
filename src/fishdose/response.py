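"""Xenograft response analysis: growth trends, Dunnett contrasts, RECIST-style calls.

Each xenografted embryo contributes a stained-area time series (2 hpi,
1 dpi, 2 dpi).  Areas are normalised to the 2 hpi baseline (*relative
area*), which removes the variability of graft size among embryos.  The
analysis then

* tests growth within a group over time (one-way repeated-measures ANOVA,
  embryo as the repeated unit),
* compares each treated group's endpoint ratio against the control group
  (one-way ANOVA followed by Dunnett's many-to-one test), and
* classifies the response of each patient x regimen: with D the percent
  decrease of the treated group's mean endpoint ratio relative to the
  control group's, the call is CR (complete response) if D >= 90, PR
  (partial response) if D >= 30, NR otherwise.  Thresholds are inclusive
  and CR counts as PR in cohort tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, InputError

__all__ = [
    "TIME_POINTS",
    "EmbryoTrack",
    "relative_area",
    "tracks_from_frame",
    "GroupStats",
    "group_trend",
    "repeated_measures_anova",
    "DunnettResult",
    "dunnett_compare",
    "endpoint_ratios",
    "ResponseCall",
    "classify_response",
    "classify_cohort",
    "CohortTable",
    "cohort_table",
    "pyknotic_fraction",
    "compare_pyknotic",
]

TIME_POINTS = ("2hpi", "1dpi", "2dpi")


@dataclass(frozen=True)
class EmbryoTrack:
    """One embryo's stained-area time series.

    ``areas`` maps time point -> area (arbitrary units); the baseline is
    mandatory, later points may be missing (embryo dropout).
    """

    patient_id: str
    group: str
    areas: Mapping[str, float]
    embryo_id: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.areas) - set(TIME_POINTS)
        if unknown:
            raise InputError(f"unknown time points {sorted(unknown)}")


def relative_area(track: EmbryoTrack, baseline: str = "2hpi") -> dict[str, float]:
    """Areas divided by the baseline area; the baseline maps to exactly 1."""
    if baseline not in track.areas or track.areas[baseline] is None:
        raise InputError(f"baseline time point {baseline!r} missing for embryo "
                         f"{track.embryo_id!r}")
    base = track.areas[baseline]
    if not base > 0:
        raise InputError(f"baseline area must be > 0, got {base!r}")
    return {
        tp: track.areas[tp] / base
        for tp in TIME_POINTS
        if tp in track.areas and track.areas[tp] is not None
    }


def tracks_from_frame(df: pd.DataFrame) -> list[EmbryoTrack]:
    """Parse the areas-table dialect into tracks.

    Expected columns: patient_id, group, embryo_id and area_2hpi,
    area_1dpi, area_2dpi (blank = missing observation).
    """
    required = {"patient_id", "group", "area_2hpi"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"areas table missing columns {sorted(missing)}")
    tracks = []
    for i, row in df.iterrows():
        areas = {}
        for tp in TIME_POINTS:
            col = f"area_{tp}"
            if col in df.columns and pd.notna(row[col]):
                areas[tp] = float(row[col])
        if "2hpi" not in areas:
            raise InputError(f"row {i}: missing baseline area_2hpi")
        tracks.append(
            EmbryoTrack(
                patient_id=str(row["patient_id"]),
                group=str(row["group"]),
                areas=areas,
                embryo_id=str(row.get("embryo_id", i)),
            )
        )
    return tracks


def repeated_measures_anova(matrix: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA across columns (classical decomposition).

    ``matrix`` is subjects x time points, complete cases only.  Returns
    ``(F, p)``.  Degenerate conventions: zero between-time variance gives
    ``p = 1`` (no time effect); zero residual variance with a nonzero time
    effect gives ``p = 0``.  No sphericity correction is applied.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise InputError("need >= 2 subjects and >= 2 time points")
    n, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    ss_time = n * float(((time_means - grand) ** 2).sum())
    ss_within_subj = float(((y - subj_means[:, None]) ** 2).sum())
    ss_error = ss_within_subj - ss_time
    df_time, df_error = k - 1, (n - 1) * (k - 1)
    scale = float((y**2).sum()) + 1.0
    if ss_time <= 1e-12 * scale:
        return 0.0, 1.0
    if ss_error <= 1e-12 * scale:
        return float("inf"), 0.0
    f = (ss_time / df_time) / (ss_error / df_error)
    return f, float(stats.f.sf(f, df_time, df_error))


@dataclass(frozen=True)
class GroupStats:
    """Per-time-point summary of one group's relative-area trajectories."""

    group: str
    n: int
    mean: dict[str, float]
    sem: dict[str, float]
    f_statistic: float | None
    p_value: float | None
    n_complete: int
    reason: str = ""

    @property
    def significant_growth(self) -> bool | None:
        if self.p_value is None:
            return None
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "mean": dict(self.mean),
            "sem": dict(self.sem),
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "n_complete": self.n_complete,
            "reason": self.reason,
        }


def group_trend(tracks: Sequence[EmbryoTrack], baseline: str = "2hpi") -> GroupStats:
    """Mean/SEM relative area per time point and the within-group time trend.

    Means and SEMs use every embryo observed at a time point; the
    repeated-measures ANOVA uses complete cases (all time points present).
    """
    if not tracks:
        raise InputError("no tracks supplied")
    groups = {t.group for t in tracks}
    if len(groups) > 1:
        raise InputError(f"tracks from multiple groups: {sorted(groups)}")
    rel = [relative_area(t, baseline) for t in tracks]
    mean, sem = {}, {}
    for tp in TIME_POINTS:
        vals = np.array([r[tp] for r in rel if tp in r])
        if vals.size:
            mean[tp] = float(vals.mean())
            sem[tp] = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    complete = [r for r in rel if all(tp in r for tp in TIME_POINTS)]
    f = p = None
    reason = ""
    if len(complete) >= 2:
        y = np.array([[r[tp] for tp in TIME_POINTS] for r in complete])
        f, p = repeated_measures_anova(y)
    else:
        reason = "fewer than 2 embryos with all time points"
    return GroupStats(
        group=tracks[0].group,
        n=len(tracks),
        mean=mean,
        sem=sem,
        f_statistic=f,
        p_value=p,
        n_complete=len(complete),
        reason=reason,
    )


def endpoint_ratios(
    tracks: Sequence[EmbryoTrack], baseline: str = "2hpi", endpoint: str = "2dpi"
) -> np.ndarray:
    """Per-embryo endpoint/baseline area ratios, complete cases at the endpoint."""
    out = []
    for t in tracks:
        if baseline in t.areas and endpoint in t.areas:
            out.append(t.areas[endpoint] / t.areas[baseline])
    return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one contrasts against control."""

    anova_f: float
    anova_p: float
    adjusted_p: dict[str, float]
    statistics: dict[str, float]
    excluded: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "anova_f": self.anova_f,
            "anova_p": self.anova_p,
            "adjusted_p": dict(self.adjusted_p),
            "statistics": dict(self.statistics),
            "excluded": list(self.excluded),
        }


def dunnett_compare(
    control: Sequence[float], treated: Mapping[str, Sequence[float]], seed: int = 0
) -> DunnettResult:
    """Compare each treated group's values against control.

    One-way ANOVA over all groups, then Dunnett's test (multivariate-t
    critical values as implemented in scipy) for the many-to-one contrasts.
    Groups with fewer than 2 observations are excluded with a warning.
    """
    control = np.asarray(control, dtype=float)
    if control.size < 2:
        raise InputError("control group needs >= 2 observations")
    if not treated:
        raise InputError("no treated groups supplied")
    kept, excluded = {}, []
    for name, vals in treated.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            excluded.append(name)
            warnings.warn(f"group {name!r} excluded from Dunnett test (n < 2)")
        else:
            kept[name] = vals
    if not kept:
        raise InputError("no treated group with n >= 2")
    names = list(kept)
    f, p = stats.f_oneway(control, *kept.values())
    rng = np.random.default_rng(seed)
    res = stats.dunnett(*kept.values(), control=control, random_state=rng)
    return DunnettResult(
        anova_f=float(f),
        anova_p=float(p),
        adjusted_p={n: float(pv) for n, pv in zip(names, res.pvalue)},
        statistics={n: float(s) for n, s in zip(names, res.statistic)},
        excluded=tuple(excluded),
    )


@dataclass(frozen=True)
class ResponseCall:
    """Classification of one patient x regimen response."""

    patient_id: str
    regimen: str
    percent_decrease: float
    call: str  # 'CR', 'PR' or 'NR'
    treated_mean: float
    control_mean: float

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "regimen": self.regimen,
            "percent_decrease": self.percent_decrease,
            "call": self.call,
            "treated_mean": self.treated_mean,
            "control_mean": self.control_mean,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ResponseCall":
        return cls(
            patient_id=d["patient_id"],
            regimen=d["regimen"],
            percent_decrease=d["percent_decrease"],
            call=d["call"],
            treated_mean=d["treated_mean"],
            control_mean=d["control_mean"],
        )


def classify_response(
    treated_mean: float,
    control_mean: float,
    patient_id: str = "",
    regimen: str = "",
    pr_threshold: float = 30.0,
    cr_threshold: float = 90.0,
) -> ResponseCall:
    """RECIST-style call from group-mean endpoint ratios.

    percent_decrease = 100 * (1 - treated/control); thresholds are
    inclusive ("at least" a 30% / 90% decrease).
    """
    if not control_mean > 0:
        raise DomainError(f"control mean must be > 0, got {control_mean!r}")
    if not 0 < pr_threshold < cr_threshold <= 100:
        raise InputError("thresholds must satisfy 0 < PR < CR <= 100")
    decrease = 100.0 * (1.0 - treated_mean / control_mean)
    if decrease >= cr_threshold:
        call = "CR"
    elif decrease >= pr_threshold:
        call = "PR"
    else:
        call = "NR"
    return ResponseCall(
        patient_id=patient_id,
        regimen=regimen,
        percent_decrease=decrease,
        call=call,
        treated_mean=treated_mean,
        control_mean=control_mean,
    )


def classify_cohort(
    tracks: Sequence[EmbryoTrack],
    baseline: str = "2hpi",
    endpoint: str = "2dpi",
    control_group: str = "control",
    pr_threshold: float = 30.0,
    cr_threshold: float = 90.0,
) -> list[ResponseCall]:
    """One response call per patient x regimen from raw tracks.

    For every patient the control group's mean endpoint ratio is the
    reference; each treated group's mean endpoint ratio is classified
    against it.  Embryos missing the endpoint observation are dropped
    (complete-case analysis).
    """
    calls = []
    patients = sorted({t.patient_id for t in tracks})
    for pid in patients:
        mine = [t for t in tracks if t.patient_id == pid]
        ctrl = endpoint_ratios(
            [t for t in mine if t.group == control_group], baseline, endpoint
        )
        if ctrl.size == 0:
            raise InputError(f"patient {pid!r}: no control embryos with endpoint data")
        control_mean = float(ctrl.mean())
        for group in sorted({t.group for t in mine} - {control_group}):
            ratios = endpoint_ratios(
                [t for t in mine if t.group == group], baseline, endpoint
            )
            if ratios.size == 0:
                warnings.warn(
                    f"patient {pid!r}, group {group!r}: no embryos with endpoint data"
                )
                continue
            calls.append(
                classify_response(
                    float(ratios.mean()),
                    control_mean,
                    patient_id=pid,
                    regimen=group,
                    pr_threshold=pr_threshold,
                    cr_threshold=cr_threshold,
                )
            )
    return calls


@dataclass(frozen=True)
class CohortTable:
    """Cohort response rates per regimen; CR is nested inside PR."""

    cancer_type: str
    rows: tuple[dict, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))

    def to_dict(self) -> dict:
        return {"cancer_type": self.cancer_type, "rows": [dict(r) for r in self.rows]}


def cohort_table(calls: Iterable[ResponseCall], cancer_type: str = "") -> CohortTable:
    """Tabulate %PR and %CR per regimen across patients.

    %PR counts both PR and CR calls (a complete response is also at least
    a partial one); percentages are carried at 2 decimals.
    """
    calls = list(calls)
    seen = set()
    for c in calls:
        key = (c.patient_id, c.regimen)
        if key in seen:
            raise InputError(f"duplicate call for patient {c.patient_id!r}, "
                             f"regimen {c.regimen!r}")
        seen.add(key)
    rows = []
    regimens = sorted({c.regimen for c in calls})
    for reg in regimens:
        sub = [c for c in calls if c.regimen == reg]
        n = len(sub)
        n_cr = sum(c.call == "CR" for c in sub)
        n_pr = sum(c.call in ("PR", "CR") for c in sub)
        rows.append(
            {
                "regimen": reg,
                "n_patients": n,
                "pct_pr": round(100.0 * n_pr / n, 2),
                "pct_cr": round(100.0 * n_cr / n, 2),
            }
        )
    return CohortTable(cancer_type=cancer_type, rows=tuple(rows))


def pyknotic_fraction(
    counts: Sequence[tuple[float, float]]
) -> tuple[float, float | None, np.ndarray]:
    """Mean percent of pyknotic nuclei across samples.

    ``counts`` holds (pyknotic, total) pairs.  Returns (mean %, SEM %,
    per-sample percentages); SEM is ``None`` for a single sample.
    """
    if not counts:
        raise InputError("no samples supplied")
    per = []
    for pyk, total in counts:
        if not total > 0:
            raise InputError("total nucleus count must be > 0")
        per.append(100.0 * pyk / total)
    per = np.asarray(per)
    mean = float(per.mean())
    sem = float(per.std(ddof=1) / np.sqrt(per.size)) if per.size > 1 else None
    return mean, sem, per


def compare_pyknotic(
    treated: Sequence[tuple[float, float]], control: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Unpaired two-sample t-test on per-sample pyknotic percentages."""
    _, _, a = pyknotic_fraction(treated)
    _, _, b = pyknotic_fraction(control)
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)
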