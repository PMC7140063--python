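"""Seeded generators for synthetic safety assays and xenograft cohorts.

The analysis was designed around two experiment shapes whose raw per-embryo
data are not public, so the generators reproduce their statistical
structure and return the ground truth alongside the data:

* **Safety assay** — for each concentration on a grid, each of several
  replicates of ~30 embryos is drawn from the trinomial (normal, aberrant,
  dead) implied by two straight incidence lines: normal% decreasing and
  dead% increasing with (log-)concentration.  The true IC50/LD25 follow
  analytically from the lines.
* **Xenograft cohort** — each embryo's stained area grows multiplicatively,
  ``area(t) = baseline * g^((1-e) t) * noise``, with daily growth factor
  ``g``, a treatment effect ``e`` in [0, 1] that attenuates growth (e = 0
  untreated, e = 1 full growth arrest), lognormal measurement noise and
  random embryo dropout.  The noise-free construction yields each
  patient x regimen's true percent decrease versus control, hence its true
  PR/CR/NR label.

Identical seeds give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .response import EmbryoTrack, TIME_POINTS
from .safety import PhenotypeTable

__all__ = [
    "SafetySimConfig",
    "SafetyTruth",
    "gen_safety",
    "CohortSimConfig",
    "gen_cohort",
    "cohort_tracks",
]


@dataclass(frozen=True)
class SafetySimConfig:
    """True incidence lines and sampling plan of a synthetic safety assay.

    Lines are in percent versus concentration (``scale='linear'``) or
    log10-concentration (``scale='log10'``).  Defaults put the true IC50 at
    0.10 mg/mL and the true LD25 at 0.20 mg/mL on a 5-point grid spanning
    them, with 3 replicates of 30 embryos (n = 90 per concentration).
    """

    regimen: str = "SYNTH"
    scale: str = "linear"
    normal_intercept: float = 100.0
    normal_slope: float = -500.0
    dead_intercept: float = 0.0
    dead_slope: float = 125.0
    concentrations: tuple[float, ...] = (0.02, 0.05, 0.10, 0.15, 0.20)
    embryos_per_replicate: int = 30
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.concentrations) < 3:
            raise InputError("concentration grid needs >= 3 points")
        if self.scale not in ("linear", "log10"):
            raise InputError("scale must be 'linear' or 'log10'")

    def _x(self, conc: np.ndarray) -> np.ndarray:
        return np.log10(conc) if self.scale == "log10" else conc

    def normal_percent(self, conc) -> np.ndarray:
        return self.normal_intercept + self.normal_slope * self._x(np.asarray(conc, float))

    def dead_percent(self, conc) -> np.ndarray:
        return self.dead_intercept + self.dead_slope * self._x(np.asarray(conc, float))

    def invert(self, endpoint: str, threshold: float) -> float:
        """Concentration at which the true line crosses ``threshold`` percent."""
        if endpoint == "normal":
            slope, intercept = self.normal_slope, self.normal_intercept
        else:
            slope, intercept = self.dead_slope, self.dead_intercept
        if slope == 0:
            return float("nan")  # flat line never crosses the threshold
        x = (threshold - intercept) / slope
        return float(10.0**x if self.scale == "log10" else x)


@dataclass(frozen=True)
class SafetyTruth:
    ic50: float
    ld25: float


def gen_safety(config: SafetySimConfig) -> tuple[PhenotypeTable, SafetyTruth]:
    """Draw a synthetic phenotype table and return it with its ground truth.

    Per concentration and replicate, embryo fates are a single trinomial
    draw with p(dead) from the mortality line, p(normal) from the
    normal-phenotype line and p(aberrant) the clipped remainder.
    Probabilities falling outside [0, 1] are clipped (with a warning when
    normal + dead exceeds 1 and must be rescaled).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for conc in config.concentrations:
        p_n = float(np.clip(config.normal_percent(conc) / 100.0, 0.0, 1.0))
        p_d = float(np.clip(config.dead_percent(conc) / 100.0, 0.0, 1.0))
        if p_n + p_d > 1.0:
            warnings.warn(
                f"c={conc:g}: normal+dead probability {p_n + p_d:.3f} > 1, rescaling"
            )
            total = p_n + p_d
            p_n, p_d = p_n / total, p_d / total
        p_a = max(0.0, 1.0 - p_n - p_d)
        probs = np.array([p_n, p_a, p_d])
        probs = probs / probs.sum()
        for rep in range(config.replicates):
            n_norm, n_ab, n_dead = rng.multinomial(config.embryos_per_replicate, probs)
            rows.append(
                {
                    "concentration_mg_ml": conc,
                    "replicate": rep + 1,
                    "n_normal": int(n_norm),
                    "n_aberrant": int(n_ab),
                    "n_dead": int(n_dead),
                }
            )
    table = PhenotypeTable(regimen=config.regimen, data=pd.DataFrame(rows))
    truth = SafetyTruth(ic50=config.invert("normal", 50.0), ld25=config.invert("dead", 25.0))
    return table, truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Sampling plan of a synthetic patient-derived-xenograft cohort.

    Each of ``patients`` patients contributes one control group and one
    group per regimen, ``embryos_per_group`` embryos each.  Baseline areas
    are lognormal (median ``baseline_median`` arbitrary units, coefficient
    of variation ``baseline_cv``); areas then grow by factor
    ``growth_per_day`` per day, attenuated by the treatment effect.

    Effects can be supplied explicitly via ``effects`` (mapping
    ``(patient_id, regimen) -> e``); otherwise each patient x regimen is a
    responder with probability ``responder_prob`` and its effect is drawn
    uniformly from ``responder_effect_range`` (else from
    ``nonresponder_effect_range``) — drug regimens tend to either work or
    not, so the effect distribution is bimodal.
    """

    cancer_type: str = "colon"
    patients: int = 8
    regimens: tuple[str, ...] = ("5-FU", "FOLFOX", "FOLFIRI", "FOLFOXIRI")
    embryos_per_group: int = 8
    baseline_median: float = 1.0e4
    baseline_cv: float = 0.30
    growth_per_day: float = 2.0
    effects: Mapping[tuple[str, str], float] | None = None
    responder_prob: float = 0.5
    nonresponder_effect_range: tuple[float, float] = (0.0, 0.15)
    responder_effect_range: tuple[float, float] = (0.35, 0.90)
    noise_cv: float = 0.15
    dropout_per_day: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.growth_per_day > 0:
            raise InputError("growth_per_day must be > 0")
        if self.noise_cv < 0 or self.baseline_cv < 0:
            raise InputError("coefficients of variation must be >= 0")
        if not 0 <= self.dropout_per_day < 1:
            raise InputError("dropout_per_day must be in [0, 1)")
        if self.effects is not None:
            bad = [e for e in self.effects.values() if not 0 <= e <= 1]
            if bad:
                raise InputError(f"treatment effects must lie in [0, 1], got {bad}")

    def patient_ids(self) -> list[str]:
        prefix = self.cancer_type[:1].upper() or "X"
        return [f"{prefix}{i + 1:03d}" for i in range(self.patients)]

    def true_decrease_pct(self, effect: float) -> float:
        """Noise-free percent decrease vs control at the 2 dpi endpoint."""
        g = self.growth_per_day
        return 100.0 * (1.0 - g ** (-2.0 * effect))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def gen_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort areas table and the ground-truth responder labels.

    Returns ``(areas, truth)``: ``areas`` in the standard dialect
    (patient_id, cancer_type, group, embryo_id, area_2hpi, area_1dpi,
    area_2dpi with NaN = dropout) and ``truth`` with one row per
    patient x regimen (effect, true_decrease_pct, label).
    """
    rng = np.random.default_rng(config.seed)
    sigma_b = np.sqrt(np.log1p(config.baseline_cv**2))
    g = config.growth_per_day

    area_rows, truth_rows = [], []
    for pid in config.patient_ids():
        # effect per group; control is always e = 0
        group_effects: dict[str, float] = {"control": 0.0}
        for reg in config.regimens:
            if config.effects is not None:
                try:
                    e = float(config.effects[(pid, reg)])
                except KeyError as exc:
                    raise InputError(f"no effect supplied for {(pid, reg)}") from exc
            else:
                lo, hi = (
                    config.responder_effect_range
                    if rng.random() < config.responder_prob
                    else config.nonresponder_effect_range
                )
                e = float(rng.uniform(lo, hi))
            group_effects[reg] = e
            decrease = config.true_decrease_pct(e)
            label = "CR" if decrease >= 90 else "PR" if decrease >= 30 else "NR"
            truth_rows.append(
                {
                    "patient_id": pid,
                    "regimen": reg,
                    "effect": e,
                    "true_decrease_pct": decrease,
                    "label": label,
                }
            )
        for group, e in group_effects.items():
            n = config.embryos_per_group
            baselines = (
                config.baseline_median
                * np.exp(rng.normal(0.0, sigma_b, size=n))
            )
            noise = _lognormal_factor(rng, config.noise_cv, (n, 3))
            days = np.array([0.0, 1.0, 2.0])
            growth = g ** ((1.0 - e) * days)  # noise-free relative trajectory
            for i in range(n):
                areas = baselines[i] * growth * noise[i]
                row = {
                    "patient_id": pid,
                    "cancer_type": config.cancer_type,
                    "group": group,
                    "embryo_id": f"{pid}-{group}-{i + 1}",
                    "area_2hpi": areas[0],
                    "area_1dpi": np.nan,
                    "area_2dpi": np.nan,
                }
                survive_d1 = rng.random() >= config.dropout_per_day
                if survive_d1:
                    row["area_1dpi"] = areas[1]
                    if rng.random() >= config.dropout_per_day:
                        row["area_2dpi"] = areas[2]
                area_rows.append(row)
    areas = pd.DataFrame(area_rows)
    truth = pd.DataFrame(truth_rows)
    return areas, truth


def cohort_tracks(areas: pd.DataFrame) -> list[EmbryoTrack]:
    """Convenience: parse a generated areas table into tracks."""
    from .response import tracks_from_frame

    return tracks_from_frame(areas)
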