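"""Embryo safety study: dose-response fits, MTD and equivalent-dose selection.

The safety assay exposes groups of zebrafish embryos to increasing
fish-water concentrations of a regimen (labelled by its index drug) and
scores each embryo as *normal*, *aberrant* or *dead*.  Incidences (% of
exposed embryos) are regressed on concentration with an ordinary
least-squares straight line, on both a linear and a log10 concentration
scale; the scale with the higher R^2 is kept.  Inverting the fitted line at
a threshold incidence yields

* IC50 — the concentration at which the normal-phenotype incidence drops
  to 50%, and
* LD25 — the concentration lethal to 25% of the embryos.

Dividing the regimen's equivalent plasma concentration (EPC) by these gives
the dimensionless exposure ratios EPC/IC50 and EPC/LD25.  The maximum
tolerated dose (MTD) is the larger of the 75th percentiles of the two ratio
distributions across regimens, and the equivalent dose (ED) is the largest
dilution factor above the MTD that still shows efficacy.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ComputationUndefinedError, DomainError, InputError

__all__ = [
    "PHENOTYPES",
    "PhenotypeTable",
    "tally_phenotypes",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_dose_response",
    "SafetySummary",
    "safety_ratios",
    "percentile_75",
    "MTDResult",
    "compute_mtd",
    "EDDecision",
    "select_ed",
    "load_reference_table",
    "reference_summaries",
]

PHENOTYPES = ("normal", "aberrant", "dead")


@dataclass(frozen=True)
class PhenotypeTable:
    """Embryo phenotype counts per tested concentration of the index drug.

    ``data`` columns: concentration_mg_ml, n_normal, n_aberrant, n_dead
    (optionally replicate).  Counts are non-negative and per-row totals are
    the number of exposed embryos.
    """

    regimen: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"concentration_mg_ml", "n_normal", "n_aberrant", "n_dead"}
        missing = required - set(self.data.columns)
        if missing:
            raise InputError(f"phenotype table missing columns {sorted(missing)}")
        counts = self.data[["n_normal", "n_aberrant", "n_dead"]]
        if (counts.to_numpy() < 0).any():
            raise InputError("phenotype counts must be non-negative")

    def pooled(self) -> pd.DataFrame:
        """Counts pooled over replicates, one row per concentration."""
        return (
            self.data.groupby("concentration_mg_ml", as_index=False)[
                ["n_normal", "n_aberrant", "n_dead"]
            ].sum()
        )

    def incidences(self) -> pd.DataFrame:
        """Pooled incidences in percent, one row per concentration."""
        pooled = self.pooled()
        total = pooled[["n_normal", "n_aberrant", "n_dead"]].sum(axis=1)
        if (total == 0).any():
            raise InputError("a concentration row has zero exposed embryos")
        out = pd.DataFrame({"concentration_mg_ml": pooled["concentration_mg_ml"]})
        for ph in PHENOTYPES:
            out[ph] = 100.0 * pooled[f"n_{ph}"] / total
        return out


def tally_phenotypes(records: pd.DataFrame | Iterable[Mapping], regimen: str = "") -> PhenotypeTable:
    """Aggregate per-embryo records into a :class:`PhenotypeTable`.

    Each record needs ``concentration_mg_ml``, ``phenotype`` (one of
    ``normal``/``aberrant``/``dead``) and optionally ``replicate``.
    """
    df = pd.DataFrame(records)
    if df.empty:
        return PhenotypeTable(
            regimen=regimen,
            data=pd.DataFrame(
                columns=["concentration_mg_ml", "replicate", "n_normal", "n_aberrant", "n_dead"]
            ),
        )
    if "phenotype" not in df.columns or "concentration_mg_ml" not in df.columns:
        raise InputError("records need 'concentration_mg_ml' and 'phenotype' columns")
    unknown = set(df["phenotype"]) - set(PHENOTYPES)
    if unknown:
        raise InputError(f"unknown phenotype labels: {sorted(unknown)}")
    keys = ["concentration_mg_ml"]
    if "replicate" in df.columns:
        keys.append("replicate")
    wide = (
        df.groupby(keys)["phenotype"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(PHENOTYPES), fill_value=0)
        .rename(columns={ph: f"n_{ph}" for ph in PHENOTYPES})
        .reset_index()
    )
    wide.columns.name = None
    return PhenotypeTable(regimen=regimen, data=wide)


@dataclass(frozen=True)
class _LineFit:
    scale: str  # 'linear' or 'log10'
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class DoseResponseResults:
    """Fitted incidence line and its inverted threshold concentration.

    ``inverted_dose`` solves incidence(c) = threshold_percent on the selected
    scale; IC50 for the normal endpoint at 50%, LD25 for the dead endpoint
    at 25%.  ``extrapolated`` flags a solution outside the tested range.
    Both candidate fits are kept for audit in ``fits``.
    """

    regimen: str
    endpoint: str
    threshold_percent: float
    scale: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    inverted_dose: float
    extrapolated: bool
    concentration_range: tuple[float, float]
    fits: tuple[_LineFit, ...] = field(repr=False, default=())

    def predict(self, concentration: np.ndarray | float) -> np.ndarray | float:
        """Predicted incidence (%) at the given concentration(s)."""
        c = np.asarray(concentration, dtype=float)
        x = np.log10(c) if self.scale == "log10" else c
        return self.intercept + self.slope * x

    def summary(self) -> str:
        lines = [
            f"Dose-response fit: {self.regimen or '(unnamed)'} / endpoint={self.endpoint}",
            f"  selected scale : {self.scale}",
            f"  incidence(%)   = {self.intercept:.4g} + {self.slope:.4g} * "
            + ("log10(c)" if self.scale == "log10" else "c"),
            f"  R^2            = {self.r_squared:.4f}   p = {self.p_value:.3g}",
            f"  inverted dose  @ {self.threshold_percent:g}%: {self.inverted_dose:.4g} mg/mL"
            + ("  [extrapolated]" if self.extrapolated else ""),
            f"  tested range   : [{self.concentration_range[0]:.4g}, "
            f"{self.concentration_range[1]:.4g}] mg/mL",
        ]
        for f in self.fits:
            lines.append(
                f"  candidate {f.scale:>6}: R^2 = {f.r_squared:.4f}, "
                f"slope = {f.slope:.4g}, intercept = {f.intercept:.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "regimen": self.regimen,
            "endpoint": self.endpoint,
            "threshold_percent": self.threshold_percent,
            "scale": self.scale,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "inverted_dose": self.inverted_dose,
            "extrapolated": self.extrapolated,
            "concentration_range": list(self.concentration_range),
            "candidate_fits": [
                {
                    "scale": f.scale,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r_squared": f.r_squared,
                    "p_value": f.p_value,
                }
                for f in self.fits
            ],
        }


_DEFAULT_THRESHOLDS = {"normal": 50.0, "dead": 25.0}


class DoseResponseModel:
    """Straight-line incidence model for one endpoint of a safety assay.

    Parameters
    ----------
    table
        Phenotype counts per concentration.
    endpoint
        ``'normal'`` (for IC50) or ``'dead'`` (for LD25).
    threshold_percent
        Incidence solved for by inversion; defaults to 50 for the normal
        endpoint and 25 for the dead endpoint.

    ``fit()`` regresses pooled incidence (%) on concentration on both the
    linear and the log10 scale (zero-concentration rows are excluded from
    the log fit) and selects the scale with the higher R^2.
    """

    def __init__(
        self,
        table: PhenotypeTable,
        endpoint: str = "normal",
        threshold_percent: float | None = None,
    ) -> None:
        if endpoint not in ("normal", "dead"):
            raise InputError(f"endpoint must be 'normal' or 'dead', got {endpoint!r}")
        self.table = table
        self.endpoint = endpoint
        self.threshold_percent = (
            _DEFAULT_THRESHOLDS[endpoint] if threshold_percent is None else float(threshold_percent)
        )

    def fit(self) -> DoseResponseResults:
        inc = self.table.incidences()
        conc = inc["concentration_mg_ml"].to_numpy(dtype=float)
        y = inc[self.endpoint].to_numpy(dtype=float)
        if len(np.unique(conc)) < 3:
            raise InputError("need at least 3 distinct concentrations to fit")

        fits: list[_LineFit] = []
        res = stats.linregress(conc, y)
        fits.append(
            _LineFit("linear", res.slope, res.intercept, res.rvalue**2, res.pvalue)
        )
        pos = conc > 0
        if pos.sum() >= 3 and len(np.unique(conc[pos])) >= 3:
            res = stats.linregress(np.log10(conc[pos]), y[pos])
            fits.append(
                _LineFit("log10", res.slope, res.intercept, res.rvalue**2, res.pvalue)
            )
        best = max(fits, key=lambda f: f.r_squared)

        if best.slope == 0 or not np.isfinite(best.slope):
            raise ComputationUndefinedError(
                "zero-slope fit: threshold inversion is undefined"
            )
        x_star = (self.threshold_percent - best.intercept) / best.slope
        dose = 10.0**x_star if best.scale == "log10" else x_star
        lo, hi = float(conc.min()), float(conc.max())
        return DoseResponseResults(
            regimen=self.table.regimen,
            endpoint=self.endpoint,
            threshold_percent=self.threshold_percent,
            scale=best.scale,
            slope=best.slope,
            intercept=best.intercept,
            r_squared=best.r_squared,
            p_value=best.p_value,
            inverted_dose=float(dose),
            extrapolated=not (lo <= dose <= hi),
            concentration_range=(lo, hi),
            fits=tuple(fits),
        )


def fit_dose_response(
    table: PhenotypeTable, endpoint: str = "normal", threshold_percent: float | None = None
) -> DoseResponseResults:
    """Convenience wrapper: ``DoseResponseModel(...).fit()``."""
    return DoseResponseModel(table, endpoint, threshold_percent).fit()


@dataclass(frozen=True)
class SafetySummary:
    """One regimen's dimensionless exposure ratios.

    For a fixed-mass-ratio combination the ratios are identical whichever
    component drug's EPC and IC50/LD25 are used.
    """

    regimen: str
    epc: float
    ic50: float
    ld25: float
    ratio_ic50: float
    ratio_ld25: float

    def to_dict(self) -> dict:
        return {
            "regimen": self.regimen,
            "epc": self.epc,
            "ic50": self.ic50,
            "ld25": self.ld25,
            "ratio_ic50": self.ratio_ic50,
            "ratio_ld25": self.ratio_ld25,
        }


def safety_ratios(epc: float, ic50: float, ld25: float, regimen: str = "") -> SafetySummary:
    """EPC/IC50 and EPC/LD25 for one regimen (all in mg/mL, ratios unit-free)."""
    for name, v in (("EPC", epc), ("IC50", ic50), ("LD25", ld25)):
        if not v > 0:
            raise DomainError(f"{name} must be strictly positive, got {v!r}")
    return SafetySummary(
        regimen=regimen,
        epc=epc,
        ic50=ic50,
        ld25=ld25,
        ratio_ic50=epc / ic50,
        ratio_ld25=epc / ld25,
    )


def percentile_75(values: Sequence[float], p: float = 75.0) -> float:
    """Percentile by the rank = p/100 * (n + 1) rule with linear interpolation.

    This is the convention of common spreadsheet/Prism box plots (numpy's
    ``method='weibull'``); ranks outside [1, n] clamp to the extremes.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InputError("percentile of an empty list is undefined")
    if arr.size < 2:
        raise InputError("need at least 2 values for a percentile")
    return float(np.percentile(arr, p, method="weibull"))


@dataclass(frozen=True)
class MTDResult:
    """75th percentiles of the two ratio columns and their maximum.

    ``mtd`` is computed on values rounded to 1 decimal (the precision at
    which the percentiles are reported); unrounded percentiles are kept.
    """

    p75_ic50: float
    p75_ld25: float
    mtd: float

    def to_dict(self) -> dict:
        return {"p75_ic50": self.p75_ic50, "p75_ld25": self.p75_ld25, "mtd": self.mtd}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MTDResult":
        return cls(p75_ic50=d["p75_ic50"], p75_ld25=d["p75_ld25"], mtd=d["mtd"])


def compute_mtd(
    ratio_ic50: Sequence[float], ratio_ld25: Sequence[float], percentile: float = 75.0
) -> MTDResult:
    """MTD = max of the (1-decimal rounded) 75th percentiles of the ratios."""
    p_ic = percentile_75(ratio_ic50, percentile)
    p_ld = percentile_75(ratio_ld25, percentile)
    return MTDResult(p75_ic50=p_ic, p75_ld25=p_ld, mtd=max(round(p_ic, 1), round(p_ld, 1)))


@dataclass(frozen=True)
class EDDecision:
    """Outcome of the equivalent-dose selection among candidate dilutions.

    Dilution factors at or below the MTD are unsafe (too concentrated) and
    are excluded; among the remaining candidates flagged effective the
    largest dilution factor (the lowest exposure consistent with efficacy)
    is selected.  ``ed`` is ``None`` when no safe candidate is effective.
    """

    mtd: float
    candidates: tuple[tuple[float, bool], ...]
    ed: float | None
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "mtd": self.mtd,
            "candidates": [{"df": df, "effective": eff} for df, eff in self.candidates],
            "ed": self.ed,
            "reason": self.reason,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EDDecision":
        return cls(
            mtd=d["mtd"],
            candidates=tuple((c["df"], c["effective"]) for c in d["candidates"]),
            ed=d["ed"],
            reason=d.get("reason", ""),
        )


def select_ed(candidates: Mapping[float, bool], mtd: float) -> EDDecision:
    """Select the equivalent dose from dilution-factor screening results.

    ``candidates`` maps dilution factor -> efficacy flag.
    """
    if not candidates:
        raise InputError("no candidate dilution factors supplied")
    if any(df <= 0 for df in candidates):
        raise DomainError("dilution factors must be strictly positive")
    ordered = tuple(sorted(candidates.items(), key=lambda kv: -kv[0]))
    safe_effective = [df for df, eff in ordered if df > mtd and eff]
    if safe_effective:
        return EDDecision(mtd=mtd, candidates=ordered, ed=max(safe_effective))
    return EDDecision(
        mtd=mtd,
        candidates=ordered,
        ed=None,
        reason="no effective dilution above MTD",
    )


def load_reference_table(path: str | Path | None = None) -> pd.DataFrame:
    """The published safety summary of the ten studied regimens.

    Per-drug rows with EPC, IC50 and LD25 (mg/mL, as printed, i.e. rounded
    to display precision) and per-regimen exposure ratios on the index-drug
    row.  This table is the desk-reproducible anchor for the MTD.
    """
    if path is None:
        source = importlib.resources.files("fishdose.data") / "safety_reference.csv"
        with importlib.resources.as_file(source) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def reference_summaries(path: str | Path | None = None) -> list[SafetySummary]:
    """Published per-regimen summaries, with the ratios as printed.

    The printed ratio cells were formed from unrounded fit intermediates,
    so they are carried verbatim rather than recomputed from the (rounded)
    printed EPC and IC50/LD25 columns.
    """
    ref = load_reference_table(path)
    rows = ref.dropna(subset=["epc_ic50"])
    return [
        SafetySummary(
            regimen=row["regimen"],
            epc=row["epc_mg_ml"],
            ic50=row["ic50_mg_ml"],
            ld25=row["ld25_mg_ml"],
            ratio_ic50=row["epc_ic50"],
            ratio_ld25=row["epc_ld25"],
        )
        for _, row in rows.iterrows()
    ]
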