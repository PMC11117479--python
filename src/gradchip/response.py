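"""Stemness readouts from per-cell reporter calls, plus synthetic cohorts.

Input is tabular: one row per cell with a boolean reporter status
(``hes5_positive``); image segmentation happens upstream and is out of
scope. The synthetic-cohort generator draws per-cell differentiation
events from a logistic dose-response curve and exists to exercise the
pipeline end-to-end, not to model mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .errors import ValidationError
from .planner import DoseMatrix

__all__ = [
    "CellRecord",
    "StemnessSummary",
    "ResponseModel",
    "stemness_fraction",
    "summarize_condition",
    "synth_cells",
    "cells_to_frame",
    "fit_response_model",
    "MIN_REPEATS",
]

#: Minimum repeat count before a summary is flagged as under-replicated.
MIN_REPEATS = 5


@dataclass(frozen=True)
class CellRecord:
    """One cell's reporter call in one chamber at one observation time."""

    array: int
    chamber: int
    condition: str
    time_h: float
    hes5_positive: bool

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValidationError(f"time_h must be >= 0, got {self.time_h}")


@dataclass(frozen=True)
class StemnessSummary:
    """Per-condition stemness fraction with dispersion over repeats."""

    condition: str
    time_h: float
    fraction_positive: float
    sd: float
    n_repeats: int
    below_minimum: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_positive <= 1.0:
            raise ValidationError(
                f"fraction_positive must be in [0, 1], got {self.fraction_positive}"
            )
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")


def _positives(cells: "Sequence[CellRecord] | pd.DataFrame") -> tuple[int, int]:
    if isinstance(cells, pd.DataFrame):
        if "hes5_positive" not in cells.columns:
            raise ValidationError("cell table must have a hes5_positive column")
        values = cells["hes5_positive"].astype(bool)
        return int(values.sum()), int(len(values))
    cells = list(cells)
    return sum(bool(c.hes5_positive) for c in cells), len(cells)


def stemness_fraction(cells: "Sequence[CellRecord] | pd.DataFrame") -> float:
    """Fraction of reporter-positive cells; order and labels are irrelevant."""
    positive, total = _positives(cells)
    if total == 0:
        raise ValidationError("stemness fraction is undefined for an empty cell list")
    return positive / total


def summarize_condition(
    groups: Iterable["Sequence[CellRecord] | pd.DataFrame"],
    condition: str,
    time_h: float,
) -> StemnessSummary:
    """Mean and sample (n-1) standard deviation of per-repeat fractions.

    A single repeat gets sd 0. Fewer than MIN_REPEATS repeats raises the
    below-minimum flag but is not an error.
    """
    fractions = [stemness_fraction(g) for g in groups]
    if not fractions:
        raise ValidationError("at least one repeat is required")
    mean = float(np.mean(fractions))
    sd = float(np.std(fractions, ddof=1)) if len(fractions) > 1 else 0.0
    return StemnessSummary(
        condition=condition,
        time_h=time_h,
        fraction_positive=mean,
        sd=sd,
        n_repeats=len(fractions),
        below_minimum=len(fractions) < MIN_REPEATS,
    )


@dataclass(frozen=True)
class ResponseModel:
    """Logistic dose -> differentiation-probability curve for synthetic cohorts.

    p(dose) = baseline + (max - baseline) / (1 + exp(-steepness*(dose - midpoint)))
    """

    baseline_differentiation: float
    max_differentiation: float
    dose_midpoint: float  # ng/mL
    steepness: float  # per ng/mL
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_differentiation <= self.max_differentiation <= 1.0:
            raise ValidationError(
                "need 0 <= baseline_differentiation <= max_differentiation <= 1, got "
                f"({self.baseline_differentiation}, {self.max_differentiation})"
            )
        if self.dose_midpoint <= 0:
            raise ValidationError(
                f"dose_midpoint must be > 0, got {self.dose_midpoint}"
            )

    def differentiation_probability(self, dose: "float | np.ndarray") -> "float | np.ndarray":
        span = self.max_differentiation - self.baseline_differentiation
        return self.baseline_differentiation + span * expit(
            self.steepness * (np.asarray(dose, dtype=float) - self.dose_midpoint)
        )


def synth_cells(
    dose_matrix: DoseMatrix,
    model: ResponseModel,
    cells_per_chamber: int,
    array: int = 1,
    condition: str = "synthetic",
    time_h: float = 48.0,
) -> list[CellRecord]:
    """Draw a per-chamber cohort; each cell differentiates independently.

    The effective dose of a chamber is the summed concentration of all drugs
    in its dose-matrix row. Deterministic for a given model seed.
    """
    if cells_per_chamber < 1:
        raise ValidationError(
            f"cells_per_chamber must be >= 1, got {cells_per_chamber}"
        )
    rng = np.random.default_rng(model.seed)
    records: list[CellRecord] = []
    doses = dose_matrix.concentrations.sum(axis=1)
    for chamber in range(1, dose_matrix.n_chambers + 1):
        p = float(model.differentiation_probability(doses[chamber - 1]))
        differentiated = rng.random(cells_per_chamber) < p
        records.extend(
            CellRecord(
                array=array,
                chamber=chamber,
                condition=condition,
                time_h=time_h,
                hes5_positive=not bool(d),
            )
            for d in differentiated
        )
    return records


def cells_to_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "array": [c.array for c in cells],
            "chamber": [c.chamber for c in cells],
            "condition": [c.condition for c in cells],
            "time_h": [c.time_h for c in cells],
            "hes5_positive": [c.hes5_positive for c in cells],
        }
    )


def fit_response_model(
    doses: Sequence[float],
    differentiated: Sequence[int],
    totals: Sequence[int],
    steepness_bounds: tuple[float, float] = (1e-4, 10.0),
) -> ResponseModel:
    """Binomial maximum-likelihood fit of the logistic dose-response curve.

    ``differentiated[i]`` of ``totals[i]`` cells differentiated at
    ``doses[i]``. Returns the fitted model (seed 0).
    """
    doses = np.asarray(doses, dtype=float)
    ks = np.asarray(differentiated, dtype=float)
    ns = np.asarray(totals, dtype=float)
    if not (len(doses) == len(ks) == len(ns)) or len(doses) < 3:
        raise ValidationError("need >= 3 dose groups of equal-length arrays")

    def nll(theta: np.ndarray) -> float:
        lo, hi, mid, steep = theta
        p = lo + (hi - lo) * expit(steep * (doses - mid))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return float(-np.sum(ks * np.log(p) + (ns - ks) * np.log1p(-p)))

    frac = ks / ns
    x0 = np.array(
        [
            max(frac.min(), 1e-3),
            min(max(frac.max(), 2e-3), 1 - 1e-3),
            float(np.median(doses)),
            4.0 / max(doses.max() - doses.min(), 1.0),
        ]
    )
    bounds = [
        (1e-6, 1 - 1e-6),
        (1e-6, 1 - 1e-6),
        (max(doses.min(), 1e-6), doses.max()),
        steepness_bounds,
    ]
    best = None
    for steep0 in (x0[3], 5 * x0[3], 0.2 * x0[3]):
        start = x0.copy()
        start[3] = steep0
        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    lo, hi, mid, steep = best.x
    lo, hi = min(lo, hi), max(lo, hi)
    return ResponseModel(
        baseline_differentiation=float(lo),
        max_differentiation=float(hi),
        dose_midpoint=float(mid),
        steepness=float(steep),
        seed=0,
    )
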