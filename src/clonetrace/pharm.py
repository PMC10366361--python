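"""Dose-response fitting, IC50 fold changes, and Loewe-additivity synergy.

Viability (fraction of untreated control) versus dose is fitted with the
four-parameter logistic (4PL)

    v(d) = floor + (ceiling - floor) / (1 + (d / IC50)^h),   h > 0

so v decreases monotonically from ``ceiling`` toward ``floor`` with
half-maximal inhibition at ``IC50``.  Collateral sensitivity is
quantified as the IC50 fold change between a reference line and a
drug-resistant derivative.

Drug-combination grids are scored against the Loewe additivity null:
for a dose pair (a, b) the expected inhibition y solves

    a / A(y) + b / B(y) = 1

where A and B invert the single-agent fits (the dose of each agent
alone producing inhibition y).  The synergy score is the mean excess of
observed over expected inhibition in percentage points; scores between
-10 and +10 are additive, above +10 synergistic, below -10 antagonistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

ADDITIVE = "additive"
SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"

#: Percentage-point band treated as additive (boundaries inclusive).
LOEWE_THRESHOLD = 10.0


def four_pl(dose: np.ndarray, floor: float, ceiling: float, ic50: float, hill: float) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    return floor + (ceiling - floor) / (1.0 + (dose / ic50) ** hill)


@dataclass
class DoseResponseCurve:
    """A fitted four-parameter logistic dose-response curve."""

    doses: np.ndarray
    viability: np.ndarray
    floor: float
    ceiling: float
    ic50: float
    hill: float
    residuals: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    extrapolated: bool = False  # IC50 outside [min dose / 10, max dose * 10]

    def predict(self, dose: np.ndarray | float) -> np.ndarray:
        return four_pl(np.asarray(dose, dtype=float), self.floor, self.ceiling, self.ic50, self.hill)

    def inhibition_range(self) -> tuple[float, float]:
        """Open interval of inhibitions reachable at finite positive dose."""
        return 1.0 - self.ceiling, 1.0 - self.floor

    def inverse(self, inhibition: float) -> float:
        """Dose producing the given inhibition (1 - viability)."""
        lo, hi = self.inhibition_range()
        if not lo < inhibition < hi:
            raise ValueError(
                f"inhibition {inhibition:.4f} outside achievable range ({lo:.4f}, {hi:.4f})"
            )
        v = 1.0 - inhibition
        return self.ic50 * ((self.ceiling - v) / (v - self.floor)) ** (1.0 / self.hill)


def fit_dose_response(
    doses: np.ndarray, viability: np.ndarray, max_inhibition_floor: float = 0.0
) -> DoseResponseCurve:
    """Least-squares 4PL fit of viability (fraction of control) vs dose.

    ``viability`` may be (n_doses,) or (n_doses, n_replicates); replicate
    values are fitted jointly.  The Hill slope is constrained positive
    (monotone decreasing viability).  Non-convergence and flat data are
    flagged (``converged=False``, NaN IC50) rather than raised; an IC50
    outside [min dose / 10, max dose * 10] is flagged extrapolated.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.ndim != 1 or len(np.unique(doses)) < 4:
        raise ValueError("need >= 4 distinct doses")
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    v = np.asarray(viability, dtype=float)
    if v.ndim == 2:
        d_fit = np.repeat(doses, v.shape[1])
        v_fit = v.reshape(-1)
    else:
        d_fit, v_fit = doses, v
    if len(d_fit) != len(v_fit):
        raise ValueError("doses and viability shapes disagree")

    span = v_fit.max() - v_fit.min()
    if span < 1e-3:  # no dose effect to fit
        return DoseResponseCurve(
            doses=doses, viability=v, floor=float(v_fit.mean()), ceiling=float(v_fit.mean()),
            ic50=float("nan"), hill=float("nan"), residuals=np.zeros_like(v_fit),
            converged=False, extrapolated=False,
        )

    p0 = [max(v_fit.min(), 1e-6), min(v_fit.max(), 1.5), float(np.median(doses)), 1.0]
    bounds = ([0.0, 0.0, doses.min() / 1e4, 0.05], [1.5, 2.0, doses.max() * 1e4, 20.0])
    try:
        popt, _ = optimize.curve_fit(
            four_pl, d_fit, v_fit, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError:
        return DoseResponseCurve(
            doses=doses, viability=v, floor=float("nan"), ceiling=float("nan"),
            ic50=float("nan"), hill=float("nan"), residuals=None, converged=False,
        )
    floor, ceiling, ic50, hill = map(float, popt)
    residuals = v_fit - four_pl(d_fit, *popt)
    extrapolated = not (doses.min() / 10.0 <= ic50 <= doses.max() * 10.0)
    return DoseResponseCurve(
        doses=doses, viability=v, floor=floor, ceiling=ceiling, ic50=ic50, hill=hill,
        residuals=residuals, converged=True, extrapolated=extrapolated,
    )


def fold_change(ic50_reference: float, ic50_test: float) -> dict[str, float | str]:
    """IC50 fold change between a reference line and a test (resistant) line.

    Returns the fold in the direction observed: ``resistance`` when the
    test IC50 is higher (fold = test/reference), ``sensitization`` when
    lower (fold = reference/test).
    """
    if ic50_reference <= 0 or ic50_test <= 0 or not (
        math.isfinite(ic50_reference) and math.isfinite(ic50_test)
    ):
        raise ValueError("IC50 values must be positive and finite")
    if ic50_test >= ic50_reference:
        return {"fold": ic50_test / ic50_reference, "direction": "resistance"}
    return {"fold": ic50_reference / ic50_test, "direction": "sensitization"}


@dataclass
class SynergyMatrix:
    """Observed combination-viability grid with its single-agent fits.

    ``grid`` is indexed by dose of drug A (rows) and dose of drug B
    (columns) and must include the zero-dose row and column carrying the
    single-agent responses.  A single background-drug design (one agent
    held at a fixed dose while the other is titrated) is simply a grid
    with one nonzero row.
    """

    grid: pd.DataFrame
    curve_a: DoseResponseCurve
    curve_b: DoseResponseCurve

    def __post_init__(self) -> None:
        if 0.0 not in self.grid.index or 0.0 not in self.grid.columns:
            raise ValueError("grid must include the zero-dose row and column")


def loewe_expected_inhibition(
    a: float, b: float, curve_a: DoseResponseCurve, curve_b: DoseResponseCurve, tol: float = 1e-8
) -> float:
    """Inhibition y solving the Loewe equation a/A(y) + b/B(y) = 1.

    Solved by bracketing bisection on the shared achievable inhibition
    range; combinations beyond (or below) what both agents can reach are
    clamped to the range boundary.
    """
    if a < 0 or b < 0:
        raise ValueError("doses must be non-negative")
    if a == 0 and b == 0:
        return 0.0
    if a == 0:
        return _single_agent_inhibition(curve_b, b)
    if b == 0:
        return _single_agent_inhibition(curve_a, a)

    lo_a, hi_a = curve_a.inhibition_range()
    lo_b, hi_b = curve_b.inhibition_range()
    lo = max(lo_a, lo_b, 0.0)
    hi = min(hi_a, hi_b)
    if hi <= lo:
        raise ValueError("single-agent fits share no achievable inhibition range")
    eps = (hi - lo) * 1e-9

    def excess(y: float) -> float:
        return a / curve_a.inverse(y) + b / curve_b.inverse(y) - 1.0

    y_lo, y_hi = lo + eps, hi - eps
    # excess decreases in y: more inhibition demands larger iso-effect doses
    if excess(y_lo) <= 0:
        return y_lo
    if excess(y_hi) >= 0:
        return y_hi
    return float(optimize.brentq(excess, y_lo, y_hi, xtol=tol))


def _single_agent_inhibition(curve: DoseResponseCurve, dose: float) -> float:
    return float(1.0 - curve.predict(dose))


def classify_score(score: float, threshold: float = LOEWE_THRESHOLD) -> str:
    """Interaction class from a synergy score; the +/-10 boundaries are additive."""
    if score > threshold:
        return SYNERGISTIC
    if score < -threshold:
        return ANTAGONISTIC
    return ADDITIVE


def loewe_score(sm: SynergyMatrix) -> tuple[float, str, pd.DataFrame]:
    """Mean percentage-point excess inhibition over the Loewe expectation.

    Averages 100 * (observed inhibition - expected inhibition) over all
    combination cells where both doses are nonzero, and classifies the
    mean with the +/-10 thresholds.  Also returns the per-cell excess grid.
    """
    a_doses = [d for d in sm.grid.index if d > 0]
    b_doses = [d for d in sm.grid.columns if d > 0]
    if not a_doses or not b_doses:
        raise ValueError("grid has no nonzero-dose combination cells")
    excess = pd.DataFrame(index=a_doses, columns=b_doses, dtype=float)
    for a in a_doses:
        for b in b_doses:
            observed = 1.0 - float(sm.grid.loc[a, b])
            expected = loewe_expected_inhibition(a, b, sm.curve_a, sm.curve_b)
            excess.loc[a, b] = 100.0 * (observed - expected)
    score = float(excess.to_numpy(dtype=float).mean())
    return score, classify_score(score), excess
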