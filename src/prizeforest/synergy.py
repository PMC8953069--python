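"""Growth-inhibition readout and ZIP (zero interaction potency) synergy scoring.

Percent growth inhibition is derived from real-time impedance cell-index (CI)
traces at a fixed timepoint (72 h in the study): inhibition = 1 - CI_treated /
CI_control.  For a two-drug dose matrix, the ZIP reference assumes the drugs
act independently, so the expected combination inhibition is

    y_zip(i, j) = y1(d_i) + y2(d_j) - y1(d_i) * y2(d_j)

with y1, y2 the monotherapy curves smoothed by four-parameter logistic fits.
The per-cell delta is observed minus expected; the mean delta over all
combination cells is the reported synergy score — positive means synergy,
negative antagonism.  (The full published ZIP model additionally refits
potency along each row and column; this implementation scores deviation from
the independence surface built from the monotherapy fits alone, which
preserves the sign/classification contract.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError

__all__ = [
    "DoseResponseMatrix",
    "SynergySummary",
    "inhibition_from_ci",
    "fit_logistic4",
    "zip_delta",
]

log = logging.getLogger(__name__)


@dataclass
class DoseResponseMatrix:
    """Inhibition fractions on a dose grid, monotherapy row/column included.

    ``inhibition[i, j]`` is the inhibition at (doses1[i], doses2[j]); both
    dose vectors start at 0, so row 0 / column 0 hold the monotherapies and
    cell (0, 0) is untreated (inhibition 0).
    """

    doses1: np.ndarray
    doses2: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        self.doses1 = np.asarray(self.doses1, dtype=float)
        self.doses2 = np.asarray(self.doses2, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.inhibition.shape != (len(self.doses1), len(self.doses2)):
            raise InputError("inhibition matrix shape does not match dose grids")
        for d in (self.doses1, self.doses2):
            if d[0] != 0:
                raise InputError("dose grids must start at 0 (monotherapy axis)")
            if not np.all(np.diff(d) > 0):
                raise InputError("doses must be strictly increasing")
        if abs(self.inhibition[0, 0]) > 1e-9:
            raise InputError("inhibition at (0, 0) must be 0")
        clipped = (self.inhibition < 0) | (self.inhibition > 1)
        if clipped.any():
            log.info("clipping %d inhibition values into [0, 1]", int(clipped.sum()))
            self.inhibition = np.clip(self.inhibition, 0.0, 1.0)

    def monotherapy(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(doses1>0, y1, doses2>0, y2)."""
        return (
            self.doses1[1:],
            self.inhibition[1:, 0],
            self.doses2[1:],
            self.inhibition[0, 1:],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.inhibition, index=self.doses1, columns=self.doses2
        )
        df.index.name = "dose1\\dose2"
        df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "DoseResponseMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        values = df.to_numpy(dtype=float)
        if np.nanmax(values) > 1.5:  # percent dialect
            values = values / 100.0
        return cls(
            doses1=df.index.to_numpy(dtype=float),
            doses2=df.columns.to_numpy(dtype=float),
            inhibition=values,
        )


@dataclass
class SynergySummary:
    """Per-cell ZIP deltas, their mean, and the sign-based classification."""

    delta: pd.DataFrame
    mean_delta: float
    classification: str
    fit1: dict | None = None
    fit2: dict | None = None

    def __post_init__(self) -> None:
        expect = (
            "synergistic" if self.mean_delta > 0
            else "antagonistic" if self.mean_delta < 0
            else "additive"
        )
        if self.classification != expect:
            raise InputError("classification inconsistent with the sign of mean delta")


def inhibition_from_ci(ci_treated, ci_control, t: float = 72.0) -> float:
    """Growth inhibition at time ``t`` from two cell-index time series.

    Series are pandas Series indexed by time (hours) or (time, value) arrays;
    values at ``t`` are linearly interpolated.  inhibition = 1 - CI_t/CI_c,
    clipped to [0, 1].
    """

    def at(series) -> float:
        if isinstance(series, pd.Series):
            times = series.index.to_numpy(dtype=float)
            vals = series.to_numpy(dtype=float)
        else:
            arr = np.asarray(series, dtype=float)
            times, vals = arr[:, 0], arr[:, 1]
        if t < times.min() or t > times.max():
            raise InputError(f"series does not cover t={t}")
        return float(np.interp(t, times, vals))

    ci_c = at(ci_control)
    if ci_c <= 0:
        raise InputError(f"control CI at t={t} must be positive")
    return float(np.clip(1.0 - at(ci_treated) / ci_c, 0.0, 1.0))


def _logistic4(d, ymin, ymax, ec50, hill):
    return ymin + (ymax - ymin) / (1.0 + (ec50 / d) ** hill)


def fit_logistic4(doses, y) -> dict:
    """Least-squares 4-parameter logistic fit of an inhibition curve.

    Bounds: ymin in [0, 0.3], ymax in [0.3, 1], hill > 0, ec50 within an
    extended dose range.  Raises on failure (callers fall back to the
    observed values).
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(y, dtype=float)
    p0 = [
        max(float(y.min()), 0.01),
        min(max(float(y.max()), 0.31), 1.0),
        float(np.sqrt(doses.min() * doses.max())),
        1.0,
    ]
    p0[0] = min(p0[0], 0.29)
    bounds = (
        [0.0, 0.3, doses.min() / 100.0, 0.05],
        [0.3, 1.0, doses.max() * 100.0, 10.0],
    )
    popt, _ = curve_fit(
        _logistic4, doses, y, p0=p0, bounds=bounds, maxfev=20000,
        ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    return dict(zip(("ymin", "ymax", "ec50", "hill"), map(float, popt)))


def zip_delta(drm: DoseResponseMatrix) -> SynergySummary:
    """ZIP delta surface and its mean over all combination cells.

    Monotherapy rows are smoothed with 4PL fits (falling back to the observed
    values if a fit fails); delta(i,j) = y_obs(i,j) - (y1 + y2 - y1*y2).
    """
    d1, y1_obs, d2, y2_obs = drm.monotherapy()
    if len(d1) == 0 or len(d2) == 0:
        raise InputError("monotherapy row and column are required")

    def smooth(d, y, label):
        try:
            fit = fit_logistic4(d, y)
            return _logistic4(d, **fit), fit
        except Exception as err:  # fit failure -> observed values
            log.warning("4PL fit failed for %s (%s); using observed values", label, err)
            return y, None

    y1, fit1 = smooth(d1, y1_obs, "drug 1")
    y2, fit2 = smooth(d2, y2_obs, "drug 2")

    expected = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]
    observed = drm.inhibition[1:, 1:]
    delta = observed - expected
    mean_delta = float(delta.mean())
    classification = (
        "synergistic" if mean_delta > 0
        else "antagonistic" if mean_delta < 0
        else "additive"
    )
    return SynergySummary(
        delta=pd.DataFrame(delta, index=d1, columns=d2),
        mean_delta=mean_delta,
        classification=classification,
        fit1=fit1,
        fit2=fit2,
    )
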