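"""External calibration with regression-based detection limits.

Calibration series are fitted per replicate injection series by ordinary
least squares (response vs concentration in nM).  The pooled slope S is
the mean of the per-replicate slopes, and the standard deviation of the
per-replicate y-intercepts serves as the response standard deviation
sigma, from which

    LOD = 3.3 * sigma / S        LOQ = 10 * sigma / S

(the standard-deviation-of-the-response-and-slope method of the ICH
Q2(R1) guideline).  With a single replicate series the residual standard
deviation of that fit is used instead and the curve is flagged.
Concentrations are reported in nM; unit conversion to uM/nmol happens at
module boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


class QuantStatus(str, enum.Enum):
    OK = "ok"
    BETWEEN_LOD_LOQ = "between_lod_loq"
    BELOW_LOD = "below_lod"
    INVALID = "invalid"


@dataclass
class CalibrationCurve:
    compound_id: str
    levels: np.ndarray  # nM
    slope: float  # response per nM
    intercept: float  # response units
    sigma_intercept: float  # response units
    lod: float  # nM
    loq: float  # nM
    r2: float
    sigma_source: str = "intercepts"  # or "residual" (single-series fallback)


def fit_calibration(
    levels: np.ndarray,
    responses: np.ndarray,
    compound_id: str = "",
) -> CalibrationCurve:
    """Fit a calibration curve from replicate response series.

    Parameters
    ----------
    levels
        Concentration levels in nM, length ``n_levels`` (>= 3).
    responses
        Array of shape ``(n_replicates, n_levels)`` (or 1-D for a single
        series, which falls back to the residual-SD estimate of sigma).
    """
    levels = np.asarray(levels, dtype=float)
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if levels.size < 3:
        raise ValueError("need at least 3 calibration levels")
    if responses.shape[1] != levels.size:
        raise ValueError("responses must have one column per level")

    fits = [stats.linregress(levels, row) for row in responses]
    slopes = np.array([f.slope for f in fits])
    intercepts = np.array([f.intercept for f in fits])
    slope = float(np.mean(slopes))
    intercept = float(np.mean(intercepts))
    if slope <= 0:
        raise ValueError("calibration slope must be positive")

    if responses.shape[0] >= 2:
        sigma = float(np.std(intercepts, ddof=1))
        source = "intercepts"
    else:
        resid = responses[0] - (slope * levels + intercept)
        sigma = float(np.sqrt(np.sum(resid**2) / max(levels.size - 2, 1)))
        source = "residual"

    # pooled r2 over all points
    x = np.tile(levels, responses.shape[0])
    y = responses.ravel()
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    return CalibrationCurve(
        compound_id=compound_id,
        levels=levels,
        slope=slope,
        intercept=intercept,
        sigma_intercept=sigma,
        lod=LOD_FACTOR * sigma / slope,
        loq=LOQ_FACTOR * sigma / slope,
        r2=r2,
        sigma_source=source,
    )


@dataclass
class Quantification:
    conc_nM: float
    status: QuantStatus

    @property
    def conc_uM(self) -> float:
        return self.conc_nM / 1000.0

    @property
    def censored_conc_nM(self) -> float:
        """Concentration with below-LOD values treated as 0 for amount sums."""
        return 0.0 if self.status in (QuantStatus.BELOW_LOD, QuantStatus.INVALID) else self.conc_nM


def quantify(response: float, curve: CalibrationCurve) -> Quantification:
    """Invert the calibration: conc = (response - intercept) / slope, in nM.

    The raw value is retained for diagnostics even below the LOD; callers
    summing amounts should use :attr:`Quantification.censored_conc_nM`.
    A negative response (after blank correction) is invalid.
    """
    if not np.isfinite(response):
        return Quantification(0.0, QuantStatus.BELOW_LOD)
    if response < 0:
        return Quantification(np.nan, QuantStatus.INVALID)
    conc = (response - curve.intercept) / curve.slope
    if conc < curve.lod:
        status = QuantStatus.BELOW_LOD
    elif conc < curve.loq:
        status = QuantStatus.BETWEEN_LOD_LOQ
    else:
        status = QuantStatus.OK
    return Quantification(conc, status)


def exact_curve(compound_id: str, response_factor_per_uM: float) -> CalibrationCurve:
    """Idealised curve for a proportional detector (slope per nM, no offset)."""
    return CalibrationCurve(
        compound_id=compound_id,
        levels=np.array([0.0]),
        slope=response_factor_per_uM / 1000.0,
        intercept=0.0,
        sigma_intercept=0.0,
        lod=0.0,
        loq=0.0,
        r2=1.0,
    )


def simulate_calibration(
    levels_nM: np.ndarray,
    response_factor_per_uM: float,
    noise_cv: float,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Synthetic replicate calibration responses for a proportional detector."""
    levels_nM = np.asarray(levels_nM, dtype=float)
    rng = np.random.default_rng(seed)
    truth = response_factor_per_uM * levels_nM / 1000.0
    out = np.tile(truth, (n_replicates, 1))
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        out = out * rng.lognormal(-0.5 * sigma**2, sigma, size=out.shape)
    return out
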