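"""Causal-effect estimators on harmonized summary statistics.

All estimators consume a :class:`~netmr.harmonize.HarmonizedSet` and return
an :class:`MrEstimate` on the beta scale (log odds ratio when the outcome is
binary; the OR triple is attached at construction and exponentiation never
happens inside the arithmetic).

* ``wald_ratio`` — single-SNP ratio β_out/β_exp with first-order delta SE.
* ``ivw_fixed`` — fixed-effect inverse-variance-weighted meta-analysis of the
  per-SNP ratios; algebraically identical to weighted least squares of β_out
  on β_exp through the origin with weights 1/se_out².
* ``grs_estimate`` — the genetic-risk-score summary estimator; numerically
  identical to ``ivw_fixed`` and kept as a named method for report parity.
* ``ivw_mre`` — same point estimate with the SE inflated by the square root
  of the overdispersion φ = max(1, Q/(k−1)).
* ``egger`` — weighted regression of β_out on β_exp *with* an intercept; the
  intercept estimates directional pleiotropy, the slope the causal effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import EstimationError, InsufficientInstrumentsError
from .harmonize import HarmonizedRecord, HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.96  # conventional 95% half-width multiplier


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal estimate with 95% CI and two-sided p."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    or_scale: tuple[float, float, float] | None = None  # (OR, lo, hi) for binary outcomes


def _estimate(method: str, beta: float, se: float, k: int,
              df: int | None = None, binary: bool = False) -> MrEstimate:
    lo, hi = beta - Z95 * se, beta + Z95 * se
    if se == 0:
        p = 1.0 if beta == 0 else np.nextafter(0, 1)
    elif df is not None:
        p = 2.0 * stats.t.sf(abs(beta / se), df)
    else:
        p = 2.0 * stats.norm.sf(abs(beta / se))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    ors = (math.exp(beta), math.exp(lo), math.exp(hi)) if binary else None
    return MrEstimate(method, beta, se, lo, hi, p, k, ors)


def wald_ratio(record: HarmonizedRecord, binary: bool = False) -> MrEstimate:
    """Single-SNP causal ratio β_out/β_exp (first-order SE)."""
    if record.beta_exp == 0:
        raise EstimationError(f"{record.variant_id}: exposure beta is 0, ratio undefined")
    beta = record.beta_out / record.beta_exp
    se = record.se_out / abs(record.beta_exp)
    return _estimate("wald", beta, se, 1, binary=binary)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    w = bx * bx / (sy * sy)
    s_xy = float(np.sum(bx * by / (sy * sy)))
    s_xx = float(np.sum(w))
    return s_xy / s_xx, 1.0 / math.sqrt(s_xx)


def q_statistic(hset: HarmonizedSet) -> float:
    """Cochran's Q of the per-SNP ratios about the fixed-effect IVW estimate."""
    bx, _, by, sy = hset.arrays()
    beta, _ = _ivw_core(bx, by, sy)
    w = bx * bx / (sy * sy)
    ratios = by / bx
    return float(np.sum(w * (ratios - beta) ** 2))


def ivw_fixed(hset: HarmonizedSet) -> MrEstimate:
    """Fixed-effect IVW estimate; falls back to the Wald ratio at k = 1."""
    if hset.k == 0:
        raise InsufficientInstrumentsError("no harmonized records")
    if hset.k == 1:
        logger.info("ivw_fixed: single instrument, falling back to Wald ratio")
        return wald_ratio(hset.records[0], binary=hset.outcome_binary)
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise EstimationError("zero exposure beta in harmonized set")
    beta, se = _ivw_core(bx, by, sy)
    return _estimate("ivw_fe", beta, se, hset.k, binary=hset.outcome_binary)


def grs_estimate(hset: HarmonizedSet) -> MrEstimate:
    """Genetic-risk-score summary estimator (identical to fixed-effect IVW)."""
    est = ivw_fixed(hset)
    return MrEstimate("grs", est.beta, est.se, est.ci_low, est.ci_high,
                      est.pvalue, est.k, est.or_scale)


def ivw_mre(hset: HarmonizedSet) -> MrEstimate:
    """IVW with multiplicative random effects: SE × √max(1, Q/(k−1))."""
    if hset.k < 3:
        raise InsufficientInstrumentsError(f"ivw_mre needs k >= 3, got {hset.k}")
    fe = ivw_fixed(hset)
    phi = max(1.0, q_statistic(hset) / (hset.k - 1))
    se = fe.se * math.sqrt(phi)
    return _estimate("ivw_mre", fe.beta, se, hset.k, binary=hset.outcome_binary)


@dataclass(frozen=True)
class EggerResult:
    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_p: float

    @property
    def directional_pleiotropy(self) -> bool:
        """The conventional verdict: pleiotropy iff intercept p <= 0.05."""
        return self.intercept_p <= 0.05


def egger(hset: HarmonizedSet) -> EggerResult:
    """MR-Egger weighted regression with intercept.

    Exposure effects are re-oriented non-negative first (the estimate must
    not depend on arbitrary effect-allele choices).  Weights are 1/se_out²;
    dispersion is estimated from the weighted residuals and both slope and
    intercept are tested against t with k − 2 degrees of freedom.
    """
    k = hset.k
    if k < 3:
        raise InsufficientInstrumentsError(f"egger needs k >= 3, got {k}")
    bx, _, by, sy = hset.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    if np.allclose(x, x[0]):
        raise EstimationError("zero variance in exposure betas: Egger regression degenerate")
    w = 1.0 / (sy * sy)
    # weighted normal equations for y = a + b x
    sw, swx, swxx = float(np.sum(w)), float(np.sum(w * x)), float(np.sum(w * x * x))
    swy, swxy = float(np.sum(w * y)), float(np.sum(w * x * y))
    det = sw * swxx - swx * swx
    if det <= 0:
        raise EstimationError("singular Egger design")
    a = (swxx * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    resid = y - a - b * x
    sigma2 = float(np.sum(w * resid * resid)) / (k - 2)
    var_a = sigma2 * swxx / det
    var_b = sigma2 * sw / det
    se_a, se_b = math.sqrt(var_a), math.sqrt(var_b)
    slope = _estimate("egger_slope", b, se_b, k, df=k - 2, binary=hset.outcome_binary)
    p_a = 2.0 * stats.t.sf(abs(a / se_a), k - 2) if se_a > 0 else 1.0
    return EggerResult(slope, a, se_a, p_a)
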