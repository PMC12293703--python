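"""Heterogeneity and pleiotropy diagnostics for an MR analysis.

Covers Cochran's Q with the I² index, the MR-PRESSO global / outlier /
distortion tests (parametric bootstrap of the residual sum of squares),
leave-one-out influence analysis, and the decision rule that picks the
fixed-effect or multiplicative-random-effects IVW estimate: fixed effects are
reported when Q's p > 0.05 *and* I² < 25%, otherwise the random-effects SE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MrEstimate, _estimate, _ivw_core, ivw_fixed, q_statistic
from .exceptions import EstimationError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with its chi-square p and the I² percentage."""

    q: float
    df: int
    pvalue: float
    i2: float


def cochran_q(hset: HarmonizedSet) -> HeterogeneityStats:
    """Q = Σ w_j (ratio_j − β_IVW)² with w_j = β_exp²/se_out²; df = k − 1."""
    if hset.k < 2:
        raise InsufficientInstrumentsError("cochran_q needs k >= 2")
    q = q_statistic(hset)
    df = hset.k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityStats(q, df, p, i2)


@dataclass
class PressoResult:
    """MR-PRESSO output: global RSS test, flagged outliers, distortion test,
    and the IVW estimate recomputed on the outlier-free set."""

    rss_obs: float
    global_p: float
    outlier_ids: list[str]
    outlier_pvalues: dict[str, float]
    distortion_p: float | None
    corrected: MrEstimate
    n_sim: int
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized via sum subtraction."""
    w = bx * bx / (sy * sy)
    c = bx * by / (sy * sy)
    s_xy, s_xx = np.sum(c, axis=-1, keepdims=True), np.sum(w, axis=-1, keepdims=True)
    return (s_xy - c) / (s_xx - w)


def presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    *,
    seed: int,
    n_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO with a parametric bootstrap of the leave-one-out RSS.

    Global test: observed RSS = Σ_j (β_out_j − β̂_(−j) β_exp_j)² compared with
    replicates simulated under the no-pleiotropy model β*_exp ~ N(β_exp,
    se_exp²), β*_out ~ N(β̂_(−j) β_exp, se_out²); empirical p with +1
    smoothing.  Outlier test: each SNP's observed squared residual against
    its own bootstrap distribution, Bonferroni-corrected across k.
    Distortion test: the corrected-minus-full slope difference against the
    distribution of differences under random removal of the same number of
    SNPs.  The corrected estimate is IVW on the retained set.
    """
    if hset.k < 4:
        raise InsufficientInstrumentsError(f"presso needs k >= 4, got {hset.k}")
    if n_sim < 100:
        raise EstimationError("presso needs n_sim >= 100 for a meaningful empirical p")
    if hset.k / (n_sim + 1) >= outlier_alpha:
        warnings.warn(
            f"presso outlier test underpowered: Bonferroni floor k/(n_sim+1) = "
            f"{hset.k / (n_sim + 1):.3f} >= alpha = {outlier_alpha}; raise n_sim",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = hset.arrays()
    k = hset.k

    loo = _loo_slopes(bx, by, sy)
    resid2_obs = (by - loo * bx) ** 2
    rss_obs = float(np.sum(resid2_obs))

    bx_s = rng.normal(bx, sx, size=(n_sim, k))
    by_s = rng.normal(loo * bx, sy, size=(n_sim, k))
    loo_s = _loo_slopes(bx_s, by_s, sy)
    resid2_s = (by_s - loo_s * bx_s) ** 2
    rss_s = np.sum(resid2_s, axis=1)
    global_p = (1 + int(np.sum(rss_s >= rss_obs))) / (n_sim + 1)

    raw_p = (1 + np.sum(resid2_s >= resid2_obs, axis=0)) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * k)
    ids = hset.ids()
    outlier_ids = [ids[j] for j in range(k) if adj_p[j] < outlier_alpha]
    outlier_pvalues = {ids[j]: float(adj_p[j]) for j in range(k)}

    if len(outlier_ids) == k:
        raise EstimationError("presso flagged every instrument: removal degenerate")

    retained = [i for i in ids if i not in set(outlier_ids)]
    corrected = ivw_fixed(hset.subset(retained))

    distortion_p: float | None = None
    if outlier_ids:
        slope_full, _ = _ivw_core(bx, by, sy)
        obs_diff = corrected.beta - slope_full
        m = len(outlier_ids)
        diffs = np.empty(n_distortion)
        for i in range(n_distortion):
            keep = np.ones(k, dtype=bool)
            keep[rng.choice(k, size=m, replace=False)] = False
            slope_sub, _ = _ivw_core(bx[keep], by[keep], sy[keep])
            diffs[i] = slope_sub - slope_full
        distortion_p = (1 + int(np.sum(np.abs(diffs) >= abs(obs_diff)))) / (n_distortion + 1)

    return PressoResult(rss_obs, global_p, outlier_ids, outlier_pvalues,
                        distortion_p, corrected, n_sim, seed)


def iterative_outlier_removal(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    *,
    seed: int,
    global_alpha: float = 0.05,
    max_iter: int = 5,
) -> tuple[HarmonizedSet, list[PressoResult], list[str]]:
    """Repeat PRESSO outlier removal until the global test is non-significant
    (p > ``global_alpha``), no outliers are flagged, too few SNPs remain, or
    ``max_iter`` rounds have run.  Stands in for external pleiotropy-catalog
    screening.  Returns (final set, per-round results, removed ids)."""
    current = hset
    results: list[PressoResult] = []
    removed: list[str] = []
    for it in range(max_iter):
        if current.k < 4:
            break
        res = presso(current, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed + it)
        results.append(res)
        if res.global_p > global_alpha or not res.outlier_ids:
            break
        removed.extend(res.outlier_ids)
        current = current.subset([i for i in current.ids() if i not in set(res.outlier_ids)])
    return current, results, removed


@dataclass
class LooResult:
    """Leave-one-out re-estimates; ``flags`` lists variants whose exclusion
    changes the estimate's sign or the CI's exclusion of zero."""

    estimates: list[tuple[str, MrEstimate]]
    flags: list[str] = field(default_factory=list)


def leave_one_out(hset: HarmonizedSet) -> LooResult:
    if hset.k < 3:
        raise InsufficientInstrumentsError("leave_one_out needs k >= 3")
    bx, _, by, sy = hset.arrays()
    full = ivw_fixed(hset)
    w = bx * bx / (sy * sy)
    c = bx * by / (sy * sy)
    s_xy, s_xx = float(np.sum(c)), float(np.sum(w))
    ids = hset.ids()
    estimates, flags = [], []
    full_excludes_zero = not (full.ci_low <= 0 <= full.ci_high)
    for j, vid in enumerate(ids):
        beta_j = (s_xy - c[j]) / (s_xx - w[j])
        se_j = 1.0 / math.sqrt(s_xx - w[j])
        est = _estimate("ivw_fe_loo", beta_j, se_j, hset.k - 1, binary=hset.outcome_binary)
        estimates.append((vid, est))
        excludes_zero = not (est.ci_low <= 0 <= est.ci_high)
        if np.sign(beta_j) != np.sign(full.beta) or excludes_zero != full_excludes_zero:
            flags.append(vid)
    return LooResult(estimates, flags)


def robustness_policy(
    het: HeterogeneityStats,
    egger_intercept_p: float,
    fe: MrEstimate,
    mre: MrEstimate,
) -> tuple[MrEstimate, str]:
    """Pick the reported estimate: fixed-effect IVW when Q's p > 0.05 and
    I² < 25% (both strict), otherwise multiplicative random effects.  The
    Egger-intercept verdict is always part of the rationale (directional
    pleiotropy iff intercept p <= 0.05)."""
    pleio = "directional pleiotropy" if egger_intercept_p <= 0.05 else "no directional pleiotropy"
    if het.pvalue > 0.05 and het.i2 < 25.0:
        return fe, (f"fixed-effect IVW: Q p = {het.pvalue:.3g} > 0.05 and "
                    f"I2 = {het.i2:.1f}% < 25%; Egger intercept: {pleio}")
    return mre, (f"IVW-mre: heterogeneity present (Q p = {het.pvalue:.3g}, "
                 f"I2 = {het.i2:.1f}%); Egger intercept: {pleio}")
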