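"""Causal estimators and diagnostics for two-sample MR.

All estimators consume non-dropped :class:`~micromr.sumstats.HarmonizedPair`
records and return :class:`MREstimate`. Confidence intervals use 1.96 normal
quantiles and p-values a two-sided normal reference throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from micromr.sumstats import HarmonizedPair

Z95 = 1.959963984540054

LN2 = math.log(2.0)

WALD_RATIO = "wald_ratio"
IVW = "ivw"
EGGER = "egger"
WEIGHTED_MEDIAN = "weighted_median"
WEIGHTED_MODE = "weighted_mode"


class EstimatorError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    method: str
    beta_xy: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    exposure_unit: str = "per_SD"
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None

    def odds_ratio(self) -> tuple[float, float, float]:
        return to_odds_ratio(self)


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _estimate(method: str, beta: float, se: float, n_snps: int, **extra) -> MREstimate:
    return MREstimate(
        method=method,
        beta_xy=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0),
        n_snps=n_snps,
        **extra,
    )


def _check(pairs: Sequence[HarmonizedPair], minimum: int, method: str) -> None:
    if any(p.dropped for p in pairs):
        raise EstimatorError(f"{method}: dropped pairs passed to estimator")
    if len(pairs) < minimum:
        raise EstimatorError(f"{method}: needs >= {minimum} pairs, got {len(pairs)}")


def _arrays(pairs: Sequence[HarmonizedPair]):
    bx = np.array([p.exposure_beta for p in pairs])
    by = np.array([p.outcome_beta for p in pairs])
    sy = np.array([p.outcome_se for p in pairs])
    return bx, by, sy


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP ratio estimate with first-order delta SE."""
    _check([pair], 1, WALD_RATIO)
    if pair.exposure_beta == 0:
        raise EstimatorError("wald_ratio: exposure beta is zero, ratio undefined")
    beta = pair.outcome_beta / pair.exposure_beta
    se = pair.outcome_se / abs(pair.exposure_beta)
    return _estimate(WALD_RATIO, beta, se, 1)


def ivw(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """Fixed-effects inverse-variance-weighted estimate.

    Zero-intercept regression of outcome betas on exposure betas with weights
    1/outcome_se²; fixed-effects SE = sqrt(1/Σ wᵢxᵢ²).
    """
    _check(pairs, 2, IVW)
    bx, by, sy = _arrays(pairs)
    w = 1.0 / sy**2
    swx2 = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by) / swx2)
    se = math.sqrt(1.0 / swx2)
    est = _estimate(IVW, beta, se, len(pairs))
    q = cochrans_q(pairs, est)
    return replace(est, q_stat=q[0], q_df=q[1], q_p=q[2])


def _orient(bx: np.ndarray, by: np.ndarray):
    """Flip pairs so every exposure beta is non-negative (Egger identification)."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def egger(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """MR-Egger: weighted straight-line fit with a free intercept.

    The slope is the causal estimate; the intercept tests directional
    pleiotropy. SEs use the weighted-least-squares covariance with residual
    dispersion floored at 1 (fixed-effects floor).
    """
    _check(pairs, 3, EGGER)
    bx, by, sy = _arrays(pairs)
    bx, by = _orient(bx, by)
    w = 1.0 / sy**2
    slope, slope_se, icpt, icpt_se = _wls_line(bx, by, w)
    est = _estimate(
        EGGER,
        slope,
        slope_se,
        len(pairs),
        egger_intercept=icpt,
        egger_intercept_se=icpt_se,
        egger_intercept_p=_normal_p(icpt / icpt_se),
    )
    return est


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y = a + b x; returns (b, se_b, a, se_a)."""
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    sxy = np.sum(w * (x - mx) * (y - my))
    b = sxy / sxx
    a = my - b * mx
    resid = y - a - b * x
    dof = len(x) - 2
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 1.0
    disp = max(1.0, sigma2)
    se_b = math.sqrt(disp / sxx)
    se_a = math.sqrt(disp * (1.0 / sw + mx**2 / sxx))
    return float(b), float(se_b), float(a), float(se_a)


def _ratio_weights(pairs: Sequence[HarmonizedPair]):
    bx, by, sy = _arrays(pairs)
    ratios = by / bx
    # first-order inverse-variance weights for per-SNP ratios
    weights = (bx / sy) ** 2
    return ratios, weights


def weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Value at cumulative normalized weight 0.5 with linear interpolation."""
    order = np.argsort(ratios, kind="stable")
    b = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cum[0] >= 0.5:
        return float(b[0])
    if cum[-1] <= 0.5:
        return float(b[-1])
    i = int(np.searchsorted(cum, 0.5, side="left"))
    if cum[i] == 0.5:
        return float(b[i])
    lo, hi = i - 1, i
    frac = (0.5 - cum[lo]) / (cum[hi] - cum[lo])
    return float(b[lo] + frac * (b[hi] - b[lo]))


def _bootstrap_se(pairs, point_fn, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    bx, by, sy = _arrays(pairs)
    sx = np.array([p.exposure_se for p in pairs])
    ests = np.empty(n_boot)
    for i in range(n_boot):
        bx_i = rng.normal(bx, sx)
        by_i = rng.normal(by, sy)
        ests[i] = point_fn(by_i / bx_i, (bx_i / sy) ** 2)
    return float(np.std(ests, ddof=1))


def weighted_median(
    pairs: Sequence[HarmonizedPair], n_boot: int = 5000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimate; SE by seeded parametric bootstrap."""
    _check(pairs, 3, WEIGHTED_MEDIAN)
    ratios, weights = _ratio_weights(pairs)
    beta = weighted_median_estimate(ratios, weights)
    se = _bootstrap_se(pairs, weighted_median_estimate, n_boot, seed)
    return _estimate(WEIGHTED_MEDIAN, beta, se, len(pairs))


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman rule on the per-SNP ratios."""
    n = len(ratios)
    s = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    spread = min(x for x in (s, mad) if x > 0) if (s > 0 or mad > 0) else 0.0
    if spread == 0.0:
        return max(phi, 1e-12) * 1e-12
    return phi * 0.9 * spread * n ** (-0.2)


def weighted_mode_estimate(
    ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0, grid_size: int = 2001
) -> float:
    """Maximizer of the inverse-variance-weighted gaussian KDE over ratios."""
    h = _mode_bandwidth(ratios, phi)
    if h <= 0 or np.ptp(ratios) == 0:
        return float(ratios[0])
    lo = ratios.min() - 3 * h
    hi = ratios.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.einsum(
        "j,ij->i", weights / weights.sum(),
        np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
    )
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    pairs: Sequence[HarmonizedPair],
    phi: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode estimate; SE by seeded parametric bootstrap."""
    _check(pairs, 3, WEIGHTED_MODE)
    ratios, weights = _ratio_weights(pairs)
    beta = weighted_mode_estimate(ratios, weights, phi)
    se = _bootstrap_se(
        pairs, lambda r, w: weighted_mode_estimate(r, w, phi), n_boot, seed
    )
    return _estimate(WEIGHTED_MODE, beta, se, len(pairs))


def cochrans_q(
    pairs: Sequence[HarmonizedPair], reference: MREstimate
) -> tuple[float, int, float]:
    """Heterogeneity of per-SNP ratios around a reference estimate.

    Q = Σ wᵢ (bᵢ − b_ref)² with first-order weights; df = n − 1.
    """
    _check(pairs, 2, "cochrans_q")
    ratios, weights = _ratio_weights(pairs)
    q = float(np.sum(weights * (ratios - reference.beta_xy) ** 2))
    df = len(pairs) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def leave_one_out(pairs: Sequence[HarmonizedPair]) -> list[dict]:
    """IVW re-estimated with each SNP omitted, plus the all-SNP row.

    Rows are plot-ready dicts with ``omitted`` set to the left-out variant_id
    (or "none" for the full set). With exactly 3 pairs the leave-one-out rows
    fall back to the Wald ratio of the remaining pair when only one survives.
    """
    _check(pairs, 3, "leave_one_out")
    rows = []
    for i, p in enumerate(pairs):
        rest = [q for j, q in enumerate(pairs) if j != i]
        est = ivw(rest) if len(rest) >= 2 else wald_ratio(rest[0])
        rows.append(_loo_row(p.variant_id, est))
    rows.append(_loo_row("none", ivw(pairs)))
    return rows


def _loo_row(omitted: str, est: MREstimate) -> dict:
    return {
        "omitted": omitted,
        "beta_xy": est.beta_xy,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "n_snps": est.n_snps,
    }


def scale_binary_exposure(est: MREstimate, trait_type: str = "binary") -> MREstimate:
    """Rescale a per-log-odds estimate to per approximate doubling of liability.

    Multiplies the causal log-OR and its SE by ln 2 and recomputes CI and p.
    Only meaningful for binary (presence/absence) exposures.
    """
    if trait_type != "binary":
        raise EstimatorError("liability doubling scale applies to binary exposures only")
    if est.exposure_unit != "per_SD":
        raise EstimatorError("estimate already scaled")
    beta = est.beta_xy * LN2
    se = est.se * LN2
    return replace(
        est,
        beta_xy=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta / se) if se > 0 else est.pvalue,
        exposure_unit="per_doubling_liability",
    )


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """(OR, lower, upper) by exponentiating the estimate and its CI."""
    return math.exp(est.beta_xy), math.exp(est.ci_low), math.exp(est.ci_high)


def all_estimators(
    pairs: Sequence[HarmonizedPair], n_boot: int = 5000, seed: int = 0
) -> list[MREstimate]:
    """The battery used in sensitivity analyses for a multi-SNP instrument."""
    ests = [ivw(pairs)]
    if len(pairs) >= 3:
        ests.append(egger(pairs))
        ests.append(weighted_median(pairs, n_boot=n_boot, seed=seed))
        ests.append(weighted_mode(pairs, n_boot=n_boot, seed=seed + 1))
    return ests
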