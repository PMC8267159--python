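"""Causal-effect estimators for two-sample MR.

Implements the Wald ratio (single instrument), inverse-variance-weighted
combination, MR-Egger regression, and the weighted-median estimator, together
with the instrument-count dispatch rule used by the atlas pipeline:

* J == 1 -> Wald ratio only
* J == 2 -> IVW only
* J >= 3 -> IVW, MR-Egger, weighted median
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import CollinearityError, DispatchError, UndefinedRatioError
from .summary_data import HarmonizedInstrumentSet

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "run_all",
]

_Z95 = float(sps.norm.ppf(0.975))


@dataclass
class MREstimate:
    """One estimator's causal-effect result (log-odds per SD of exposure)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or": self.or_,
            "or_low": self.or_low,
            "or_high": self.or_high,
            "pval": self.pval,
        }
        d.update(self.extras)
        return d


def _require(h: HarmonizedInstrumentSet, min_j: int, method: str) -> None:
    if len(h) < min_j:
        raise DispatchError(
            f"{method} requires at least {min_j} instruments, got {len(h)}"
        )


def _check_gamma_nonzero(h: HarmonizedInstrumentSet) -> None:
    if np.any(h.gamma == 0):
        bad = [v for v, g in zip(h.variant_ids, h.gamma) if g == 0]
        raise UndefinedRatioError(f"zero exposure effect for {bad}")


def _normal_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def wald_ratio(h: HarmonizedInstrumentSet) -> MREstimate:
    """Single-instrument ratio estimate, Gamma / gamma.

    The SE uses the first-order delta method, ``se_y / |gamma|`` — adequate
    when the instrument is strong (large F), which holds for every single-SNP
    exposure this package targets.
    """
    if len(h) != 1:
        raise DispatchError(f"wald_ratio requires exactly 1 instrument, got {len(h)}")
    _check_gamma_nonzero(h)
    g = float(h.gamma[0])
    beta = float(h.Gamma[0]) / g
    se = float(h.se_y[0]) / abs(g)
    return MREstimate(
        method="wald_ratio",
        beta=beta,
        se=se,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        pval=_normal_p(beta / se),
        n_snp=1,
        extras={"variant_id": h.variant_ids[0]},
    )


def ivw(
    h: HarmonizedInstrumentSet,
    effects: str = "multiplicative",
    min_instruments: int = 2,
) -> MREstimate:
    """Inverse-variance-weighted combination of per-SNP Wald ratios.

    Equivalent to zero-intercept weighted least squares of ``Gamma`` on
    ``gamma`` with weights ``se_y**-2``. ``effects`` selects how Cochran's Q
    heterogeneity feeds the reported SE:

    * ``"fixed"`` — plain fixed-effect SE;
    * ``"multiplicative"`` (default) — fixed-effect SE inflated by
      ``max(1, sqrt(Q / (J - 1)))``;
    * ``"additive"`` — DerSimonian-Laird tau^2 on the ratio scale.

    Q and its degrees of freedom are always stored in ``extras`` along with
    the uninflated fixed-effect SE.
    """
    _require(h, min_instruments, "ivw")
    _check_gamma_nonzero(h)
    g, G, sy = h.gamma, h.Gamma, h.se_y
    w = sy**-2.0
    den = float(np.sum(g * g * w))
    beta = float(np.sum(g * G * w)) / den
    se_fixed = den**-0.5
    resid = G - beta * g
    q = float(np.sum(w * resid * resid))
    df = len(h) - 1
    q_pval = float(sps.chi2.sf(q, df)) if df > 0 else float("nan")

    if effects == "fixed":
        se = se_fixed
    elif effects == "multiplicative":
        se = se_fixed * max(1.0, math.sqrt(q / df)) if df > 0 else se_fixed
    elif effects == "additive":
        r = G / g
        w0 = g * g * w  # inverse ratio-variance weights
        sw = float(np.sum(w0))
        denom = sw - float(np.sum(w0 * w0)) / sw
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
        w1 = 1.0 / (1.0 / w0 + tau2)
        beta = float(np.sum(w1 * r)) / float(np.sum(w1))
        se = float(np.sum(w1)) ** -0.5
    else:
        raise ValueError(f"unknown effects model {effects!r}")

    return MREstimate(
        method="ivw",
        beta=beta,
        se=se,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        pval=_normal_p(beta / se),
        n_snp=len(h),
        extras={
            "q_stat": q,
            "q_df": df,
            "q_pval": q_pval,
            "se_fixed": se_fixed,
            "effects": effects,
        },
    )


def mr_egger(h: HarmonizedInstrumentSet) -> MREstimate:
    """MR-Egger: weighted regression of ``Gamma`` on ``gamma`` with a free
    intercept.

    Instruments are first oriented so every exposure effect is non-negative
    (joint sign flips leave ratio estimates unchanged). The slope is the
    pleiotropy-adjusted causal estimate; the intercept (stored in ``extras``)
    estimates the mean directional-pleiotropy effect. SEs carry a residual
    dispersion floored at 1 and inference uses a t distribution on J - 2 df.
    """
    _require(h, 3, "mr_egger")
    _check_gamma_nonzero(h)
    sign = np.sign(h.gamma)
    g = h.gamma * sign
    G = h.Gamma * sign
    if np.ptp(g) == 0:
        raise CollinearityError("all exposure effects identical; Egger fit degenerate")
    w = h.se_y**-2.0

    sw = float(np.sum(w))
    swg = float(np.sum(w * g))
    swgg = float(np.sum(w * g * g))
    swG = float(np.sum(w * G))
    swgG = float(np.sum(w * g * G))
    det = sw * swgg - swg * swg
    intercept = (swgg * swG - swg * swgG) / det
    slope = (sw * swgG - swg * swG) / det

    resid = G - intercept - slope * g
    df = len(h) - 2
    sigma2 = float(np.sum(w * resid * resid)) / df
    mult = max(1.0, math.sqrt(sigma2))  # dispersion floored at 1
    se_int = mult * math.sqrt(swgg / det)
    se_slope = mult * math.sqrt(sw / det)

    tq = float(sps.t.ppf(0.975, df))
    p_slope = float(2.0 * sps.t.sf(abs(slope / se_slope), df))
    p_int = float(2.0 * sps.t.sf(abs(intercept / se_int), df))
    return MREstimate(
        method="mr_egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pval=p_slope,
        n_snp=len(h),
        extras={
            "intercept": intercept,
            "intercept_se": se_int,
            "intercept_p": p_int,
            "dispersion": math.sqrt(sigma2),
            "df": df,
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(
    h: HarmonizedInstrumentSet, n_boot: int = 1000, *, seed: int
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP ratios get inverse-variance weights ``gamma**2 / se_y**2``; the
    estimate interpolates the sorted ratios at cumulative weight 0.5 and is
    consistent while valid instruments hold >50% of the weight. The SE
    resamples (gamma, Gamma) from normal(observed, SE) ``n_boot`` times; the
    seed is mandatory for reproducibility. The point estimate is
    deterministic — only the SE is stochastic.
    """
    _require(h, 3, "weighted_median")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    _check_gamma_nonzero(h)
    # orient gamma >= 0 so results are bit-identical under harmonization flips
    sign = np.sign(h.gamma)
    g = h.gamma * sign
    G = h.Gamma * sign
    sy = h.se_y
    sx = h.se_x

    beta = _weighted_median_point(G / g, g * g / (sy * sy))

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gs = g + rng.standard_normal(len(g)) * sx
        Gs = G + rng.standard_normal(len(g)) * sy
        gs = np.where(gs == 0, 1e-300, gs)
        boots[b] = _weighted_median_point(Gs / gs, gs * gs / (sy * sy))
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        pval=_normal_p(beta / se),
        n_snp=len(h),
        extras={"n_boot": n_boot, "seed": seed},
    )


def run_all(
    h: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> list[MREstimate]:
    """Run every estimator the instrument count permits.

    J = 1 -> [wald_ratio]; J = 2 -> [ivw]; J >= 3 -> [ivw, mr_egger,
    weighted_median]. The first element is the default headline estimate
    (see the pipeline for the Egger-substitution rule).
    """
    j = len(h)
    if j == 1:
        return [wald_ratio(h)]
    if j == 2:
        return [ivw(h)]
    return [ivw(h), mr_egger(h), weighted_median(h, n_boot=n_boot, seed=seed)]
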