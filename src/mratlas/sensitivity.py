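"""Sensitivity battery: single-SNP and leave-one-out analyses, Cochran's Q,
the Egger intercept (directional pleiotropy) test, funnel data, and the
MR-PRESSO global / outlier / distortion tests."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, ivw, mr_egger
from .summary_data import HarmonizedInstrumentSet

__all__ = [
    "single_snp",
    "leave_one_out",
    "cochran_q",
    "egger_intercept_test",
    "funnel_data",
    "presso_global",
    "presso_outlier",
    "presso_distortion",
    "presso",
    "PressoResult",
    "SensitivityReport",
    "sensitivity_report",
]


def single_snp(h: HarmonizedInstrumentSet) -> pd.DataFrame:
    """Per-SNP Wald ratio estimates (one row per instrument)."""
    beta = h.Gamma / h.gamma
    se = h.se_y / np.abs(h.gamma)
    z = beta / se
    return pd.DataFrame(
        {
            "variant_id": h.variant_ids,
            "beta": beta,
            "se": se,
            "pval": 2.0 * sps.norm.sf(np.abs(z)),
        }
    )


def leave_one_out(h: HarmonizedInstrumentSet) -> pd.DataFrame:
    """IVW re-estimated J times, omitting one instrument each time.

    Requires J >= 3 so every reduced set still supports IVW.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs >= 3 instruments, got {j}"
        )
    rows = []
    for k in range(j):
        est = ivw(h.subset([i for i in range(j) if i != k]))
        rows.append(
            {
                "omitted": h.variant_ids[k],
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(rows)


def cochran_q(h: HarmonizedInstrumentSet) -> tuple[float, int, float]:
    """Cochran's Q for heterogeneity around the fixed-effect IVW slope."""
    est = ivw(h, effects="fixed")
    return est.extras["q_stat"], est.extras["q_df"], est.extras["q_pval"]


def egger_intercept_test(h: HarmonizedInstrumentSet) -> tuple[float, float, float]:
    """(intercept, SE, two-sided t p-value on J-2 df) from the Egger fit.

    A non-zero intercept indicates directional pleiotropy.
    """
    est = mr_egger(h)
    ex = est.extras
    return ex["intercept"], ex["intercept_se"], ex["intercept_p"]


def funnel_data(h: HarmonizedInstrumentSet) -> pd.DataFrame:
    """Per-SNP (ratio estimate, precision) pairs for funnel plotting.

    Precision is the reciprocal of the ratio's first-order SE, |gamma|/se_y.
    Symmetry is judged against the Egger intercept test rather than a
    bespoke asymmetry statistic.
    """
    return pd.DataFrame(
        {
            "variant_id": h.variant_ids,
            "ratio": h.Gamma / h.gamma,
            "precision": np.abs(h.gamma) / h.se_y,
        }
    )


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    # leave-one-out IVW slope for each element, in closed form
    num = np.sum(g * G * w) - g * G * w
    den = np.sum(g * g * w) - g * g * w
    return num / den


def _sq_residuals(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    b = _loo_slopes(g, G, w)
    r = G - b * g
    return w * r * r


def _simulate_residuals(
    h: HarmonizedInstrumentSet, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Parametric null residuals, shape (n_sim, J).

    Each replicate redraws gamma* ~ N(gamma, se_x) and
    Gamma* ~ N(b_loo * gamma, se_y), then recomputes the leave-one-out
    weighted squared residuals exactly as for the observed data.
    """
    g, G, sx, sy = h.gamma, h.Gamma, h.se_x, h.se_y
    w = sy**-2.0
    b_loo = _loo_slopes(g, G, w)
    j = len(g)
    gs = g + rng.standard_normal((n_sim, j)) * sx
    Gs = b_loo * g + rng.standard_normal((n_sim, j)) * sy
    num_tot = np.sum(gs * Gs * w, axis=1, keepdims=True)
    den_tot = np.sum(gs * gs * w, axis=1, keepdims=True)
    b_sim = (num_tot - gs * Gs * w) / (den_tot - gs * gs * w)
    r = Gs - b_sim * gs
    return w * r * r


def _require_presso(h: HarmonizedInstrumentSet, n_sim: int) -> None:
    if len(h) < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs >= 4 instruments, got {len(h)}"
        )
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")


def presso_global(
    h: HarmonizedInstrumentSet, n_sim: int = 1000, *, seed: int
) -> tuple[float, float]:
    """MR-PRESSO global test for horizontal pleiotropy.

    The observed statistic is the sum over instruments of the weighted
    squared residual from the leave-one-out IVW fit; its null distribution is
    built by ``n_sim`` parametric simulations. Returns
    ``(rss_obs, global_p)`` with the add-one p-value
    ``(1 + #{RSS* >= rss_obs}) / (n_sim + 1)``, so the p-value can never fall
    below ``1 / (n_sim + 1)``.
    """
    _require_presso(h, n_sim)
    w = h.se_y**-2.0
    rss_obs = float(np.sum(_sq_residuals(h.gamma, h.Gamma, w)))
    sim = _simulate_residuals(h, n_sim, np.random.default_rng(seed))
    rss_sim = sim.sum(axis=1)
    global_p = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    return rss_obs, global_p


def presso_outlier(
    h: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    *,
    seed: int,
    alpha: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """MR-PRESSO outlier test.

    Per-SNP p-values are the tail frequencies of each SNP's simulated squared
    residual against its observed one, Bonferroni-adjusted by J. Returns
    ``(adjusted p-values, flagged variant IDs)``. Intended to run only after
    a significant global test (the pipeline enforces that conditional logic).
    """
    _require_presso(h, n_sim)
    w = h.se_y**-2.0
    d_obs = _sq_residuals(h.gamma, h.Gamma, w)
    sim = _simulate_residuals(h, n_sim, np.random.default_rng(seed))
    p_raw = (1.0 + np.sum(sim >= d_obs[None, :], axis=0)) / (n_sim + 1.0)
    p_adj = np.minimum(1.0, p_raw * len(h))
    outliers = [v for v, p in zip(h.variant_ids, p_adj) if p < alpha]
    return p_adj, outliers


def presso_distortion(
    h: HarmonizedInstrumentSet,
    outliers: list[str],
    n_sim: int = 1000,
    *,
    seed: int,
) -> tuple[float, float]:
    """MR-PRESSO distortion test.

    The distortion statistic is ``100 * (beta_corrected - beta_raw) /
    |beta_corrected|`` (percent change after outlier removal). The null
    removes ``len(outliers)`` instruments drawn uniformly at random from the
    NON-outlier set ``n_sim`` times and recomputes the same statistic; the
    p-value is the two-sided tail frequency with the add-one correction.
    (Sampling from the non-outliers matches the reference implementation of
    the test and keeps a dominant outlier detectable.)
    """
    j = len(h)
    m = len(outliers)
    if m == 0:
        raise ValueError("distortion test requires a non-empty outlier set")
    if m >= j - 1:
        raise ValueError("outlier removal would leave fewer than 2 instruments")
    unknown = set(outliers) - set(h.variant_ids)
    if unknown:
        raise ValueError(f"outliers not in instrument set: {sorted(unknown)}")

    beta_raw = ivw(h).beta
    beta_corr = ivw(h.drop_ids(outliers)).beta
    d_obs = 100.0 * (beta_corr - beta_raw) / abs(beta_corr)

    rng = np.random.default_rng(seed)
    d_null = np.empty(n_sim)
    idx_all = np.arange(j)
    outlier_set = set(outliers)
    idx_clean = np.array(
        [i for i in range(j) if h.variant_ids[i] not in outlier_set]
    )
    if m > idx_clean.size:
        raise ValueError("more outliers than non-outlier instruments")
    for s in range(n_sim):
        removed = rng.choice(idx_clean, size=m, replace=False)
        keep = np.setdiff1d(idx_all, removed)
        b_sub = ivw(h.subset(keep)).beta
        d_null[s] = 100.0 * (b_sub - beta_raw) / abs(b_sub)
    p = (1.0 + float(np.sum(np.abs(d_null) >= abs(d_obs)))) / (n_sim + 1.0)
    return d_obs, p


@dataclass
class PressoResult:
    """Outcome of the three-stage MR-PRESSO battery."""

    rss_obs: float
    global_p: float
    n_sim: int
    outlier_p: np.ndarray | None = None
    outliers: list[str] = field(default_factory=list)
    beta_raw: MREstimate | None = None
    beta_corrected: MREstimate | None = None
    distortion: float | None = None
    distortion_p: float | None = None
    outlier_performed: bool = False
    distortion_performed: bool = False


def presso(
    h: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    *,
    seed: int,
    global_alpha: float = 0.05,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Run the full conditional MR-PRESSO battery.

    The outlier test runs only when the global test is significant at
    ``global_alpha``; the distortion test only when outliers are flagged and
    enough instruments remain.
    """
    rss_obs, global_p = presso_global(h, n_sim, seed=seed)
    res = PressoResult(
        rss_obs=rss_obs, global_p=global_p, n_sim=n_sim, beta_raw=ivw(h)
    )
    if global_p >= global_alpha:
        return res
    res.outlier_performed = True
    # same seed as the global stage -> shared simulated residual stream
    res.outlier_p, res.outliers = presso_outlier(
        h, n_sim, seed=seed, alpha=outlier_alpha
    )
    if not res.outliers:
        return res
    if len(res.outliers) >= len(h) - 1:
        return res  # no corrected estimate possible; flags still reported
    res.beta_corrected = ivw(h.drop_ids(res.outliers))
    res.distortion_performed = True
    res.distortion, res.distortion_p = presso_distortion(
        h, res.outliers, n_sim, seed=seed + 1
    )
    return res


@dataclass
class SensitivityReport:
    """Everything the sensitivity battery produces for one trait pair."""

    single_snp: pd.DataFrame | None = None
    loo: pd.DataFrame | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    funnel: pd.DataFrame | None = None
    presso: PressoResult | None = None

    def summary_lines(self) -> list[str]:
        lines = []
        if self.q_stat is not None:
            lines.append(
                f"Cochran Q = {self.q_stat:.3f} on {self.q_df} df "
                f"(p = {self.q_pval:.3g})"
            )
        if self.egger_intercept is not None:
            lines.append(
                f"Egger intercept = {self.egger_intercept:.4f} "
                f"(SE {self.egger_intercept_se:.4f}, p = {self.egger_intercept_p:.3g})"
            )
        if self.presso is not None:
            p = self.presso
            lines.append(f"MR-PRESSO global p = {p.global_p:.4g}")
            if p.outlier_performed:
                lines.append(f"MR-PRESSO outliers: {p.outliers or 'none'}")
            if p.distortion_performed:
                lines.append(
                    f"MR-PRESSO distortion = {p.distortion:.2f}% "
                    f"(p = {p.distortion_p:.3g})"
                )
        return lines

    def write(self, path: str | Path) -> None:
        """Serialize as a multi-section TSV bundle (sections start with '#')."""
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for line in self.summary_lines():
                fh.write(f"# {line}\n")
            for name, table in (
                ("single_snp", self.single_snp),
                ("leave_one_out", self.loo),
                ("funnel", self.funnel),
            ):
                if table is not None:
                    fh.write(f"#section {name}\n")
                    table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def sensitivity_report(
    h: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    *,
    seed: int,
) -> SensitivityReport:
    """Run every sensitivity analysis the instrument count permits.

    single-SNP and funnel need J >= 1 (reported whenever J >= 2 to be
    meaningful), leave-one-out / Q / Egger intercept need J >= 3, and
    MR-PRESSO needs J >= 4.
    """
    rep = SensitivityReport()
    j = len(h)
    if j >= 2:
        rep.single_snp = single_snp(h)
        rep.funnel = funnel_data(h)
        rep.q_stat, rep.q_df, rep.q_pval = cochran_q(h)
    if j >= 3:
        rep.loo = leave_one_out(h)
        (
            rep.egger_intercept,
            rep.egger_intercept_se,
            rep.egger_intercept_p,
        ) = egger_intercept_test(h)
    if j >= 4:
        rep.presso = presso(h, n_sim, seed=seed)
    return rep
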