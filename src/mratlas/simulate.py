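"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works entirely on the summary level: exposure effects are drawn
per-SD, outcome effects on the log-odds scale with SEs implied by the
case/control composition, and the causal model is

    Gamma_j = beta * gamma_j + alpha_j (+ outlier offset) + noise

with alpha_j = 0 for valid instruments. Pleiotropy can be balanced or
directional and can violate the InSIDE condition (alpha correlated with
instrument strength). Everything is reproducible from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .summary_data import LDMatrix, SummaryStats, VariantAssociation

__all__ = [
    "PleiotropySpec",
    "GeneratorSpec",
    "SyntheticTruth",
    "simulate_gwas_pair",
    "simulate_ld_matrix",
    "make_atlas_fixture",
    "simulate_directed_pair",
]

# non-palindromic allele pairs only, so harmonization never drops a variant
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass(frozen=True)
class PleiotropySpec:
    """Horizontal-pleiotropy configuration for the invalid fraction."""

    fraction: float = 0.0
    mu: float = 0.0  # mean direct effect (directional when != 0)
    tau: float = 0.0  # SD of direct effects
    inside: bool = True  # False -> alpha scales with instrument strength

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one simulated exposure/outcome pair."""

    j: int = 30
    beta: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_exposure: int = 50_000
    n_cases: int = 11_348
    n_controls: int = 15_861
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    outliers: tuple[tuple[int, float], ...] = ()
    #: range of true standardized instrument effects (|gamma|/se_x); the lower
    #: bound controls the probability of passing genome-wide significance.
    gamma_z_range: tuple[float, float] = (10.0, 20.0)
    #: with random signs, directional pleiotropy cancels in the oriented
    #: frame; set False (all exposure-increasing coding) to study it.
    random_gamma_sign: bool = True
    #: separate strength range for invalid instruments (None = same as valid);
    #: a lower range keeps the invalid fraction a minority of the IVW weight,
    #: the regime where the weighted median stays consistent.
    invalid_z_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j < 1:
            raise ValueError("j must be >= 1")
        if min(self.n_exposure, self.n_cases, self.n_controls) <= 0:
            raise ValueError("sample sizes must be positive")
        for idx, _ in self.outliers:
            if not (0 <= idx < self.j):
                raise ValueError(f"outlier index {idx} outside [0, {self.j})")


@dataclass
class SyntheticTruth:
    """The generating parameters realized for one simulated dataset."""

    spec: GeneratorSpec
    gamma_true: np.ndarray
    alpha: np.ndarray
    invalid_idx: np.ndarray
    outlier_idx: np.ndarray
    maf: np.ndarray
    se_x: np.ndarray
    se_y: np.ndarray


def _variant_records(
    ids, chroms, poss, eas, oas, maf, beta, se, n
) -> list[VariantAssociation]:
    from scipy import stats as sps

    pvals = 2.0 * sps.norm.sf(np.abs(beta / se))
    return [
        VariantAssociation(
            variant_id=ids[i],
            chrom=chroms[i],
            pos=int(poss[i]),
            effect_allele=eas[i],
            other_allele=oas[i],
            eaf=float(maf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pval=float(max(pvals[i], 1e-300)),
            n=n,
        )
        for i in range(len(ids))
    ]


def _layout(j: int, prefix: str) -> tuple[list[str], list[str], np.ndarray]:
    """Variant IDs and genome layout; SNPs are spaced far apart so default
    clumping never collapses them."""
    ids = [f"{prefix}rs{i + 1}" for i in range(j)]
    chroms = [str(i % 22 + 1) for i in range(j)]
    poss = 1_000_000 + (np.arange(j) // 22) * 50_000_000
    return ids, chroms, poss


def simulate_gwas_pair(
    spec: GeneratorSpec, id_prefix: str = ""
) -> tuple[SummaryStats, SummaryStats, SyntheticTruth]:
    """Simulate one exposure/outcome summary-statistics pair.

    The exposure SE is ``1 / sqrt(2 maf (1 - maf) n_exposure)`` (per-SD
    scale) and the outcome SE is the log-odds analogue
    ``1 / sqrt(2 maf (1 - maf) N K(1 - K))``. Outlier offsets are expressed
    in units of the affected SNP's outcome SE.
    """
    rng = np.random.default_rng(spec.seed)
    j = spec.j
    maf = rng.uniform(*spec.maf_range, size=j)
    het = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(het * spec.n_exposure)
    n_out = spec.n_cases + spec.n_controls
    kvar = spec.n_cases * spec.n_controls / n_out**2
    se_y = 1.0 / np.sqrt(het * n_out * kvar)

    z = rng.uniform(*spec.gamma_z_range, size=j)

    plei = spec.pleiotropy
    n_invalid = int(round(plei.fraction * j))
    invalid_idx = rng.choice(j, size=n_invalid, replace=False) if n_invalid else (
        np.empty(0, dtype=int)
    )
    if n_invalid and spec.invalid_z_range is not None:
        z[invalid_idx] = rng.uniform(*spec.invalid_z_range, size=n_invalid)
    if spec.random_gamma_sign:
        z = z * rng.choice([-1.0, 1.0], size=j)
    gamma_true = z * se_x

    alpha = np.zeros(j)
    if n_invalid:
        direct = plei.mu + plei.tau * rng.standard_normal(n_invalid)
        if not plei.inside:
            # violate InSIDE: scale direct effects with instrument strength
            strength = np.abs(gamma_true[invalid_idx])
            direct = direct * strength / strength.mean()
        alpha[invalid_idx] = direct

    Gamma_true = spec.beta * gamma_true + alpha
    outlier_idx = np.array([k for k, _ in spec.outliers], dtype=int)
    for k, offset in spec.outliers:
        Gamma_true[k] += offset * se_y[k]

    gamma_hat = gamma_true + rng.standard_normal(j) * se_x
    Gamma_hat = Gamma_true + rng.standard_normal(j) * se_y

    ids, chroms, poss = _layout(j, id_prefix)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=j)
    eas = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oas = [_ALLELE_PAIRS[i][1] for i in pair_idx]

    exposure = SummaryStats(
        trait_name=f"{id_prefix or 'sim'}_exposure",
        records=_variant_records(
            ids, chroms, poss, eas, oas, maf, gamma_hat, se_x, spec.n_exposure
        ),
        trait_type="continuous",
    )
    outcome = SummaryStats(
        trait_name=f"{id_prefix or 'sim'}_outcome",
        records=_variant_records(
            ids, chroms, poss, eas, oas, maf, Gamma_hat, se_y, n_out
        ),
        trait_type="binary",
        n_cases=spec.n_cases,
        n_controls=spec.n_controls,
    )
    truth = SyntheticTruth(
        spec=spec,
        gamma_true=gamma_true,
        alpha=alpha,
        invalid_idx=np.sort(invalid_idx),
        outlier_idx=outlier_idx,
        maf=maf,
        se_x=se_x,
        se_y=se_y,
    )
    return exposure, outcome, truth


def simulate_ld_matrix(
    block_sizes: list[int],
    rho: float,
    spacing_bp: int = 10_000,
    chrom: str = "1",
    id_prefix: str = "ld_",
) -> LDMatrix:
    """Block-diagonal LD with AR(1) decay inside each block.

    Within a block, r between positions i and j is ``rho ** |i - j|`` so
    r^2 decays as ``rho ** (2 |i - j|)``; the matrix is positive
    semi-definite by construction. Positions advance by ``spacing_bp`` within
    and between blocks on a single chromosome.
    """
    if any(b < 1 for b in block_sizes):
        raise ValueError("block sizes must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    n = sum(block_sizes)
    r2 = np.zeros((n, n))
    start = 0
    for b in block_sizes:
        idx = np.arange(b)
        block_r = rho ** np.abs(idx[:, None] - idx[None, :])
        r2[start : start + b, start : start + b] = block_r**2
        start += b
    np.fill_diagonal(r2, 1.0)
    ids = [f"{id_prefix}rs{i + 1}" for i in range(n)]
    positions = 1_000_000 + np.arange(n) * spacing_bp
    return LDMatrix(ids, r2, positions=positions)


def _required_beta(
    r_squared: float, n_outcome: int, kvar: float, alpha: float, target_power: float
) -> float:
    from scipy import stats as sps

    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    z_pow = sps.norm.ppf(target_power)
    return float((z_crit + z_pow) / np.sqrt(n_outcome * r_squared * kvar))


def make_atlas_fixture(
    n_traits: int,
    n_significant: int,
    seed: int,
    j: int = 30,
    n_exposure: int = 50_000,
    n_cases: int = 11_348,
    n_controls: int = 15_861,
    target_power: float = 0.995,
    max_beta: float = 0.5,
) -> tuple[dict[str, SummaryStats], SummaryStats, pd.DataFrame]:
    """A miniature trait panel with exactly ``n_significant`` true effects.

    Causal effects for the truth-positive traits are sized so their analytic
    power at the panel's Bonferroni threshold exceeds ``target_power``; the
    remaining traits are null. Returns ``(exposure panel, pooled outcome
    panel, truth table)``. Raises when the requested power is unattainable
    without exceeding ``max_beta``, naming the limiting parameter.
    """
    if n_significant > n_traits:
        raise ValueError("n_significant cannot exceed n_traits")
    rng = np.random.default_rng(seed)
    positive = set(rng.choice(n_traits, size=n_significant, replace=False).tolist())

    n_out = n_cases + n_controls
    alpha_bonf = 0.05 / n_traits
    # conservative R^2 bound from the weakest admissible instrument draws
    z_lo = 10.0
    r2_min = j * z_lo**2 / n_exposure
    beta_needed = _required_beta(r2_min, n_out, 0.25, alpha_bonf, target_power)
    if beta_needed > max_beta:
        raise ValueError(
            "infeasible power request: detecting the Bonferroni-corrected "
            f"effect with power {target_power} needs |beta| = {beta_needed:.3f} "
            f"> max_beta = {max_beta}; limiting parameter: n_exposure/j "
            f"(instrument R^2 = {r2_min:.4f})"
        )

    panel: dict[str, SummaryStats] = {}
    outcome_records: list[VariantAssociation] = []
    rows = []
    for t in range(n_traits):
        name = f"trait_{t + 1:02d}"
        beta_true = beta_needed * 1.2 if t in positive else 0.0
        spec = GeneratorSpec(
            j=j,
            beta=beta_true,
            n_exposure=n_exposure,
            n_cases=n_cases,
            n_controls=n_controls,
            seed=derive_seed(seed, "atlas_fixture", name),
        )
        exposure, outcome, _truth = simulate_gwas_pair(spec, id_prefix=f"{name}_")
        exposure = replace(exposure, trait_name=name)
        panel[name] = exposure
        outcome_records.extend(outcome.records)
        rows.append(
            {"trait": name, "beta_true": beta_true, "is_positive": t in positive}
        )

    outcome_panel = SummaryStats(
        trait_name="outcome",
        records=outcome_records,
        trait_type="binary",
        n_cases=n_cases,
        n_controls=n_controls,
    )
    return panel, outcome_panel, pd.DataFrame(rows)


def simulate_directed_pair(
    beta_ab: float,
    seed: int,
    j: int = 30,
    n_sample: int = 50_000,
) -> tuple[SummaryStats, SummaryStats]:
    """Two trait GWAS panels with a one-way causal effect A -> B.

    Each panel covers both traits' instrument SNPs, so MR can be run in both
    directions: A's instruments show effect ``beta_ab`` on B, while B's
    instruments show no effect on A.
    """
    rng = np.random.default_rng(seed)

    def draw(prefix: str, child_seed: int):
        sub = np.random.default_rng(child_seed)
        maf = sub.uniform(0.1, 0.5, size=j)
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_sample)
        # moderate strength keeps the induced cross-trait effects (beta_ab *
        # gamma) below genome-wide significance in the reverse direction
        z = sub.uniform(10.0, 12.0, size=j) * sub.choice([-1.0, 1.0], size=j)
        ids, chroms, poss = _layout(j, prefix)
        pair_idx = sub.integers(0, len(_ALLELE_PAIRS), size=j)
        eas = [_ALLELE_PAIRS[i][0] for i in pair_idx]
        oas = [_ALLELE_PAIRS[i][1] for i in pair_idx]
        return maf, se, z * se, ids, chroms, poss, eas, oas

    maf_a, se_a, gam_a, ids_a, chr_a, pos_a, ea_a, oa_a = draw(
        "A_", derive_seed(seed, "pair", "A")
    )
    maf_b, se_b, gam_b, ids_b, chr_b, pos_b, ea_b, oa_b = draw(
        "B_", derive_seed(seed, "pair", "B")
    )

    # panel A: own instruments strong; B's instruments null on A (no B -> A)
    beta_a_own = gam_a + rng.standard_normal(j) * se_a
    beta_a_bsnps = rng.standard_normal(j) * se_b
    # panel B: own instruments strong; A's instruments carry beta_ab * gamma_A
    beta_b_own = gam_b + rng.standard_normal(j) * se_b
    beta_b_asnps = beta_ab * gam_a + rng.standard_normal(j) * se_a

    panel_a = SummaryStats(
        trait_name="trait_A",
        records=(
            _variant_records(ids_a, chr_a, pos_a, ea_a, oa_a, maf_a, beta_a_own, se_a, n_sample)
            + _variant_records(ids_b, chr_b, pos_b, ea_b, oa_b, maf_b, beta_a_bsnps, se_b, n_sample)
        ),
    )
    panel_b = SummaryStats(
        trait_name="trait_B",
        records=(
            _variant_records(ids_b, chr_b, pos_b, ea_b, oa_b, maf_b, beta_b_own, se_b, n_sample)
            + _variant_records(ids_a, chr_a, pos_a, ea_a, oa_a, maf_a, beta_b_asnps, se_a, n_sample)
        ),
    )
    return panel_a, panel_b
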