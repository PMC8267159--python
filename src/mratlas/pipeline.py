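"""Atlas orchestration: all exposures x outcomes, estimator dispatch,
sensitivity battery, power diagnostics, Bonferroni tiering, and the
bidirectional causal network among significant traits."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from ._utils import derive_seed
from .errors import (
    HarmonizationError,
    MRAtlasError,
    NoInstrumentsError,
)
from .estimators import MREstimate, run_all
from .power import OutcomeMeta, PowerProfile, power_profile
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_data import (
    GENOME_WIDE_P,
    LDMatrix,
    SummaryStats,
    harmonize,
    ld_clump,
    select_instruments,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeSpec",
    "AtlasConfig",
    "AtlasResult",
    "AtlasRun",
    "classify_tier",
    "bonferroni_threshold",
    "run_pair",
    "run_atlas",
    "build_network",
    "network_edge_table",
]

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NULL = "null"


@dataclass
class OutcomeSpec:
    """One outcome GWAS with its case/control composition."""

    name: str
    stats: SummaryStats
    n_cases: int
    n_controls: int

    @property
    def meta(self) -> OutcomeMeta:
        return OutcomeMeta(self.name, self.n_cases, self.n_controls)


@dataclass
class AtlasConfig:
    """Everything one atlas run needs."""

    exposures: dict[str, SummaryStats]
    outcomes: list[OutcomeSpec]
    ld: LDMatrix | None = None
    p_instrument: float = GENOME_WIDE_P
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    #: number of traits behind the Bonferroni correction; defaults to the
    #: panel size (the reference analysis used 60).
    n_traits_bonferroni: int | None = None
    master_seed: int = 0
    n_boot: int = 1000
    n_sim: int = 1000
    network_alpha: float = 0.05
    #: substitute the Egger slope as headline when its intercept test is
    #: significant (directional pleiotropy detected)
    egger_substitution: bool = True
    egger_intercept_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValueError("need at least one exposure and one outcome")
        if not (0.0 < self.p_instrument < 1.0):
            raise ValueError("p_instrument must lie in (0, 1)")

    @property
    def n_tests(self) -> int:
        return self.n_traits_bonferroni or len(self.exposures)


def bonferroni_threshold(n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 0.05 / n_tests


def classify_tier(pval: float, n_tests: int) -> str:
    """significant if p < 0.05/n_tests; suggestive if in [0.05/n_tests, 0.05);
    null otherwise (p = 0.05 is null — strict upper bound)."""
    if not (0.0 < pval <= 1.0):
        raise ValueError(f"pval {pval} outside (0, 1]")
    cut = bonferroni_threshold(n_tests)
    if pval < cut:
        return TIER_SIGNIFICANT
    if pval < 0.05:
        return TIER_SUGGESTIVE
    return TIER_NULL


@dataclass
class AtlasResult:
    """Everything computed for one (exposure, outcome) pair."""

    exposure: str
    outcome: str
    status: str = "ok"  # "ok" | "not_analyzable"
    reason: str = ""
    n_snp: int = 0
    estimates: list[MREstimate] = field(default_factory=list)
    headline: MREstimate | None = None
    sensitivity: SensitivityReport | None = None
    power: PowerProfile | None = None
    tier: str = ""


def _pick_headline(
    estimates: list[MREstimate], config: AtlasConfig
) -> MREstimate:
    headline = estimates[0]  # wald (J=1) or ivw
    if config.egger_substitution:
        for est in estimates:
            if (
                est.method == "mr_egger"
                and est.extras["intercept_p"] < config.egger_intercept_alpha
            ):
                headline = est
                break
    return headline


def run_pair(
    exposure: SummaryStats, outcome: OutcomeSpec, config: AtlasConfig
) -> AtlasResult:
    """Select -> clump -> harmonize -> estimate -> sensitivity -> power -> tier
    for a single pair. Failures that make the pair unanalyzable are captured
    in the result rather than raised."""
    res = AtlasResult(exposure=exposure.trait_name, outcome=outcome.name)
    seed = derive_seed(config.master_seed, exposure.trait_name, outcome.name)
    try:
        instruments = select_instruments(exposure, config.p_instrument)
        instruments = ld_clump(
            instruments, config.ld, config.clump_r2, config.clump_window_kb
        )
        h = harmonize(instruments, outcome.stats)
    except (NoInstrumentsError, HarmonizationError) as exc:
        res.status = "not_analyzable"
        res.reason = str(exc)
        logger.warning("%s vs %s: %s", exposure.trait_name, outcome.name, exc)
        return res

    res.n_snp = len(h)
    res.estimates = run_all(h, n_boot=config.n_boot, seed=seed)
    res.headline = _pick_headline(res.estimates, config)
    res.sensitivity = sensitivity_report(h, n_sim=config.n_sim, seed=seed + 1)
    try:
        res.power = power_profile(instruments, outcome.meta)
    except ValueError as exc:  # e.g. missing eaf
        logger.info("power profile unavailable for %s: %s", exposure.trait_name, exc)
    res.tier = classify_tier(res.headline.pval, config.n_tests)
    return res


@dataclass
class AtlasRun:
    """Results of one full atlas run."""

    config: AtlasConfig
    results: dict[tuple[str, str], AtlasResult]

    @property
    def bonferroni(self) -> float:
        return bonferroni_threshold(self.config.n_tests)

    def significant_traits(self, outcome_name: str | None = None) -> list[str]:
        if outcome_name is None:
            outcome_name = self.config.outcomes[0].name
        return [
            r.exposure
            for (_, out), r in self.results.items()
            if out == outcome_name and r.tier == TIER_SIGNIFICANT
        ]

    def results_table(self) -> pd.DataFrame:
        """One row per (exposure, outcome, method); headline rows flagged."""
        rows = []
        for (exp, out), r in self.results.items():
            if r.status != "ok":
                rows.append(
                    {
                        "exposure": exp,
                        "outcome": out,
                        "status": r.status,
                        "reason": r.reason,
                    }
                )
                continue
            for est in r.estimates:
                rows.append(
                    {
                        "exposure": exp,
                        "outcome": out,
                        "status": "ok",
                        "reason": "",
                        "method": est.method,
                        "headline": est is r.headline,
                        "tier": r.tier if est is r.headline else "",
                        "n_snp": est.n_snp,
                        "beta": est.beta,
                        "se": est.se,
                        "or": est.or_,
                        "or_low": est.or_low,
                        "or_high": est.or_high,
                        "pval": est.pval,
                        "q_stat": est.extras.get("q_stat"),
                        "q_df": est.extras.get("q_df"),
                        "egger_intercept": est.extras.get("intercept"),
                        "egger_intercept_p": est.extras.get("intercept_p"),
                    }
                )
        return pd.DataFrame(rows)

    def write_results_tsv(self, path) -> None:
        self.results_table().to_csv(
            path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
        )

    def run_metadata(self) -> dict:
        return {
            "n_exposures": len(self.config.exposures),
            "n_outcomes": len(self.config.outcomes),
            "n_tests_bonferroni": self.config.n_tests,
            "bonferroni_threshold": self.bonferroni,
            "bonferroni_threshold_printed": f"{self.bonferroni:.4f}",
            "p_instrument": self.config.p_instrument,
            "clump_r2": self.config.clump_r2,
            "clump_window_kb": self.config.clump_window_kb,
            "master_seed": self.config.master_seed,
        }


def run_atlas(config: AtlasConfig) -> AtlasRun:
    """Run every exposure against every outcome.

    Per-pair failures are isolated: a trait whose instruments vanish is
    reported as not analyzable and the pipeline continues. Deterministic
    given the master seed.
    """
    results: dict[tuple[str, str], AtlasResult] = {}
    for name in sorted(config.exposures):
        for outcome in config.outcomes:
            try:
                res = run_pair(config.exposures[name], outcome, config)
            except MRAtlasError as exc:  # defensive: isolate per-pair failures
                res = AtlasResult(
                    exposure=name,
                    outcome=outcome.name,
                    status="not_analyzable",
                    reason=f"unexpected: {exc}",
                )
                logger.error("%s vs %s failed: %s", name, outcome.name, exc)
            results[(name, outcome.name)] = res
    return AtlasRun(config=config, results=results)


def build_network(
    panels: dict[str, SummaryStats],
    significant: list[str],
    config: AtlasConfig,
    atlas_run: AtlasRun | None = None,
    outcome_name: str | None = None,
) -> nx.DiGraph:
    """Bidirectional MR network among significant traits.

    For every ordered pair of significant traits, the MR pipeline runs with
    one as exposure and the other as outcome (each trait's GWAS panel serves
    as the outcome panel for the others); a directed edge is added when the
    headline p-value is below ``config.network_alpha`` (nominal — no
    multiplicity correction). When an atlas run is supplied, edges from each
    significant trait to the disease outcome are added as well. Trait pairs
    with no usable instruments are skipped and logged. No self-edges.
    """
    graph = nx.DiGraph()
    if outcome_name is None:
        outcome_name = config.outcomes[0].name
    graph.add_node(outcome_name, kind="outcome")
    for trait in significant:
        graph.add_node(trait, kind="trait")

    for src in significant:
        for dst in significant:
            if src == dst:
                continue
            try:
                instruments = select_instruments(panels[src], config.p_instrument)
                instruments = ld_clump(
                    instruments, config.ld, config.clump_r2, config.clump_window_kb
                )
                h = harmonize(instruments, panels[dst])
            except (NoInstrumentsError, HarmonizationError) as exc:
                logger.warning("network %s -> %s skipped: %s", src, dst, exc)
                continue
            seed = derive_seed(config.master_seed, "network", src, dst)
            estimates = run_all(h, n_boot=config.n_boot, seed=seed)
            est = _pick_headline(estimates, config)
            if est.pval < config.network_alpha:
                graph.add_edge(
                    src,
                    dst,
                    beta=est.beta,
                    se=est.se,
                    pval=est.pval,
                    sign=1 if est.beta > 0 else -1,
                    weight=abs(est.beta),
                    method=est.method,
                )

    if atlas_run is not None:
        for trait in significant:
            res = atlas_run.results.get((trait, outcome_name))
            if res is None or res.headline is None:
                continue
            est = res.headline
            graph.add_edge(
                trait,
                outcome_name,
                beta=est.beta,
                se=est.se,
                pval=est.pval,
                sign=1 if est.beta > 0 else -1,
                weight=abs(est.beta),
                method=est.method,
            )
    return graph


def network_edge_table(graph: nx.DiGraph) -> pd.DataFrame:
    """Edge list as a DataFrame: source target beta se pval sign method."""
    rows = [
        {
            "source": u,
            "target": v,
            "beta": d["beta"],
            "se": d["se"],
            "pval": d["pval"],
            "sign": d["sign"],
            "method": d["method"],
        }
        for u, v, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "beta", "se", "pval", "sign", "method"]
    )
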