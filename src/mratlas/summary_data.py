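"""GWAS summary statistics: I/O, validation, instrument selection, LD clumping,
and allele harmonization into estimator-ready instrument sets.

All downstream causal estimators consume a :class:`HarmonizedInstrumentSet`,
which carries, for each instrument, the variant-exposure effect ``gamma`` with
standard error ``se_x`` and the variant-outcome effect ``Gamma`` with standard
error ``se_y``, expressed for a common effect allele.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateVariantError,
    FormatError,
    HarmonizationError,
    NoInstrumentsError,
)

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Columns a summary-statistics TSV must provide, in canonical order.
REQUIRED_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: Effect-allele-frequency band inside which a palindromic variant's strand
#: cannot be called from frequency alone; such variants are dropped.
PALINDROMIC_EAF_BAND = (0.42, 0.58)

GENOME_WIDE_P = 5e-8


@dataclass
class VariantAssociation:
    """One variant's association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None = None

    def validation_errors(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            errs.append(f"invalid effect_allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            errs.append(f"invalid other_allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            errs.append("effect_allele equals other_allele")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            errs.append(f"eaf {self.eaf} outside [0, 1]")
        if not math.isfinite(self.beta):
            errs.append("non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            errs.append(f"se {self.se} not > 0")
        if not (0.0 < self.pval <= 1.0):
            errs.append(f"pval {self.pval} outside (0, 1]")
        if self.pos <= 0:
            errs.append(f"pos {self.pos} not positive")
        return errs

    @property
    def is_palindromic(self) -> bool:
        return self.other_allele == COMPLEMENT.get(self.effect_allele)


@dataclass
class SummaryStats:
    """All per-variant association records for one trait."""

    trait_name: str
    records: list[VariantAssociation]
    trait_type: str = "continuous"
    n_cases: int | None = None
    n_controls: int | None = None
    #: rows rejected during reading, as (row label, reason); not compared.
    rejected: list[tuple[str, str]] = field(
        default_factory=list, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.variant_id in seen:
                raise DuplicateVariantError(
                    f"duplicate variant_id {rec.variant_id!r} in trait "
                    f"{self.trait_name!r}"
                )
            seen.add(rec.variant_id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def by_id(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": r.eaf,
                    "beta": r.beta,
                    "se": r.se,
                    "pval": r.pval,
                    "n": r.n,
                }
            )
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def _parse_float(value: str, allow_missing: bool = False) -> float | None:
    if value is None or value == "" or value.upper() in ("NA", "NAN", "."):
        if allow_missing:
            return None
        raise ValueError("missing value")
    return float(value)


def read_summary_tsv(
    path: str | Path,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    The file must be UTF-8 with a header row containing at least
    :data:`REQUIRED_COLUMNS`; ``eaf`` and ``n`` may be ``NA``. Rows that
    violate the per-variant invariants are rejected individually and listed
    (with reasons) in ``SummaryStats.rejected``; structural problems raise.

    Raises
    ------
    FormatError
        If a required column is missing.
    DuplicateVariantError
        If the same ``variant_id`` appears twice.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[VariantAssociation] = []
    rejected: list[tuple[str, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        label = f"line {i} ({getattr(row, 'variant_id', '?')})"
        try:
            n_raw = _parse_float(row.n, allow_missing=True)
            rec = VariantAssociation(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(float(row.pos)),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                eaf=_parse_float(row.eaf, allow_missing=True),
                beta=_parse_float(row.beta),
                se=_parse_float(row.se),
                pval=_parse_float(row.pval),
                n=int(n_raw) if n_raw is not None else None,
            )
        except (ValueError, TypeError) as exc:
            rejected.append((label, f"unparseable field: {exc}"))
            continue
        errs = rec.validation_errors()
        if errs:
            rejected.append((label, "; ".join(errs)))
            continue
        records.append(rec)

    stats = SummaryStats(
        trait_name=trait_name or path.stem,
        records=records,
        trait_type=trait_type,
        n_cases=n_cases,
        n_controls=n_controls,
        rejected=rejected,
    )
    logger.info(
        "%s: read %d rows, rejected %d, retained %d",
        path,
        len(df),
        len(rejected),
        len(records),
    )
    return stats


def write_summary_tsv(stats: SummaryStats, path: str | Path) -> None:
    """Write ``stats`` in the canonical TSV layout (floats at full precision)."""
    path = Path(path)

    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, float):
            return format(x, ".17g")
        return str(x)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(REQUIRED_COLUMNS) + "\n")
        for r in stats.records:
            fh.write(
                "\t".join(
                    fmt(v)
                    for v in (
                        r.variant_id,
                        r.chrom,
                        r.pos,
                        r.effect_allele,
                        r.other_allele,
                        r.eaf,
                        r.beta,
                        r.se,
                        r.pval,
                        r.n,
                    )
                )
                + "\n"
            )


def select_instruments(
    stats: SummaryStats, p_threshold: float = GENOME_WIDE_P
) -> SummaryStats:
    """Keep records with ``pval`` strictly below ``p_threshold``.

    Raises :class:`NoInstrumentsError` when nothing survives, so an empty
    instrument set can never propagate silently.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold {p_threshold} outside (0, 1]")
    kept = [r for r in stats.records if r.pval < p_threshold]
    if not kept:
        raise NoInstrumentsError(
            f"trait {stats.trait_name!r}: no variants with p < {p_threshold:g}"
        )
    logger.info(
        "%s: %d/%d variants pass p < %g",
        stats.trait_name,
        len(kept),
        len(stats),
        p_threshold,
    )
    return replace(stats, records=kept, rejected=[])


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 shape does not match variant_ids")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 must be symmetric")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2_between(self, a: str, b: str) -> float | None:
        """r^2 between two variants, or None if either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read an LD matrix from a square file (header row + ID column) or a
    long-format triple file with columns ``id_a id_b r2``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) == ["id_a", "id_b", "r2"] and df.shape[1] == 3:
        ids = sorted(set(df["id_a"]).union(df["id_b"]))
        index = {v: i for i, v in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, v in df.itertuples(index=False):
            mat[index[a], index[b]] = v
            mat[index[b], index[a]] = v
        return LDMatrix(ids, mat)
    df = df.set_index(df.columns[0])
    return LDMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def ld_clump(
    stats: SummaryStats,
    ld: LDMatrix | None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
) -> SummaryStats:
    """Greedy LD clumping.

    Repeatedly keep the remaining variant with the lowest p-value (ties broken
    lexicographically by ID for determinism) and discard every remaining
    variant on the same chromosome within ``window_kb`` (center-to-center)
    whose r^2 with it exceeds ``r2_max``. Variants absent from ``ld`` are
    treated as independent, with a warning. Output is ordered by p ascending.
    """
    pending = sorted(stats.records, key=lambda r: (r.pval, r.variant_id))
    kept: list[VariantAssociation] = []
    window_bp = window_kb * 1000.0
    while pending:
        top = pending.pop(0)
        kept.append(top)
        survivors: list[VariantAssociation] = []
        for rec in pending:
            if rec.chrom == top.chrom and abs(rec.pos - top.pos) <= window_bp:
                r2 = ld.r2_between(top.variant_id, rec.variant_id) if ld else None
                if r2 is None and ld is not None:
                    logger.warning(
                        "clump: pair (%s, %s) missing from LD matrix; "
                        "treated as independent",
                        top.variant_id,
                        rec.variant_id,
                    )
                if r2 is not None and r2 > r2_max:
                    logger.debug(
                        "clump: %s discarded (r2=%.4g with %s)",
                        rec.variant_id,
                        r2,
                        top.variant_id,
                    )
                    continue
            survivors.append(rec)
        pending = survivors
    logger.info(
        "%s: clumping retained %d/%d variants (r2<=%g, window %g kb)",
        stats.trait_name,
        len(kept),
        len(stats),
        r2_max,
        window_kb,
    )
    return replace(stats, records=kept, rejected=[])


@dataclass(eq=False)
class HarmonizedInstrumentSet:
    """Instruments with exposure and outcome effects on a common effect allele.

    Arrays are parallel over the J instruments. ``gamma``/``se_x`` are the
    variant-exposure effects and SEs, ``Gamma``/``se_y`` the variant-outcome
    effects and SEs after allele alignment.
    """

    variant_ids: list[str]
    gamma: np.ndarray
    se_x: np.ndarray
    Gamma: np.ndarray
    se_y: np.ndarray
    effect_allele: list[str] = field(default_factory=list)
    other_allele: list[str] = field(default_factory=list)
    palindromic: np.ndarray | None = None
    flipped: np.ndarray | None = None
    exposure_name: str = ""
    outcome_name: str = ""
    dropped: list[tuple[str, str]] = field(
        default_factory=list, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        j = len(self.variant_ids)
        if j < 1:
            raise HarmonizationError("instrument set must contain at least one variant")
        for name in ("gamma", "se_x", "Gamma", "se_y"):
            if getattr(self, name).shape != (j,):
                raise ValueError(f"{name} must have shape ({j},)")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all standard errors must be > 0")
        if self.palindromic is None:
            self.palindromic = np.zeros(j, dtype=bool)
        if self.flipped is None:
            self.flipped = np.zeros(j, dtype=bool)
        if not self.effect_allele:
            self.effect_allele = ["A"] * j
        if not self.other_allele:
            self.other_allele = ["G"] * j

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HarmonizedInstrumentSet):
            return NotImplemented
        return (
            self.variant_ids == other.variant_ids
            and np.array_equal(self.gamma, other.gamma)
            and np.array_equal(self.se_x, other.se_x)
            and np.array_equal(self.Gamma, other.Gamma)
            and np.array_equal(self.se_y, other.se_y)
            and self.effect_allele == other.effect_allele
            and self.other_allele == other.other_allele
            and np.array_equal(self.palindromic, other.palindromic)
            and np.array_equal(self.flipped, other.flipped)
        )

    @classmethod
    def from_arrays(
        cls,
        gamma: Sequence[float],
        Gamma: Sequence[float],
        se_y: Sequence[float],
        se_x: Sequence[float] | None = None,
        variant_ids: Sequence[str] | None = None,
        **kwargs,
    ) -> "HarmonizedInstrumentSet":
        """Convenience constructor for tests and simulations."""
        gamma = np.asarray(gamma, dtype=float)
        if se_x is None:
            se_x = np.full_like(gamma, 1e-6)
        if variant_ids is None:
            variant_ids = [f"rs{i + 1}" for i in range(len(gamma))]
        return cls(
            variant_ids=list(variant_ids),
            gamma=gamma,
            se_x=np.asarray(se_x, dtype=float),
            Gamma=np.asarray(Gamma, dtype=float),
            se_y=np.asarray(se_y, dtype=float),
            **kwargs,
        )

    def subset(self, indices: Iterable[int]) -> "HarmonizedInstrumentSet":
        idx = np.asarray(list(indices), dtype=int)
        return HarmonizedInstrumentSet(
            variant_ids=[self.variant_ids[i] for i in idx],
            gamma=self.gamma[idx],
            se_x=self.se_x[idx],
            Gamma=self.Gamma[idx],
            se_y=self.se_y[idx],
            effect_allele=[self.effect_allele[i] for i in idx],
            other_allele=[self.other_allele[i] for i in idx],
            palindromic=self.palindromic[idx],
            flipped=self.flipped[idx],
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
        )

    def drop_ids(self, ids: Iterable[str]) -> "HarmonizedInstrumentSet":
        drop = set(ids)
        keep = [i for i, v in enumerate(self.variant_ids) if v not in drop]
        return self.subset(keep)


def _in_ambiguity_band(eaf: float) -> bool:
    lo, hi = PALINDROMIC_EAF_BAND
    return lo <= eaf <= hi


def harmonize(
    exposure: SummaryStats, outcome: SummaryStats
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect allele for every shared
    variant.

    Rules, applied per variant:

    * identical allele pair (same orientation) -> unchanged;
    * swapped alleles -> outcome beta sign-flipped, eaf complemented;
    * strand-complement (and complement+swap) pairs -> resolved analogously;
    * palindromic (A/T, C/G) variants -> orientation called from effect-allele
      frequencies when both lie outside the ambiguity band
      :data:`PALINDROMIC_EAF_BAND` (discordant frequencies imply a flip);
      otherwise dropped;
    * irreconcilable allele pairs -> dropped.

    Dropped variants are reported in ``HarmonizedInstrumentSet.dropped``.
    Harmonizing an already-aligned pair is a no-op.
    """
    out_by_id = outcome.by_id()
    shared = [r for r in exposure.records if r.variant_id in out_by_id]
    if not shared:
        raise HarmonizationError(
            f"no shared variants between {exposure.trait_name!r} "
            f"and {outcome.trait_name!r}"
        )

    ids: list[str] = []
    gamma, se_x, Gamma, se_y = [], [], [], []
    eas, oas = [], []
    pal_flags, flip_flags = [], []
    dropped: list[tuple[str, str]] = []

    for exp in shared:
        out = out_by_id[exp.variant_id]
        ea_x, oa_x = exp.effect_allele, exp.other_allele
        ea_y, oa_y = out.effect_allele, out.other_allele
        beta_y = out.beta
        eaf_y = out.eaf
        flipped = False

        if exp.is_palindromic:
            if {ea_y, oa_y} != {ea_x, oa_x}:
                dropped.append((exp.variant_id, "irreconcilable alleles"))
                continue
            if ea_y != ea_x:  # reported for the complementary label
                beta_y = -beta_y
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
            if exp.eaf is None or eaf_y is None:
                dropped.append((exp.variant_id, "palindromic, missing eaf"))
                continue
            if _in_ambiguity_band(exp.eaf) or _in_ambiguity_band(eaf_y):
                dropped.append(
                    (exp.variant_id, "palindromic, eaf in ambiguity band")
                )
                continue
            if (exp.eaf < 0.5) != (eaf_y < 0.5):  # discordant -> strand flip
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
                flipped = True
        else:
            pair = (ea_y, oa_y)
            comp_pair = (COMPLEMENT[ea_y], COMPLEMENT[oa_y])
            if pair == (ea_x, oa_x) or comp_pair == (ea_x, oa_x):
                pass
            elif pair == (oa_x, ea_x) or comp_pair == (oa_x, ea_x):
                beta_y = -beta_y
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
                flipped = True
            else:
                dropped.append((exp.variant_id, "irreconcilable alleles"))
                continue

        ids.append(exp.variant_id)
        gamma.append(exp.beta)
        se_x.append(exp.se)
        Gamma.append(beta_y)
        se_y.append(out.se)
        eas.append(ea_x)
        oas.append(oa_x)
        pal_flags.append(exp.is_palindromic)
        flip_flags.append(flipped)

    if not ids:
        raise HarmonizationError(
            f"all {len(shared)} shared variants dropped during harmonization: "
            + "; ".join(f"{v} ({r})" for v, r in dropped)
        )
    if dropped:
        logger.info(
            "harmonize(%s, %s): dropped %d of %d shared variants",
            exposure.trait_name,
            outcome.trait_name,
            len(dropped),
            len(shared),
        )
    return HarmonizedInstrumentSet(
        variant_ids=ids,
        gamma=np.array(gamma),
        se_x=np.array(se_x),
        Gamma=np.array(Gamma),
        se_y=np.array(se_y),
        effect_allele=eas,
        other_allele=oas,
        palindromic=np.array(pal_flags, dtype=bool),
        flipped=np.array(flip_flags, dtype=bool),
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        dropped=dropped,
    )
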