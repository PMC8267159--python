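"""Shared test helpers."""
from __future__ import annotations

from mratlas.summary_data import SummaryStats, VariantAssociation


def va(
    variant_id: str,
    ea: str = "A",
    oa: str = "G",
    beta: float = 0.1,
    se: float = 0.01,
    pval: float = 1e-10,
    eaf: float | None = 0.3,
    chrom: str = "1",
    pos: int = 1_000_000,
    n: int | None = 10_000,
) -> VariantAssociation:
    return VariantAssociation(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def stats(name: str, records) -> SummaryStats:
    return SummaryStats(trait_name=name, records=list(records))
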