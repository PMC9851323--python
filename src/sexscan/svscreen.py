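"""Inversion genotypes from discordant read-pair evidence fractions.

Read pairs mapping to the same chromosome farther apart than the insert
size and in the same orientation support an inversion.  The fraction
f = n_support / n_total of informative pairs classifies the genotype:
f < 25% homozygous reference arrangement, 25% < f < 100% heterozygous.
Boundary conventions (flagged in output because the rule leaves them
open): f = 0.25 exactly is called homRef, f = 1.0 homozygous inverted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class ReadPairEvidence:
    """Inversion-supporting vs informative read-pair counts for a region."""

    chrom: str
    start: int
    end: int
    n_support: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_support <= self.n_total:
            raise ValueError("need 0 <= n_support <= n_total")


def genotype_inversion(
    ev: ReadPairEvidence, het_lo: float = 0.25, hom_hi: float = 1.0
) -> str:
    """Classify one region: homRef | het | homInv | uninformative.

    Monotone in f = n_support/n_total: f <= het_lo -> homRef,
    het_lo < f < hom_hi -> het, f >= hom_hi -> homInv; no informative
    pairs -> uninformative.
    """
    if ev.n_total == 0:
        return "uninformative"
    f = ev.n_support / ev.n_total
    if f <= het_lo:
        return "homRef"
    if f < hom_hi:
        return "het"
    return "homInv"


def genotype_evidence_table(
    evidence: pd.DataFrame, het_lo: float = 0.25, hom_hi: float = 1.0
) -> pd.DataFrame:
    """Genotype every row of an evidence table (chrom, start, end,
    n_support, n_total); appends 'fraction', 'genotype' and a
    'boundary_call' flag for fractions exactly at a class boundary."""
    rows = []
    for _, r in evidence.iterrows():
        ev = ReadPairEvidence(
            chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
            n_support=int(r["n_support"]), n_total=int(r["n_total"]),
        )
        f = ev.n_support / ev.n_total if ev.n_total else float("nan")
        rows.append(
            {**r, "fraction": f, "genotype": genotype_inversion(ev, het_lo, hom_hi),
             "boundary_call": f in (het_lo, hom_hi)}
        )
    return pd.DataFrame(rows)
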