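"""Per-position codon usage across tripeptide repeat regions.

The repeat tract is read as units of three codons; position 1 encodes
Thr/Arg/Lys, position 2 Ala/Pro, position 3 Ala. Counting codons per
position exposes the strong usage biases of the family (e.g. Thr almost
always ACA, Arg/Lys exclusively AGA/AAA) and a bounded distance between
per-position frequency profiles quantifies how alike two genes' coding
patterns are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .repeat_scanner import RepeatRegion

POSITIONS = (1, 2, 3)


@dataclass
class CodonUsageTable:
    """Codon counts and per-position conditional frequencies for one gene."""

    gene_id: str
    counts: dict = field(default_factory=dict)       # (pos, codon) -> int
    frequencies: dict = field(default_factory=dict)  # (pos, codon) -> float

    def position_total(self, pos: int) -> int:
        return sum(c for (p, _), c in self.counts.items() if p == pos)

    def codons_at(self, pos: int) -> dict:
        return {cod: c for (p, cod), c in self.counts.items() if p == pos}


def position_codon_counts(
    region: RepeatRegion,
    gene_id: str = "",
    include_other: bool = False,
) -> CodonUsageTable:
    """Accumulate codon counts at unit positions 1-3 over a repeat region.

    OTHER (unclassifiable) units are excluded by default so spacer-rich or
    degraded tracts do not distort the repeat-codon statistics.
    """
    if region.is_empty:
        raise ValueError("cannot tabulate an empty repeat region")
    counts: dict[tuple[int, str], int] = {}
    for unit in region.units:
        if unit.unit_class == "OTHER" and not include_other:
            continue
        for pos, codon in zip(POSITIONS, unit.codons):
            counts[(pos, codon)] = counts.get((pos, codon), 0) + 1
    table = CodonUsageTable(gene_id=gene_id, counts=counts)
    for pos in POSITIONS:
        total = table.position_total(pos)
        if total == 0:
            continue
        for (p, codon), c in counts.items():
            if p == pos:
                table.frequencies[(p, codon)] = c / total
    return table


@dataclass(frozen=True)
class BiasFlag:
    kind: str        # absent | depleted
    codon: str
    position: int
    amino_acid: str
    frequency: float


#: codon-position biases the family is known for; always examined
WATCHED = (("ACG", 1), ("CCC", 2), ("GCT", 2), ("CCT", 2))


def _amino_acid(codon: str) -> str:
    return str(Seq(codon).translate())


def codon_bias_flags(
    table: CodonUsageTable,
    depleted_threshold: float = 0.02,
) -> list[BiasFlag]:
    """Flag synonymous codons that are absent or depleted at a position.

    A codon is *absent* at a position when other synonymous codons for the
    same amino acid are used there but it never is; *depleted* when its
    share among those synonymous codons is positive but below the
    threshold. The classic family biases (ACG for Thr at position 1, CCC
    and CCT for Pro and GCT for Ala at position 2) are always checked;
    other synonymous families are scanned the same way.
    """
    flags: list[BiasFlag] = []
    for pos in POSITIONS:
        used = table.codons_at(pos)
        if not used:
            continue
        by_aa: dict[str, dict[str, int]] = {}
        for codon, c in used.items():
            by_aa.setdefault(_amino_acid(codon), {})[codon] = c
        candidates = {(codon, pos) for codon, p in WATCHED if p == pos}
        candidates.update((codon, pos) for codon in used)
        for codon, _ in sorted(candidates):
            aa = _amino_acid(codon)
            fam = by_aa.get(aa)
            if not fam:
                continue  # amino acid unused at this position
            total = sum(fam.values())
            freq = fam.get(codon, 0) / total
            if fam.get(codon, 0) == 0:
                flags.append(BiasFlag("absent", codon, pos, aa, 0.0))
            elif freq < depleted_threshold:
                flags.append(BiasFlag("depleted", codon, pos, aa, freq))
    return flags


def usage_distance(a: CodonUsageTable, b: CodonUsageTable) -> float:
    """Mean per-position total-variation distance between usage profiles.

    Bounded in [0, 1]; zero iff the conditional frequencies are identical
    at every position; one when the codon sets are disjoint everywhere. A
    position populated in one table but empty in the other contributes the
    maximal distance 1; a position empty in both contributes 0.
    """
    if not a.counts or not b.counts:
        raise ValueError("usage tables must be non-empty")
    total = 0.0
    for pos in POSITIONS:
        fa = {c: f for (p, c), f in a.frequencies.items() if p == pos}
        fb = {c: f for (p, c), f in b.frequencies.items() if p == pos}
        if not fa and not fb:
            continue
        if not fa or not fb:
            total += 1.0
            continue
        codons = set(fa) | set(fb)
        total += 0.5 * sum(abs(fa.get(c, 0.0) - fb.get(c, 0.0)) for c in codons)
    return total / len(POSITIONS)


def usage_wide_table(tables: list[CodonUsageTable]) -> pd.DataFrame:
    """Gene x (position:codon) frequency matrix for export."""
    rows = {}
    for t in tables:
        rows[t.gene_id] = {
            f"pos{p}:{codon}": freq for (p, codon), freq in sorted(t.frequencies.items())
        }
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()
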