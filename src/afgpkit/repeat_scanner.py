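"""Locate and frame the tripeptide-repeat tract of an AFGP CDS.

AFGP coding regions are imperfect tandem repeats of a 9-nt unit encoding
[Thr/Arg/Lys]-[Ala/Pro]-Ala. Thr-led units (Thr-Ala-Ala, Thr-Pro-Ala) are
the glycosylated "repeats" proper; Arg/Lys-led units are spacers that act
as protease cleavage residues in the polyprotein precursor. The scanner
tiles the CDS into 9-nt units in every nucleotide frame and residue phase
and returns the highest-scoring contiguous run of units whose impurity
(fraction of unclassifiable units) stays below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

#: unit classes; first residue decides repeat (T) vs spacer (R/K)
UNIT_CLASSES = ("TAA", "TPA", "RAA", "KAA", "OTHER")

_POS1 = {"T", "R", "K"}
_POS2 = {"A", "P"}


def translate_cds(cds: str) -> str:
    """Translate a codon-framed DNA string with the standard code.

    Stops are kept as '*'; ambiguous codons (any N) become 'X'. The length
    must be divisible by 3.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate())


def classify_unit(residues: str) -> str:
    """Class of a tripeptide unit from its three residues.

    Position 1 in {T,R,K}, position 2 in {A,P}, position 3 = A; any other
    combination is OTHER. Of the nominally valid grid only the four classes
    the gene family actually uses are named (TAA, TPA, RAA, KAA); R/K with
    Pro at position 2 does not occur and maps to OTHER.
    """
    if len(residues) != 3:
        raise ValueError("unit must have exactly 3 residues")
    p1, p2, p3 = residues
    if p3 != "A" or p1 not in _POS1 or p2 not in _POS2:
        return "OTHER"
    name = f"{p1}{p2}A"
    return name if name in UNIT_CLASSES else "OTHER"


@dataclass(frozen=True)
class TripeptideUnit:
    """One 9-nt unit: three codons, their residues and the unit class."""

    index: int
    codons: tuple[str, str, str]
    residues: str
    unit_class: str

    @classmethod
    def from_dna(cls, index: int, dna9: str) -> "TripeptideUnit":
        if len(dna9) != 9:
            raise ValueError("unit DNA must be 9 nt")
        codons = (dna9[0:3], dna9[3:6], dna9[6:9])
        residues = translate_cds(dna9)
        return cls(index, codons, residues, classify_unit(residues))

    @property
    def is_repeat(self) -> bool:
        return self.residues[0] == "T" and self.unit_class != "OTHER"

    @property
    def is_spacer(self) -> bool:
        return self.residues[0] in ("R", "K") and self.unit_class != "OTHER"


@dataclass
class RepeatRegion:
    """The framed repeat tract: offsets into the CDS plus its units."""

    cds_offset_start: int
    cds_offset_end: int
    units: list[TripeptideUnit] = field(default_factory=list)

    @classmethod
    def empty(cls) -> "RepeatRegion":
        return cls(0, 0, [])

    @property
    def is_empty(self) -> bool:
        return not self.units

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_repeat_units(self) -> int:
        return sum(u.is_repeat for u in self.units)

    @property
    def n_spacer_units(self) -> int:
        return sum(u.is_spacer for u in self.units)

    @property
    def n_other_units(self) -> int:
        return sum(u.unit_class == "OTHER" for u in self.units)

    @property
    def residues(self) -> str:
        return "".join(u.residues for u in self.units)

    def __post_init__(self) -> None:
        span = self.cds_offset_end - self.cds_offset_start
        if span != 9 * len(self.units):
            raise ValueError("region span must equal 9 x unit count")

    @classmethod
    def from_cds_slice(cls, cds: str, start: int, n_units: int) -> "RepeatRegion":
        units = [
            TripeptideUnit.from_dna(i, cds[start + 9 * i : start + 9 * i + 9])
            for i in range(n_units)
        ]
        return cls(start, start + 9 * n_units, units)


def _unit_classes_at_offset(cds: str, offset: int) -> list[str]:
    n = (len(cds) - offset) // 9
    out = []
    for i in range(n):
        s = offset + 9 * i
        out.append(classify_unit(translate_cds(cds[s : s + 9])))
    return out


def find_repeat_region(
    cds: str,
    min_units: int = 4,
    max_other_frac: float = 0.1,
) -> RepeatRegion:
    """Best-scoring tripeptide-repeat run over all frames and phases.

    For every nucleotide offset 0..8 the CDS is tiled into 9-nt units and
    every run [i, j) of consecutive units is scored by its number of
    classifiable (non-OTHER) units. A run qualifies when it has at least
    ``min_units`` units, its OTHER fraction is at most ``max_other_frac``,
    and its first and last units are classifiable (leading/trailing OTHER
    trimmed). Ties between equal-scoring runs are broken by smallest
    offset, then leftmost start, then shortest run, so the result is
    deterministic. Returns an empty region when nothing qualifies.
    """
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    best = None  # (score, offset, start_nt, n_units)
    for offset in range(9):
        classes = _unit_classes_at_offset(cds, offset)
        n = len(classes)
        if n < min_units:
            continue
        other = [c == "OTHER" for c in classes]
        # prefix sums of OTHER counts
        pref = [0]
        for o in other:
            pref.append(pref[-1] + o)
        for i in range(n):
            if other[i]:
                continue
            for j in range(i + min_units, n + 1):
                if other[j - 1]:
                    continue
                n_other = pref[j] - pref[i]
                length = j - i
                if n_other > max_other_frac * length:
                    continue
                score = length - n_other
                key = (-score, offset, i, length)
                if best is None or key < best:
                    best = key
    if best is None:
        return RepeatRegion.empty()
    _, offset, i, length = best
    return RepeatRegion.from_cds_slice(cds, offset + 9 * i, length)


def find_all_repeat_regions(
    cds: str,
    min_units: int = 4,
    max_other_frac: float = 0.1,
) -> list[RepeatRegion]:
    """Greedy cover: best region, then best in the remaining flanks, etc.

    Used to detect tracts split by long insertions. Regions are returned
    in CDS order and never overlap.
    """
    segments = [(0, len(cds))]
    found: list[RepeatRegion] = []
    while segments:
        lo, hi = segments.pop()
        if hi - lo < 9 * min_units:
            continue
        sub = find_repeat_region(cds[lo:hi], min_units, max_other_frac)
        if sub.is_empty:
            continue
        region = RepeatRegion.from_cds_slice(
            cds, lo + sub.cds_offset_start, sub.n_units
        )
        found.append(region)
        segments.append((lo, region.cds_offset_start))
        segments.append((region.cds_offset_end, hi))
    found.sort(key=lambda r: r.cds_offset_start)
    return found


def units_to_table(region: RepeatRegion) -> list[dict]:
    """Per-unit rows (index, codons, residues, class) for TSV export."""
    return [
        {
            "index": u.index,
            "codon1": u.codons[0],
            "codon2": u.codons[1],
            "codon3": u.codons[2],
            "residues": u.residues,
            "unit_class": u.unit_class,
        }
        for u in region.units
    ]
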