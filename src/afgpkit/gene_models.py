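"""Gene/pseudogene classification, polyprotein digestion and mass prediction.

A functional AFGP gene encodes one polyprotein: signal/propeptide, then a
long (Thr-Ala/Pro-Ala)n tract with occasional Arg/Lys-Ala-Ala spacer units,
then a short characteristic C-terminus. Trypsin-like proteases cleave at
the carboxyl side of Arg and Lys, so each spacer is a potential cleavage
site; exhaustive cleavage releases the mature size isoforms. Each mature
isoform carries one O-linked galactosyl-N-acetylgalactosamine disaccharide
per Thr, which dominates the molecular mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .repeat_scanner import (
    RepeatRegion,
    find_all_repeat_regions,
    find_repeat_region,
    translate_cds,
)
from .seqio import GeneRecord

SITE_TYPES = ("single_Arg", "single_Lys", "RAAR")

SIZE_BINS = ("AFGP8", "AFGP7", "AFGP6_group", "AFGP1_5_group", "sub_AFGP")


@dataclass(frozen=True)
class CleavageSite:
    """A predicted protease cut: the spacer unit and the site motif type.

    ``residue_span`` is the number of linker residues excised (3 for a
    single Arg/Lys spacer unit, 4 for the Arg-Ala-Ala-Arg motif, which
    spans the unit boundary into the successor unit).
    """

    unit_index: int
    site_type: str
    residue_span: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"bad site type {self.site_type!r}")


@dataclass
class MatureIsoform:
    """A predicted cleavage product of the AFGP polyprotein."""

    source_gene: str
    ordinal: int
    n_repeats: int
    residue_composition: dict = field(default_factory=dict)
    n_thr: int = 0
    mass_da: float = 0.0
    size_bin: str = "sub_AFGP"
    unit_indices: tuple = ()


@dataclass(frozen=True)
class MassModel:
    """Average-mass model for glycosylated AFGP peptides.

    Residue masses are standard average residue (dehydrated) masses in Da;
    one water is added per peptide and one dehydrated disaccharide adduct
    (galactosyl-N-acetylgalactosamine, 365.33 Da) per glycosylated Thr.
    The repeats only use Thr/Ala/Pro/Arg/Lys, but imperfect units can
    carry any standard residue, so the full 20-residue table is kept;
    unknown symbols (X, stops) still raise.
    """

    residue_avg_mass: tuple = (
        ("T", 101.10), ("A", 71.08), ("P", 97.12), ("R", 156.19),
        ("K", 128.17), ("G", 57.05), ("S", 87.08), ("V", 99.13),
        ("C", 103.14), ("L", 113.16), ("I", 113.16), ("N", 114.10),
        ("D", 115.09), ("Q", 128.13), ("E", 129.12), ("M", 131.19),
        ("H", 137.14), ("F", 147.18), ("Y", 163.18), ("W", 186.21),
    )
    water: float = 18.02
    disaccharide_adduct: float = 365.33

    def residue_mass(self, residue: str) -> float:
        for r, m in self.residue_avg_mass:
            if r == residue:
                return m
        raise KeyError(f"no average mass for residue {residue!r}")


DEFAULT_MASS_MODEL = MassModel()


@dataclass
class Classification:
    status: str                  # functional | pseudogene | non_afgp
    pseudogene_reason: str = "none"


def classify_gene(
    record: GeneRecord,
    region: RepeatRegion | None = None,
    min_five_prime_nt: int = 30,
    insertion_threshold_nt: int = 500,
    min_units: int = 4,
    max_other_frac: float = 0.1,
) -> Classification:
    """Decide functional vs pseudogene (with reason) for one gene.

    Functional requires: a start codon opening the CDS, a non-repetitive
    5' coding segment of at least ``min_five_prime_nt``, the repeat tract
    in frame with the start, no internal stop, and a terminal stop codon.
    Failures map to the three observed pseudogene defects, checked in the
    order 5'-truncation, long coding insertion, frameshift; a CDS with no
    repeat tract and no ORF is reported as non-AFGP.
    """
    cds = record.cds
    if region is None:
        region = find_repeat_region(cds, min_units, max_other_frac)

    has_start = cds.startswith("ATG")
    if region.is_empty:
        return Classification("non_afgp")

    if not has_start or region.cds_offset_start < min_five_prime_nt:
        return Classification("pseudogene", "five_prime_truncated")

    # a long interrupting tract splits the repeats into distant runs
    runs = find_all_repeat_regions(cds, min_units, max_other_frac)
    for a, b in zip(runs, runs[1:]):
        if b.cds_offset_start - a.cds_offset_end >= insertion_threshold_nt:
            return Classification("pseudogene", "coding_insertion")

    if len(cds) % 3 != 0 or region.cds_offset_start % 3 != 0:
        return Classification("pseudogene", "frameshift_indel")
    aa = translate_cds(cds)
    if "*" in aa[:-1]:
        return Classification("pseudogene", "frameshift_indel")
    if not aa.endswith("*"):
        return Classification("pseudogene", "frameshift_indel")
    return Classification("functional")


def find_cleavage_sites(region: RepeatRegion) -> list[CleavageSite]:
    """Enumerate cleavage sites over a framed repeat region.

    Every Lys-Ala-Ala unit is a single-Lys site; an Arg-Ala-Ala unit whose
    successor unit begins with Arg forms the four-residue Arg-Ala-Ala-Arg
    motif (the successor unit is consumed into the linker), otherwise it is
    a single-Arg site. Overlapping motifs resolve leftmost-first.
    """
    sites: list[CleavageSite] = []
    units = region.units
    claimed: set[int] = set()
    for i, u in enumerate(units):
        if i in claimed:
            continue
        if u.unit_class == "KAA":
            sites.append(CleavageSite(i, "single_Lys", 3))
            claimed.add(i)
        elif u.unit_class == "RAA":
            nxt = units[i + 1] if i + 1 < len(units) else None
            if nxt is not None and nxt.residues[0] == "R":
                sites.append(CleavageSite(i, "RAAR", 4))
                claimed.update((i, i + 1))
            else:
                sites.append(CleavageSite(i, "single_Arg", 3))
                claimed.add(i)
    return sites


def linker_unit_indices(sites: list[CleavageSite]) -> set[int]:
    """Unit indices excised as linker residues.

    An RAAR linker consumes its RAA unit and the successor unit whose
    leading Arg completes the motif (the successor's residual Ala-Ala
    dipeptide is excised with the linker rather than left on a product).
    """
    out: set[int] = set()
    for s in sites:
        out.add(s.unit_index)
        if s.site_type == "RAAR":
            out.add(s.unit_index + 1)
    return out


def digest_polyprotein(
    region: RepeatRegion,
    sites: list[CleavageSite] | None = None,
    source_gene: str = "",
    mass_model: MassModel = DEFAULT_MASS_MODEL,
    min_repeats: int = 1,
) -> list[MatureIsoform]:
    """Exhaustively cleave a repeat region into mature isoforms.

    Products are the maximal runs of units strictly between linker spans;
    linker residues are excised. Products are reported when they contain
    at least ``min_repeats`` Thr-led units (set 0 to keep Thr-free
    fragments). Unit conservation (products + linkers = region) is checked
    on every call.
    """
    if sites is None:
        sites = find_cleavage_sites(region)
    linkers = linker_unit_indices(sites)
    n = region.n_units
    products: list[list[int]] = []
    current: list[int] = []
    for i in range(n):
        if i in linkers:
            if current:
                products.append(current)
                current = []
        else:
            current.append(i)
    if current:
        products.append(current)

    covered = sum(len(p) for p in products) + len(linkers)
    if covered != n:
        raise AssertionError(
            f"unit conservation violated: {covered} != {n} units"
        )

    isoforms = []
    for ordinal, idxs in enumerate(products):
        units = [region.units[i] for i in idxs]
        comp: dict[str, int] = {}
        for u in units:
            for r in u.residues:
                comp[r] = comp.get(r, 0) + 1
        n_repeats = sum(u.is_repeat for u in units)
        n_thr = comp.get("T", 0)
        iso = MatureIsoform(
            source_gene=source_gene,
            ordinal=ordinal,
            n_repeats=n_repeats,
            residue_composition=comp,
            n_thr=n_thr,
            unit_indices=tuple(idxs),
        )
        iso.mass_da = peptide_mass(iso, mass_model)
        iso.size_bin = assign_isoform_bin(iso.mass_da, iso.n_repeats)
        isoforms.append(iso)
    return [iso for iso in isoforms if iso.n_repeats >= min_repeats]


def peptide_mass(isoform: MatureIsoform, model: MassModel = DEFAULT_MASS_MODEL) -> float:
    """Average glycopeptide mass: residues + one water + adduct per Thr."""
    total = model.water
    for residue, count in isoform.residue_composition.items():
        total += model.residue_mass(residue) * count
    total += isoform.n_thr * model.disaccharide_adduct
    return total


def isoform_from_repeats(
    n_repeats: int,
    unit: str = "TAA",
    source_gene: str = "synthetic",
    mass_model: MassModel = DEFAULT_MASS_MODEL,
) -> MatureIsoform:
    """Convenience constructor: an isoform of ``n_repeats`` identical units."""
    comp: dict[str, int] = {}
    for r in unit * n_repeats:
        comp[r] = comp.get(r, 0) + 1
    iso = MatureIsoform(
        source_gene=source_gene,
        ordinal=0,
        n_repeats=n_repeats,
        residue_composition=comp,
        n_thr=comp.get("T", 0),
    )
    iso.mass_da = peptide_mass(iso, mass_model)
    iso.size_bin = assign_isoform_bin(iso.mass_da, iso.n_repeats)
    return iso


#: mass boundaries (Da) for the historical size-isoform groups; 9200 Da is
#: the midpoint of the gap between the AFGP6 group (<= 7.9 kDa) and the
#: AFGP1-5 group (>= 10.5 kDa)
AFGP6_LOW = 4200.0
AFGP6_HIGH = 9200.0


def assign_isoform_bin(mass_da: float, n_repeats: int) -> str:
    """Historical AFGP size class for a predicted isoform.

    The two smallest classes are defined by repeat count (AFGP8 = four
    repeats, AFGP7 = five); larger products fall into the AFGP6 or AFGP1-5
    mass ranges; fragments below four repeats are sub-AFGP.
    """
    if n_repeats < 4:
        return "sub_AFGP"
    if n_repeats == 4:
        return "AFGP8"
    if n_repeats == 5:
        return "AFGP7"
    if mass_da >= AFGP6_HIGH:
        return "AFGP1_5_group"
    return "AFGP6_group"


def family_summary(
    records: list[GeneRecord],
    regions: dict[str, RepeatRegion],
    isoforms: dict[str, list[MatureIsoform]],
) -> pd.DataFrame:
    """Per-species family table: counts, isoforms, repeat range, composition.

    Composition percentages are over the translated repeat regions of all
    genes of the species (all residues of all units, OTHER included).
    """
    rows = []
    by_species: dict[str, list[GeneRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)
    for species in sorted(by_species):
        recs = by_species[species]
        n_pseudo = {r: 0 for r in ("five_prime_truncated", "frameshift_indel",
                                   "coding_insertion")}
        n_functional = 0
        repeat_counts = []
        comp: dict[str, int] = {}
        n_iso = 0
        for rec in recs:
            if rec.status == "functional":
                n_functional += 1
            elif rec.pseudogene_reason in n_pseudo:
                n_pseudo[rec.pseudogene_reason] += 1
            for iso in isoforms.get(rec.id, []):
                n_iso += 1
                repeat_counts.append(iso.n_repeats)
            region = regions.get(rec.id)
            if region is not None and not region.is_empty:
                for r in region.residues:
                    comp[r] = comp.get(r, 0) + 1
        total_res = sum(comp.values())
        row = {
            "species": species,
            "n_genes": len(recs),
            "n_functional": n_functional,
            "n_pseudogene": sum(n_pseudo.values()),
            **{f"n_{k}": v for k, v in n_pseudo.items()},
            "n_isoforms": n_iso,
            "repeats_min": min(repeat_counts) if repeat_counts else 0,
            "repeats_max": max(repeat_counts) if repeat_counts else 0,
        }
        for aa in ("T", "A", "P", "R", "K"):
            row[f"pct_{aa}"] = (
                100.0 * comp.get(aa, 0) / total_res if total_res else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def isoform_table(isoforms: dict[str, list[MatureIsoform]]) -> pd.DataFrame:
    rows = [
        {
            "gene": gid,
            "ordinal": iso.ordinal,
            "n_repeats": iso.n_repeats,
            "n_thr": iso.n_thr,
            "mass_da": round(iso.mass_da, 2),
            "size_bin": iso.size_bin,
        }
        for gid, isos in isoforms.items()
        for iso in isos
    ]
    return pd.DataFrame(rows)
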