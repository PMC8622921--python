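"""Ground-truthed simulator of AFGP gene-family evolution.

The generator grows a gene family from a single ancestral gene carrying a
perfect (Thr-Ala-Ala)n tract coded ACA-GCA-GCA, under the mechanisms that
shaped the real family: slipped-strand mispairing duplicating blocks of
9-nt units in place, point substitution with transition bias (a middle-base
substitution of a position-1 ACA codon yields AGA or AAA, minting Arg/Lys
cleavage residues from Thr codons), whole-gene duplication bifurcating the
true gene tree, and pseudogenization by 5' truncation, small frameshifting
indels, or a long coding insertion. Every emitted sequence is paired with
machine-readable ground truth (unit inventory, cleavage sites, status, the
true tree and the full event log), so every pipeline stage can be scored
without external data.

The model is a discrete-generation event process: within a generation each
gene draws Poisson event counts in the fixed order slippage, substitution,
duplication, pseudogenization, from a single seeded random stream, so a
(seed, config) pair replays byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .family_evolution import FamilyTree, robinson_foulds
from .gene_models import find_cleavage_sites
from .repeat_scanner import RepeatRegion, TripeptideUnit
from .seqio import GeneRecord

_STOPS = {"TAA", "TAG", "TGA"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"


@dataclass
class SimConfig:
    """Simulator parameters; all rates are per gene per generation unless noted.

    ``substitution_rate`` and ``flank_substitution_rate`` are per-site
    per-generation (coding region and flanks respectively); keeping them
    separate lets coding sequence stay clean while flanks diverge, which is
    how family trees become recoverable from flanks in low-noise runs.
    """

    seed: int = 0
    species: str = "Sim"
    n_initial_units: int = 12
    generations: int = 100
    slippage_rate: float = 0.02
    slippage_block_mean: float = 2.0
    substitution_rate: float = 1e-4       # per coding site per generation
    flank_substitution_rate: float = 1e-3  # per flank site per generation
    ts_tv_ratio: float = 2.0
    cleavage_genesis: float = 0.5          # P(ACA->AGA) vs ACA->AAA at pos-1 middle base
    gene_duplication_rate: float = 0.02
    pseudogenization_rate: float = 0.002
    reason_mix: tuple = (
        ("five_prime_truncated", 1.0),
        ("frameshift_indel", 1.0),
        ("coding_insertion", 1.0),
    )
    flank_length_5: int = 1140
    flank_length_3: int = 325
    stub_codons: int = 20                  # 5' non-repetitive coding codons after ATG
    cterm_dna: str = "CCGGTTGGA"           # Pro-Val-Gly characteristic C-terminus
    insertion_length: int = 600

    def __post_init__(self) -> None:
        for name in (
            "slippage_rate", "substitution_rate", "flank_substitution_rate",
            "gene_duplication_rate", "pseudogenization_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_initial_units < 1:
            raise ValueError("n_initial_units must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.cleavage_genesis <= 1.0:
            raise ValueError("cleavage_genesis must be a probability")
        if len(self.cterm_dna) % 3 != 0:
            raise ValueError("cterm_dna must be codon-length")
        self.reason_mix = tuple((str(r), float(w)) for r, w in self.reason_mix)
        if any(w < 0 for _, w in self.reason_mix) or not any(
            w > 0 for _, w in self.reason_mix
        ):
            raise ValueError("reason_mix weights must be non-negative, not all zero")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["reason_mix"] = [list(x) for x in self.reason_mix]
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "reason_mix" in data:
            data["reason_mix"] = tuple(tuple(x) for x in data["reason_mix"])
        return cls(**data)


class _TreeNode:
    __slots__ = ("label", "start", "split", "children")

    def __init__(self, label: str, start: float):
        self.label = label
        self.start = start
        self.split: float | None = None
        self.children: list["_TreeNode"] = []

    def newick(self, end_time: float) -> str:
        if not self.children:
            return f"{self.label}:{end_time - self.start:.10g}"
        inner = ",".join(c.newick(end_time) for c in self.children)
        return f"({inner}):{self.split - self.start:.10g}"


@dataclass
class _SimGene:
    """Mutable per-gene state during simulation."""

    id: str
    flank5: str
    pre: str                      # ATG + 5' non-repetitive coding stub
    units: list                   # list of 9-nt strings
    cterm: str
    stop: str
    flank3: str
    status: str = "functional"
    reason: str = "none"
    insertion: tuple | None = None  # (unit boundary index, inserted seq)

    def cds_parts(self) -> list[str]:
        parts = [self.pre]
        ins_at, ins_seq = self.insertion if self.insertion else (None, None)
        for i, u in enumerate(self.units):
            if ins_at == i:
                parts.append(ins_seq)
            parts.append(u)
        if ins_at == len(self.units):
            parts.append(ins_seq)
        parts.append(self.cterm)
        parts.append(self.stop)
        return parts

    @property
    def cds(self) -> str:
        return "".join(self.cds_parts())

    @property
    def seq(self) -> str:
        return self.flank5 + self.cds + self.flank3

    def unit_offsets(self) -> list[int]:
        """CDS nt offset of each unit start, insertion accounted for."""
        offsets = []
        pos = len(self.pre)
        ins_at, ins_seq = self.insertion if self.insertion else (None, None)
        for i in range(len(self.units)):
            if ins_at == i:
                pos += len(ins_seq)
            offsets.append(pos)
            pos += 9
        return offsets


@dataclass
class GroundTruth:
    """Everything the generator knows about the family it emitted."""

    config: dict
    genes: dict = field(default_factory=dict)
    tree_newick: str = ""
    events: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "genes": self.genes,
                    "tree_newick": self.tree_newick,
                    "events": self.events,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _root_newick(root: _TreeNode, end_time: float) -> str:
    if not root.children:
        return f"{root.label};"
    s = root.newick(end_time)
    return s[: s.rfind(")") + 1] + ";"  # drop the root's own edge length


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _random_coding(rng, n_codons: int) -> str:
    """Random codons avoiding stops (and ATG re-starts are allowed)."""
    out = []
    for _ in range(n_codons):
        codon = _random_seq(rng, 3)
        while codon in _STOPS:
            codon = _random_seq(rng, 3)
        out.append(codon)
    return "".join(out)


def _substitute_base(rng, base: str, ts_tv_ratio: float) -> str:
    kappa = ts_tv_ratio
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    tvs = [b for b in _BASES if b != base and b != _TRANSITION[base]]
    return tvs[int(rng.integers(0, len(tvs)))]


def simulate_family(config: SimConfig):
    """Run the generational event model; return (GeneRecords, GroundTruth)."""
    rng = np.random.default_rng(config.seed)
    gene_counter = [0]

    def new_id() -> str:
        gene_counter[0] += 1
        return f"{config.species}_AFGP{gene_counter[0]}"

    ancestor = _SimGene(
        id=new_id(),
        flank5=_random_seq(rng, config.flank_length_5),
        pre="ATG" + _random_coding(rng, config.stub_codons),
        units=["ACAGCAGCA"] * config.n_initial_units,
        cterm=config.cterm_dna,
        stop="TGA",
        flank3=_random_seq(rng, config.flank_length_3),
    )
    genes: list[_SimGene] = [ancestor]
    tree_nodes = {ancestor.id: _TreeNode(ancestor.id, 0.0)}
    root = tree_nodes[ancestor.id]
    events: list[dict] = []

    for gen in range(1, config.generations + 1):
        for gene in list(genes):
            if gene.status == "functional":
                _do_slippage(rng, gene, config, gen, events)
            _do_substitution(rng, gene, config, gen, events)
            if gene.status == "functional":
                _do_duplication(
                    rng, gene, config, gen, events, genes, tree_nodes, new_id
                )
                _do_pseudogenization(rng, gene, config, gen, events)

    records = [
        GeneRecord(
            id=g.id,
            species=config.species,
            seq=g.seq,
            cds_start=len(g.flank5),
            cds_end=len(g.flank5) + len(g.cds),
            strand="+",
            status=g.status,
            pseudogene_reason=g.reason,
        )
        for g in genes
    ]
    truth = GroundTruth(
        config=config.as_dict(),
        genes={g.id: _gene_truth(g) for g in genes},
        tree_newick=_root_newick(root, float(config.generations)),
        events=events,
    )
    if not records:
        raise ValueError("configuration produced zero genes")
    return records, truth


def _do_slippage(rng, gene, config, gen, events) -> None:
    for _ in range(rng.poisson(config.slippage_rate)):
        n = len(gene.units)
        if n == 0:
            break
        start = int(rng.integers(0, n))
        p = 1.0 / config.slippage_block_mean
        size = min(int(rng.geometric(p)), n - start)
        block = gene.units[start : start + size]
        gene.units[start + size : start + size] = [u for u in block]
        events.append(
            {
                "generation": gen,
                "type": "slippage",
                "gene": gene.id,
                "start_unit": start,
                "block_size": size,
            }
        )


def _do_substitution(rng, gene, config, gen, events) -> None:
    # coding sites
    cds = gene.cds
    for _ in range(rng.poisson(config.substitution_rate * len(cds))):
        pos = int(rng.integers(0, len(cds)))
        _apply_cds_substitution(rng, gene, pos, config, gen, events)
    # flank sites
    for attr in ("flank5", "flank3"):
        flank = getattr(gene, attr)
        if not flank:
            continue
        for _ in range(rng.poisson(config.flank_substitution_rate * len(flank))):
            pos = int(rng.integers(0, len(flank)))
            old = flank[pos]
            new = _substitute_base(rng, old, config.ts_tv_ratio)
            flank = flank[:pos] + new + flank[pos + 1 :]
            events.append(
                {
                    "generation": gen,
                    "type": "flank_substitution",
                    "gene": gene.id,
                    "flank": attr,
                    "position": pos,
                    "old": old,
                    "new": new,
                }
            )
        setattr(gene, attr, flank)


def _apply_cds_substitution(rng, gene, pos, config, gen, events) -> None:
    parts = gene.cds_parts()
    # locate the part containing pos
    acc = 0
    for idx, part in enumerate(parts):
        if pos < acc + len(part):
            offset = pos - acc
            break
        acc += len(part)
    old = part[offset]
    # which structural element is this part?
    unit_index = _part_unit_index(gene, idx)
    if (
        unit_index is not None
        and offset == 1
        and part[0:3] == "ACA"
    ):
        # position-1 codon middle base of an ACA: cleavage-residue genesis
        new = "G" if rng.random() < config.cleavage_genesis else "A"
    else:
        new = _substitute_base(rng, old, config.ts_tv_ratio)
    new_part = part[:offset] + new + part[offset + 1 :]
    _set_part(gene, idx, new_part)
    events.append(
        {
            "generation": gen,
            "type": "substitution",
            "gene": gene.id,
            "cds_position": pos,
            "old": old,
            "new": new,
        }
    )


def _part_layout(gene) -> list[tuple[str, int]]:
    """(kind, unit_index_or_-1) for each part returned by cds_parts."""
    layout: list[tuple[str, int]] = [("pre", -1)]
    ins_at = gene.insertion[0] if gene.insertion else None
    for i in range(len(gene.units)):
        if ins_at == i:
            layout.append(("insertion", -1))
        layout.append(("unit", i))
    if ins_at == len(gene.units):
        layout.append(("insertion", -1))
    layout.append(("cterm", -1))
    layout.append(("stop", -1))
    return layout


def _part_unit_index(gene, part_idx: int) -> int | None:
    kind, ui = _part_layout(gene)[part_idx]
    return ui if kind == "unit" else None


def _set_part(gene, part_idx: int, new_part: str) -> None:
    kind, ui = _part_layout(gene)[part_idx]
    if kind == "pre":
        gene.pre = new_part
    elif kind == "unit":
        gene.units[ui] = new_part
    elif kind == "insertion":
        gene.insertion = (gene.insertion[0], new_part)
    elif kind == "cterm":
        gene.cterm = new_part
    else:
        gene.stop = new_part


def _do_duplication(rng, gene, config, gen, events, genes, tree_nodes, new_id) -> None:
    for _ in range(rng.poisson(config.gene_duplication_rate)):
        child = _SimGene(
            id=new_id(),
            flank5=gene.flank5,
            pre=gene.pre,
            units=list(gene.units),
            cterm=gene.cterm,
            stop=gene.stop,
            flank3=gene.flank3,
            insertion=gene.insertion,
        )
        genes.append(child)
        node = tree_nodes[gene.id]
        node.split = float(gen)
        cont = _TreeNode(gene.id, float(gen))
        born = _TreeNode(child.id, float(gen))
        node.children = [cont, born]
        node.label = None
        tree_nodes[gene.id] = cont
        tree_nodes[child.id] = born
        events.append(
            {
                "generation": gen,
                "type": "duplication",
                "gene": gene.id,
                "child": child.id,
            }
        )


def _do_pseudogenization(rng, gene, config, gen, events) -> None:
    if rng.poisson(config.pseudogenization_rate) < 1:
        return
    reasons = [r for r, _ in config.reason_mix]
    weights = np.array([w for _, w in config.reason_mix], dtype=float)
    reason = reasons[int(rng.choice(len(reasons), p=weights / weights.sum()))]
    if reason == "five_prime_truncated":
        cut = max(len(gene.pre) - 23, 1)
        gene.pre = gene.pre[cut:]
    elif reason == "frameshift_indel":
        size = int(rng.integers(1, 3))
        pos = int(rng.integers(3, max(4, len(gene.pre))))
        if rng.random() < 0.5:
            gene.pre = gene.pre[:pos] + _random_seq(rng, size) + gene.pre[pos:]
        else:
            gene.pre = gene.pre[:pos] + gene.pre[pos + size :]
    else:  # coding_insertion
        boundary = int(rng.integers(1, max(2, len(gene.units))))
        gene.insertion = (boundary, _random_seq(rng, config.insertion_length))
    gene.status = "pseudogene"
    gene.reason = reason
    events.append(
        {"generation": gen, "type": "pseudogenization", "gene": gene.id,
         "reason": reason}
    )


def _gene_truth(gene: _SimGene) -> dict:
    units = [TripeptideUnit.from_dna(i, u) for i, u in enumerate(gene.units)]
    region = RepeatRegion(0, 9 * len(units), units)
    sites = find_cleavage_sites(region)
    offsets = gene.unit_offsets()
    return {
        "repeat_unit_count": region.n_repeat_units,
        "n_units": len(units),
        "unit_classes": [u.unit_class for u in units],
        "unit_cds_offsets": offsets,
        "cleavage_sites": [
            {
                "unit_index": s.unit_index,
                "cds_offset": offsets[s.unit_index],
                "site_type": s.site_type,
            }
            for s in sites
        ],
        "status": gene.status,
        "pseudogene_reason": gene.reason,
        "cterm_residues": str(Seq(gene.cterm).translate()),
        "insertion_at_unit": gene.insertion[0] if gene.insertion else None,
    }


def simulate_species_pair(
    config: SimConfig,
    species_a: str = "A",
    species_b: str = "B",
    divergence_generations: int = 50,
):
    """Speciation-then-divergence helper for orthology benchmarks.

    A family is simulated in the common ancestor, then duplicated into two
    species whose flanks (and coding sequence, at the configured rates)
    diverge independently for ``divergence_generations`` with duplication,
    slippage and pseudogenization switched off. True orthologs are the
    same ancestral gene index in the two species.
    """
    records, truth = simulate_family(config)
    rng = np.random.default_rng(config.seed + 1)
    out: dict[str, list[GeneRecord]] = {species_a: [], species_b: []}
    ortho_pairs = []
    cterm = {}
    for rec in records:
        gnum = rec.id.split("AFGP")[-1]
        pair = []
        for sp in (species_a, species_b):
            seq = rec.seq
            flank_sites = rec.cds_start + (len(seq) - rec.cds_end)
            n_sub = rng.poisson(
                config.flank_substitution_rate
                * flank_sites
                * divergence_generations
            )
            s = list(seq)
            for _ in range(n_sub):
                while True:
                    pos = int(rng.integers(0, len(s)))
                    if pos < rec.cds_start or pos >= rec.cds_end:
                        break
                s[pos] = _substitute_base(rng, s[pos], config.ts_tv_ratio)
            gid = f"{sp}_AFGP{gnum}"
            out[sp].append(
                GeneRecord(
                    id=gid,
                    species=sp,
                    seq="".join(s),
                    cds_start=rec.cds_start,
                    cds_end=rec.cds_end,
                    status=rec.status,
                    pseudogene_reason=rec.pseudogene_reason,
                )
            )
            cterm[gid] = truth.genes[rec.id]["cterm_residues"]
            pair.append(gid)
        ortho_pairs.append(tuple(pair))
    return out, sorted(ortho_pairs), cterm


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def truth_compare(truth: GroundTruth, predicted: dict) -> dict:
    """Score pipeline predictions against simulator ground truth.

    ``predicted`` maps gene id to a dict with keys ``repeat_count``,
    ``cleavage_sites`` (list of (cds_offset, site_type)), ``status``; an
    optional top-level key ``"__tree__"`` holds an inferred FamilyTree or
    newick string. Returns exact-match rate for repeat counts, precision/
    recall for cleavage sites matched by CDS offset and type, a status
    confusion matrix, and the Robinson-Foulds distance when trees are
    given.
    """
    pred_genes = {k: v for k, v in predicted.items() if k != "__tree__"}
    missing = sorted(set(truth.genes) ^ set(pred_genes))
    if missing:
        raise ValueError(f"gene id mismatch between truth and predictions: {missing}")

    n = len(truth.genes)
    exact = sum(
        truth.genes[g]["repeat_unit_count"] == pred_genes[g]["repeat_count"]
        for g in truth.genes
    )
    true_sites = {
        (g, s["cds_offset"], s["site_type"])
        for g, t in truth.genes.items()
        for s in t["cleavage_sites"]
    }
    pred_sites = {
        (g, off, st)
        for g, p in pred_genes.items()
        for off, st in p.get("cleavage_sites", [])
    }
    tp = len(true_sites & pred_sites)
    precision = tp / len(pred_sites) if pred_sites else 1.0
    recall = tp / len(true_sites) if true_sites else 1.0

    status_df = pd.crosstab(
        pd.Series({g: t["status"] for g, t in truth.genes.items()}, name="truth"),
        pd.Series({g: pred_genes[g].get("status", "NA") for g in truth.genes},
                  name="predicted"),
    )
    status_acc = (
        sum(
            truth.genes[g]["status"] == pred_genes[g].get("status")
            for g in truth.genes
        )
        / n
    )

    report = {
        "n_genes": n,
        "repeat_count_exact_match": exact / n,
        "cleavage_site_precision": precision,
        "cleavage_site_recall": recall,
        "status_accuracy": status_acc,
        "status_confusion": status_df,
    }
    inferred = predicted.get("__tree__")
    if inferred is not None and truth.tree_newick and n >= 3:
        if isinstance(inferred, str):
            inferred = FamilyTree(inferred)
        report["rf_distance"] = robinson_foulds(
            FamilyTree(truth.tree_newick), inferred
        )
    return report
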