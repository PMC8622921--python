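"""End-to-end pipeline: scan -> classify -> digest -> codon -> trees -> report.

One reproducible run over a FASTA of gene-scale sequences (plus an optional
coordinate table giving CDS offsets and species per gene). Every stage
failure is tagged with the stage name; the fully-resolved configuration is
archived into the output directory so a run can be replayed, and the JSON
report carries a hash of that configuration. Output content is a pure
function of (inputs, config) — no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon_stats import (
    codon_bias_flags,
    position_codon_counts,
    usage_distance,
    usage_wide_table,
)
from .family_evolution import assign_orthologs, nj_tree_from_seqs
from .gene_models import (
    classify_gene,
    digest_polyprotein,
    family_summary,
    find_cleavage_sites,
    isoform_table,
)
from .repeat_scanner import (
    find_all_repeat_regions,
    find_repeat_region,
    units_to_table,
)
from .seqio import (
    GeneRecord,
    Gff3Feature,
    canonical_attributes,
    gene_features,
    read_fasta,
    write_gff3,
)


class ConfigError(ValueError):
    """Bad or missing configuration / inputs (pre-flight)."""


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage tag."""


@dataclass
class RunConfig:
    fasta: str = ""
    coords: str | None = None          # TSV: id, species, cds_start, cds_end, strand
    outdir: str = "afgpkit_out"
    species: str = "unknown"           # fallback when no coordinate table
    min_units: int = 4
    max_other_frac: float = 0.1
    min_five_prime_nt: int = 30
    insertion_threshold_nt: int = 500
    min_repeats: int = 1
    depleted_threshold: float = 0.02
    distance_model: str = "JC69"
    build_trees: bool = True
    bootstrap_replicates: int = 0
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_records(config: RunConfig) -> list[GeneRecord]:
    pairs = read_fasta(config.fasta)
    coords = None
    if config.coords:
        coords = pd.read_csv(config.coords, sep="\t").set_index("id")
    records = []
    for gid, seq in pairs:
        if coords is not None and gid in coords.index:
            row = coords.loc[gid]
            rec = GeneRecord(
                id=gid,
                species=str(row.get("species", config.species)),
                seq=seq,
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
                strand=str(row.get("strand", "+")),
            )
        else:
            rec = GeneRecord(
                id=gid, species=config.species, seq=seq,
                cds_start=0, cds_end=len(seq),
            )
        records.append(rec)
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report; returns the report dict."""
    if not config.fasta or not Path(config.fasta).exists():
        raise ConfigError(f"input FASTA not found: {config.fasta!r}")
    if config.coords and not Path(config.coords).exists():
        raise ConfigError(f"coordinate table not found: {config.coords!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (ConfigError, StageError):
            raise
        except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    records = stage("load", _load_records, config)

    regions, genes_out, isoforms, tables = {}, [], {}, []
    unit_rows, flag_rows = [], []
    for rec in records:
        region = stage(
            "scan", find_repeat_region, rec.cds,
            config.min_units, config.max_other_frac,
        )
        regions[rec.id] = region
        cls = stage(
            "classify", classify_gene, rec, region,
            config.min_five_prime_nt, config.insertion_threshold_nt,
            config.min_units, config.max_other_frac,
        )
        if cls.status in ("functional", "pseudogene"):
            rec.status = cls.status
            rec.pseudogene_reason = cls.pseudogene_reason
        # the best tract drives digestion; a long insertion can split the
        # tract, so gene-level unit totals and site lists span every run
        all_regions = [] if region.is_empty else stage(
            "scan", find_all_repeat_regions, rec.cds,
            config.min_units, config.max_other_frac,
        )
        site_rows = []
        for reg in all_regions:
            for s in stage("cleave", find_cleavage_sites, reg):
                site_rows.append(
                    {
                        "unit_index": s.unit_index,
                        "cds_offset": reg.cds_offset_start + 9 * s.unit_index,
                        "site_type": s.site_type,
                    }
                )
        site_rows.sort(key=lambda s: s["cds_offset"])
        sites = [] if region.is_empty else stage(
            "cleave", find_cleavage_sites, region
        )
        isos = [] if region.is_empty else stage(
            "digest", digest_polyprotein, region, sites,
            rec.id, min_repeats=config.min_repeats,
        )
        isoforms[rec.id] = isos
        if not region.is_empty:
            table = stage("codon", position_codon_counts, region, rec.id)
            tables.append(table)
            for f in stage(
                "codon", codon_bias_flags, table, config.depleted_threshold
            ):
                flag_rows.append(
                    {"gene": rec.id, "kind": f.kind, "codon": f.codon,
                     "position": f.position, "amino_acid": f.amino_acid,
                     "frequency": round(f.frequency, 6)}
                )
            for row in units_to_table(region):
                unit_rows.append({"gene": rec.id, **row})
        genes_out.append(
            {
                "id": rec.id,
                "species": rec.species,
                "status": cls.status,
                "pseudogene_reason": cls.pseudogene_reason,
                "n_units": region.n_units,
                "n_repeat_units": region.n_repeat_units,
                "n_spacer_units": region.n_spacer_units,
                "n_repeat_units_total": sum(r.n_repeat_units for r in all_regions),
                "n_tracts": len(all_regions),
                "cds_offset_start": region.cds_offset_start,
                "cds_offset_end": region.cds_offset_end,
                "n_cleavage_sites": len(site_rows),
                "n_isoforms": len(isos),
                "cleavage_sites": site_rows,
            }
        )

    # GFF3 annotations
    for rec in records:
        feats = gene_features(rec)
        region = regions[rec.id]
        if not region.is_empty:
            rstart = rec.cds_start + region.cds_offset_start
            feats.append(
                Gff3Feature(
                    rec.id, "afgpkit", "repeat_region",
                    rstart, rec.cds_start + region.cds_offset_end, rec.strand,
                    canonical_attributes({"ID": f"{rec.id}.repeats"}),
                )
            )
            for g in genes_out:
                if g["id"] != rec.id:
                    continue
                for k, s in enumerate(g["cleavage_sites"]):
                    pos = rec.cds_start + s["cds_offset"]
                    feats.append(
                        Gff3Feature(
                            rec.id, "afgpkit", "cleavage_site",
                            pos, pos + 9, rec.strand,
                            canonical_attributes(
                                {"ID": f"{rec.id}.site{k}",
                                 "site_type": s["site_type"]}
                            ),
                        )
                    )
        rec.annotations["features"] = feats
    stage("gff3", write_gff3, outdir / "annotations.gff3", records)

    # tables
    summary = stage("summary", family_summary, records, regions, isoforms)
    summary.to_csv(outdir / "family_summary.tsv", sep="\t", index=False)
    isoform_table(isoforms).to_csv(outdir / "isoforms.tsv", sep="\t", index=False)
    pd.DataFrame(unit_rows).to_csv(outdir / "units.tsv", sep="\t", index=False)
    pd.DataFrame(flag_rows).to_csv(outdir / "codon_flags.tsv", sep="\t", index=False)
    if tables:
        usage_wide_table(tables).to_csv(outdir / "codon_usage.tsv", sep="\t")

    usage_d = {}
    for i, a in enumerate(tables):
        for b in tables[i + 1 :]:
            usage_d[f"{a.gene_id}|{b.gene_id}"] = round(usage_distance(a, b), 6)

    # trees from flanks (equal-length, gap-free mode)
    trees = {}
    ortholog_pairs = None
    if config.build_trees and len(records) >= 3:
        for side, attr in (("5", "flank5"), ("3", "flank3")):
            seqs = [(r.id, getattr(r, attr)) for r in records if getattr(r, attr)]
            lens = {len(s) for _, s in seqs}
            if len(seqs) >= 3 and len(lens) == 1 and lens != {0}:
                tree = stage(
                    "tree", nj_tree_from_seqs, seqs, config.distance_model
                )
                trees[side] = tree
                with open(outdir / f"tree{side}.nwk", "w") as fh:
                    fh.write(tree.newick + "\n")
        if len(trees) == 2 and len({r.species for r in records}) >= 2:
            cterm = {
                r.id: r.annotations.get("cterm_residues", "") for r in records
            }
            ortholog_pairs = stage(
                "orthologs", assign_orthologs, trees["5"], trees["3"], cterm
            )

    report = {
        "afgpkit_version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_genes": len(records),
        "genes": genes_out,
        "family_summary": summary.to_dict(orient="records"),
        "usage_distances": usage_d,
        "trees": {side: t.newick for side, t in trees.items()},
        "ortholog_pairs": ortholog_pairs,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
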