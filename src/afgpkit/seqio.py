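"""Sequence I/O and the core gene record model.

Internal coordinates are 0-based half-open throughout; emitted GFF3 is
1-based inclusive per the GFF3 specification. Minus-strand records are
normalised to coding orientation at load time so that downstream stages
(repeat scanning, digestion) can assume a coding-strand CDS.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_LETTERS = set("ACGTN")

STATUSES = ("functional", "pseudogene")
PSEUDOGENE_REASONS = (
    "none",
    "five_prime_truncated",
    "frameshift_indel",
    "coding_insertion",
)


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass
class GeneRecord:
    """One AFGP gene or pseudogene with its flanks and status.

    ``seq`` holds the full region (5' flank + CDS + 3' flank) on the
    coding strand; ``cds_start``/``cds_end`` are 0-based half-open
    offsets into ``seq``.
    """

    id: str
    species: str
    seq: str
    cds_start: int
    cds_end: int
    strand: str = "+"
    status: str = "functional"
    pseudogene_reason: str = "none"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - DNA_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-ACGTN letters {sorted(bad)}"
            )
        if not (0 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise ValueError(
                f"record {self.id!r}: CDS [{self.cds_start},{self.cds_end}) "
                f"out of range for sequence of length {len(self.seq)}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"record {self.id!r}: bad strand {self.strand!r}")
        if self.status not in STATUSES:
            raise ValueError(f"record {self.id!r}: bad status {self.status!r}")
        if self.pseudogene_reason not in PSEUDOGENE_REASONS:
            raise ValueError(
                f"record {self.id!r}: bad reason {self.pseudogene_reason!r}"
            )
        if self.status == "functional" and self.pseudogene_reason != "none":
            raise ValueError(
                f"record {self.id!r}: functional records must have reason 'none'"
            )

    @property
    def flank5(self) -> str:
        return self.seq[: self.cds_start]

    @property
    def flank3(self) -> str:
        return self.seq[self.cds_end :]

    @property
    def cds(self) -> str:
        return extract_cds(self)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_cds(record: GeneRecord) -> str:
    """CDS substring on the coding strand.

    For '-' strand records the stored slice is reverse-complemented so the
    returned string always reads 5'->3' in coding orientation.
    """
    if not (0 <= record.cds_start < record.cds_end <= len(record.seq)):
        raise ValueError("CDS coordinates out of range")
    sub = record.seq[record.cds_start : record.cds_end]
    return revcomp(sub) if record.strand == "-" else sub


def normalize_orientation(record: GeneRecord) -> GeneRecord:
    """Return a coding-orientation copy of a '-' strand record.

    The original orientation is remembered in ``annotations['original_strand']``
    so writers can restore it; '+' records are returned unchanged.
    """
    if record.strand == "+":
        return record
    n = len(record.seq)
    flipped = GeneRecord(
        id=record.id,
        species=record.species,
        seq=revcomp(record.seq),
        cds_start=n - record.cds_end,
        cds_end=n - record.cds_start,
        strand="+",
        status=record.status,
        pseudogene_reason=record.pseudogene_reason,
        annotations=dict(record.annotations),
    )
    flipped.annotations["original_strand"] = "-"
    return flipped


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered ``(id, sequence)`` pairs.

    Sequences are uppercased; duplicate ids, empty sequences and headerless
    leading sequence lines are rejected with the offending line number.
    """
    with open(path) as fh:
        text = fh.read()
    _prescan_fasta(text, str(path))
    out = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def _prescan_fasta(text: str, name: str) -> None:
    seen: dict[str, int] = {}
    current: str | None = None
    current_line = 0
    has_seq = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current is not None and not has_seq:
                raise FastaParseError(
                    f"{name}:{current_line}: record {current!r} has no sequence"
                )
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise FastaParseError(f"{name}:{lineno}: empty FASTA header")
            if header in seen:
                raise FastaParseError(
                    f"{name}:{lineno}: duplicate id {header!r} "
                    f"(first seen at line {seen[header]})"
                )
            seen[header] = lineno
            current, current_line, has_seq = header, lineno, False
        else:
            if current is None:
                raise FastaParseError(
                    f"{name}:{lineno}: sequence before any '>' header"
                )
            has_seq = True
    if current is not None and not has_seq:
        raise FastaParseError(
            f"{name}:{current_line}: record {current!r} has no sequence"
        )
    if current is None and text.strip():
        raise FastaParseError(f"{name}:1: no FASTA records found")


def write_fasta(path, records) -> None:
    """Write ``(id, seq)`` pairs (or GeneRecords) to FASTA, order preserved."""
    seqrecs = []
    for rec in records:
        if isinstance(rec, GeneRecord):
            rid, seq = rec.id, rec.seq
        else:
            rid, seq = rec
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

#: canonical attribute order for stable output
_ATTR_ORDER = ("ID", "Parent", "Name", "site_type", "unit_class", "status",
               "pseudogene_reason", "n_repeats", "size_bin")


@dataclass(frozen=True)
class Gff3Feature:
    """One GFF3 feature line; start/end are 0-based half-open internally."""

    seqid: str
    source: str
    type: str
    start: int   # 0-based
    end: int     # half-open
    strand: str
    attributes: tuple[tuple[str, str], ...]

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes)
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.type,
                str(self.start + 1),       # 1-based inclusive
                str(self.end),
                ".",
                self.strand,
                ".",
                attrs or ".",
            ]
        )


def canonical_attributes(attrs: dict) -> tuple[tuple[str, str], ...]:
    """Order attributes canonically: known keys first, rest alphabetical."""
    known = [(k, str(attrs[k])) for k in _ATTR_ORDER if k in attrs]
    rest = sorted((k, str(v)) for k, v in attrs.items() if k not in _ATTR_ORDER)
    return tuple(known + rest)


def write_gff3(path, records: list[GeneRecord]) -> None:
    """Emit gene/CDS plus any annotated repeat/cleavage features as GFF3.

    Each record must carry a ``features`` list in ``annotations`` (built by
    the annotation stages); records without one are rejected.
    """
    lines = ["##gff-version 3"]
    for rec in records:
        feats = rec.annotations.get("features")
        if feats is None:
            raise ValueError(f"record {rec.id!r} has no annotated features")
        for f in feats:
            lines.append(f.to_line())
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> list[Gff3Feature]:
    """Read GFF3 lines back into features (coordinates re-zeroed)."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            attrs = tuple(
                tuple(kv.split("=", 1))
                for kv in cols[8].split(";")
                if kv and kv != "."
            )
            feats.append(
                Gff3Feature(
                    seqid=cols[0],
                    source=cols[1],
                    type=cols[2],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return feats


def gene_features(record: GeneRecord, source: str = "afgpkit") -> list[Gff3Feature]:
    """Basic gene + CDS features for a record, on the forward axis."""
    attrs = canonical_attributes(
        {
            "ID": record.id,
            "status": record.status,
            "pseudogene_reason": record.pseudogene_reason,
        }
    )
    gene = Gff3Feature(record.id, source, "gene", 0, len(record.seq),
                       record.strand, attrs)
    cds = Gff3Feature(
        record.id, source, "CDS", record.cds_start, record.cds_end,
        record.strand,
        canonical_attributes({"ID": f"{record.id}.cds", "Parent": record.id}),
    )
    return [gene, cds]
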