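"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open throughout the package; GFF3
emission converts to the on-disk 1-based inclusive convention. FASTA input is
uppercased on read (public-database dumps mix case) and restricted to the
{A,C,G,T,N} alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

_VALID_RESIDUES = frozenset("ACGTN")
_SPECIES_RE = re.compile(r"species=([^;\t]+)")

#: feature kind -> Sequence Ontology friendly GFF3 type
SO_TYPES = {
    "element": "LTR_retrotransposon",
    "LTR5": "long_terminal_repeat",
    "LTR3": "long_terminal_repeat",
    "TSD": "target_site_duplication",
    "PBS": "primer_binding_site",
    "PPT": "RR_tract",
    "A_rich": "A_rich_region",
    "domain": "polypeptide_domain",
    "PTD": "polypeptide_domain",
}


@dataclass(frozen=True)
class GenomicSequence:
    """A named nucleotide sequence with an optional species label."""

    id: str
    residues: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise ValueError(f"sequence id {self.id!r} is empty or contains whitespace")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"illegal residue {self.residues[pos]!r} in sequence {self.id!r} "
                f"at offset {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AnnotationRecord:
    """One feature interval on a named sequence (0-based half-open)."""

    seq_id: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    score: float | None = None
    feature_id: str | None = None
    parent: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.kind} on {self.seq_id}"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a FASTA file into GenomicSequence records.

    Residues are uppercased; N is allowed. A ``species=<label>`` token in the
    description line is picked up as the species label. Raises ``ValueError``
    for an empty file or for residues outside {A,C,G,T,N} (naming the record
    and offset).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    out = []
    for rec in records:
        desc = rec.description or ""
        m = _SPECIES_RE.search(desc)
        species = m.group(1).strip() if m else ""
        out.append(
            GenomicSequence(
                id=rec.id, residues=str(rec.seq), species=species, description=desc
            )
        )
    return out


def write_fasta(seqs: Iterable[GenomicSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            desc = s.description
            if s.species and "species=" not in desc:
                desc = (desc + " " if desc else "") + f"species={s.species}"
            header = f">{s.id}" + (f" {desc}" if desc else "")
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


def validate_containment(records: Sequence[AnnotationRecord]) -> None:
    """Check that every child feature lies inside its parent's interval."""
    by_id = {r.feature_id: r for r in records if r.feature_id}
    for r in records:
        if r.parent:
            parent = by_id.get(r.parent)
            if parent is None:
                raise ValueError(f"feature {r.feature_id or r.kind} names unknown parent {r.parent}")
            if r.kind == "TSD":
                continue  # TSD flanks abut, not nest
            if not (parent.start <= r.start and r.end <= parent.end):
                raise ValueError(
                    f"feature {r.feature_id or r.kind} [{r.start},{r.end}) outside "
                    f"parent {r.parent} [{parent.start},{parent.end})"
                )


def _gff3_attributes(r: AnnotationRecord) -> str:
    parts = []
    if r.feature_id:
        parts.append(f"ID={r.feature_id}")
    if r.parent:
        parts.append(f"Parent={r.parent}")
    parts.append(f"kind={r.kind}")
    for k, v in r.attributes.items():
        parts.append(f"{k}={v}")
    return ";".join(parts)


def write_gff3(
    records: Sequence[AnnotationRecord],
    path: str | Path,
    seq_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write annotation records as GFF3 (1-based inclusive on disk).

    ``seq_lengths`` maps sequence ids to lengths; when given, intervals are
    validated against it and ``##sequence-region`` pragmas are emitted.
    """
    if seq_lengths is not None:
        for r in records:
            if r.seq_id not in seq_lengths:
                raise ValueError(f"record references unknown sequence {r.seq_id!r}")
            if r.end > seq_lengths[r.seq_id]:
                raise ValueError(
                    f"interval [{r.start},{r.end}) outside sequence {r.seq_id!r} "
                    f"of length {seq_lengths[r.seq_id]}"
                )
    validate_containment(records)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seq_lengths:
            for sid in sorted({r.seq_id for r in records} & set(seq_lengths)):
                fh.write(f"##sequence-region {sid} 1 {seq_lengths[sid]}\n")
        for r in records:
            so_type = SO_TYPES.get(r.kind, r.kind)
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(
                "\t".join(
                    [
                        r.seq_id,
                        "centroscan",
                        so_type,
                        str(r.start + 1),
                        str(r.end),
                        score,
                        r.strand,
                        ".",
                        _gff3_attributes(r),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    """Read annotation records written by :func:`write_gff3`."""
    out: list[AnnotationRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs: dict = {}
            for item in cols[8].split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attrs[key] = value
            kind = attrs.pop("kind", cols[2])
            out.append(
                AnnotationRecord(
                    seq_id=cols[0],
                    kind=kind,
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    score=None if cols[5] == "." else float(cols[5]),
                    feature_id=attrs.pop("ID", None),
                    parent=attrs.pop("Parent", None),
                    attributes=attrs,
                )
            )
    return out


#: column order of the per-element summary table
ELEMENT_TABLE_COLUMNS = [
    "element_id", "seq_id", "species", "family", "group", "clade",
    "start", "end", "strand", "element_length", "ltr_length",
    "tsd", "pbs_length", "ppt_length", "age_my",
]


def write_element_table(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write the per-element summary TSV (family, group, lengths, TSD, age...)."""
    import pandas as pd

    df = pd.DataFrame(list(rows))
    cols = [c for c in ELEMENT_TABLE_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in ELEMENT_TABLE_COLUMNS
    ]
    if len(df):
        df = df[cols]
    df.to_csv(path, sep="\t", index=False)


def write_newick(tree, path: str | Path) -> None:
    """Serialize a PhyloTree to Newick (supports as internal node labels)."""
    labels = tree.leaf_labels()
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def read_newick(path: str | Path):
    """Read a Newick file back into a PhyloTree (via dendropy)."""
    import dendropy

    from .phylo import Node, PhyloTree

    dt = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            return Node(
                label=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length or 0.0,
            )
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                support = None
        return Node(
            label=None,
            length=dnode.edge.length or 0.0,
            support=support,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dt.seed_node)
    tree = PhyloTree(root)
    labels = tree.leaf_labels()
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in Newick file")
    return tree
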