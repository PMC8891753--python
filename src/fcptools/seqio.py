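"""Protein FASTA and binding-site annotation I/O.

All residue coordinates in the public API are 1-based, following the
crystallographic convention used for light-harvesting complex structures.
Sequences are uppercase strings over the 20 canonical amino acids plus
``X`` (unknown residue); ``X`` never satisfies a binding-site match.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

FAMILIES = ("lhcf", "lhcr", "lhcx", "lhcz", "unclassified")

PIGMENT_CLASSES = ("chl_a", "chl_c", "fx")
LIGAND_CLASSES = ("central", "h_bond")


class SeqIOError(ValueError):
    """Raised for malformed sequence or annotation inputs."""


@dataclass
class ProteinRecord:
    """A single protein sequence with provenance and optional family label."""

    id: str
    sequence: str
    species: str = ""
    family_label: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein record has an empty id")
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )
        if self.family_label is not None and self.family_label not in FAMILIES:
            raise SeqIOError(
                f"record {self.id!r}: unknown family label {self.family_label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BindingSiteAnnotation:
    """A reference pigment-binding residue on a crystallographically
    characterised Lhcf protein.

    ``ref_pos`` is the 1-based residue index on ``ref_seq_id``.  A site may
    carry alternate residues (e.g. "T or V" central ligands) which count as
    present but are reported separately from the primary residue.
    ``conserved_flag`` marks whether the ligand position is conserved
    relative to the plant LHCII chlorophyll sites.
    """

    site_id: str
    pigment_class: str
    ligand_class: str
    ref_seq_id: str
    ref_pos: int
    primary_residue: str
    alternate_residues: frozenset[str] = frozenset()
    conserved_flag: bool = True

    def __post_init__(self) -> None:
        if self.pigment_class not in PIGMENT_CLASSES:
            raise SeqIOError(
                f"site {self.site_id!r}: unknown pigment class {self.pigment_class!r}"
            )
        if self.ligand_class not in LIGAND_CLASSES:
            raise SeqIOError(
                f"site {self.site_id!r}: unknown ligand class {self.ligand_class!r}"
            )
        if self.ref_pos < 1:
            raise SeqIOError(f"site {self.site_id!r}: ref_pos must be >= 1")
        if self.primary_residue not in set(AMINO_ACIDS):
            raise SeqIOError(
                f"site {self.site_id!r}: invalid primary residue "
                f"{self.primary_residue!r}"
            )
        self.alternate_residues = frozenset(self.alternate_residues)
        if self.primary_residue in self.alternate_residues:
            raise SeqIOError(
                f"site {self.site_id!r}: primary residue listed as alternate"
            )

    @property
    def allowed_residues(self) -> frozenset[str]:
        return self.alternate_residues | {self.primary_residue}


def _species_from_description(desc: str) -> str:
    for token in desc.split():
        if token.startswith("species="):
            return token[len("species=") :].replace("_", " ")
    return ""


def read_fasta(
    path: str | Path, species_table: dict[str, str] | None = None
) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    The id is the first whitespace-delimited header token.  Species is taken
    from a ``species=`` key in the description when present, else from the
    optional ``species_table`` mapping of id to species name.
    """
    path = Path(path)
    if not path.exists():
        raise SeqIOError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SeqIOError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id) :].strip()
        species = _species_from_description(desc)
        if not species and species_table:
            species = species_table.get(entry.id, "")
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=str(entry.seq),
                species=species,
                description=desc,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as multi-FASTA, wrapped at 60 columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqs = []
    for rec in records:
        desc = rec.description
        if rec.species and "species=" not in desc:
            tag = f"species={rec.species.replace(' ', '_')}"
            desc = f"{desc} {tag}".strip()
        seqs.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


def read_species_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, species) sidecar TSV."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table[row[0]] = row[1]
    return table


ANNOTATION_COLUMNS = [
    "site_id",
    "pigment_class",
    "ligand_class",
    "ref_seq_id",
    "ref_pos",
    "primary_residue",
    "alternate_residues",
    "conserved_flag",
]


def read_site_annotations(
    path: str | Path, refs: Sequence[ProteinRecord]
) -> list[BindingSiteAnnotation]:
    """Read a binding-site annotation TSV and cross-check it against the
    reference sequences.

    Every row must name a resolvable reference sequence, and the residue at
    ``ref_pos`` of that sequence must equal ``primary_residue``; rows that
    disagree are rejected with the offending ``site_id`` named.
    """
    by_id = {r.id: r for r in refs}
    annotations: list[BindingSiteAnnotation] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != ANNOTATION_COLUMNS:
            raise SeqIOError(
                f"annotation TSV {path} must have columns {ANNOTATION_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            alts = frozenset(
                a for a in row["alternate_residues"].split(",") if a
            )
            ann = BindingSiteAnnotation(
                site_id=row["site_id"],
                pigment_class=row["pigment_class"],
                ligand_class=row["ligand_class"],
                ref_seq_id=row["ref_seq_id"],
                ref_pos=int(row["ref_pos"]),
                primary_residue=row["primary_residue"],
                alternate_residues=alts,
                conserved_flag=row["conserved_flag"].strip().lower() == "true",
            )
            ref = by_id.get(ann.ref_seq_id)
            if ref is None:
                raise SeqIOError(
                    f"site {ann.site_id!r}: unknown reference sequence "
                    f"{ann.ref_seq_id!r}"
                )
            if ann.ref_pos > len(ref):
                raise SeqIOError(
                    f"site {ann.site_id!r}: ref_pos {ann.ref_pos} beyond end of "
                    f"{ref.id!r} (length {len(ref)})"
                )
            found = ref.sequence[ann.ref_pos - 1]
            if found != ann.primary_residue:
                raise SeqIOError(
                    f"site {ann.site_id!r}: reference {ref.id!r} has {found!r} "
                    f"at position {ann.ref_pos}, annotation says "
                    f"{ann.primary_residue!r}"
                )
            annotations.append(ann)
    return annotations


def write_site_annotations(
    annotations: Iterable[BindingSiteAnnotation], path: str | Path
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(ANNOTATION_COLUMNS)
        for ann in annotations:
            writer.writerow(
                [
                    ann.site_id,
                    ann.pigment_class,
                    ann.ligand_class,
                    ann.ref_seq_id,
                    ann.ref_pos,
                    ann.primary_residue,
                    ",".join(sorted(ann.alternate_residues)),
                    "true" if ann.conserved_flag else "false",
                ]
            )
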