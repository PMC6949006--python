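"""Reading and writing per-locus alignments and the sample-role map.

Each locus of the study is one aligned FASTA file containing the two
parental panels and the putative hybrids.  Sequence headers follow the
grammar ``>sample_id[|clone_id][|role]``: the role token, when present,
overrides the sample map, so both map-driven and header-driven labelling
are accepted.  Alignment columns are 1-based and inclusive throughout the
package, matching how site positions are reported in the field.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

ROLES = ("parent_a", "parent_b", "hybrid")
READ_TYPES = ("direct", "clone")

#: residues kept verbatim after normalisation; anything else becomes 'N'
_VALID = set("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised for ragged alignments or length mismatches."""


class MappingError(KeyError):
    """Raised when a FASTA header cannot be resolved against the sample map."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: a direct Sanger read or a single clone read."""

    sample_id: str
    locus: str
    role: str
    read_type: str  # "direct" or "clone"
    sequence: str
    clone_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.sample_id}")
        if self.read_type not in READ_TYPES:
            raise ValueError(f"unknown read_type {self.read_type!r}")
        if (self.clone_id is not None) != (self.read_type == "clone"):
            raise ValueError(
                f"{self.sample_id}: clone_id must be present exactly for clone reads"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LocusAlignment:
    """All records of one locus, sharing a common alignment length."""

    locus: str
    marker_class: str  # "nuclear" or "chloroplast"
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.marker_class not in ("nuclear", "chloroplast"):
            raise ValueError(f"unknown marker_class {self.marker_class!r}")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            bad = next(r for r in self.records if len(r) != len(self.records[0]))
            raise AlignmentError(
                f"locus {self.locus}: ragged alignment; record {bad.sample_id} "
                f"has length {len(bad)}, expected {len(self.records[0])}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0]) if self.records else 0


@dataclass
class SampleMap:
    """sample_id -> (role, display name)."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def role_of(self, sample_id: str) -> str:
        try:
            return self.entries[sample_id][0]
        except KeyError:
            raise MappingError(f"sample_id {sample_id!r} absent from sample map")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMap":
        entries: dict[str, tuple[str, str]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                role = row["role"]
                if role not in ROLES:
                    raise ValueError(f"sample map: unknown role {role!r}")
                entries[row["sample_id"]] = (role, row.get("name", row["sample_id"]))
        return cls(entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["sample_id", "role", "name"])
            for sid, (role, name) in self.entries.items():
                w.writerow([sid, role, name])


def normalize_sequence(seq: str) -> str:
    """Uppercase; '?' and '.' (and any other unknown residue) become 'N'."""
    out = []
    for ch in seq.upper():
        out.append(ch if ch in _VALID else "N")
    return "".join(out)


def _parse_header(header: str, sample_map: SampleMap) -> tuple[str, str | None, str]:
    parts = header.split("|")
    if not parts or not parts[0]:
        raise MappingError(f"empty FASTA header {header!r}")
    sample_id = parts[0]
    clone_id: str | None = None
    role: str | None = None
    for tok in parts[1:]:
        if tok in ROLES:
            role = tok
        elif clone_id is None:
            clone_id = tok
        else:
            raise MappingError(f"header {header!r} does not match grammar")
    if role is None:
        role = sample_map.role_of(sample_id)
    return sample_id, clone_id, role


def read_locus_fasta(
    path: str | Path,
    locus: str,
    marker_class: str,
    sample_map: SampleMap,
) -> LocusAlignment:
    """Read one locus's aligned FASTA into a :class:`LocusAlignment`.

    Headers follow ``>sample_id[|clone_id][|role]``; a record carrying a
    clone_id is a clone-phased read, otherwise it is a direct read.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sample_id, clone_id, role = _parse_header(rec.id, sample_map)
        records.append(
            SequenceRecord(
                sample_id=sample_id,
                clone_id=clone_id,
                locus=locus,
                role=role,
                read_type="clone" if clone_id is not None else "direct",
                sequence=normalize_sequence(str(rec.seq)),
            )
        )
    return LocusAlignment(locus=locus, marker_class=marker_class, records=records)


def write_locus_fasta(aln: LocusAlignment, path: str | Path) -> None:
    """Write normalized FASTA with the package's header grammar."""
    bio = []
    for r in aln.records:
        hid = r.sample_id
        if r.clone_id is not None:
            hid += f"|{r.clone_id}"
        hid += f"|{r.role}"
        bio.append(_BioRecord(Seq(r.sequence), id=hid, description=""))
    SeqIO.write(bio, str(path), "fasta")


def partition_by_role(
    aln: LocusAlignment,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (parent_a, parent_b, hybrid) lists, input order kept."""
    a = [r for r in aln.records if r.role == "parent_a"]
    b = [r for r in aln.records if r.role == "parent_b"]
    h = [r for r in aln.records if r.role == "hybrid"]
    return a, b, h


def alignment_length(aln: LocusAlignment) -> int:
    """Number of alignment columns (1-based indexing downstream)."""
    return aln.length
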