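"""Reference sequences, class labels and region annotations.

Every coordinate in this package is 1-based and inclusive on the sense
strand of the reference, the convention in which snRNA positions are
reported in the literature (e.g. the U1-70K binding site at U1 nucleotides
20-27).  BED (0-based, half-open) is produced only at the export boundary.

RNA references are stored in the DNA alphabet (U -> T on input) so that
snRNA, SL RNA and genomic contigs share one alignment alphabet.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REF_CLASSES = ("U1", "U2", "U4", "U5", "U6", "SL", "tRNA", "rRNA", "genomic")
SNRNA_CLASSES = ("U1", "U2", "U4", "U5", "U6")
DECOY_CLASSES = ("tRNA", "rRNA")
#: classes whose tags constitute the biological signal of the assay
SIGNAL_CLASSES = SNRNA_CLASSES + ("SL",)

VALID_CHARS = frozenset("ACGTN")
SL_LENGTH_DEFAULT = 139


@dataclass(frozen=True)
class ReferenceSequence:
    """A named reference with a class label; sequence over {A,C,G,T,N}."""

    id: str
    ref_class: str
    seq: str

    def __post_init__(self) -> None:
        if self.ref_class not in REF_CLASSES:
            raise ValueError(
                f"unknown ref_class {self.ref_class!r} for {self.id!r}; "
                f"expected one of {REF_CLASSES}"
            )
        if len(self.seq) == 0:
            raise ValueError(f"reference {self.id!r} has empty sequence")
        for i, c in enumerate(self.seq):
            if c not in VALID_CHARS:
                raise ValueError(
                    f"invalid character {c!r} in reference {self.id!r} "
                    f"at position {i + 1}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RegionAnnotation:
    """A named region on a reference, 1-based inclusive."""

    ref_id: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad region {self.name!r} on {self.ref_id!r}: "
                f"need 1 <= start <= end, got {self.start}..{self.end}"
            )

    def to_bed_fields(self) -> tuple[str, int, int, str]:
        """(chrom, chromStart, chromEnd, name) in 0-based half-open BED."""
        return (self.ref_id, self.start - 1, self.end, self.name)

    @classmethod
    def from_bed_fields(cls, chrom: str, start: int, end: int, name: str) -> "RegionAnnotation":
        return cls(ref_id=chrom, name=name, start=start + 1, end=end)


@dataclass
class ReferenceSet:
    """All references of one analysis plus their region annotations.

    ``sl_ref_id`` names the single SL RNA sequence used by the separate
    SL alignment pass (the SL locus is a multi-copy tandem array in the
    genome, so SL reads cannot map uniquely there).
    """

    sequences: dict[str, ReferenceSequence]
    annotations: list[RegionAnnotation] = field(default_factory=list)
    sl_ref_id: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, sl_length: int = SL_LENGTH_DEFAULT) -> None:
        for ann in self.annotations:
            if ann.ref_id not in self.sequences:
                raise ValueError(f"annotation {ann.name!r} references unknown id {ann.ref_id!r}")
            if ann.end > self.sequences[ann.ref_id].length:
                raise ValueError(
                    f"annotation {ann.name!r} exceeds length of {ann.ref_id!r}"
                )
        if self.sl_ref_id is not None:
            if self.sl_ref_id not in self.sequences:
                raise ValueError(f"sl_ref_id {self.sl_ref_id!r} not in reference set")
            sl = self.sequences[self.sl_ref_id]
            if sl.ref_class != "SL":
                raise ValueError(f"sl_ref_id {self.sl_ref_id!r} has class {sl.ref_class}, not SL")
            if sl.length != sl_length:
                raise ValueError(
                    f"SL reference {self.sl_ref_id!r} has length {sl.length}, "
                    f"expected {sl_length}"
                )

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.sequences

    def get(self, ref_id: str) -> ReferenceSequence:
        try:
            return self.sequences[ref_id]
        except KeyError:
            raise KeyError(f"unknown reference {ref_id!r}") from None

    def length(self, ref_id: str) -> int:
        return self.get(ref_id).length

    def by_class(self, *classes: str) -> list[ReferenceSequence]:
        return [s for s in self.sequences.values() if s.ref_class in classes]

    def ref_class(self, ref_id: str) -> str:
        return self.get(ref_id).ref_class

    @property
    def sl_reference(self) -> ReferenceSequence:
        if self.sl_ref_id is None:
            raise ValueError("reference set has no SL reference configured")
        return self.sequences[self.sl_ref_id]


def resolve_class(ref_id: str, class_map: Mapping[str, str]) -> str:
    """Look up a reference class: exact id first, then ``prefix*`` rules."""
    if ref_id in class_map:
        return class_map[ref_id]
    for key, cls in class_map.items():
        if key.endswith("*") and ref_id.startswith(key[:-1]):
            return cls
    raise ValueError(f"no reference class configured for id {ref_id!r}")


def load_references(
    fasta_path: str | Path,
    class_map: Mapping[str, str],
    sl_length: int = SL_LENGTH_DEFAULT,
) -> ReferenceSet:
    """Load a FASTA reference set, assigning classes from ``class_map``.

    U is converted to T on input.  Ids without a configured class raise
    rather than defaulting; duplicate ids and non-IUPAC characters raise.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(str(fasta_path))
    sequences: dict[str, ReferenceSequence] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate reference id {record.id!r}")
        seq = str(record.seq).upper().replace("U", "T")
        cls = resolve_class(record.id, class_map)
        sequences[record.id] = ReferenceSequence(id=record.id, ref_class=cls, seq=seq)
    if not sequences:
        raise ValueError(f"no sequences in {fasta_path}")
    sl_ids = [s.id for s in sequences.values() if s.ref_class == "SL"]
    sl_ref_id = sl_ids[0] if len(sl_ids) == 1 else None
    return ReferenceSet(sequences=sequences, sl_ref_id=sl_ref_id)


def write_fasta(refset: ReferenceSet, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="")
        for s in refset.sequences.values()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def load_class_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: reference id (``prefix*`` allowed) <tab> class."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ValueError(f"malformed class-map row: {row!r}")
            out[row[0]] = row[1]
    return out


def write_class_map(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in refset.sequences.values():
            fh.write(f"{s.id}\t{s.ref_class}\n")


# Canonical regions of the trypanosome snRNA/SL system:
#   U1 5' terminal region 1-9 (U1C contact region), U1-70K site AUCACGAA at
#   20-27, the SL 5' splice-site cluster 36-43 (the mini-exon ends after
#   position 39), the SL central loop 79-82, and the invariant U6 ACAGAG
#   box at 37-42.
_DEFAULT_ANNOTATIONS: tuple[tuple[str, str, int, int], ...] = (
    ("U1", "five_prime_terminal", 1, 9),
    ("U1", "u1_70k_site", 20, 27),
    ("SL", "five_prime_splice_site_cluster", 36, 43),
    ("SL", "central_loop", 79, 82),
    ("U6", "acagag_box", 37, 42),
)


def build_default_annotations(refset: ReferenceSet) -> list[RegionAnnotation]:
    """Default snRNA/SL region annotations, clipped to reference length.

    Targets are located by reference class (U1, SL, U6), so the ids in the
    FASTA are free-form.  A missing target class is an error.
    """
    by_class: dict[str, ReferenceSequence] = {}
    for cls in ("U1", "SL", "U6"):
        seqs = refset.by_class(cls)
        if not seqs:
            raise ValueError(f"annotation target {cls} missing")
        by_class[cls] = seqs[0]
    out: list[RegionAnnotation] = []
    for cls, name, start, end in _DEFAULT_ANNOTATIONS:
        ref = by_class[cls]
        if start > ref.length:
            raise ValueError(
                f"annotation {name!r} starts beyond the end of {ref.id!r}"
            )
        out.append(
            RegionAnnotation(ref_id=ref.id, name=name, start=start, end=min(end, ref.length))
        )
    return out


def write_annotations(annotations: Iterable[RegionAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\tname\tstart\tend\n")
        for a in annotations:
            fh.write(f"{a.ref_id}\t{a.name}\t{a.start}\t{a.end}\n")


def load_annotations(path: str | Path) -> list[RegionAnnotation]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                RegionAnnotation(
                    ref_id=row["ref_id"],
                    name=row["name"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
    return out


def write_bed(annotations: Iterable[RegionAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            chrom, start, end, name = a.to_bed_fields()
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def load_bed(path: str | Path) -> list[RegionAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            out.append(RegionAnnotation.from_bed_fields(chrom, int(start), int(end), name))
    return out


def with_annotations(refset: ReferenceSet, annotations: Iterable[RegionAnnotation]) -> ReferenceSet:
    """A copy of ``refset`` with ``annotations`` appended (validated)."""
    return ReferenceSet(
        sequences=dict(refset.sequences),
        annotations=list(refset.annotations) + list(annotations),
        sl_ref_id=refset.sl_ref_id,
    )
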