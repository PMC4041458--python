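"""Raw-read processing: demultiplexing, UMI extraction, adapter trimming.

An iCLIP read begins with a 5' header of ``lead_random + sample_barcode +
trail_random`` nucleotides.  The two random parts concatenated (in read
order) form the unique molecular identifier (UMI) used downstream to
collapse PCR duplicates; the fixed part identifies the multiplexed sample.
After header removal, the 3' sequencing adapter is trimmed and inserts
shorter than ``min_len`` (default 15 nt, the shortest confidently mappable
cDNA on these small references) are discarded but counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

UNASSIGNED = "UNASSIGNED"

DEFAULT_ADAPTER = "AGATCGGAAGAGCGGTTCAG"
DEFAULT_MIN_LEN = 15
UMI_DELIMITER = " UMI:"


@dataclass(frozen=True)
class BarcodeLayout:
    """Positions of random-mers and the sample barcode in the 5' header."""

    lead_random_len: int = 3
    sample_len: int = 4
    trail_random_len: int = 2

    def __post_init__(self) -> None:
        if self.lead_random_len < 0 or self.trail_random_len < 0:
            raise ValueError("random-mer lengths must be >= 0")
        if self.sample_len < 1:
            raise ValueError("sample barcode length must be >= 1")

    @property
    def header_len(self) -> int:
        return self.lead_random_len + self.sample_len + self.trail_random_len

    @property
    def umi_len(self) -> int:
        return self.lead_random_len + self.trail_random_len


DEFAULT_LAYOUT = BarcodeLayout()
#: default multiplex: tagged-protein samples plus the wild-type control lane;
#: pairwise Hamming distance 4 keeps assignment unambiguous up to max_mm=1
DEFAULT_SAMPLE_BARCODES: dict[str, str] = {"u1c": "ACGT", "u70k": "CATG", "wt": "GTCA"}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def validate_barcode_set(
    sample_barcodes: Mapping[str, str],
    layout: BarcodeLayout | None = None,
    min_distance: int = 2,
) -> None:
    """Reject barcode sets that would make demultiplexing unsafe."""
    items = sorted(sample_barcodes.items())
    if not items:
        raise ValueError("empty barcode set")
    lengths = {len(b) for _, b in items}
    if len(lengths) != 1:
        raise ValueError("sample barcodes must all have the same length")
    if layout is not None and lengths != {layout.sample_len}:
        raise ValueError(
            f"barcode length {lengths.pop()} does not match layout sample_len "
            f"{layout.sample_len}"
        )
    for i, (sa, ba) in enumerate(items):
        for sb, bb in items[i + 1 :]:
            d = hamming(ba, bb)
            if d < min_distance:
                raise ValueError(
                    f"barcodes {sa!r} ({ba}) and {sb!r} ({bb}) are at Hamming "
                    f"distance {d} < {min_distance}"
                )


def demultiplex(
    read_seq: str,
    layout: BarcodeLayout,
    sample_barcodes: Mapping[str, str],
    max_mm: int = 0,
) -> str:
    """Assign a read to a sample by its fixed barcode, or ``UNASSIGNED``.

    A read is assigned iff exactly one barcode lies within ``max_mm``
    mismatches of the observed barcode field; zero or several candidates
    (ambiguity) give ``UNASSIGNED``, as does a read shorter than the header.
    """
    if len(read_seq) < layout.header_len:
        return UNASSIGNED
    observed = read_seq[layout.lead_random_len : layout.lead_random_len + layout.sample_len]
    candidates = [
        sample
        for sample, barcode in sample_barcodes.items()
        if hamming(observed, barcode) <= max_mm
    ]
    if len(candidates) == 1:
        return candidates[0]
    return UNASSIGNED


def extract_umi(read_seq: str, layout: BarcodeLayout) -> tuple[str, str]:
    """Return (umi, remainder): random-mer parts in read order, header removed."""
    if len(read_seq) < layout.header_len:
        raise ValueError(
            f"read of length {len(read_seq)} shorter than header ({layout.header_len})"
        )
    lead = read_seq[: layout.lead_random_len]
    trail = read_seq[
        layout.lead_random_len + layout.sample_len : layout.header_len
    ]
    return lead + trail, read_seq[layout.header_len :]


def _mismatch_positions(insert: str, adapter: str) -> np.ndarray:
    """Mismatch count of ``adapter`` against every window of ``insert``."""
    ins = np.frombuffer(insert.encode("ascii"), dtype=np.uint8)
    ad = np.frombuffer(adapter.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ins, len(ad))
    return (windows != ad).sum(axis=1)


def trim_adapter(
    insert: str,
    adapter: str,
    min_overlap: int = 3,
    max_mm_rate: float = 0.1,
) -> str:
    """Remove the 3' adapter and everything after it (single pass).

    The leftmost full internal occurrence of the adapter (mismatch fraction
    <= ``max_mm_rate``) wins; failing that, the longest terminal suffix of
    the insert matching a prefix of the adapter with overlap >=
    ``min_overlap`` is removed.  If neither exists the insert is returned
    unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    la = len(adapter)
    n = len(insert)
    if n >= la:
        allowed = int(max_mm_rate * la)
        mism = _mismatch_positions(insert, adapter)
        hits = np.nonzero(mism <= allowed)[0]
        if hits.size:
            return insert[: int(hits[0])]
    for ov in range(min(la, n), min_overlap - 1, -1):
        allowed = int(max_mm_rate * ov)
        if hamming(insert[n - ov :], adapter[:ov]) <= allowed:
            return insert[: n - ov]
    return insert


def length_filter(insert: str, min_len: int = DEFAULT_MIN_LEN) -> bool:
    """True iff the trimmed insert is long enough to align (>= min_len)."""
    return len(insert) >= min_len


@dataclass(frozen=True)
class ProcessedRead:
    read_id: str
    sample_id: str
    umi: str
    insert: str

    @property
    def insert_len(self) -> int:
        return len(self.insert)


@dataclass
class ProcessingStats:
    """Read accounting; categories partition the input exactly."""

    n_input: int = 0
    n_unassigned_barcode: int = 0
    n_too_short: int = 0
    n_passed: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_input != self.n_unassigned_barcode + self.n_too_short + self.n_passed:
            raise AssertionError("processing accounting identity violated")
        if sum(self.per_sample.values()) != self.n_passed:
            raise AssertionError("per-sample pass counts do not sum to n_passed")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_unassigned_barcode": self.n_unassigned_barcode,
            "n_too_short": self.n_too_short,
            "n_passed": self.n_passed,
            "per_sample": dict(sorted(self.per_sample.items())),
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def process_reads(
    reads: Iterable[tuple[str, str]],
    layout: BarcodeLayout = DEFAULT_LAYOUT,
    sample_barcodes: Mapping[str, str] = DEFAULT_SAMPLE_BARCODES,
    adapter: str = DEFAULT_ADAPTER,
    max_mm: int = 0,
    min_len: int = DEFAULT_MIN_LEN,
    min_overlap: int = 3,
    max_mm_rate: float = 0.1,
) -> tuple[list[ProcessedRead], ProcessingStats]:
    """Demultiplex, strip the header, trim the adapter and length-filter.

    ``reads`` is an iterable of ``(read_id, sequence)``.  Reads shorter
    than the header count as barcode-unassigned; reads whose trimmed
    insert is below ``min_len`` are counted but not emitted.
    """
    validate_barcode_set(sample_barcodes, layout, min_distance=max(2, 2 * max_mm + 1))
    passed: list[ProcessedRead] = []
    stats = ProcessingStats(per_sample={s: 0 for s in sample_barcodes})
    for read_id, seq in reads:
        stats.n_input += 1
        seq = seq.upper()
        sample = demultiplex(seq, layout, sample_barcodes, max_mm=max_mm)
        if sample == UNASSIGNED:
            stats.n_unassigned_barcode += 1
            continue
        umi, remainder = extract_umi(seq, layout)
        insert = trim_adapter(remainder, adapter, min_overlap=min_overlap, max_mm_rate=max_mm_rate)
        if not length_filter(insert, min_len=min_len):
            stats.n_too_short += 1
            continue
        stats.n_passed += 1
        stats.per_sample[sample] += 1
        passed.append(ProcessedRead(read_id=read_id, sample_id=sample, umi=umi, insert=insert))
    stats.check()
    return passed, stats


def iter_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    for record in SeqIO.parse(str(path), "fastq"):
        yield record.id, str(record.seq)


def process_fastq(path: str | Path, **kwargs) -> tuple[list[ProcessedRead], ProcessingStats]:
    return process_reads(iter_fastq(path), **kwargs)


def write_processed_fastq(
    reads: Iterable[ProcessedRead],
    out_dir: str | Path,
    delimiter: str = UMI_DELIMITER,
    quality_char: str = "I",
) -> dict[str, Path]:
    """One insert FASTQ per sample; UMI carried in the read description."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handles: dict[str, object] = {}
    paths: dict[str, Path] = {}
    try:
        for r in reads:
            if r.sample_id not in handles:
                paths[r.sample_id] = out_dir / f"{r.sample_id}.fastq"
                handles[r.sample_id] = open(paths[r.sample_id], "w")
            fh = handles[r.sample_id]
            fh.write(f"@{r.read_id}{delimiter}{r.umi}\n{r.insert}\n+\n{quality_char * r.insert_len}\n")
    finally:
        for fh in handles.values():
            fh.close()
    return paths


def read_processed_fastq(path: str | Path, sample_id: str, delimiter: str = UMI_DELIMITER) -> list[ProcessedRead]:
    out = []
    for record in SeqIO.parse(str(path), "fastq"):
        desc = record.description
        if delimiter.strip() and delimiter.strip() in desc:
            umi = desc.split(delimiter.strip())[-1].lstrip(":").strip()
            umi = umi.split()[0] if umi else ""
        else:
            umi = ""
        out.append(ProcessedRead(read_id=record.id, sample_id=sample_id, umi=umi, insert=str(record.seq)))
    return out
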