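"""Ungapped read alignment to a small reference set, with SL rescue.

The mapper is an exhaustive Hamming-distance scan: every placement of the
insert on every allowed reference/strand is scored, and the best stratum
(all placements at the minimum distance <= max_mm) is returned.  On
references this small an exact scan is both fast (vectorised over
positions) and provably correct against a position-by-position oracle,
which a heuristic seeded aligner is not.

Strand policy: RNA-class references are searched on the sense strand only
(iCLIP cDNAs are sense copies of the bound RNA); genomic contigs are
searched on both strands.

Two passes mirror the multi-copy SL RNA locus problem: pass 1 (the
"genome" pass) uses every reference except the standalone SL sequence;
reads left multi-mapped or unmapped are then aligned to the 139-nt SL RNA
alone, where an SL-array read becomes uniquely placeable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reads import ProcessedRead
from .references import DECOY_CLASSES, ReferenceSet

STATUS_UNIQUE = "unique"
STATUS_MULTI = "multi"
STATUS_UNMAPPED = "unmapped"
STATUS_EXCLUDED = "excluded_class"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    read_id: str
    ref_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    n_mismatch: int


@dataclass(frozen=True)
class MappingResult:
    read_id: str
    status: str
    best: Alignment | None
    n_best_hits: int


class ReferenceIndex:
    """Byte-array views of the references for vectorised window scoring."""

    def __init__(self, refset: ReferenceSet, exclude_classes: Sequence[str] = ()):
        self.refset = refset
        self._arrays: list[tuple[str, str, np.ndarray]] = []
        for ref in refset.sequences.values():
            if ref.ref_class in exclude_classes:
                continue
            arr = np.frombuffer(ref.seq.encode("ascii"), dtype=np.uint8)
            self._arrays.append((ref.id, ref.ref_class, arr))

    def scan(self, insert: str, max_mm: int, read_id: str = "") -> list[Alignment]:
        """All best-stratum placements of ``insert`` (distance <= max_mm)."""
        fwd = np.frombuffer(insert.encode("ascii"), dtype=np.uint8)
        rev = np.frombuffer(revcomp(insert).encode("ascii"), dtype=np.uint8)
        n = len(insert)
        hits: list[tuple[int, str, int, str]] = []  # (mm, ref_id, start0, strand)
        best = max_mm
        for ref_id, ref_class, arr in self._arrays:
            if n > arr.size:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, n)
            queries = [("+", fwd)]
            if ref_class == "genomic":
                queries.append(("-", rev))
            for strand, q in queries:
                mism = (windows != q).sum(axis=1)
                for pos in np.nonzero(mism <= best)[0]:
                    hits.append((int(mism[pos]), ref_id, int(pos), strand))
        if not hits:
            return []
        d_star = min(h[0] for h in hits)
        return [
            Alignment(read_id=read_id, ref_id=r, start=p + 1, end=p + n, strand=s, n_mismatch=mm)
            for mm, r, p, s in hits
            if mm == d_star
        ]


def align_read(
    insert: str,
    refset: ReferenceSet | ReferenceIndex,
    max_mm: int = 1,
    read_id: str = "",
) -> list[Alignment]:
    """Best-stratum ungapped placements of one insert (see module docs)."""
    index = refset if isinstance(refset, ReferenceIndex) else ReferenceIndex(refset)
    return index.scan(insert, max_mm=max_mm, read_id=read_id)


def classify(hits: Sequence[Alignment], refset: ReferenceSet, read_id: str = "") -> MappingResult:
    """Unique / multi / unmapped / excluded_class from a best stratum."""
    if hits and not read_id:
        read_id = hits[0].read_id
    if len(hits) == 0:
        return MappingResult(read_id=read_id, status=STATUS_UNMAPPED, best=None, n_best_hits=0)
    if len(hits) > 1:
        return MappingResult(read_id=read_id, status=STATUS_MULTI, best=None, n_best_hits=len(hits))
    hit = hits[0]
    if refset.ref_class(hit.ref_id) in DECOY_CLASSES:
        return MappingResult(read_id=read_id, status=STATUS_EXCLUDED, best=hit, n_best_hits=1)
    return MappingResult(read_id=read_id, status=STATUS_UNIQUE, best=hit, n_best_hits=1)


def sl_rescue_pass(
    non_unique: Iterable[tuple[ProcessedRead, MappingResult]],
    refset: ReferenceSet,
    max_mm: int = 1,
) -> dict[str, MappingResult]:
    """Realign genome-ambiguous reads to the single SL RNA sequence.

    Reads unique on SL become ``unique`` with ``ref_id = sl_ref_id``;
    anything else keeps its prior status.  Only reads with prior status
    multi or unmapped may enter (precondition).
    """
    sl = refset.sl_reference  # raises if absent
    sl_only = ReferenceSet(sequences={sl.id: sl}, sl_ref_id=sl.id)
    index = ReferenceIndex(sl_only)
    out: dict[str, MappingResult] = {}
    for read, prior in non_unique:
        if prior.status not in (STATUS_MULTI, STATUS_UNMAPPED):
            raise ValueError(
                f"read {read.read_id!r} with status {prior.status!r} must not "
                "enter the SL rescue pass"
            )
        hits = index.scan(read.insert, max_mm=max_mm, read_id=read.read_id)
        if len(hits) == 1:
            out[read.read_id] = MappingResult(
                read_id=read.read_id, status=STATUS_UNIQUE, best=hits[0], n_best_hits=1
            )
        else:
            out[read.read_id] = prior
    return out


def map_reads(
    processed: Sequence[ProcessedRead],
    refset: ReferenceSet,
    max_mm: int = 1,
    sl_rescue: bool = True,
) -> dict[str, MappingResult]:
    """Two-pass mapping driver: genome pass, then SL rescue.

    Pass 1 excludes the standalone SL reference; a read unique in pass 1
    is never reassigned.  Returns one final MappingResult per read.
    """
    index = ReferenceIndex(refset, exclude_classes=("SL",) if sl_rescue else ())
    results: dict[str, MappingResult] = {}
    rescue_pool: list[tuple[ProcessedRead, MappingResult]] = []
    for read in processed:
        hits = index.scan(read.insert, max_mm=max_mm, read_id=read.read_id)
        res = classify(hits, refset, read_id=read.read_id)
        results[read.read_id] = res
        if sl_rescue and res.status in (STATUS_MULTI, STATUS_UNMAPPED):
            rescue_pool.append((read, res))
    if sl_rescue and rescue_pool and refset.sl_ref_id is not None:
        results.update(sl_rescue_pass(rescue_pool, refset, max_mm=max_mm))
    return results


def status_counts(results: Iterable[MappingResult]) -> Counter:
    return Counter(r.status for r in results)


def write_mapping_tsv(
    results: Iterable[MappingResult],
    path: str | Path,
    reads: Sequence[ProcessedRead] | None = None,
) -> None:
    """Mapping-status TSV; sample/UMI columns included when reads given."""
    by_id = {r.read_id: r for r in reads} if reads is not None else {}
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tref_id\tstart\tstrand\tn_best_hits\tsample_id\tumi\n")
        for res in results:
            ref_id = res.best.ref_id if res.best else "."
            start = res.best.start if res.best else 0
            strand = res.best.strand if res.best else "."
            read = by_id.get(res.read_id)
            sample = read.sample_id if read else "."
            umi = read.umi if read else "."
            fh.write(
                f"{res.read_id}\t{res.status}\t{ref_id}\t{start}\t{strand}\t"
                f"{res.n_best_hits}\t{sample}\t{umi}\n"
            )


def write_sam(
    results: Iterable[MappingResult],
    refset: ReferenceSet,
    path: str | Path,
    reads: Sequence[ProcessedRead] | None = None,
) -> None:
    """Minimal SAM export of unique alignments (FLAG strand, POS, NM tag)."""
    by_id = {r.read_id: r for r in reads} if reads is not None else {}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for ref in refset.sequences.values():
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{ref.length}\n")
        fh.write("@PG\tID:tryclip\tPN:tryclip\n")
        for res in results:
            if res.status != STATUS_UNIQUE or res.best is None:
                continue
            aln = res.best
            flag = 16 if aln.strand == "-" else 0
            read = by_id.get(res.read_id)
            seq = read.insert if read else "*"
            if read and aln.strand == "-":
                seq = revcomp(seq)
            length = aln.end - aln.start + 1
            qual = "I" * length if read else "*"
            fh.write(
                f"{res.read_id}\t{flag}\t{aln.ref_id}\t{aln.start}\t255\t"
                f"{length}M\t*\t0\t0\t{seq}\t{qual}\tNM:i:{aln.n_mismatch}\n"
            )
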