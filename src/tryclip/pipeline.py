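"""End-to-end driver: FASTQ -> processed reads -> mapping -> profiles."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import align as _align
from . import profiles as _profiles
from . import reads as _reads
from .references import ReferenceSet


@dataclass
class PipelineResult:
    stats: _reads.ProcessingStats
    mapping: dict[str, _align.MappingResult]
    status_counts: dict[str, int]
    n_dropped_edge: int
    events: list[_profiles.CrosslinkEvent]
    counts: dict[tuple[str, str, int], int]
    profiles: list[_profiles.CrosslinkProfile]
    class_dist: _profiles.ClassDistribution
    #: per-read final assignment (read_id, sample_id, status, ref_id, site)
    read_assignments: pd.DataFrame = field(repr=False, default=None)

    def profile(self, ref_id: str, sample_id: str | None = None) -> _profiles.CrosslinkProfile:
        """The (optionally sample-specific, otherwise merged) profile of a ref."""
        matching = [p for p in self.profiles if p.ref_id == ref_id]
        if sample_id is not None:
            matching = [p for p in matching if p.sample_id == sample_id]
        if not matching:
            raise KeyError(f"no profile for {ref_id!r} (sample {sample_id!r})")
        if len(matching) == 1:
            return matching[0]
        return _profiles.merge_replicates(matching)


def run_pipeline(
    reads: Iterable[tuple[str, str]] | str | Path,
    refset: ReferenceSet,
    layout: _reads.BarcodeLayout = _reads.DEFAULT_LAYOUT,
    sample_barcodes: Mapping[str, str] = _reads.DEFAULT_SAMPLE_BARCODES,
    adapter: str = _reads.DEFAULT_ADAPTER,
    demux_max_mm: int = 0,
    align_max_mm: int = 1,
    min_len: int = _reads.DEFAULT_MIN_LEN,
    sl_rescue: bool = True,
    display_overrides: Mapping[str, int] | None = None,
) -> PipelineResult:
    """Run processing, two-pass alignment and UMI-deduplicated profiling."""
    if isinstance(reads, (str, Path)):
        reads = _reads.iter_fastq(reads)
    processed, stats = _reads.process_reads(
        reads,
        layout=layout,
        sample_barcodes=sample_barcodes,
        adapter=adapter,
        max_mm=demux_max_mm,
        min_len=min_len,
    )
    mapping = _align.map_reads(processed, refset, max_mm=align_max_mm, sl_rescue=sl_rescue)

    events: list[_profiles.CrosslinkEvent] = []
    n_dropped_edge = 0
    assignment_rows = []
    for read in processed:
        res = mapping[read.read_id]
        ref_id, site = "", 0
        if res.status == _align.STATUS_UNIQUE:
            event = _profiles.assign_crosslink(res, read.umi, read.sample_id, refset)
            if event is None:
                n_dropped_edge += 1
            else:
                events.append(event)
                ref_id, site = event.ref_id, event.site
        assignment_rows.append((read.read_id, read.sample_id, res.status, ref_id, site))

    counts = _profiles.dedup_count(events)
    return PipelineResult(
        stats=stats,
        mapping=mapping,
        status_counts=dict(_align.status_counts(mapping.values())),
        n_dropped_edge=n_dropped_edge,
        events=events,
        counts=counts,
        profiles=_profiles.build_profiles(counts, refset, display_overrides),
        class_dist=_profiles.class_distribution(counts, refset),
        read_assignments=pd.DataFrame(
            assignment_rows, columns=["read_id", "sample_id", "status", "ref_id", "site"]
        ),
    )
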