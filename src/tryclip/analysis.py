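"""Quantitative readouts over crosslink profiles.

Region fractions, descriptive peak calls, replicate agreement, and the
antiparallel base-pairing register between an snRNA segment and a
pre-mRNA 5' splice site (the U1- and U6-style registers), optionally
overlaid with crosslink tag counts.

Splice-site coordinates on the target follow the -1/+1 convention: the
``splice_index`` marks the last exonic nucleotide, exon positions count
back as -1, -2, ... and intron positions forward as +1, +2, ...
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .profiles import CrosslinkProfile
from .references import RegionAnnotation

PAIR_WC = "WC"
PAIR_GU = "GU"
PAIR_NONE = "none"

_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "T"), ("T", "G")}


def region_fraction(
    profile: CrosslinkProfile,
    region: RegionAnnotation | tuple[int, int],
) -> float:
    """Fraction of displayed tags inside a region.

    The denominator is the displayed (mappable) range 1..display_end, the
    range over which profile statistics such as "~40% of crosslink sites
    in the 5' terminal region" are meaningful.
    """
    if isinstance(region, RegionAnnotation):
        start, end = region.start, region.end
    else:
        start, end = region
    if not (1 <= start <= end):
        raise ValueError(f"bad region {start}..{end}")
    total = int(profile.displayed.sum())
    if total == 0:
        raise ValueError("region_fraction undefined on a zero-total profile")
    end = min(end, profile.display_end)
    if start > profile.display_end:
        return 0.0
    return float(profile.counts[start - 1 : end].sum()) / total


@dataclass(frozen=True)
class PeakCall:
    ref_id: str
    position: int  # 5'-most position of the peak (plateau start)
    height: int
    prominence_fraction: float
    plateau_extent: int = 1


def call_peaks(
    profile: CrosslinkProfile,
    min_fraction: float = 0.1,
    min_separation: int = 2,
) -> list[PeakCall]:
    """Descriptive local-maximum peak report over the displayed range.

    A position (or plateau of equal values) is a peak when every flanking
    position within ``min_separation`` is strictly lower and its height is
    at least ``min_fraction`` of the profile maximum.  Peaks are returned
    in decreasing height order (ties by position).
    """
    x = profile.displayed
    m = int(x.max()) if x.size else 0
    if m == 0:
        return []
    threshold = min_fraction * m
    peaks: list[PeakCall] = []
    i = 0
    n = x.size
    while i < n:
        v = int(x[i])
        j = i
        while j + 1 < n and x[j + 1] == v:
            j += 1
        if v > 0 and v >= threshold:
            lo = max(0, i - min_separation)
            hi = min(n, j + 1 + min_separation)
            flanks = np.concatenate([x[lo:i], x[j + 1 : hi]])
            if flanks.size == 0 or (flanks < v).all():
                peaks.append(
                    PeakCall(
                        ref_id=profile.ref_id,
                        position=i + 1,
                        height=v,
                        prominence_fraction=v / m,
                        plateau_extent=j - i + 1,
                    )
                )
        i = j + 1
    peaks.sort(key=lambda p: (-p.height, p.position))
    return peaks


def replicate_agreement(
    p1: CrosslinkProfile,
    p2: CrosslinkProfile,
    method: str = "pearson",
) -> float:
    """Correlation of two replicate profiles over 1..display_end."""
    if p1.ref_id != p2.ref_id or p1.length != p2.length:
        raise ValueError("replicate_agreement requires profiles on the same reference")
    end = min(p1.display_end, p2.display_end)
    a = p1.counts[:end].astype(float)
    b = p2.counts[:end].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    if method == "pearson":
        return float(_stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(_stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def _pair_type(rna_base: str, target_base: str, allow_gu: bool) -> str:
    pair = (rna_base, target_base)
    if pair in _WC_PAIRS:
        return PAIR_WC
    if allow_gu and pair in _GU_PAIRS:
        return PAIR_GU
    return PAIR_NONE


def splice_label(position: int, splice_index: int) -> int:
    """-1/+1 label of a 1-based target position around the splice site."""
    return position - splice_index if position > splice_index else position - splice_index - 1


@dataclass(frozen=True)
class DuplexRegister:
    """An antiparallel snRNA / 5'-splice-site pairing register.

    The snRNA segment ``rna_range`` is read 3'->5' against the target
    read 5'->3'; ``offset`` is the 0-based target position opposite the
    3' end of the snRNA segment.  ``pair_mask`` covers the overlapping
    positions only, in target order.
    """

    rna_id: str
    rna_range: tuple[int, int]
    rna_segment: str  # 5'->3', positions rna_range[0]..rna_range[1]
    target_seq: str
    splice_index: int
    offset: int
    pair_mask: tuple[str, ...]
    n_paired: int
    #: (rna_position, target_position) per mask entry, both 1-based
    paired_positions: tuple[tuple[int, int], ...]
    rna_counts: Mapping[int, int] | None = None
    marks: tuple[int, ...] = ()
    flank_marks: tuple[int, ...] = ()

    @property
    def target_labels(self) -> tuple[int, ...]:
        return tuple(splice_label(t, self.splice_index) for _, t in self.paired_positions)


def duplex_register(
    rna_seq: str,
    rna_range: tuple[int, int],
    target_seq: str,
    splice_index: int,
    offset: int = 0,
    allow_gu: bool = True,
    rna_id: str = "",
) -> DuplexRegister:
    """Score the base-pairing register of an snRNA segment on a target.

    Watson-Crick pairs (A:U/T, G:C, both orientations) and, by default,
    G:U wobble pairs count as paired.  Sequences are handled in the DNA
    alphabet (U == T).
    """
    start, end = rna_range
    rna_seq = rna_seq.upper().replace("U", "T")
    target = target_seq.upper().replace("U", "T")
    if not (1 <= start <= end <= len(rna_seq)):
        raise ValueError(f"rna_range {start}..{end} outside sequence of length {len(rna_seq)}")
    segment = rna_seq[start - 1 : end]
    mask: list[str] = []
    paired_positions: list[tuple[int, int]] = []
    # antiparallel: 3' end of the segment (rna position `end`) faces target
    # position offset+1, walking 3'->5' on the RNA and 5'->3' on the target
    for j, rna_base in enumerate(reversed(segment)):
        t_idx = offset + j  # 0-based target index
        if t_idx < 0 or t_idx >= len(target):
            continue
        mask.append(_pair_type(rna_base, target[t_idx], allow_gu))
        paired_positions.append((end - j, t_idx + 1))
    if target and not mask:
        raise ValueError(f"offset {offset} places the segment entirely off the target")
    n_paired = sum(1 for m in mask if m != PAIR_NONE)
    return DuplexRegister(
        rna_id=rna_id or "rna",
        rna_range=(start, end),
        rna_segment=segment,
        target_seq=target,
        splice_index=splice_index,
        offset=offset,
        pair_mask=tuple(mask),
        n_paired=n_paired,
        paired_positions=tuple(paired_positions),
    )


def annotate_register_with_crosslinks(
    register: DuplexRegister,
    profiles: Iterable[CrosslinkProfile] | CrosslinkProfile,
    threshold: int = 1,
    flank_window: int = 5,
) -> DuplexRegister:
    """Overlay crosslink tag counts on the snRNA side of a register.

    Every snRNA position in ``rna_range`` receives its profile count;
    positions with count >= ``threshold`` are marked, and marked positions
    within ``flank_window`` nucleotides outside the range are reported as
    flanking marks (strong crosslinks often sit just outside the paired
    segment, e.g. flanking the U6 ACAGAG box).
    """
    if isinstance(profiles, CrosslinkProfile):
        candidates = [profiles]
    else:
        candidates = list(profiles)
    matching = [p for p in candidates if p.ref_id == register.rna_id]
    if not matching:
        raise ValueError(f"no profile for reference {register.rna_id!r}")
    counts = np.sum([p.counts for p in matching], axis=0)
    start, end = register.rna_range
    rna_counts = {pos: int(counts[pos - 1]) for pos in range(start, end + 1)}
    marks = tuple(p for p, c in sorted(rna_counts.items()) if c >= threshold)
    flank_positions = [
        pos
        for pos in range(max(1, start - flank_window), min(len(counts), end + flank_window) + 1)
        if pos < start or pos > end
    ]
    flank_marks = tuple(p for p in flank_positions if counts[p - 1] >= max(threshold, 1))
    return replace(register, rna_counts=rna_counts, marks=marks, flank_marks=flank_marks)


def render_register(register: DuplexRegister) -> str:
    """Plain-text diagram of a pairing register with crosslink marks."""
    if not register.paired_positions:
        return "(empty register)"
    t_positions = [t for _, t in register.paired_positions]
    t0, t1 = min(t_positions), max(t_positions)
    start, end = register.rna_range
    rna_by_target = {t: r for r, t in register.paired_positions}
    mask_by_target = {
        t: m for (_, t), m in zip(register.paired_positions, register.pair_mask)
    }
    target_chars, pair_chars, rna_chars, mark_chars = [], [], [], []
    for t in range(t0, t1 + 1):
        target_chars.append(register.target_seq[t - 1])
        r = rna_by_target.get(t)
        if r is None:
            pair_chars.append(" ")
            rna_chars.append("-")
            mark_chars.append(" ")
        else:
            pair_chars.append({"WC": "|", "GU": ":", "none": " "}[mask_by_target[t]])
            rna_chars.append(register.rna_segment[r - start])
            marked = register.marks and r in register.marks
            mark_chars.append("*" if marked else " ")
    pad = " " * 18
    lines = [
        f"target  5'->3'    {''.join(target_chars)}   (positions {t0}..{t1}; "
        f"5'ss after {register.splice_index})",
        f"{pad}{''.join(pair_chars)}   (| WC, : GU)",
        f"{register.rna_id:>7s} 3'->5'    {''.join(rna_chars)}   (positions {end}..{start})",
    ]
    if register.rna_counts is not None:
        lines.append(f"{pad}{''.join(mark_chars)}   (* crosslinked)")
        if register.flank_marks:
            lines.append(
                f"flanking crosslink marks on {register.rna_id}: "
                + ", ".join(str(p) for p in register.flank_marks)
            )
    return "\n".join(lines)
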