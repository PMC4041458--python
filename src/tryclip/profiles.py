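"""UMI-deduplicated single-nucleotide crosslink profiles.

In the iCLIP cDNA-truncation model, reverse transcription stops at the
protein-RNA adduct, so the 5' end of a mapped read starts one nucleotide
downstream of the crosslinked base: a plus-strand read starting at
reference position ``start`` marks the crosslink at ``start - 1`` (a
minus-strand genomic read ending at ``end`` marks ``end + 1``).  Reads
whose inferred site falls off the reference are dropped and counted.

Tag counts are "random-barcode filtered": at each (sample, reference,
site) the count is the number of *distinct* UMIs observed, which collapses
PCR duplicates while keeping independent ligation events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import STATUS_UNIQUE, MappingResult
from .references import SNRNA_CLASSES, ReferenceSet

#: the last 15 nt of each reference cannot carry a mappable tag (a read
#: starting there would be shorter than the minimum insert), so profiles
#: are displayed without them by default
DISPLAY_TRIM = 15
#: per-reference display overrides, keyed by ref_class (printed profile
#: ranges truncate the 139-nt SL RNA at 123, not 124)
DEFAULT_DISPLAY_OVERRIDES_BY_CLASS: dict[str, int] = {"SL": 123}

CountMap = Mapping[tuple[str, str, int], int]


@dataclass(frozen=True)
class CrosslinkEvent:
    """One unit of crosslink evidence: (sample, reference, site, UMI)."""

    sample_id: str
    ref_id: str
    site: int  # 1-based crosslinked nucleotide
    umi: str


def assign_crosslink(
    mapping: MappingResult,
    umi: str,
    sample_id: str,
    refset: ReferenceSet,
) -> CrosslinkEvent | None:
    """Place the crosslink one nucleotide 5' of the read (None = edge drop)."""
    if mapping.status != STATUS_UNIQUE or mapping.best is None:
        raise ValueError(
            f"assign_crosslink requires a unique mapping, got {mapping.status!r}"
        )
    aln = mapping.best
    length = refset.length(aln.ref_id)
    site = aln.start - 1 if aln.strand == "+" else aln.end + 1
    if not (1 <= site <= length):
        return None
    return CrosslinkEvent(sample_id=sample_id, ref_id=aln.ref_id, site=site, umi=umi)


def dedup_count(events: Iterable[CrosslinkEvent]) -> dict[tuple[str, str, int], int]:
    """Distinct-UMI tag count per (sample, reference, site)."""
    seen: set[tuple[str, str, int, str]] = set()
    counts: dict[tuple[str, str, int], int] = {}
    for ev in events:
        key = (ev.sample_id, ev.ref_id, ev.site, ev.umi)
        if key in seen:
            continue
        seen.add(key)
        counts[key[:3]] = counts.get(key[:3], 0) + 1
    return counts


@dataclass
class CrosslinkProfile:
    """Per-nucleotide deduplicated tag counts on one reference."""

    sample_id: str
    ref_id: str
    counts: np.ndarray  # shape (L,), counts[i] is position i+1
    display_end: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("profile counts must be a non-empty 1-d vector")
        if not (1 <= self.display_end <= self.counts.size):
            raise ValueError("display_end out of range")

    @property
    def length(self) -> int:
        return int(self.counts.size)

    def count_at(self, position: int) -> int:
        if not (1 <= position <= self.length):
            raise IndexError(f"position {position} outside 1..{self.length}")
        return int(self.counts[position - 1])

    @property
    def displayed(self) -> np.ndarray:
        """Counts over the displayed (mappable) range 1..display_end."""
        return self.counts[: self.display_end]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _display_end(ref_id: str, refset: ReferenceSet, overrides: Mapping[str, int]) -> int:
    if ref_id in overrides:
        return overrides[ref_id]
    cls = refset.ref_class(ref_id)
    if cls in DEFAULT_DISPLAY_OVERRIDES_BY_CLASS:
        return DEFAULT_DISPLAY_OVERRIDES_BY_CLASS[cls]
    return max(1, refset.length(ref_id) - DISPLAY_TRIM)


def build_profiles(
    counts: CountMap,
    refset: ReferenceSet,
    display_overrides: Mapping[str, int] | None = None,
) -> list[CrosslinkProfile]:
    """One profile per (sample, reference) holding any tag; zero-filled.

    References without tags yield no profile (sparse output).
    ``display_overrides`` maps ref_id -> display_end and takes precedence
    over the default L - 15 rule and the SL-class override.
    """
    overrides = dict(display_overrides or {})
    grouped: dict[tuple[str, str], dict[int, int]] = {}
    for (sample, ref_id, site), n in counts.items():
        length = refset.length(ref_id)
        if not (1 <= site <= length):
            raise ValueError(f"site {site} beyond reference {ref_id!r} (length {length})")
        grouped.setdefault((sample, ref_id), {})[site] = n
    profiles = []
    for (sample, ref_id), per_site in sorted(grouped.items()):
        vec = np.zeros(refset.length(ref_id), dtype=np.int64)
        for site, n in per_site.items():
            vec[site - 1] = n
        profiles.append(
            CrosslinkProfile(
                sample_id=sample,
                ref_id=ref_id,
                counts=vec,
                display_end=_display_end(ref_id, refset, overrides),
            )
        )
    return profiles


def merge_replicates(
    profiles: Sequence[CrosslinkProfile], sample_id: str | None = None
) -> CrosslinkProfile:
    """Element-wise sum across replicates (no normalisation)."""
    if not profiles:
        raise ValueError("no profiles to merge")
    ref_ids = {p.ref_id for p in profiles}
    lengths = {p.length for p in profiles}
    if len(ref_ids) != 1 or len(lengths) != 1:
        raise ValueError("merge_replicates requires a single reference and length")
    total = np.sum([p.counts for p in profiles], axis=0)
    if sample_id is None:
        sample_id = "+".join(dict.fromkeys(p.sample_id for p in profiles))
    return CrosslinkProfile(
        sample_id=sample_id,
        ref_id=profiles[0].ref_id,
        counts=total,
        display_end=profiles[0].display_end,
    )


@dataclass
class ClassDistribution:
    """Tag totals per reference class, with SL as a separate line item.

    Fractions are over the non-SL total, matching the convention of
    reporting snRNA shares of uniquely mapped genome tags while the
    separately aligned SL RNA tags are listed on their own.
    """

    counts: dict[str, int]  # keys: U1, U2, U4, U5, U6, others
    sl_count: int
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if not self.fractions:
            self.fractions = {
                k: (v / total if total else 0.0) for k, v in self.counts.items()
            }
        if total and abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise AssertionError("class fractions do not sum to 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "sl_count": self.sl_count,
            "fractions": dict(self.fractions),
            "total_non_sl": self.total,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def class_distribution(counts: CountMap, refset: ReferenceSet) -> ClassDistribution:
    """Aggregate deduplicated tags by reference class.

    snRNA classes are counted individually, everything else that is
    neither SL nor a decoy falls into ``others``; SL tags (the separate
    alignment pass) are excluded from the snRNA denominator.
    """
    per_class = {cls: 0 for cls in SNRNA_CLASSES}
    per_class["others"] = 0
    sl_count = 0
    for (_sample, ref_id, _site), n in counts.items():
        cls = refset.ref_class(ref_id)
        if cls == "SL":
            sl_count += n
        elif cls in per_class:
            per_class[cls] += n
        else:
            per_class["others"] += n
    return ClassDistribution(counts=per_class, sl_count=sl_count)


def profiles_to_table(profiles: Iterable[CrosslinkProfile], sparse: bool = True) -> pd.DataFrame:
    """Long-format profile table: sample_id, ref_id, position, tag_count."""
    rows = []
    for p in profiles:
        positions = np.nonzero(p.counts)[0] + 1 if sparse else np.arange(1, p.length + 1)
        for pos in positions:
            rows.append((p.sample_id, p.ref_id, int(pos), int(p.counts[pos - 1])))
    return pd.DataFrame(rows, columns=["sample_id", "ref_id", "position", "tag_count"])


def write_profile_tsv(profiles: Iterable[CrosslinkProfile], path: str | Path) -> None:
    profiles_to_table(profiles).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path, refset: ReferenceSet) -> list[CrosslinkProfile]:
    df = pd.read_csv(path, sep="\t")
    counts = {
        (r.sample_id, r.ref_id, int(r.position)): int(r.tag_count)
        for r in df.itertuples()
    }
    return build_profiles(counts, refset)
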