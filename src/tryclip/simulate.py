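"""Synthetic iCLIP libraries with known ground truth.

The generator emulates the structure of a multiplexed trypanosome iCLIP
lane: single-end reads whose 5' header carries a leading random-mer, a
fixed sample barcode and a trailing random-mer; a truncated-cDNA insert
whose first base sits one nucleotide downstream of the crosslinked
reference position; the 3' sequencing adapter; and deterministic 'A'
padding out to the read length.  A truth table records, for every read,
the sample, reference, crosslink site and UMI actually drawn, so every
downstream stage can be checked exactly.

The toy reference set contains the full small-RNA cast of the system:
U1 (75 nt, with the U1-70K site AUCACGAA at 20-27), U2, U4, U5, U6
(97 nt, ACAGAG box at 37-42), the 139-nt SL RNA (mini-exon = first 39 nt,
5' splice site after position 39), tRNA/rRNA decoys, and a genomic contig
embedding a tandem array of exact SL copies plus a poly(A)-polymerase-like
exon-GT...AG-intron-exon gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .reads import (
    DEFAULT_ADAPTER,
    DEFAULT_LAYOUT,
    DEFAULT_SAMPLE_BARCODES,
    BarcodeLayout,
    validate_barcode_set,
)
from .references import (
    DECOY_CLASSES,
    SIGNAL_CLASSES,
    ReferenceSequence,
    ReferenceSet,
    RegionAnnotation,
    build_default_annotations,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: crosslink sites below 2 are unobservable (the read would have to start
#: at or before position 1); sites above L - MIN_INSERT leave an insert too
#: short to pass the length filter, mirroring the display truncation
MIN_SITE = 2
MIN_INSERT = 15


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(list("ACGT"), size=n).view(f"U{n}")[0] if n else ""


@dataclass
class SimulationConfig:
    """All knobs of one simulated lane; randomness flows from ``seed``."""

    n_reads: int = 50_000
    layout: BarcodeLayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    sample_barcodes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLE_BARCODES)
    )
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 105
    insert_length_dist: tuple[int, int, str] = (15, 40, "uniform")
    substitution_error_rate: float = 0.0
    background_fraction: float = 0.05
    sl_copies_in_genome: int = 3
    seed: int = 0

    def validate(self) -> None:
        validate_barcode_set(self.sample_barcodes, self.layout, min_distance=2)
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must be in [0, 1)")
        if self.sl_copies_in_genome < 2:
            raise ValueError("sl_copies_in_genome must be >= 2 (multi-copy array)")
        lo, hi, name = self.insert_length_dist
        if name != "uniform":
            raise ValueError(f"unsupported insert length distribution {name!r}")
        if not (1 <= lo <= hi):
            raise ValueError("insert length bounds must satisfy 1 <= min <= max")
        if self.read_length < self.layout.header_len + MIN_INSERT:
            raise ValueError(
                "read_length must accommodate the header plus a minimal insert"
            )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["layout"] = [self.layout.lead_random_len, self.layout.sample_len, self.layout.trail_random_len]
        d["insert_length_dist"] = list(self.insert_length_dist)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        lead, sample, trail = d.pop("layout")
        lo, hi, name = d.pop("insert_length_dist")
        return cls(
            layout=BarcodeLayout(lead, sample, trail),
            insert_length_dist=(int(lo), int(hi), str(name)),
            **d,
        )


@dataclass
class TruthProfile:
    """Ground-truth crosslink distribution: (ref_id, site) -> probability."""

    weights: dict[tuple[str, int], float]

    def validate(self, refset: ReferenceSet) -> None:
        total = 0.0
        for (ref_id, pos), w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight at ({ref_id}, {pos})")
            length = refset.length(ref_id)
            if not (MIN_SITE <= pos <= length - 1):
                raise ValueError(
                    f"truth position {pos} on {ref_id!r} outside [{MIN_SITE}, {length - 1}]"
                )
            total += w
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"truth weights sum to {total}, expected 1.0")

    def support(self) -> tuple[list[tuple[str, int]], np.ndarray]:
        keys = sorted(self.weights)
        probs = np.array([self.weights[k] for k in keys], dtype=float)
        return keys, probs / probs.sum()

    def region_mass(self, ref_id: str, start: int, end: int) -> float:
        return sum(
            w for (r, p), w in self.weights.items() if r == ref_id and start <= p <= end
        )


def _allowed_sites(length: int, min_insert: int = MIN_INSERT) -> range:
    """Sites whose truncated-cDNA read survives the length filter."""
    return range(MIN_SITE, length - min_insert + 1)


def make_truth_profile(
    refset: ReferenceSet,
    peak_spec: Sequence[tuple[str, tuple[int, int], float]] = (),
    background_fraction: float = 0.0,
    seed: int = 0,
    min_insert: int = MIN_INSERT,
) -> TruthProfile:
    """Build a ground-truth site distribution from regional masses.

    ``peak_spec`` lists (ref_id, (start, end), mass); each region's mass is
    spread uniformly over its positions (clipped to the observable range)
    and matches the requested mass exactly.  ``background_fraction`` goes
    uniformly to tRNA/rRNA decoy positions, and any remaining mass is
    spread uniformly over snRNA/SL positions not covered by a peak region.
    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    del seed
    peak_mass = sum(m for _, _, m in peak_spec)
    total = peak_mass + background_fraction
    if total > 1.0 + 1e-12:
        raise ValueError(f"peak + background mass {total} exceeds 1")
    weights: dict[tuple[str, int], float] = {}
    reserved: set[tuple[str, int]] = set()
    for ref_id, (start, end), mass in peak_spec:
        allowed = _allowed_sites(refset.length(ref_id), min_insert)
        positions = [p for p in range(start, end + 1) if p in allowed]
        if not positions:
            raise ValueError(
                f"peak region {start}-{end} on {ref_id!r} has no observable position"
            )
        for p in positions:
            key = (ref_id, p)
            weights[key] = weights.get(key, 0.0) + mass / len(positions)
            reserved.add(key)
    if background_fraction > 0:
        decoy_positions = [
            (ref.id, p)
            for ref in refset.by_class(*DECOY_CLASSES)
            for p in _allowed_sites(ref.length, min_insert)
        ]
        if not decoy_positions:
            raise ValueError("background mass requested but no decoy references present")
        for key in decoy_positions:
            weights[key] = weights.get(key, 0.0) + background_fraction / len(decoy_positions)
    remainder = 1.0 - total
    if remainder > 1e-12:
        free = [
            (ref.id, p)
            for ref in refset.by_class(*SIGNAL_CLASSES)
            for p in _allowed_sites(ref.length, min_insert)
            if (ref.id, p) not in reserved
        ]
        if not free:
            raise ValueError("remaining mass but no free signal position to place it on")
        for key in free:
            weights[key] = weights.get(key, 0.0) + remainder / len(free)
    profile = TruthProfile(weights=weights)
    profile.validate(refset)
    return profile


# -- toy reference construction ---------------------------------------------

_TOY_LENGTHS = {"U1": 75, "U2": 148, "U4": 125, "U5": 62, "U6": 97}
_SL_LENGTH = 139
_MINI_EXON = 39


def _plant(seq: list[str], motif: str, start_1based: int) -> None:
    seq[start_1based - 1 : start_1based - 1 + len(motif)] = list(motif)


def _candidate_refset(rng: np.random.Generator, sl_copies: int) -> ReferenceSet:
    seqs: dict[str, ReferenceSequence] = {}

    u1 = list(_rand_seq(rng, _TOY_LENGTHS["U1"]))
    _plant(u1, "ATCACGAA", 20)  # U1-70K binding site (AUCACGAA)
    _plant(u1, "ACTTTG", 45)  # Sm site (ACUUUG)
    seqs["U1"] = ReferenceSequence("U1", "U1", "".join(u1))

    for name in ("U2", "U4", "U5"):
        seqs[name] = ReferenceSequence(name, name, _rand_seq(rng, _TOY_LENGTHS[name]))

    u6 = list(_rand_seq(rng, _TOY_LENGTHS["U6"]))
    _plant(u6, "ACAGAG", 37)  # invariant ACAGAG box
    seqs["U6"] = ReferenceSequence("U6", "U6", "".join(u6))

    sl = list(_rand_seq(rng, _SL_LENGTH))
    _plant(sl, "GT", _MINI_EXON + 1)  # intron-side 5' splice site dinucleotide
    sl_seq = "".join(sl)
    seqs["SL"] = ReferenceSequence("SL", "SL", sl_seq)

    seqs["tRNA_decoy"] = ReferenceSequence("tRNA_decoy", "tRNA", _rand_seq(rng, 72))
    seqs["rRNA_decoy"] = ReferenceSequence("rRNA_decoy", "rRNA", _rand_seq(rng, 120))

    # genomic contig: SL tandem array, then a PAP-like exon-intron-exon gene
    parts: list[str] = [_rand_seq(rng, 150)]
    sl_spans: list[tuple[int, int]] = []
    offset = len(parts[0])
    for _ in range(sl_copies):
        sl_spans.append((offset + 1, offset + _SL_LENGTH))
        parts.append(sl_seq)
        offset += _SL_LENGTH
        spacer = _rand_seq(rng, 60)
        parts.append(spacer)
        offset += len(spacer)
    exon1 = _rand_seq(rng, 60)
    intron = "GT" + _rand_seq(rng, 76) + "AG"
    exon2 = _rand_seq(rng, 60)
    gene_start = offset + 1
    parts.extend([exon1, intron, exon2, _rand_seq(rng, 150)])
    contig = "".join(parts)
    seqs["contig1"] = ReferenceSequence("contig1", "genomic", contig)

    e1s, e1e = gene_start, gene_start + 59
    ins, ine = e1e + 1, e1e + 80
    e2s, e2e = ine + 1, ine + 60
    annotations = [
        RegionAnnotation("contig1", f"sl_copy_{i + 1}", s, e)
        for i, (s, e) in enumerate(sl_spans)
    ] + [
        RegionAnnotation("contig1", "pap_exon1", e1s, e1e),
        RegionAnnotation("contig1", "pap_intron", ins, ine),
        RegionAnnotation("contig1", "pap_exon2", e2s, e2e),
        RegionAnnotation("contig1", "pap_5ss_last_exonic", e1e, e1e),
    ]
    refset = ReferenceSet(sequences=seqs, annotations=annotations, sl_ref_id="SL")
    refset.annotations.extend(build_default_annotations(refset))
    return refset


def _kmer_clean(refset: ReferenceSet, k: int = MIN_INSERT) -> bool:
    """True iff every k-mer has a single unambiguous mapping locus.

    SL k-mers legitimately recur (standalone SL + each contig array copy);
    any other repeated k-mer, including across the contig minus strand,
    could defeat unique mapping and disqualifies the candidate.
    """
    from .align import revcomp

    sl_spans = [
        (a.start, a.end) for a in refset.annotations if a.name.startswith("sl_copy_")
    ]

    def contig_label(pos0: int) -> str:
        # pos0: 0-based window start on the contig plus strand
        for s, e in sl_spans:
            if s - 1 <= pos0 and pos0 + k <= e:
                return "SL"
        return "contig"

    occurrences: dict[str, list[str]] = {}
    for ref in refset.sequences.values():
        if ref.ref_class == "genomic":
            for i in range(ref.length - k + 1):
                occurrences.setdefault(ref.seq[i : i + k], []).append(contig_label(i))
            rc = revcomp(ref.seq)
            for i in range(ref.length - k + 1):
                pos0 = ref.length - k - i  # plus-strand start of this window
                label = "SL_rc" if contig_label(pos0) == "SL" else "contig_rc"
                occurrences.setdefault(rc[i : i + k], []).append(label)
        else:
            for i in range(ref.length - k + 1):
                occurrences.setdefault(ref.seq[i : i + k], []).append(ref.id)
    for labels in occurrences.values():
        groups = set("SL" if lab == "SL" else lab for lab in labels)
        if len(groups) > 1:
            return False
        lab = labels[0]
        if lab in ("SL", "SL_rc"):
            continue
        if len(labels) > 1:
            return False
    return True


def make_toy_reference_set(seed: int = 0, sl_copies: int = 3) -> ReferenceSet:
    """Deterministic toy reference set for the trypanosome snRNA system.

    Candidates are drawn from ``seed`` and re-drawn (deterministically)
    until no 15-mer outside the SL array is shared between mapping loci,
    so that error-free reads from any signal reference map uniquely and
    SL reads map exactly to the array copies.
    """
    if sl_copies < 2:
        raise ValueError("sl_copies must be >= 2")
    for attempt in range(64):
        rng = np.random.default_rng([seed, sl_copies, attempt])
        refset = _candidate_refset(rng, sl_copies)
        if _kmer_clean(refset):
            return refset
    raise RuntimeError("could not construct a collision-free toy reference set")


# -- read simulation ---------------------------------------------------------


def simulate_reads(
    refset: ReferenceSet,
    truth: TruthProfile | Mapping[str, TruthProfile],
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one lane; returns (reads, truth_table).

    ``reads`` is a list of (read_id, sequence); the truth table records
    read_id, sample_id, ref_id, site and umi for every read.  All
    randomness flows from ``config.seed`` through a single generator in a
    fixed draw order (samples, sites, insert lengths, UMIs, errors), so
    identical configs give identical output.

    ``truth`` may be one shared TruthProfile or a per-sample mapping.
    """
    config.validate()
    samples = sorted(config.sample_barcodes)
    per_sample: dict[str, TruthProfile]
    if isinstance(truth, TruthProfile):
        per_sample = {s: truth for s in samples}
    else:
        per_sample = dict(truth)
        if sorted(per_sample) != samples:
            raise ValueError("per-sample truth must cover exactly the configured samples")
    supports = {}
    for s in samples:
        per_sample[s].validate(refset)
        supports[s] = per_sample[s].support()

    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    layout = config.layout
    lo, hi, _ = config.insert_length_dist

    sample_idx = rng.integers(0, len(samples), size=n)
    site_idx = np.empty(n, dtype=np.int64)
    for j, s in enumerate(samples):
        mask = sample_idx == j
        keys, probs = supports[s]
        site_idx[mask] = rng.choice(len(keys), size=int(mask.sum()), p=probs)
    insert_len = rng.integers(lo, hi + 1, size=n)
    umi_codes = rng.integers(0, 4, size=(n, layout.umi_len))

    reads: list[tuple[str, str]] = []
    rows = []
    err = config.substitution_error_rate
    for i in range(n):
        s = samples[sample_idx[i]]
        keys, _ = supports[s]
        ref_id, site = keys[site_idx[i]]
        seq = refset.get(ref_id).seq
        insert = seq[site : site + int(insert_len[i])]  # starts at site + 1 (1-based)
        umi = "".join("ACGT"[c] for c in umi_codes[i])
        lead, trail = umi[: layout.lead_random_len], umi[layout.lead_random_len :]
        body = lead + config.sample_barcodes[s] + trail + insert + config.adapter
        read = (body + "A" * config.read_length)[: config.read_length]
        if err > 0.0:
            arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
            mask = rng.random(arr.size) < err
            if mask.any():
                idx = np.nonzero(mask)[0]
                base_idx = np.searchsorted(_BASES, arr[idx])
                arr[idx] = _BASES[(base_idx + rng.integers(1, 4, size=idx.size)) % 4]
                read = arr.tobytes().decode("ascii")
        read_id = f"read{i:06d}"
        reads.append((read_id, read))
        rows.append((read_id, s, ref_id, site, umi))
    table = pd.DataFrame(rows, columns=["read_id", "sample_id", "ref_id", "site", "umi"])
    return reads, table


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_truth_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def truth_dedup_counts(table: pd.DataFrame) -> dict[tuple[str, str, int], int]:
    """Distinct-UMI counts per (sample, ref, site) from a truth table."""
    dedup = table.drop_duplicates(subset=["sample_id", "ref_id", "site", "umi"])
    grouped = dedup.groupby(["sample_id", "ref_id", "site"]).size()
    return {
        (s, r, int(p)): int(v) for (s, r, p), v in grouped.items()
    }
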