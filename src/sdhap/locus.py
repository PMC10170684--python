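"""Reference locus model: coordinates, segments, SD blocks and label maps.

The locus is modelled as a set of segmental-duplication (SD) blocks, each
built from copies of a small inventory of segments (the "segment grammar"),
separated by unique sequence.  All internal coordinates are 0-based,
half-open; 1-based dialects (CMAP, printed genome coordinates) are converted
at the I/O boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_MOTIF = "CTTAAG"  # DLE-1 recognition site

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based, half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: {self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand: {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class LabelMap:
    """Ordered motif-label positions on one map (consensus map or in-silico digest)."""

    map_id: str
    length: int
    labels: np.ndarray  # bp positions, strictly increasing, 0-based motif start

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.labels.size and not np.all(np.diff(self.labels) > 0):
            raise ValueError(f"labels of map {self.map_id!r} not strictly increasing")
        if self.labels.size and (self.labels[0] < 0 or self.labels[-1] > self.length):
            raise ValueError(f"labels of map {self.map_id!r} outside [0, length]")

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    def slice(self, start: float, end: float, map_id: str | None = None) -> "LabelMap":
        """Sub-map over [start, end); label positions re-based to the slice."""
        sel = self.labels[(self.labels >= start) & (self.labels < end)] - start
        return LabelMap(map_id or f"{self.map_id}[{int(start)}:{int(end)}]",
                        int(end - start), sel)

    def reversed(self) -> "LabelMap":
        return LabelMap(self.map_id, self.length,
                        np.sort(self.length - self.labels))


@dataclass
class Molecule(LabelMap):
    """A single noisy molecule; truth metadata is present iff simulated."""

    source_sample: str = ""
    origin_haplotype: str | None = None
    origin_offset: float | None = None


@dataclass
class SegmentDef:
    """One segment of the grammar (one "colored arrow" of the locus figure).

    ``parent_segment`` marks a segment that is a truncated copy of another
    (e.g. a 15-kbp partial copy of the 26-kbp segment); decomposition searches
    only root segments and renames sub-threshold hits to the derived segment.
    """

    segment_id: str
    canonical_length: int
    reference_copies: list[GenomicInterval] = field(default_factory=list)
    sequence: str | None = None
    parent_segment: str | None = None

    def __post_init__(self):
        if self.canonical_length <= 0:
            raise ValueError("canonical_length must be positive")

    @property
    def copy_count(self) -> int:
        return len(self.reference_copies)

    def label_signature(self, motif: str = DEFAULT_MOTIF) -> np.ndarray:
        """Inter-label distance vector of the canonical sequence's digest."""
        if self.sequence is None:
            raise ValueError(f"segment {self.segment_id} has no sequence")
        labels = digest_sequence(self.sequence, motif).labels
        return np.diff(labels)


@dataclass
class ReferenceLocusModel:
    """SD blocks, segment copies, critical regions and the unique spacer."""

    region: GenomicInterval
    sd_blocks: dict[str, GenomicInterval]
    critical_regions: dict[str, GenomicInterval]
    segments: list[SegmentDef]
    unique_spacer: GenomicInterval | None = None
    flags: list[str] = field(default_factory=list)

    def segment(self, segment_id: str) -> SegmentDef:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(segment_id)

    def copy_counts(self) -> dict[str, int]:
        return {s.segment_id: s.copy_count for s in self.segments}

    def all_copies(self) -> list[tuple[str, int, GenomicInterval]]:
        """Every (segment_id, copy_index, interval), sorted by position."""
        out = []
        for s in self.segments:
            for i, iv in enumerate(sorted(s.reference_copies, key=lambda v: v.start)):
                out.append((s.segment_id, i, iv))
        out.sort(key=lambda t: t[2].start)
        return out

    def block_of(self, interval: GenomicInterval) -> str | None:
        """SD block whose span overlaps the interval, else None (unique)."""
        for name, block in self.sd_blocks.items():
            if block.overlaps(interval):
                return name
        return None

    def copies_overlapping(self, interval: GenomicInterval):
        return [(sid, i, iv) for sid, i, iv in self.all_copies()
                if iv.overlaps(interval)]


def digest_sequence(seq: str, motif: str = DEFAULT_MOTIF,
                    map_id: str = "digest") -> LabelMap:
    """In-silico digestion: positions of every motif occurrence (forward scan).

    The DLE-1 motif CTTAAG is its own reverse complement, so a single forward
    scan is strand-complete.  Overlapping occurrences are all reported; N never
    matches.  Label position = first base of the occurrence, 0-based.
    """
    if not motif:
        raise ValueError("empty motif")
    if len(motif) < 4:
        raise ValueError("motif shorter than 4 bp")
    seq_u = seq.upper()
    if re.search(r"[^ACGTN]", seq_u):
        raise ValueError("sequence contains non-nucleotide characters")
    pattern = re.compile(f"(?={re.escape(motif.upper())})")
    positions = np.array([m.start() for m in pattern.finditer(seq_u)], dtype=float)
    return LabelMap(map_id, len(seq), positions)


def build_reference_model(
    segment_copies: dict[str, list[GenomicInterval]] | list[tuple[str, GenomicInterval]],
    critical_regions: dict[str, GenomicInterval],
    region: GenomicInterval,
    canonical_lengths: dict[str, int] | None = None,
    sequences: dict[str, str] | None = None,
    parent_segments: dict[str, str] | None = None,
) -> ReferenceLocusModel:
    """Assemble a locus model from segment-copy intervals and SD-block config.

    SD block envelopes are derived from the critical regions; copies falling
    outside ``region`` are retained with a flag rather than rejected, because
    published locus coordinates are not always self-consistent.
    """
    if isinstance(segment_copies, list):
        grouped: dict[str, list[GenomicInterval]] = {}
        for sid, iv in segment_copies:
            grouped.setdefault(sid, []).append(iv)
        segment_copies = grouped

    flags: list[str] = []
    segments: list[SegmentDef] = []
    seen: set[tuple[int, int]] = set()
    for sid, copies in segment_copies.items():
        copies = sorted(copies, key=lambda v: v.start)
        for iv in copies:
            key = (iv.start, iv.end)
            if key in seen:
                raise ValueError(f"duplicate copy interval {iv.start}-{iv.end}")
            seen.add(key)
            if not region.contains(GenomicInterval(iv.chrom, iv.start, iv.end)):
                flags.append(f"copy of {sid} at {iv.start}-{iv.end} outside region")
        canonical = (canonical_lengths or {}).get(
            sid, int(np.median([iv.length() for iv in copies])))
        for iv in copies:
            if not (0.5 * canonical <= iv.length() <= 1.5 * canonical):
                flags.append(f"copy of {sid} at {iv.start}-{iv.end} length-divergent")
        segments.append(SegmentDef(
            segment_id=sid, canonical_length=canonical, reference_copies=copies,
            sequence=(sequences or {}).get(sid),
            parent_segment=(parent_segments or {}).get(sid)))
    if not segments:
        flags.append("no segments")

    for name, cr in critical_regions.items():
        if not region.contains(cr):
            flags.append(f"critical region {name} extends beyond analysis region")
    if flags:
        warnings.warn("; ".join(flags), stacklevel=2)

    # published region coordinates are not always self-consistent with the
    # critical regions; keep the union envelope so every copy is addressable
    lo = min([region.start] + [cr.start for cr in critical_regions.values()]
             + [iv.start for s in segments for iv in s.reference_copies])
    hi = max([region.end] + [cr.end for cr in critical_regions.values()]
             + [iv.end for s in segments for iv in s.reference_copies])
    if (lo, hi) != (region.start, region.end):
        region = GenomicInterval(region.chrom, lo, hi, region.strand)

    blocks = dict(critical_regions)
    spacer = None
    if "SDB" in blocks and "SDC" in blocks:
        spacer = GenomicInterval(region.chrom, blocks["SDB"].end, blocks["SDC"].start)
    return ReferenceLocusModel(
        region=region, sd_blocks=blocks, critical_regions=dict(critical_regions),
        segments=segments, unique_spacer=spacer, flags=flags)
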