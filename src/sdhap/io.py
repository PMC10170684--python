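"""Readers and writers for the text formats the pipeline touches.

CMAP (Bionano consensus-map dialect, v0.2-style tab-separated text) carries
1-based label positions; BED is natively 0-based half-open.  Everything is
converted to the internal 0-based convention on read and back on write.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus import GenomicInterval, LabelMap, Molecule

_CMAP_HEADER = """\
# CMAP File Version:\t0.2
# Label Channels:\t1
# Nickase Recognition Site 1:\tCTTAAG
#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition\tStdDev\tCoverage\tOccurrence
#f int\tfloat\tint\tint\tint\tfloat\tfloat\tfloat\tfloat
"""


class CmapFormatError(ValueError):
    pass


def write_cmap(maps: list[LabelMap], path: str | Path) -> None:
    """Write label maps as CMAP; internal 0-based positions become 1-based."""
    with open(path, "w") as fh:
        fh.write(_CMAP_HEADER)
        for m in maps:
            n = m.n_labels
            for i, pos in enumerate(m.labels, start=1):
                fh.write(f"{m.map_id}\t{m.length:.1f}\t{n}\t{i}\t1\t"
                         f"{pos + 1:.3f}\t1.0\t1.0\t1.0\n")
            # channel-0 terminal row marks the map end
            fh.write(f"{m.map_id}\t{m.length:.1f}\t{n}\t{n + 1}\t0\t"
                     f"{float(m.length):.1f}\t1.0\t1.0\t1.0\n")


def read_cmap(path: str | Path) -> list[LabelMap]:
    """Read a CMAP file into label maps (positions converted to 0-based)."""
    rows: dict[str, dict] = {}
    order: list[str] = []
    saw_header = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                saw_header = True
                continue
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise CmapFormatError(f"malformed CMAP row: {line!r}")
            map_id, length, _n, _site, channel, pos = parts[:6]
            if map_id not in rows:
                rows[map_id] = {"length": float(length), "positions": []}
                order.append(map_id)
            if int(channel) == 1:
                rows[map_id]["positions"].append(float(pos) - 1.0)
    if not saw_header:
        raise CmapFormatError("missing CMAP header")
    maps = []
    for map_id in order:
        pos = np.array(rows[map_id]["positions"])
        if pos.size and np.any(np.diff(pos) <= 0):
            raise CmapFormatError(f"unsorted label positions in map {map_id!r}")
        maps.append(LabelMap(map_id, int(round(rows[map_id]["length"])), pos))
    return maps


def write_molecules_cmap(mols: list[Molecule], path: str | Path) -> None:
    write_cmap(mols, path)


# ---------------------------------------------------------------------------
# BED

def write_bed(entries: list[tuple[str, GenomicInterval]], path: str | Path) -> None:
    """BED6: name column = segment id, score 0, strand from the interval."""
    with open(path, "w") as fh:
        for name, iv in entries:
            strand = iv.strand if iv.strand in "+-" else "+"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            out.append((name, GenomicInterval(chrom, start, end, strand)))
    return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# config

def read_locus_config(path: str | Path) -> dict:
    """YAML config: region + per-block critical regions (1-based inclusive in
    the file, converted here)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    chrom = cfg["chrom"]

    def conv(pair):
        start_1, end_1 = pair
        return GenomicInterval(chrom, int(start_1) - 1, int(end_1))

    out = {
        "region": conv(cfg["region"]),
        "critical_regions": {k: conv(v) for k, v in cfg["critical_regions"].items()},
    }
    return out


def interval_from_one_based(chrom: str, start_1: int, end_1: int,
                            strand: str = ".") -> GenomicInterval:
    """Convert a 1-based inclusive span (printed coordinate dialect)."""
    return GenomicInterval(chrom, start_1 - 1, end_1, strand)
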