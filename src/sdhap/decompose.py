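"""Decompose an assembled haplotype into an ordered, oriented segment string.

A haplotype of an SD locus is represented as a string over the segment
alphabet (the colored arrows of the locus figure): each token records which
segment matched, in which orientation, over which span of the query, and
whether the copy is partial.  Sequence queries are decomposed by k-mer
seed-and-extend with edit-distance verification and best-alignment overlap
resolution; label-map queries by greedy matching of segment label signatures
against inter-label distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .locus import (DEFAULT_MOTIF, GenomicInterval, LabelMap,
                    ReferenceLocusModel, SegmentDef, digest_sequence, revcomp)

PARTIAL_MAX_FRACTION = 0.8   # below this a hit is a partial copy
DISCARD_FRACTION = 0.4       # below this a hit is noise and dropped


@dataclass(frozen=True)
class SegmentToken:
    segment_id: str
    orientation: str                 # '+' or '-'
    span_on_query: GenomicInterval
    fraction: float                  # matched length / canonical length
    partial: bool = False
    identity: float = 1.0

    def __post_init__(self):
        if not (0 < self.fraction <= 1.25):
            raise ValueError(f"fraction out of range: {self.fraction}")
        if self.partial != (self.fraction < PARTIAL_MAX_FRACTION):
            raise ValueError("partial flag inconsistent with fraction")

    @property
    def key(self) -> tuple[str, str, bool]:
        return (self.segment_id, self.orientation, self.partial)

    def __str__(self) -> str:
        return f"{self.segment_id}{self.orientation}{'*' if self.partial else ''}"

    def flipped(self, query_length: int) -> "SegmentToken":
        iv = self.span_on_query
        return SegmentToken(
            self.segment_id, "-" if self.orientation == "+" else "+",
            GenomicInterval(iv.chrom, query_length - iv.end, query_length - iv.start),
            self.fraction, self.partial, self.identity)


@dataclass
class HaplotypeStructure:
    """Ordered token string plus anchoring information."""

    tokens: list[SegmentToken]
    total_span: int
    anchors: tuple[bool, bool] = (True, True)   # proximal, distal unique flank
    label_blind: list[str] = field(default_factory=list)

    def __post_init__(self):
        for a, b in zip(self.tokens, self.tokens[1:]):
            if b.span_on_query.start < a.span_on_query.start:
                raise ValueError("tokens not ordered along the query")

    def token_string(self) -> str:
        return ",".join(str(t) for t in self.tokens)

    def keys(self) -> tuple:
        return tuple(t.key for t in self.tokens)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.tokens:
            out[t.segment_id] = out.get(t.segment_id, 0) + 1
        return out

    def reversed(self) -> "HaplotypeStructure":
        toks = [t.flipped(self.total_span) for t in reversed(self.tokens)]
        return HaplotypeStructure(toks, self.total_span,
                                  (self.anchors[1], self.anchors[0]),
                                  list(self.label_blind))

    def is_empty(self) -> bool:
        return not self.tokens


# ---------------------------------------------------------------------------
# sequence decomposition

_BASE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE[ord(b)] = i
    _BASE[ord(b.lower())] = i


def _encode(seq: str) -> np.ndarray:
    return _BASE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Per-position k-mer code; -1 where the window contains a non-ACGT base."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = enc[j:j + n]
        codes = codes * 4 + np.where(col == 4, 0, col)
        bad |= col == 4
    codes[bad] = -1
    return codes


def _cluster_seeds(qpos: np.ndarray, spos: np.ndarray, k: int,
                   diag_tol: int = 800, gap_tol: int = 5000):
    """Group co-diagonal seeds into candidate hit spans."""
    diag = qpos - spos
    order = np.lexsort((qpos, diag))
    clusters = []
    cur: list[int] = []
    for idx in order:
        if cur and (abs(diag[idx] - diag[cur[-1]]) > diag_tol
                    or qpos[idx] - qpos[cur[-1]] > gap_tol):
            clusters.append(cur)
            cur = []
        cur.append(idx)
    if cur:
        clusters.append(cur)
    out = []
    for c in clusters:
        q = qpos[c]
        s = spos[c]
        out.append((int(q.min()), int(q.max()) + k, int(s.min()), int(s.max()) + k))
    return out


def _identity(a: str, b: str) -> float:
    """Global (NW) identity between two strings via edit distance."""
    if not a or not b:
        return 0.0
    ed = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - ed / max(len(a), len(b))


def _infix_align(pattern: str, target: str):
    """Best infix placement of pattern in target: (identity, start, end)."""
    res = edlib.align(pattern, target, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0.0, 0, 0
    start, end = res["locations"][0]
    return 1.0 - res["editDistance"] / len(pattern), start, end + 1


def decompose_sequence(query: str, segments: list[SegmentDef],
                       min_identity: float = 0.90, k: int = 16,
                       anchor_margin: int = 10_000) -> HaplotypeStructure:
    """Best-alignment decomposition of a query sequence over the segment grammar.

    Each root segment is seeded against the query on both strands; candidate
    spans are verified by edit-distance alignment; overlapping hits are
    resolved best-first (higher identity, then longer, then leftmost).  Hits
    matching < 40% of the canonical length are discarded, 40–80% flagged
    partial; a partial hit is renamed to a derived segment (one declared with
    ``parent_segment``) when its matched length fits that segment.
    """
    if len(query) < 1000:
        raise ValueError("query shorter than 1 kbp")
    roots = [s for s in segments if s.parent_segment is None]
    derived = [s for s in segments if s.parent_segment is not None]
    for s in roots:
        if s.sequence is None:
            raise ValueError(f"segment {s.segment_id} has no canonical sequence")

    enc_q = _encode(query)
    qcodes = _kmer_codes(enc_q, k)
    valid = qcodes >= 0
    sort_idx = np.argsort(qcodes[valid], kind="stable")
    sorted_codes = qcodes[valid][sort_idx]
    valid_pos = np.flatnonzero(valid)[sort_idx]

    candidates = []  # (identity, length, qstart, qend, segment, orient, fraction)
    for seg in roots:
        canon = len(seg.sequence)
        for orient in "+-":
            oseq = seg.sequence if orient == "+" else revcomp(seg.sequence)
            scodes = _kmer_codes(_encode(oseq), k)
            stride = max(1, k // 3)
            spos_all, qpos_all = [], []
            for sp in range(0, scodes.size, stride):
                code = scodes[sp]
                if code < 0:
                    continue
                lo = np.searchsorted(sorted_codes, code, side="left")
                hi = np.searchsorted(sorted_codes, code, side="right")
                for qp in valid_pos[lo:hi]:
                    spos_all.append(sp)
                    qpos_all.append(int(qp))
            if not spos_all:
                continue
            for q_lo, q_hi, s_lo, s_hi in _cluster_seeds(
                    np.array(qpos_all), np.array(spos_all), k):
                matched = s_hi - s_lo
                if matched < DISCARD_FRACTION * canon * 0.8:
                    continue
                pad = max(200, int(0.05 * matched))
                if matched >= 0.9 * canon:
                    # full-length hit: place the whole segment
                    w_lo = max(0, q_lo - s_lo - pad)
                    w_hi = min(len(query), q_hi + (canon - s_hi) + pad)
                    ident, a, b = _infix_align(oseq, query[w_lo:w_hi])
                    frac = 1.0
                else:
                    w_lo = max(0, q_lo - pad)
                    w_hi = min(len(query), q_hi + pad)
                    ident, a, b = _infix_align(oseq[s_lo:s_hi], query[w_lo:w_hi])
                    frac = matched / canon
                if ident < min_identity or frac < DISCARD_FRACTION:
                    continue
                qstart, qend = w_lo + a, w_lo + b
                candidates.append((ident, qend - qstart, qstart, qend,
                                   seg, orient, min(frac, 1.25)))

    # best-alignment overlap resolution: identity desc, length desc, leftmost
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    chosen = []
    for cand in candidates:
        _, length, qs, qe, *_ = cand
        clash = False
        for other in chosen:
            os_, oe = other[2], other[3]
            ov = min(qe, oe) - max(qs, os_)
            if ov > 0.1 * min(length, oe - os_):
                clash = True
                break
        if not clash:
            chosen.append(cand)

    tokens = []
    for ident, length, qs, qe, seg, orient, frac in sorted(chosen, key=lambda c: c[2]):
        sid = seg.segment_id
        if frac < PARTIAL_MAX_FRACTION:
            for d in derived:
                if (d.parent_segment == seg.segment_id
                        and abs(length - d.canonical_length) <= 0.3 * d.canonical_length):
                    sid = d.segment_id
                    break
        tokens.append(SegmentToken(
            sid, orient, GenomicInterval("query", qs, qe),
            frac, frac < PARTIAL_MAX_FRACTION, ident))

    anchors = (bool(tokens) and tokens[0].span_on_query.start >= anchor_margin,
               bool(tokens) and len(query) - tokens[-1].span_on_query.end >= anchor_margin)
    return HaplotypeStructure(tokens, len(query), anchors)


# ---------------------------------------------------------------------------
# label-map decomposition

def _match_signature(diffs: np.ndarray, start: int, sig: np.ndarray,
                     sizing_tol: float) -> int | None:
    """Try to match a signature at diffs[start:]; returns #map intervals used.

    Allows at most one label discrepancy: either a missing map label (two
    signature intervals fused into one map interval) or an extra map label
    (two map intervals fused into one signature interval).
    """
    j, t, used_allowance = start, 0, False
    m = sig.size
    while t < m:
        if j >= diffs.size:
            return None
        d = diffs[j]
        if abs(d - sig[t]) <= sizing_tol * sig[t]:
            j += 1
            t += 1
            continue
        if (not used_allowance and t + 1 < m
                and abs(d - (sig[t] + sig[t + 1])) <= sizing_tol * (sig[t] + sig[t + 1])):
            j += 1
            t += 2
            used_allowance = True
            continue
        if (not used_allowance and j + 1 < diffs.size
                and abs(d + diffs[j + 1] - sig[t]) <= sizing_tol * sig[t]):
            j += 2
            t += 1
            used_allowance = True
            continue
        return None
    return j - start


def decompose_labelmap(lmap: LabelMap, model: ReferenceLocusModel,
                       sizing_tol: float = 0.04,
                       motif: str = DEFAULT_MOTIF) -> HaplotypeStructure:
    """Greedy left-to-right matching of segment label signatures against a map.

    The default sizing tolerance targets consensus-quality maps; raising it
    toward single-molecule sizing error (~12%) admits chance matches of
    short signatures in unique sequence — noisy molecules are matched by the
    dynamic-programming aligner instead.

    A segment is detectable from labels alone only if its canonical digest
    carries >= 4 labels (>= 3 inter-label intervals): one or two intervals
    carry no distinctive pattern and match unique sequence by chance.
    Segments below that are reported ``label_blind`` — the optical-map
    analogue of the recurrent-deletion cassette ambiguity.
    """
    sigs: list[tuple[SegmentDef, np.ndarray, np.ndarray]] = []
    blind: list[str] = []
    for seg in model.segments:
        if seg.sequence is None:
            continue
        full = digest_sequence(seg.sequence, motif).labels
        if full.size < 4:
            blind.append(seg.segment_id)
            continue
        sigs.append((seg, np.diff(full), full))
    # longer signatures first so nested/shorter ones cannot shadow them
    sigs.sort(key=lambda t: -t[1].size)

    labels = lmap.labels
    diffs = np.diff(labels)
    tokens = []
    i = 0
    while i < diffs.size:
        best = None
        for seg, sig, full in sigs:
            for orient, s in (("+", sig), ("-", sig[::-1])):
                used = _match_signature(diffs, i, s, sizing_tol)
                if used is not None:
                    first_off = full[0] if orient == "+" else (
                        len(seg.sequence) - full[-1] - len(motif))
                    last_off = len(seg.sequence) - full[-1] if orient == "+" else (
                        full[0] + len(motif))
                    start = labels[i] - first_off
                    end = labels[i + used] + last_off
                    cand = (s.size, seg, orient, used, start, end)
                    if best is None or cand[0] > best[0]:
                        best = cand
        if best is None:
            i += 1
            continue
        _, seg, orient, used, start, end = best
        tokens.append(SegmentToken(
            seg.segment_id, orient,
            GenomicInterval(lmap.map_id, int(max(0, start)), int(end)),
            1.0, False, 1.0))
        i += used
    anchors = (bool(tokens) and tokens[0].span_on_query.start >= 10_000,
               bool(tokens) and lmap.length - tokens[-1].span_on_query.end >= 10_000)
    return HaplotypeStructure(tokens, lmap.length, anchors, blind)
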