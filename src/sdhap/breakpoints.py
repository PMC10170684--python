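"""Breakpoint localization, five-class assignment, mechanism and trios.

Deletion/duplication events at an SD-flanked locus are localized from the
haplotype structure by token-string comparison against the reference model:
an NAHR event fuses two paralogous copies into one token that is claimed by
both the prefix and the suffix of the reference token string, which
identifies the proximal and distal host copies directly.  Classes are
defined by breakpoint context, not by fixed genome coordinates:

  I   deletion,   proximal in the SD-B block's first short-cassette copy,
                  distal in the SD-C paralog
  II  deletion,   proximal in the SD-B block's second cassette copy
  III deletion,   neither breakpoint in any SD
  IV  duplication, breakpoints in the Class-II paralogous cassettes
  V   duplication, both breakpoints in unique sequence between SDB and SDC
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib

from .catalog import HaplotypeRecord
from .decompose import HaplotypeStructure
from .locus import GenomicInterval, ReferenceLocusModel

DELETION, DUPLICATION = "deletion", "duplication"
NAHR, OTHER, AMBIGUOUS = "NAHR", "OTHER", "AMBIGUOUS"
UNRESOLVED = "UNRESOLVED"


@dataclass
class CNVEvent:
    sample: str
    event_type: str                     # deletion | duplication
    proximal_bp: GenomicInterval        # breakpoint uncertainty interval
    distal_bp: GenomicInterval
    size_bp: float
    resolved: bool = True
    reason: str = ""

    def __post_init__(self):
        if self.resolved:
            if self.event_type not in (DELETION, DUPLICATION):
                raise ValueError(f"bad event type {self.event_type!r}")
            if self.proximal_bp.start >= self.distal_bp.end:
                raise ValueError("proximal interval not left of distal interval")


@dataclass
class BreakpointCall:
    event: CNVEvent
    class_label: str                    # I..V or UNCLASSIFIED
    proximal_context: list[str]         # overlapping copies "segment.copyidx" or "unique"
    distal_context: list[str]
    mechanism: str
    identity_at_breakpoints: float = math.nan
    confidence: str = "copy-level"      # "cassette-level" when label-blind partials overlap
    low_confidence: bool = False


def event_from_coords(prox: float, dist: float, event_type: str,
                      chrom: str = "chr3", uncertainty: float | None = None,
                      sample: str = "") -> CNVEvent:
    """Build an event from printed point coordinates (bp).

    ``uncertainty`` is the half-width of the breakpoint interval; printed
    coordinates rounded to 10 kbp carry a +-5 kbp uncertainty, etc.
    """
    if uncertainty is None:
        uncertainty = 5_000.0
    p = GenomicInterval(chrom, int(prox - uncertainty), int(prox + uncertainty))
    d = GenomicInterval(chrom, int(dist - uncertainty), int(dist + uncertainty))
    return CNVEvent(sample, event_type, p, d, dist - prox)


# ---------------------------------------------------------------------------
# localization

def _ref_tokens(model: ReferenceLocusModel):
    """Reference token string: every copy in order, forward, with the
    partial flag for derived (truncated-paralog) segments."""
    out = []
    for sid, idx, iv in model.all_copies():
        partial = model.segment(sid).parent_segment is not None
        out.append(((sid, iv.strand if iv.strand in "+-" else "+", partial),
                    sid, idx, iv))
    return out


def localize_breakpoints(proband: HaplotypeStructure,
                         model: ReferenceLocusModel,
                         sample: str = "",
                         gap_tol: float = 5_000.0) -> CNVEvent | None:
    """Maximal-parsimony event localization from a token-string comparison.

    A fused paralog token (claimed by both the reference prefix and suffix)
    pins the breakpoints to the two host copies; a clean token gap pins them
    to the flanking intervals; a pure span change between concordant tokens
    places both breakpoints in the intervening unique sequence.  Returns
    None when the structure matches the reference.
    """
    if not (proband.anchors[0] and proband.anchors[1]):
        return CNVEvent(sample, DELETION,
                        GenomicInterval("?", 0, 1), GenomicInterval("?", 1, 2),
                        0.0, resolved=False, reason="structure not anchored on both flanks")
    ref = _ref_tokens(model)
    rkeys = [r[0] for r in ref]
    q = proband.tokens
    qkeys = [t.key for t in q]
    nq, nr = len(qkeys), len(rkeys)

    p = 0
    while p < min(nq, nr) and qkeys[p] == rkeys[p]:
        p += 1
    s = 0
    while s < min(nq, nr) and qkeys[nq - 1 - s] == rkeys[nr - 1 - s]:
        s += 1

    chrom = model.region.chrom
    if nq == nr and p == nq:
        # token-identical: look for a span change between consecutive tokens
        for j in range(1, nr):
            ref_gap = ref[j][3].start - ref[j - 1][3].end
            q_gap = q[j].span_on_query.start - q[j - 1].span_on_query.end
            delta = ref_gap - q_gap
            if abs(delta) > gap_tol:
                lo, hi = ref[j - 1][3].end, ref[j][3].start
                etype = DELETION if delta > 0 else DUPLICATION
                size = abs(delta)
                prox = GenomicInterval(chrom, lo, max(lo + 1, hi - int(size))
                                       if etype == DELETION else hi)
                dist = GenomicInterval(chrom, min(hi - 1, lo + int(size))
                                       if etype == DELETION else lo, hi)
                if dist.start < prox.start:  # duplication: same gap hosts both
                    prox = dist = GenomicInterval(chrom, lo, hi)
                return CNVEvent(sample, etype, prox, dist, float(size))
        return None

    if p + s >= nq + 1 and nq != nr:
        # fused paralog token: some query token f is claimed by both the
        # reference prefix (as ref[f]) and suffix (as ref[nr-nq+f]).  When
        # the overlap admits several junctions (identical paralog cassettes
        # in a row) they differ by less than the cassette spacing; take the
        # prefix-maximal one.
        f = min(p - 1, nq - 1)
        if f < nq - s:
            f = nq - s
        a, b = f, nr - nq + f
        iv_a, iv_b = ref[a][3], ref[b][3]
        if a < b:
            etype, prox_iv, dist_iv = DELETION, iv_a, iv_b
        else:
            etype, prox_iv, dist_iv = DUPLICATION, iv_b, iv_a
        size = float(dist_iv.start - prox_iv.start)
        return CNVEvent(sample, etype, prox_iv, dist_iv, size)

    if p + s == nq and nq < nr:
        # clean token-level deletion of ref[p .. nr-s-1]
        lo = ref[p - 1][3].end if p else model.region.start
        hi = ref[nr - s][3].start if s else model.region.end
        ref_span = hi - lo
        q_gap = (q[p].span_on_query.start - q[p - 1].span_on_query.end
                 if 0 < p <= nq - 1 else ref_span)
        size = float(ref_span - q_gap)
        prox = GenomicInterval(chrom, lo, ref[p][3].start)
        dist = GenomicInterval(chrom, ref[nr - s - 1][3].end, hi)
        return CNVEvent(sample, DELETION, prox, dist, size)

    return CNVEvent(sample, DELETION, GenomicInterval(chrom, 0, 1),
                    GenomicInterval(chrom, 1, 2), 0.0, resolved=False,
                    reason="token strings not reconcilable by a single event")


# ---------------------------------------------------------------------------
# classification

def _contexts(model: ReferenceLocusModel, iv: GenomicInterval):
    hits = model.copies_overlapping(iv)
    return hits if hits else []


def classify_event(event: CNVEvent, model: ReferenceLocusModel) -> BreakpointCall:
    """Assign one of the five breakpoint classes from breakpoint context.

    When both uncertainty intervals overlap paralogous copies of one segment
    (same orientation) the event is NAHR-compatible; the SD-B copy index of
    the proximal cassette separates Class I from Class II.  The call carries
    a cassette-level confidence qualifier when a truncated-paralog copy also
    overlaps the proximal interval (the label-blind cassette ambiguity).
    """
    if not event.resolved:
        return BreakpointCall(event, "UNCLASSIFIED", [], [], OTHER,
                              low_confidence=True)
    prox_hits = _contexts(model, event.proximal_bp)
    dist_hits = _contexts(model, event.distal_bp)
    prox_ctx = [f"{sid}.{i}" for sid, i, _ in prox_hits] or ["unique"]
    dist_ctx = [f"{sid}.{i}" for sid, i, _ in dist_hits] or ["unique"]

    # paralogous pair: same segment id on both sides, same orientation,
    # proximal copy in SDB, distal copy in SDC
    pair = None
    sdb = model.sd_blocks.get("SDB")
    sdc = model.sd_blocks.get("SDC")
    for sid_p, _ip, iv_p in prox_hits:
        for sid_d, _id, iv_d in dist_hits:
            if (sid_p == sid_d and iv_p.start != iv_d.start
                    and iv_p.strand == iv_d.strand
                    and sdb is not None and sdb.overlaps(iv_p)
                    and sdc is not None and sdc.overlaps(iv_d)):
                pair = (sid_p, iv_p, iv_d)
                break
        if pair:
            break

    confidence = "copy-level"
    if any(model.segment(sid).parent_segment is not None for sid, _, _ in prox_hits):
        confidence = "cassette-level"

    label = "UNCLASSIFIED"
    mechanism = OTHER
    if pair is not None:
        sid, iv_p, _ = pair
        seg = model.segment(sid)
        sdb_copies = sorted(
            (iv for iv in seg.reference_copies if sdb.overlaps(iv)),
            key=lambda v: v.start)
        copy_rank = next((k for k, iv in enumerate(sdb_copies)
                          if iv.start == iv_p.start), 0)
        if event.event_type == DELETION:
            label = "I" if copy_rank == 0 else "II"
        else:
            label = "IV"
        mechanism = NAHR
    elif prox_ctx == ["unique"] and dist_ctx == ["unique"]:
        label = "III" if event.event_type == DELETION else "V"
        mechanism = OTHER

    return BreakpointCall(event, label, prox_ctx, dist_ctx, mechanism,
                          confidence=confidence)


def infer_mechanism(call: BreakpointCall, proximal_seq: str | None,
                    distal_seq: str | None) -> BreakpointCall:
    """Mechanism from breakpoint-context sequence identity.

    NAHR requires paralogous same-orientation contexts at >= 98% identity;
    < 80% (or unique contexts) is OTHER; the band between is AMBIGUOUS.
    Missing sequence falls back to context only, flagged low-confidence.
    """
    paralogous = call.class_label in ("I", "II", "IV")
    if proximal_seq is None or distal_seq is None:
        call.mechanism = NAHR if paralogous else OTHER
        call.low_confidence = True
        return call
    ed = edlib.align(proximal_seq, distal_seq, mode="NW",
                     task="distance")["editDistance"]
    ident = 1.0 - ed / max(len(proximal_seq), len(distal_seq))
    call.identity_at_breakpoints = ident
    if paralogous and ident >= 0.98:
        call.mechanism = NAHR
    elif ident < 0.80 or not paralogous:
        call.mechanism = OTHER
    else:
        call.mechanism = AMBIGUOUS
    return call


# ---------------------------------------------------------------------------
# trio parent-of-origin

@dataclass
class TrioInput:
    family: str
    proband_intact: str                  # haplotype id of the intact chromosome
    proband_prox_flank: tuple            # token keys proximal of the junction
    proband_dist_flank: tuple            # token keys distal of the junction
    mother: tuple[str, str] | None
    father: tuple[str, str] | None


@dataclass
class TrioResult:
    family: str
    parent_of_origin: str                # "mother" | "father" | UNRESOLVED
    origin_haplotype: str | None = None
    intact_haplotype: str | None = None
    transmitting_parent_of_intact: str | None = None
    reason: str = ""

    def __post_init__(self):
        if (self.parent_of_origin != UNRESOLVED
                and self.transmitting_parent_of_intact is not None
                and self.parent_of_origin == self.transmitting_parent_of_intact):
            raise ValueError("origin parent cannot also transmit the intact chromosome")


def _is_prefix(flank: tuple, keys: tuple) -> bool:
    return len(flank) <= len(keys) and tuple(keys[:len(flank)]) == tuple(flank)


def _is_suffix(flank: tuple, keys: tuple) -> bool:
    return len(flank) <= len(keys) and tuple(keys[len(keys) - len(flank):]) == tuple(flank)


def _explaining_haplotypes(trio: TrioInput, hap_ids: tuple[str, str],
                           catalog: dict[str, HaplotypeRecord]) -> list[str]:
    """Haplotypes of one parent (or a single crossover between their two)
    explaining both flanks of the rearranged chromosome."""
    out = []
    keys = {h: catalog[h].token_keys for h in hap_ids if h in catalog}
    for h, k in keys.items():
        if _is_prefix(trio.proband_prox_flank, k) and _is_suffix(trio.proband_dist_flank, k):
            out.append(h)
    if not out and len(keys) == 2:
        (h1, k1), (h2, k2) = keys.items()
        for ha, ka, hb, kb in ((h1, k1, h2, k2), (h2, k2, h1, k1)):
            if _is_prefix(trio.proband_prox_flank, ka) and _is_suffix(trio.proband_dist_flank, kb):
                out.append(f"{ha}x{hb}")
    return out


def parent_of_origin(trio: TrioInput,
                     catalog: list[HaplotypeRecord]) -> TrioResult:
    """Resolve which parent transmitted the rearranged chromosome.

    The intact proband haplotype must be attributable to one parent and the
    rearranged chromosome's flanks to the other; any symmetric assignment is
    reported UNRESOLVED rather than guessed.
    """
    cat = {r.haplotype_id: r for r in catalog}
    if trio.mother is None or trio.father is None:
        present = "mother" if trio.mother is not None else (
            "father" if trio.father is not None else None)
        reason = "missing parent"
        if present is not None:
            ids = trio.mother or trio.father
            expl = _explaining_haplotypes(trio, ids, cat)
            if expl and trio.proband_intact not in ids:
                # the available parent explains the rearranged flanks and
                # cannot have donated the intact chromosome
                return TrioResult(trio.family, present, expl[0],
                                  trio.proband_intact, None,
                                  reason="single-parent inference")
        return TrioResult(trio.family, UNRESOLVED, None, trio.proband_intact,
                          None, reason=reason)

    donors = [p for p, ids in (("mother", trio.mother), ("father", trio.father))
              if trio.proband_intact in ids]
    origin_expl = {p: _explaining_haplotypes(trio, ids, cat)
                   for p, ids in (("mother", trio.mother), ("father", trio.father))}

    assignments = []
    for origin in ("mother", "father"):
        donor = "father" if origin == "mother" else "mother"
        if origin_expl[origin] and donor in donors:
            assignments.append((origin, donor, origin_expl[origin][0]))
    if len(assignments) != 1:
        return TrioResult(trio.family, UNRESOLVED, None, trio.proband_intact,
                          None,
                          reason="ambiguous assignment" if assignments
                          else "no consistent assignment")
    origin, donor, hap = assignments[0]
    return TrioResult(trio.family, origin, hap, trio.proband_intact, donor)
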