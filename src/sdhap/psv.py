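"""Crossover-interval refinement from paralogous sequence variants (PSVs).

Given the proximal and distal paralog sequences of the parent-of-origin
haplotype and the proband's junction-spanning sequence, the NAHR exchange
point is bracketed by the last PSV genotyped as proximal and the first PSV
genotyped as distal.  Pairwise alignments (junction->proximal composed with
proximal->distal) replace a 3-way MSA; for paralogs at >= 98% identity the
two are equivalent and the pairwise chain is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

PROXIMAL, DISTAL, NEITHER = "P", "D", "N"


@dataclass(frozen=True)
class PSV:
    position: int        # coordinate on the proximal copy (0-based)
    proximal_allele: str
    distal_allele: str

    def __post_init__(self):
        if self.proximal_allele == self.distal_allele:
            raise ValueError("PSV alleles must differ")


@dataclass(frozen=True)
class CrossoverInterval:
    start: int           # position of the last proximal-matching PSV
    end: int             # position of the first distal-matching PSV
    last_proximal_psv: int
    first_distal_psv: int
    n_conflicts: int

    @property
    def width(self) -> int:
        return self.end - self.start


def _nice_cigar(a: str, b: str):
    """edlib NW path as (op, length) pairs; ops: '=' handled as 'M'."""
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return res["editDistance"], out


def _affine_ops(a: str, b: str):
    """Affine-gap global alignment of a short window (query a vs target b)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    ops = []
    qa, qb = aln.aligned
    qi = ti = 0
    for (qs, qe), (ts, te) in zip(qa, qb):
        if qs > qi:
            ops.append(("I", qs - qi))
        if ts > ti:
            ops.append(("D", ts - ti))
        ops.append(("M", qe - qs))
        qi, ti = qe, te
    if len(a) > qi:
        ops.append(("I", len(a) - qi))
    if len(b) > ti:
        ops.append(("D", len(b) - ti))
    return ops


def _aligned_ops(query: str, target: str, merge_gap: int = 10):
    """Normalized global alignment ops (query vs target).

    Edit-distance alignments are not unique: ties can scatter an indel run
    or trade two substitutions for an indel pair.  Dirty windows of the
    edlib path (non-match columns, merged when separated by < ``merge_gap``
    match columns) are therefore re-aligned locally with affine gap costs,
    which prefers substitutions and consolidates gap runs.
    """
    _, raw = _nice_cigar(query, target)
    # windows of consecutive ops treated as one local realignment problem
    events = []          # (q_start, t_start, q_len, t_len)
    out = []
    q = t = 0
    pending: list[tuple[int, int, int, int]] | None = None

    def flush():
        nonlocal pending
        if pending is not None:
            qs, ts, qe, te = pending
            if qe > qs or te > ts:
                for op, ln in _affine_ops(query[qs:qe], target[ts:te]):
                    out.append((op, ln))
            pending = None

    for op, ln in raw:
        is_match = op in "=M"
        if is_match and (ln >= merge_gap or pending is None):
            flush()
            out.append(("M", ln))
            q += ln
            t += ln
            continue
        dq = ln if op in "=MXI" else 0
        dt = ln if op in "=MXD" else 0
        if pending is None:
            pending = (q, t, q + dq, t + dt)
        else:
            pending = (pending[0], pending[1], q + dq, t + dt)
        q += dq
        t += dt
    flush()
    # merge adjacent same-op runs
    merged: list[tuple[str, int]] = []
    for op, ln in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged


def _global_identity(a: str, b: str) -> float:
    ed = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - ed / max(len(a), len(b))


def find_psvs(proximal_seq: str, distal_seq: str,
              min_identity: float = 0.90) -> list[PSV]:
    """All positions where the aligned paralogs differ.

    Substitution columns emit one PSV each; an indel run collapses to a
    single PSV anchored at the run start (alleles: the run vs '-').
    """
    ident = _global_identity(proximal_seq, distal_seq)
    if ident < min_identity:
        raise ValueError(
            f"sequences are not paralogs (identity {ident:.3f} < {min_identity})")
    ops = _aligned_ops(distal_seq, proximal_seq)  # query=distal, target=proximal
    psvs: list[PSV] = []
    p = 0  # proximal coordinate
    d = 0  # distal coordinate
    for op, ln in ops:
        if op in "=MX":
            for k in range(ln):
                if proximal_seq[p + k] != distal_seq[d + k]:
                    psvs.append(PSV(p + k, proximal_seq[p + k], distal_seq[d + k]))
            p += ln
            d += ln
        elif op == "D":  # consumes target (proximal) only: deletion in distal
            psvs.append(PSV(p, proximal_seq[p:p + ln], "-"))
            p += ln
        elif op == "I":  # insertion in distal relative to proximal
            psvs.append(PSV(max(0, p - 1), "-", distal_seq[d:d + ln]))
            d += ln
    # collapse PSVs sharing an anchor position (adjacent indel bookkeeping)
    dedup: dict[int, PSV] = {}
    for v in psvs:
        dedup.setdefault(v.position, v)
    return [dedup[k] for k in sorted(dedup)]


def genotype_junction(junction_seq: str, proximal_seq: str,
                      psvs: list[PSV], min_identity: float = 0.70) -> list[str]:
    """Label each PSV position in the junction as P (proximal allele),
    D (distal allele) or N (neither / uncovered).

    The junction is aligned globally to the proximal copy; at each PSV
    position the junction residue(s) are read off through the alignment.
    """
    ident = _global_identity(junction_seq, proximal_seq)
    if ident < min_identity:
        raise ValueError(f"junction does not align (identity {ident:.3f})")
    ops = _aligned_ops(junction_seq, proximal_seq)
    # map proximal coordinate -> junction coordinate (or None inside deletions)
    prox_to_j: dict[int, int | None] = {}
    p = j = 0
    for op, ln in ops:
        if op in "=MX":
            for k in range(ln):
                prox_to_j[p + k] = j + k
            p += ln
            j += ln
        elif op == "D":  # proximal bases absent from junction
            for k in range(ln):
                prox_to_j[p + k] = None
            p += ln
        elif op == "I":
            j += ln
    out = []
    for v in psvs:
        jpos = prox_to_j.get(v.position, None)
        plen = max(len(v.proximal_allele.replace("-", "")), 1)
        if jpos is None:
            # base absent: matches a distal deletion allele, else neither
            out.append(DISTAL if v.distal_allele == "-" else NEITHER)
            continue
        obs = junction_seq[jpos:jpos + plen]
        if v.proximal_allele != "-" and obs == v.proximal_allele[:len(obs)] \
                and len(obs) == len(v.proximal_allele):
            out.append(PROXIMAL)
        elif v.distal_allele != "-" and obs and obs[0] == v.distal_allele[0] \
                and junction_seq[jpos:jpos + len(v.distal_allele)] == v.distal_allele:
            out.append(DISTAL)
        elif v.proximal_allele == "-":
            # insertion PSV: presence of inserted bases after anchor = distal
            ins = v.distal_allele
            if junction_seq[jpos + 1:jpos + 1 + len(ins)] == ins:
                out.append(DISTAL)
            else:
                out.append(PROXIMAL)
        else:
            out.append(NEITHER)
    return out


def refine_crossover(assignments: list[str], psvs: list[PSV]) -> CrossoverInterval:
    """Minimal-conflict switch point over the P/D assignment vector.

    The switch index k (between PSV k-1 and PSV k) minimises the number of
    conflicts (D before the switch + P after it), ties broken leftmost; the
    interval runs from the last P-assigned PSV before the switch to the
    first D-assigned PSV after it.  N assignments are uninformative.
    """
    if len(assignments) != len(psvs):
        raise ValueError("assignments and PSVs differ in length")
    informative = [(a, v.position) for a, v in zip(assignments, psvs)
                   if a in (PROXIMAL, DISTAL)]
    labels = [a for a, _ in informative]
    if PROXIMAL not in labels or DISTAL not in labels:
        raise ValueError("no crossover in window (need both P and D labels)")
    n = len(labels)
    best_k, best_conflicts = 0, None
    for k in range(n + 1):
        conflicts = labels[:k].count(DISTAL) + labels[k:].count(PROXIMAL)
        if best_conflicts is None or conflicts < best_conflicts:
            best_k, best_conflicts = k, conflicts
    # bracketing PSVs around the optimal switch
    left = [pos for (a, pos) in informative[:best_k] if a == PROXIMAL]
    right = [pos for (a, pos) in informative[best_k:] if a == DISTAL]
    if not left or not right:
        raise ValueError("degenerate switch (no bracketing P/D pair)")
    start, end = left[-1], right[0]
    return CrossoverInterval(start, end, start, end, int(best_conflicts))
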