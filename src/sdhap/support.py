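"""Single-molecule support evaluation for candidate haplotype maps.

Each molecule is aligned to every candidate consensus map by dynamic
programming over label positions (global on the molecule, free end-gaps on
the map), in both orientations.  A molecule supports a candidate only when
it wins by a clear score margin over the runner-up AND fully spans one of
the candidate's critical regions; a diploid genotype is then called from
supporting-molecule counts with the n >= 3 rule.

Scoring model: score = C_match * (matched labels) - sum of sizing penalties
- C_miss * (skipped map labels inside the aligned span) - C_false *
(unmatched molecule labels); the sizing penalty of a matched interval is
((dC - dM)/sigma)^2 with sigma = max(500 bp, 0.03 * dC).  Up to three
consecutive labels may be skipped/merged between matched neighbours
(optical resolution handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .locus import LabelMap, Molecule

NO_CALL = "NO_CALL"
MULTI = "MULTI"


@dataclass(frozen=True)
class AlignParams:
    c_match: float = 3.0
    c_miss: float = 1.0
    c_false: float = 1.0
    margin: float = 3.0          # winner-vs-runner-up score margin (delta)
    sigma_min: float = 500.0     # bp
    sigma_rel: float = 0.03
    max_step: int = 4            # <= 3 consecutive skipped/merged labels
    min_mol_labels: int = 5
    min_mol_length: float = 150_000.0


@dataclass
class MapAlignment:
    molecule_id: str
    cmap_id: str
    pairs: list[tuple[int, int]]        # (molecule label idx, cmap label idx)
    score: float
    span_start: float                   # molecule footprint on the cmap (bp)
    span_end: float
    orientation: str

    def __post_init__(self):
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if i1 <= i0 or j1 <= j0:
                raise ValueError("matched pairs not strictly increasing")


@njit(cache=False)
def _dp_kernel(mol, cmap, c_match, c_miss, c_false, sigma_min, sigma_rel, w):
    n = mol.size
    m = cmap.size
    neg = -1e18
    dp = np.full((n, m), neg)
    bi = np.full((n, m), -1, dtype=np.int64)
    bj = np.full((n, m), -1, dtype=np.int64)
    for i in range(n):
        for j in range(m):
            best = c_match - c_false * i   # first matched pair; map end free
            pi, pj = -1, -1
            ilo = i - w if i - w > 0 else 0
            jlo = j - w if j - w > 0 else 0
            for ii in range(ilo, i):
                for jj in range(jlo, j):
                    prev = dp[ii, jj]
                    if prev <= neg / 2:
                        continue
                    dc = cmap[j] - cmap[jj]
                    dm = mol[i] - mol[ii]
                    sigma = sigma_rel * dc
                    if sigma < sigma_min:
                        sigma = sigma_min
                    pen = ((dc - dm) / sigma) ** 2
                    cand = (prev + c_match - pen
                            - c_false * (i - ii - 1) - c_miss * (j - jj - 1))
                    if cand > best:
                        best = cand
                        pi, pj = ii, jj
            dp[i, j] = best
            bi[i, j] = pi
            bj[i, j] = pj
    # close: remaining molecule labels are false; map tail free
    best_score = neg
    bi_end = -1
    bj_end = -1
    for i in range(n):
        for j in range(m):
            s = dp[i, j] - c_false * (n - 1 - i)
            if s > best_score:
                best_score = s
                bi_end, bj_end = i, j
    return dp, bi, bj, best_score, bi_end, bj_end


def _align_oriented(mol_labels: np.ndarray, cmap: LabelMap,
                    params: AlignParams):
    dp, bi, bj, score, ie, je = _dp_kernel(
        mol_labels, cmap.labels, params.c_match, params.c_miss,
        params.c_false, params.sigma_min, params.sigma_rel, params.max_step)
    pairs = []
    i, j = ie, je
    while i >= 0:
        pairs.append((int(i), int(j)))
        i, j = int(bi[i, j]), int(bj[i, j])
        if i < 0:
            break
    pairs.reverse()
    return float(score), pairs


def align_molecule(mol: Molecule | LabelMap, cmap: LabelMap,
                   params: AlignParams = AlignParams()) -> MapAlignment:
    """Best placement of a molecule on a consensus map, either orientation."""
    if cmap.n_labels < 2:
        raise ValueError(f"cmap {cmap.map_id!r} has < 2 labels")
    if mol.n_labels < params.min_mol_labels:
        raise ValueError(
            f"molecule {mol.map_id!r} has < {params.min_mol_labels} labels")
    fwd_score, fwd_pairs = _align_oriented(mol.labels, cmap, params)
    rev_labels = np.sort(mol.length - mol.labels)
    rev_score, rev_pairs = _align_oriented(rev_labels, cmap, params)

    if fwd_score >= rev_score:
        score, pairs, labels, orient = fwd_score, fwd_pairs, mol.labels, "+"
    else:
        score, pairs, labels, orient = rev_score, rev_pairs, rev_labels, "-"
    i0, j0 = pairs[0]
    i1, j1 = pairs[-1]
    span_start = cmap.labels[j0] - labels[i0]
    span_end = cmap.labels[j1] + (mol.length - labels[i1])
    return MapAlignment(mol.map_id, cmap.map_id, pairs, score,
                        float(span_start), float(span_end), orient)


@dataclass
class SupportCall:
    sample: str
    support: dict[str, int]              # candidate cmap_id -> molecule count
    spanning: dict[str, int] = field(default_factory=dict)
    genotype: tuple[str, ...] | str = NO_CALL
    n_molecules_used: int = 0


def count_support(molecules: list[Molecule],
                  candidate_cmaps: list[LabelMap],
                  critical_regions: dict[str, list[tuple[float, float]]],
                  params: AlignParams = AlignParams(),
                  sample: str = "") -> SupportCall:
    """Count molecules unambiguously supporting each candidate haplotype.

    A molecule supports candidate h iff its best alignment is to h, by a
    margin >= params.margin over the runner-up, and its footprint fully
    contains at least one critical region of h.  Ties support nothing.
    """
    for c in candidate_cmaps:
        if not critical_regions.get(c.map_id):
            raise ValueError(f"candidate {c.map_id!r} declares no critical region")
    support = {c.map_id: 0 for c in candidate_cmaps}
    spanning = {c.map_id: 0 for c in candidate_cmaps}
    used = 0
    for mol in molecules:
        if (mol.n_labels < params.min_mol_labels
                or mol.length < params.min_mol_length):
            continue
        used += 1
        alns = [align_molecule(mol, c, params) for c in candidate_cmaps]
        order = sorted(alns, key=lambda a: -a.score)
        best = order[0]
        spans = any(best.span_start <= s and e <= best.span_end
                    for s, e in critical_regions[best.cmap_id])
        if spans:
            spanning[best.cmap_id] += 1
        if len(order) > 1 and order[0].score - order[1].score < params.margin:
            continue
        if spans:
            support[best.cmap_id] += 1
    return SupportCall(sample, support, spanning, NO_CALL, used)


def genotype_sample(call_or_counts, min_support: int = 3):
    """Diploid genotype from supporting-molecule counts (n >= min_support).

    Returns NO_CALL when nothing passes, a 1- or 2-tuple of candidate ids
    otherwise, and MULTI when more than two candidates pass (flagged for
    review rather than force-called).
    """
    counts = (call_or_counts.support if isinstance(call_or_counts, SupportCall)
              else dict(call_or_counts))
    passing = sorted((h for h, n in counts.items() if n >= min_support),
                     key=lambda h: (-counts[h], h))
    if not passing:
        genotype = NO_CALL
    elif len(passing) > 2:
        genotype = MULTI
    else:
        genotype = tuple(passing)
    if isinstance(call_or_counts, SupportCall):
        call_or_counts.genotype = genotype
    return genotype
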