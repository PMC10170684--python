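"""Synthetic SD-locus generator with recorded ground truth.

Builds a 3q29-like locus from the segment grammar — three SD blocks over a
7-segment inventory (~26/5/11/4/33/15/124 kbp), paralog copies at ~98%
identity, a ~1.48-Mbp unique spacer — plus haplotype variants, NAHR
deletion/duplication chromosomes, noisy single molecules (target N50
300 kbp, label dropout, false labels, sizing error) and population cohorts
with trios.  Every simulated object carries its construction record, so all
downstream operations can be tested as parameter-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .breakpoints import TrioInput
from .catalog import HaplotypeRecord, classify_inversions
from .decompose import HaplotypeStructure, SegmentToken
from .locus import (GenomicInterval, LabelMap, Molecule, ReferenceLocusModel,
                    SegmentDef, digest_sequence, revcomp)

_BASES = np.array(list("ACGT"))

# population haplotype-frequency vectors over the default 8-haplotype
# catalogue; each population has one enriched haplotype, mirroring the
# strong population structure typical of SD haplotypes at such loci
DEFAULT_POPULATION_FREQS = {
    "AFR": [0.10, 0.25, 0.12, 0.10, 0.10, 0.11, 0.11, 0.11],
    "AMR": [0.18, 0.08, 0.14, 0.11, 0.13, 0.12, 0.12, 0.12],
    "EAS": [0.10, 0.05, 0.10, 0.05, 0.41, 0.10, 0.10, 0.09],
    "EUR": [0.12, 0.10, 0.12, 0.10, 0.10, 0.19, 0.14, 0.13],
    "SAS": [0.26, 0.08, 0.12, 0.10, 0.10, 0.12, 0.11, 0.11],
}

HAPLOTYPE_IDS = ["H1", "H2", "H3", "H4", "H5", "H6", "H7", "H8"]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    paralog_identity: float = 0.98       # pairwise identity between copies
    spacer_length: int = 1_480_000       # unique SDB-SDC spacer, bp
    molecule_n50: float = 300_000.0      # target molecule N50, bp
    molecule_min_length: float = 150_000.0
    label_dropout: float = 0.10          # i.i.d. per-label miss rate
    false_labels_per_100kb: float = 0.8  # Poisson rate of spurious labels
    sizing_cv: float = 0.03              # per-interval Gaussian sizing error
    coverage: float = 20.0               # per haplotype
    cohort_size: int = 161
    n_trios: int = 50
    population_freqs: dict = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_POPULATION_FREQS.items()})
    indel_rate: float = 0.0              # paralog divergence indel knob

    def __post_init__(self):
        for r in (self.paralog_identity, self.label_dropout, self.sizing_cv,
                  self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.molecule_n50 <= 0 or self.coverage < 0:
            raise ValueError("bad molecule_n50/coverage")
        for pop, v in self.population_freqs.items():
            if abs(sum(v) - 1.0) > 1e-6:
                raise ValueError(f"frequencies for {pop} do not sum to 1")


@dataclass(frozen=True)
class Part:
    name: str                    # "SDA.magenta", "gapB2", "spacer", ...
    seq: str
    segment_id: str | None = None
    orientation: str = "+"
    fraction: float = 1.0
    partial: bool = False

    def __len__(self):
        return len(self.seq)


# reference layout: (part name, length, segment id); gap lengths are chosen
# so the SDA-to-SDB inverted window of the H4 variant spans 289 kbp
_LAYOUT = [
    ("flank_prox", 50_000, None),
    ("SDA.magenta", 26_000, "magenta"),
    ("gapA1", 1_500, None),
    ("SDA.blue", 5_000, "blue"),
    ("gapA2", 1_000, None),
    ("SDA.yellow", 11_000, "yellow"),
    ("gapA3", 1_000, None),
    ("SDA.red", 4_000, "red"),
    ("gapA4", 2_000, None),
    ("SDA.maroon", 33_000, "maroon"),
    ("gapAB1", 37_000, None),
    ("green", 124_000, "green"),
    ("gapAB2", 51_000, None),
    ("SDB.magenta", 26_000, "magenta"),
    ("gapB1", 10_000, None),
    ("SDB.blue1", 5_000, "blue"),
    ("gapB2", 1_000, None),
    ("SDB.orange", 15_000, "orange"),
    ("gapB3", 3_000, None),
    ("SDB.yellow", 11_000, "yellow"),
    ("gapB4", 4_000, None),
    ("SDB.red", 4_000, "red"),
    ("gapB5", 10_000, None),
    ("SDB.blue2", 5_000, "blue"),
    ("gapB6", 80_000, None),
    ("spacer", None, None),              # length from config
    ("gapC0", 80_000, None),
    ("SDC.magenta", 26_000, "magenta"),
    ("gapC1", 10_500, None),
    ("SDC.blue", 5_000, "blue"),
    ("gapC2", 500, None),
    ("SDC.yellow", 11_000, "yellow"),
    ("flank_dist", 50_000, None),
]

_SEGMENT_LENGTHS = {"magenta": 26_000, "blue": 5_000, "yellow": 11_000,
                    "red": 4_000, "maroon": 33_000, "orange": 15_000,
                    "green": 124_000}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            indel_rate: float = 0.0) -> str:
    """i.i.d. substitutions at ``rate``; optional short indels."""
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    out = "".join(arr)
    if indel_rate > 0:
        pieces = []
        last = 0
        for i in np.flatnonzero(rng.random(len(out)) < indel_rate):
            pieces.append(out[last:i])
            if rng.random() < 0.5:
                pieces.append(_random_seq(rng, int(rng.integers(1, 4))))
                pieces.append(out[i])
            last = i + 1  # deletion of one base otherwise
        pieces.append(out[last:])
        out = "".join(pieces)
    return out


@dataclass
class SimulatedLocus:
    config: SimulationConfig
    model: ReferenceLocusModel
    parts: list[Part]                    # reference haplotype
    sequence: str
    canonical: dict[str, str]            # segment id -> canonical sequence

    def part(self, name: str) -> Part:
        for p in self.parts:
            if p.name == name:
                return p
        raise KeyError(name)

    def part_interval(self, name: str) -> GenomicInterval:
        pos = 0
        for p in self.parts:
            if p.name == name:
                return GenomicInterval("sim", pos, pos + len(p))
            pos += len(p)
        raise KeyError(name)


def simulate_locus(config: SimulationConfig) -> SimulatedLocus:
    """Deterministically build the reference locus from the segment grammar.

    Each segment has one canonical random sequence; every placed copy is
    independently mutated so that any two copies sit at the configured
    pairwise identity.  The 15-kbp segment is a truncated (partial) copy of
    the 26-kbp segment, and carries no label in expectation terms rarely —
    whether it does for a given seed is recorded by digestion, not assumed.
    """
    rng = np.random.default_rng(config.seed)
    canonical = {sid: _random_seq(rng, n) for sid, n in _SEGMENT_LENGTHS.items()
                 if sid != "orange"}
    per_copy_div = (1.0 - config.paralog_identity) / 2.0
    canonical["orange"] = canonical["magenta"][:_SEGMENT_LENGTHS["orange"]]

    parts: list[Part] = []
    for name, length, sid in _LAYOUT:
        if name == "spacer":
            parts.append(Part(name, _random_seq(rng, config.spacer_length)))
        elif sid is None:
            parts.append(Part(name, _random_seq(rng, length)))
        else:
            seq = _mutate(rng, canonical[sid], per_copy_div, config.indel_rate)
            partial = sid == "orange"
            frac = (_SEGMENT_LENGTHS["orange"] / _SEGMENT_LENGTHS["magenta"]
                    if partial else 1.0)
            parts.append(Part(name, seq, sid, "+", frac, partial))

    sequence = "".join(p.seq for p in parts)

    # model: copy intervals + SD-block critical regions (+-10 kbp envelopes)
    pos = 0
    copies: dict[str, list[GenomicInterval]] = {}
    block_span: dict[str, list[int]] = {}
    for p in parts:
        if p.segment_id is not None:
            copies.setdefault(p.segment_id, []).append(
                GenomicInterval("sim", pos, pos + len(p), "+"))
            block = p.name.split(".")[0] if "." in p.name else None
            if block:
                block_span.setdefault(block, [pos, pos + len(p)])
                block_span[block][0] = min(block_span[block][0], pos)
                block_span[block][1] = max(block_span[block][1], pos + len(p))
        pos += len(p)
    total = pos
    crit = {b: GenomicInterval("sim", max(0, lo - 10_000), hi + 10_000)
            for b, (lo, hi) in block_span.items()}
    segments = []
    for sid, ivs in copies.items():
        segments.append(SegmentDef(
            sid, _SEGMENT_LENGTHS[sid], ivs, canonical[sid],
            parent_segment="magenta" if sid == "orange" else None))
    model = ReferenceLocusModel(
        region=GenomicInterval("sim", 0, total),
        sd_blocks=crit, critical_regions=crit, segments=segments,
        unique_spacer=GenomicInterval("sim", crit["SDB"].end, crit["SDC"].start))
    return SimulatedLocus(config, model, parts, sequence, canonical)


# ---------------------------------------------------------------------------
# haplotype variants

def _edit_parts(parts: list[Part], *, remove: tuple[str, ...] = (),
                duplicate: tuple[str, ...] = (),
                invert: tuple[str, str] | None = None) -> list[Part]:
    out: list[Part] = []
    for p in parts:
        if p.name in remove:
            continue
        out.append(p)
        if p.name in duplicate:
            out.append(replace(p, name=p.name + ".dup"))
    if invert is not None:
        names = [p.name for p in out]
        i, j = names.index(invert[0]), names.index(invert[1])
        window = out[i:j + 1]
        flipped = [replace(p, seq=revcomp(p.seq),
                           orientation="-" if p.orientation == "+" else "+",
                           name=p.name + ".inv")
                   for p in reversed(window)]
        out = out[:i] + flipped + out[j + 1:]
    return out


_VARIANT_EDITS = {
    "H1": {},
    "H2": {"remove": ("SDA.maroon", "SDB.yellow", "SDB.red")},
    "H3": {"duplicate": ("SDA.magenta", "SDB.yellow", "SDB.red")},
    "H4": {"invert": ("SDA.yellow", "SDB.magenta")},   # the 289-kbp inversion
    "H5": {"remove": ("SDA.yellow", "SDA.red"), "duplicate": ("SDB.magenta",)},
    "H6": {"remove": ("SDA.blue", "SDA.yellow", "SDA.red")},
    "H7": {"duplicate": ("SDA.maroon",)},
    "H8": {"remove": ("SDB.magenta",)},
}


@dataclass
class SimulatedHaplotype:
    haplotype_id: str
    parts: list[Part]
    sequence: str = ""
    structure: HaplotypeStructure | None = None

    def __post_init__(self):
        if not self.sequence:
            self.sequence = "".join(p.seq for p in self.parts)
        if self.structure is None:
            self.structure = parts_structure(self.parts)

    def part_interval(self, name: str) -> GenomicInterval:
        pos = 0
        for p in self.parts:
            if p.name == name:
                return GenomicInterval(self.haplotype_id, pos, pos + len(p))
            pos += len(p)
        raise KeyError(name)

    def sd_window(self, pad: int = 40_000) -> tuple[int, int]:
        """Span from the haplotype start through the SDB block + pad."""
        pos = end = 0
        for p in self.parts:
            if p.name.startswith("SDB.") or ".inv" in p.name:
                end = max(end, pos + len(p))
            pos += len(p)
        return 0, min(end + pad, pos)


def parts_structure(parts: list[Part]) -> HaplotypeStructure:
    """Construction-record haplotype structure (the truth decomposition)."""
    tokens = []
    pos = 0
    for p in parts:
        if p.segment_id is not None:
            tokens.append(SegmentToken(
                p.segment_id, p.orientation,
                GenomicInterval("sim", pos, pos + len(p)),
                p.fraction, p.partial))
        pos += len(p)
    return HaplotypeStructure(tokens, pos, (True, True))


def default_haplotypes(locus: SimulatedLocus,
                       ids: list[str] | None = None) -> dict[str, SimulatedHaplotype]:
    out = {}
    for hid in (ids or HAPLOTYPE_IDS):
        parts = _edit_parts(locus.parts, **_VARIANT_EDITS[hid])
        out[hid] = SimulatedHaplotype(hid, parts)
    return out


def build_catalog(locus: SimulatedLocus,
                  haplotypes: dict[str, SimulatedHaplotype]) -> list[HaplotypeRecord]:
    records = []
    for hid, hap in haplotypes.items():
        inv = classify_inversions(hap.structure, locus.model)
        records.append(HaplotypeRecord(
            haplotype_id=hid, structure=hap.structure,
            size_bp=len(hap.sequence), inversion_types=frozenset(inv)))
    return records


def candidate_critical_regions(hap: SimulatedHaplotype,
                               prox_max_mid: float = 160_000.0,
                               dist_min_mid: float = 330_000.0,
                               margin: float = 10_000.0) -> list[tuple[float, float]]:
    """Critical regions of a candidate haplotype map.

    Two windows — the proximal (SDA-side) and distal (SDB-side) SD clusters —
    that a molecule must fully span for its alignment to count as support.
    Segment parts are clustered by their current position (robust to
    inversions that relocate segments), with the long single-copy segment in
    between belonging to neither.
    """
    spans = []
    pos = 0
    for p in hap.parts:
        if p.segment_id is not None:
            spans.append((pos, pos + len(p)))
        pos += len(p)
    prox = [s for s in spans if 0.5 * (s[0] + s[1]) < prox_max_mid]
    dist = [s for s in spans if 0.5 * (s[0] + s[1]) > dist_min_mid]
    out = []
    for cluster in (prox, dist):
        if cluster:
            out.append((max(0.0, min(s[0] for s in cluster) - margin),
                        max(s[1] for s in cluster) + margin))
    return out


def genotyping_inputs(haplotypes: dict[str, SimulatedHaplotype]):
    """Candidate label maps (SD-window digests) + critical-region sidecar."""
    cands = []
    crits = {}
    for hid, hap in haplotypes.items():
        lo, hi = hap.sd_window()
        cands.append(digest_sequence(hap.sequence[lo:hi], map_id=hid))
        crits[hid] = candidate_critical_regions(hap)
    return cands, crits


# ---------------------------------------------------------------------------
# NAHR events

@dataclass
class EventTruth:
    event_type: str
    proximal_part: str
    distal_part: str
    crossover_offset: int
    junction_pos: int                    # on the rearranged sequence
    size_bp: int


def simulate_nahr_event(hap: SimulatedHaplotype, proximal_part: str,
                        distal_part: str, crossover_offset: int,
                        event_type: str = "deletion"
                        ) -> tuple[SimulatedHaplotype, EventTruth]:
    """Join paralogous copies at a crossover offset.

    A deletion joins the proximal copy's prefix to the distal copy's suffix;
    a duplication is the reciprocal join.  The copies must be same-segment
    paralogs in the same orientation (the opposite-orientation template is
    an inversion, not handled here).
    """
    pp, dp = hap.part_interval(proximal_part), hap.part_interval(distal_part)
    p_part = next(p for p in hap.parts if p.name == proximal_part)
    d_part = next(p for p in hap.parts if p.name == distal_part)
    if p_part.segment_id != d_part.segment_id:
        raise ValueError("breakpoint parts are not paralogs of one segment")
    if p_part.orientation != d_part.orientation:
        raise ValueError("opposite-orientation copies: that template is an inversion")
    if not 0 <= crossover_offset < min(len(p_part), len(d_part)):
        raise ValueError("crossover offset outside the segment")
    seq = hap.sequence
    size = dp.start - pp.start
    if event_type == "deletion":
        new_seq = seq[:pp.start + crossover_offset] + seq[dp.start + crossover_offset:]
        junction = pp.start + crossover_offset
    else:
        new_seq = seq[:dp.start + crossover_offset] + seq[pp.start + crossover_offset:]
        junction = dp.start + crossover_offset

    # parts-level reconstruction for the structure record; the fused copy
    # carries the actual chimeric junction sequence
    names = [p.name for p in hap.parts]
    i, j = names.index(proximal_part), names.index(distal_part)
    if event_type == "deletion":
        fused = replace(p_part, name=f"{proximal_part}~{distal_part}",
                        seq=p_part.seq[:crossover_offset]
                        + d_part.seq[crossover_offset:])
        new_parts = hap.parts[:i] + [fused] + hap.parts[j + 1:]
    else:
        fused = replace(p_part, name=f"{distal_part}~{proximal_part}",
                        seq=d_part.seq[:crossover_offset]
                        + p_part.seq[crossover_offset:])
        new_parts = hap.parts[:j] + [fused] + hap.parts[i + 1:]
    new_hap = SimulatedHaplotype(f"{hap.haplotype_id}.{event_type}", new_parts)
    assert new_hap.sequence == new_seq
    return new_hap, EventTruth(event_type, proximal_part, distal_part,
                               crossover_offset, junction, size)


def rearranged_flanks(rearranged: SimulatedHaplotype) -> tuple[tuple, tuple]:
    """Token keys proximal/distal of the fused junction token (inclusive of
    the fused token on the proximal side)."""
    keys = rearranged.structure.keys()
    seg_parts = [p for p in rearranged.parts if p.segment_id is not None]
    fused_idx = next(i for i, p in enumerate(seg_parts) if "~" in p.name)
    return keys[:fused_idx + 1], keys[fused_idx + 1:]


# ---------------------------------------------------------------------------
# molecules

def _exp_scale_for_n50(floor: float, n50: float) -> float:
    """Scale of the shifted-exponential length model hitting a target N50
    (base-weighted median length)."""

    def frac_above(m):
        return (n50 + m) * math.exp(-(n50 - floor) / m) / (floor + m)

    lo, hi = 1e3, 5e6
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac_above(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_molecules(hap_seqs: dict[str, str], config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       sample: str = "") -> list[Molecule]:
    """Noisy single molecules from diploid haplotype sequences.

    Fragment lengths follow a floored exponential tuned to the target N50;
    labels are dropped i.i.d., spurious labels arrive as Poisson per 100 kbp,
    inter-label distances are jittered with Gaussian sizing error, and labels
    closer than the 500-bp optical resolution are merged.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    scale = _exp_scale_for_n50(config.molecule_min_length, config.molecule_n50)
    out: list[Molecule] = []
    k = 0
    for hid, seq in hap_seqs.items():
        digest = digest_sequence(seq).labels
        L = len(seq)
        target = config.coverage * L
        covered = 0.0
        while covered < target:
            frag_len = config.molecule_min_length + rng.exponential(scale)
            start = rng.uniform(-frag_len, L)
            lo, hi = max(0.0, start), min(L, start + frag_len)
            if hi - lo < 20_000:
                continue
            covered += hi - lo
            labels = digest[(digest >= lo) & (digest < hi)] - lo
            if config.label_dropout > 0 and labels.size:
                labels = labels[rng.random(labels.size) >= config.label_dropout]
            if config.sizing_cv > 0 and labels.size:
                gaps = np.diff(np.concatenate([[0.0], labels]))
                gaps = gaps * (1.0 + rng.normal(0.0, config.sizing_cv, gaps.size))
                labels = np.cumsum(np.abs(gaps))
            n_false = rng.poisson(config.false_labels_per_100kb * (hi - lo) / 1e5)
            if n_false:
                labels = np.concatenate([labels, rng.uniform(0, hi - lo, n_false)])
            labels = np.sort(labels)
            labels = labels[(labels >= 0) & (labels < hi - lo)]
            if labels.size:  # merge below optical resolution
                keep = np.concatenate([[True], np.diff(labels) > 500.0])
                labels = labels[keep]
            out.append(Molecule(
                map_id=f"{sample}:{hid}:mol{k}", length=int(hi - lo),
                labels=labels, source_sample=sample,
                origin_haplotype=hid, origin_offset=float(lo)))
            k += 1
    return out


# ---------------------------------------------------------------------------
# parameter-recovery experiments

def genotyping_recovery_experiment(seed: int, n_samples: int = 50,
                                   candidate_ids: tuple[str, ...] =
                                   ("H1", "H2", "H3", "H4", "H5"),
                                   min_support: int = 3) -> dict:
    """Diploid genotype recovery from noisy molecules with known truth.

    Draws diploid samples over the candidate haplotypes, simulates molecules
    at the configured coverage/noise, runs support counting + genotyping and
    scores calls against truth (a single passing haplotype is read as
    homozygous).  Also counts samples free of false support (>= min_support
    molecules for an absent haplotype).
    """
    from .support import MULTI, NO_CALL, count_support, genotype_sample

    cfg = SimulationConfig(seed=seed)
    locus = simulate_locus(cfg)
    haps = default_haplotypes(locus, list(candidate_ids))
    cands, crits = genotyping_inputs(haps)
    windows = {h: haps[h].sequence[slice(*haps[h].sd_window())]
               for h in candidate_ids}
    rng = np.random.default_rng(seed + 1)
    correct = 0
    clean = 0
    for s in range(n_samples):
        truth = sorted(rng.choice(list(candidate_ids), size=2))
        pool = {}
        for h in truth:
            pool[h] = windows[h]
        mols = simulate_molecules(pool, cfg, rng, sample=f"s{s}")
        if truth[0] == truth[1]:  # homozygote: coverage from one draw only
            mols = mols + simulate_molecules(pool, cfg, rng, sample=f"s{s}b")
        call = count_support(mols, cands, crits, sample=f"s{s}")
        g = genotype_sample(call, min_support)
        if g not in (NO_CALL, MULTI):
            called = sorted(g if len(g) == 2 else (g[0], g[0]))
            correct += called == truth
        clean += all(n < min_support for h, n in call.support.items()
                     if h not in truth)
    return {"n": n_samples, "accuracy": correct / n_samples,
            "clean_fraction": clean / n_samples, "n_clean": clean}


def trio_recovery_experiment(seed: int, n_trios: int = 50) -> dict:
    """Parent-of-origin recovery over simulated trios with known truth.

    An abstention (UNRESOLVED) counts as correct only when the parental
    genotypes are genuinely symmetric, i.e. no method could identify the
    origin parent; any other disagreement with truth is an error.
    """
    from .breakpoints import UNRESOLVED, parent_of_origin

    cfg = SimulationConfig(seed=seed)
    locus = simulate_locus(cfg)
    haps = default_haplotypes(locus)
    catalog = build_catalog(locus, haps)
    trios = simulate_trios(locus, haps, cfg, np.random.default_rng(seed + 1),
                           n_trios=n_trios)
    correct = resolved_correct = donors_correct = 0
    for t in trios:
        res = parent_of_origin(t.trio_input, catalog)
        if res.parent_of_origin == t.origin_parent:
            resolved_correct += 1
            correct += 1
            donors_correct += res.transmitting_parent_of_intact != t.origin_parent
        elif res.parent_of_origin == UNRESOLVED and t.ambiguous:
            correct += 1
    return {"n": n_trios, "accuracy": correct / n_trios,
            "resolved_correct": resolved_correct,
            "donor_consistent": donors_correct}


def crossover_recovery_experiment(seed: int, n_replicates: int = 500,
                                  n_psvs: int = 100,
                                  window: int = 50_000) -> dict:
    """Crossover-interval coverage and width over seeded replicates.

    PSV positions are uniform on the window; the true crossover is uniform
    between the first and last PSV; assignments are clean (no conversion
    tracts), so the recovered interval must always contain the truth and its
    mean width approaches twice the mean PSV gap (2/rho).
    """
    from .psv import PSV, refine_crossover

    rng = np.random.default_rng(seed)
    covered = 0
    widths = []
    for _ in range(n_replicates):
        pos = np.sort(rng.choice(window, size=n_psvs, replace=False))
        x = int(rng.integers(pos[1], pos[-2]))
        asg = ["P" if p < x else "D" for p in pos]
        iv = refine_crossover(asg, [PSV(int(p), "A", "C") for p in pos])
        covered += iv.start < x <= iv.end
        widths.append(iv.width)
    rho = n_psvs / window
    return {"n": n_replicates, "coverage": covered / n_replicates,
            "mean_width": float(np.mean(widths)),
            "expected_width": 2 / rho}


# ---------------------------------------------------------------------------
# cohorts and trios

@dataclass
class TrioTruth:
    family: str
    father: tuple[str, str]
    mother: tuple[str, str]
    origin_parent: str
    origin_haplotype: str
    intact_haplotype: str
    ambiguous: bool                      # no method could resolve this trio
    trio_input: TrioInput = None


def draw_cohort(config: SimulationConfig,
                rng: np.random.Generator | None = None):
    """Per-population diploid haplotype draws; returns a DataFrame of calls."""
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pops = list(config.population_freqs)
    base = config.cohort_size // len(pops)
    sizes = [base + (1 if i < config.cohort_size % len(pops) else 0)
             for i in range(len(pops))]
    rows = []
    for pop, n in zip(pops, sizes):
        freqs = np.asarray(config.population_freqs[pop])
        ids = np.asarray(HAPLOTYPE_IDS[:freqs.size])
        for s in range(n):
            h1, h2 = rng.choice(ids, size=2, p=freqs)
            rows.append({"sample": f"{pop}_{s:03d}", "population": pop,
                         "hap1": h1, "hap2": h2})
    return pd.DataFrame(rows)


def simulate_trios(locus: SimulatedLocus,
                   haplotypes: dict[str, SimulatedHaplotype],
                   config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   n_trios: int | None = None) -> list[TrioTruth]:
    """Trios with Mendelian transmission plus one NAHR deletion.

    The rearranged chromosome carries a Class-I- or Class-II-template
    deletion on one parental haplotype; the other parent donates the intact
    chromosome.  A trio is recorded ``ambiguous`` when the parental genotypes
    are symmetric (both parents carry the origin haplotype and the intact
    haplotype), in which case no method can identify the origin parent.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mean_freq = np.mean([config.population_freqs[p]
                         for p in config.population_freqs], axis=0)
    mean_freq = mean_freq / mean_freq.sum()
    ids = np.asarray(HAPLOTYPE_IDS[:mean_freq.size])
    out = []
    for t in range(n_trios if n_trios is not None else config.n_trios):
        father = tuple(rng.choice(ids, size=2, p=mean_freq))
        mother = tuple(rng.choice(ids, size=2, p=mean_freq))
        origin_parent = "father" if rng.random() < 0.5 else "mother"
        donor = "mother" if origin_parent == "father" else "father"
        origin_hap = (father if origin_parent == "father" else mother)[
            rng.integers(0, 2)]
        intact_hap = (mother if donor == "mother" else father)[rng.integers(0, 2)]

        proximal = "SDB.blue1" if rng.random() < 0.5 else "SDB.blue2"
        offset = int(rng.integers(500, 4_500))
        rearranged, _truth = simulate_nahr_event(
            haplotypes[origin_hap], proximal, "SDC.blue", offset, "deletion")
        prox_flank, dist_flank = rearranged_flanks(rearranged)

        other = mother if origin_parent == "father" else father
        ambiguous = (origin_hap in other) and (
            intact_hap in (father if origin_parent == "father" else mother))
        out.append(TrioTruth(
            family=f"T{t:03d}", father=father, mother=mother,
            origin_parent=origin_parent, origin_haplotype=origin_hap,
            intact_haplotype=intact_hap, ambiguous=ambiguous,
            trio_input=TrioInput(
                family=f"T{t:03d}", proband_intact=intact_hap,
                proband_prox_flank=prox_flank, proband_dist_flank=dist_flank,
                mother=mother, father=father)))
    return out
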