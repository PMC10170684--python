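"""Haplotype catalogue: naming, inversion typing and population statistics.

Haplotype identity is exact token-string equality (segment id, orientation,
partial flag): any structural difference defines a distinct haplotype.
Near-misses are reported NOVEL together with the nearest catalogued
structure by token edit distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import HaplotypeStructure
from .locus import ReferenceLocusModel

NOVEL = "NOVEL"


@dataclass
class HaplotypeRecord:
    haplotype_id: str
    structure: HaplotypeStructure | None
    size_bp: int
    inversion_types: frozenset[str] = frozenset()
    first_seen_sample: str = ""
    novel: bool = False
    token_keys: tuple = ()

    def __post_init__(self):
        if self.size_bp <= 0:
            raise ValueError("size_bp must be positive")
        if self.structure is not None and not self.token_keys:
            self.token_keys = self.structure.keys()
        self.inversion_types = frozenset(self.inversion_types)


@dataclass(frozen=True)
class MatchResult:
    haplotype_id: str            # catalogue id or NOVEL
    similarity: float            # 1 - token edit distance / max length
    nearest_id: str | None = None


def _token_edit_distance(a: tuple, b: tuple) -> int:
    """Levenshtein distance over token keys."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[n]


def _flip_keys(keys: tuple) -> tuple:
    return tuple((sid, "-" if o == "+" else "+", p) for sid, o, p in reversed(keys))


def match_structure(query: HaplotypeStructure,
                    catalog: list[HaplotypeRecord],
                    sizing_tol: float = 0.12) -> MatchResult:
    """Name a structure against the catalogue; NOVEL with nearest neighbour
    otherwise.  Both query orientations are tried, since assemblies are not
    strand-resolved."""
    if query.is_empty():
        raise ValueError("empty query structure")
    qk = query.keys()
    qk_rev = _flip_keys(qk)
    best: tuple[float, str] | None = None
    for rec in catalog:
        d = min(_token_edit_distance(qk, rec.token_keys),
                _token_edit_distance(qk_rev, rec.token_keys))
        sim = 1.0 - d / max(len(qk), len(rec.token_keys))
        if d == 0:
            return MatchResult(rec.haplotype_id, 1.0, rec.haplotype_id)
        if best is None or sim > best[0]:
            best = (sim, rec.haplotype_id)
    if best is None:
        return MatchResult(NOVEL, 0.0, None)
    return MatchResult(NOVEL, best[0], best[1])


def classify_inversions(structure: HaplotypeStructure,
                        model: ReferenceLocusModel) -> set[str]:
    """Type the inversions a structure carries.

    Type I: a maximal inverted run reaching from SDA to SDC, > 2 Mbp.
    Type II: an inverted run confined to the SDA-SDB side, 200-400 kbp
    (the recurrent 289-kbp inversion).
    Type III: an inverted duplication - a segment present beyond its
    reference copy count with at least one extra/inverted copy.

    Structure spans are assumed anchored in locus-model coordinates.  Typing
    is invariant under whole-structure reversal: of the two readings, the one
    whose token spans agree better with the model's copy layout is classified
    (assemblies are not strand-resolved, so a reversed reading is the same
    chromosome).
    """
    rev = structure.reversed()
    s = max((structure, rev), key=lambda x: _layout_agreement(x, model))
    return _classify_one(s, model)


def _layout_agreement(structure: HaplotypeStructure,
                      model: ReferenceLocusModel) -> int:
    """Number of tokens whose span overlaps a reference copy of their segment."""
    n = 0
    for t in structure.tokens:
        for sid, _i, iv in model.all_copies():
            if (sid == t.segment_id
                    and t.span_on_query.start < iv.end
                    and iv.start < t.span_on_query.end):
                n += 1
                break
    return n


def _classify_one(structure: HaplotypeStructure,
                  model: ReferenceLocusModel) -> set[str]:
    types: set[str] = set()
    sda = model.sd_blocks.get("SDA")
    sdb = model.sd_blocks.get("SDB")
    sdc = model.sd_blocks.get("SDC")

    runs = []
    cur: list = []
    for t in structure.tokens:
        if t.orientation == "-":
            cur.append(t)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)

    for run in runs:
        span_start = run[0].span_on_query.start
        span_end = run[-1].span_on_query.end
        span = span_end - span_start
        touches = {name for name, block in model.sd_blocks.items()
                   if span_start < block.end and block.start < span_end}
        if sda and sdc and {"SDA", "SDC"} <= touches and span > 2_000_000:
            types.add("I")
        if (sda and sdb and "SDC" not in touches
                and span_end <= (sdc.start if sdc else np.inf)
                and 200_000 <= span <= 400_000):
            types.add("II")

    ref_counts = model.copy_counts()
    for sid, n in structure.counts().items():
        if n > ref_counts.get(sid, 0):
            if any(t.orientation == "-" for t in structure.tokens
                   if t.segment_id == sid):
                types.add("III")
    return types


# ---------------------------------------------------------------------------
# population statistics

@dataclass
class PopulationTable:
    """Haplotype x population chromosome counts."""

    counts: pd.DataFrame  # rows = haplotype_id, columns = population

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def expected(self) -> pd.DataFrame:
        obs = self.counts.values.astype(float)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        return pd.DataFrame(row @ col / obs.sum(),
                            index=self.counts.index, columns=self.counts.columns)


@dataclass
class AssociationResult:
    p_values: pd.DataFrame          # per-cell two-sided Fisher p
    q_values: pd.DataFrame          # Benjamini-Hochberg across cells
    residuals: pd.DataFrame         # Pearson residuals (obs - exp)/sqrt(exp)
    overall_p: float                # fixed-margin Monte-Carlo r x c p-value
    n_permutations: int = 0


def fisher_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric)."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def population_association(table: PopulationTable, n_permutations: int = 2000,
                           seed: int = 0) -> AssociationResult:
    """Per-cell 2x2 Fisher exact tests + Pearson residuals + overall r x c p.

    Each (haplotype, population) cell is collapsed to a 2x2 table (in/out of
    haplotype x in/out of population) and tested two-sided.  The overall
    association p-value comes from Monte-Carlo sampling of fixed-margin
    tables, using the chi-square statistic.
    """
    obs = table.counts.values.astype(int)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table needs >= 2 rows and >= 2 columns")
    total = obs.sum()
    if total == 0:
        raise ValueError("zero grand total")
    exp = table.expected().values

    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(exp > 0, (obs - exp) / np.sqrt(exp), 0.0)

    pvals = np.ones_like(exp)
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            a = obs[i, j]
            b = obs[i].sum() - a
            c = obs[:, j].sum() - a
            d = total - a - b - c
            pvals[i, j] = fisher_2x2([[a, b], [c, d]])

    q = stats.false_discovery_control(pvals.ravel()).reshape(pvals.shape)

    chi2_obs = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    rng = np.random.default_rng(seed)
    dist = stats.random_table(obs.sum(axis=1), obs.sum(axis=0))
    samples = dist.rvs(n_permutations, random_state=rng)
    chi2_null = np.nansum(
        np.where(exp > 0, (samples - exp) ** 2 / exp, 0.0), axis=(1, 2))
    overall_p = (1 + np.sum(chi2_null >= chi2_obs - 1e-9)) / (1 + n_permutations)

    idx, cols = table.counts.index, table.counts.columns
    return AssociationResult(
        p_values=pd.DataFrame(pvals, index=idx, columns=cols),
        q_values=pd.DataFrame(q, index=idx, columns=cols),
        residuals=pd.DataFrame(resid, index=idx, columns=cols),
        overall_p=float(overall_p), n_permutations=n_permutations)


@dataclass
class CatalogSummary:
    frequencies: pd.Series          # percent of chromosomes per haplotype
    counts: pd.Series
    singletons: list[str]
    n_chromosomes: int
    inversion_carrier_fraction: float | None = None


def summarize_catalog(calls: list[str],
                      catalog: list[HaplotypeRecord] | None = None) -> CatalogSummary:
    """Frequencies (percent of chromosomes), singletons and, when the
    catalogue is supplied, the fraction of chromosomes carrying any
    inversion type."""
    s = pd.Series(calls, dtype="object")
    counts = s.value_counts()
    freqs = 100.0 * counts / len(s)
    singles = sorted(counts[counts == 1].index.tolist())
    inv_frac = None
    if catalog is not None:
        inv_ids = {r.haplotype_id for r in catalog if r.inversion_types}
        inv_frac = float(np.mean([c in inv_ids for c in calls]))
    return CatalogSummary(freqs, counts, singles, len(s), inv_frac)


# ---------------------------------------------------------------------------
# catalogue TSV round-trip

def write_catalog_tsv(catalog: list[HaplotypeRecord], path) -> None:
    rows = []
    for r in catalog:
        token_string = ",".join(
            f"{sid}{o}{'*' if p else ''}" for sid, o, p in r.token_keys)
        rows.append({"haplotype_id": r.haplotype_id, "token_string": token_string,
                     "size_bp": r.size_bp,
                     "inversion_types": ";".join(sorted(r.inversion_types))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> list[HaplotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"inversion_types": "string"})
    out = []
    for _, row in df.iterrows():
        keys = []
        for tok in str(row["token_string"]).split(","):
            partial = tok.endswith("*")
            tok = tok.rstrip("*")
            keys.append((tok[:-1], tok[-1], partial))
        inv = row.get("inversion_types")
        inv_set = frozenset() if pd.isna(inv) or not str(inv) else frozenset(
            str(inv).split(";"))
        out.append(HaplotypeRecord(
            haplotype_id=row["haplotype_id"], structure=None,
            size_bp=int(row["size_bp"]), inversion_types=inv_set,
            token_keys=tuple(keys)))
    return out
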