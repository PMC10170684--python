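# Methods

## The locus model and its coordinate conventions

A locus is a `ReferenceLocusModel`: an analysis region, named SD blocks with
their critical regions, and a list of segments, each with a canonical length
(and optionally sequence) plus its reference copies. All internal
coordinates are 0-based half-open; BED is native, while CMAP positions and
printed genome coordinates (1-based inclusive) are converted at the I/O
boundary. Label position is the first base of the motif occurrence — the
convention is arbitrary but fixed, and the DLE-1 motif CTTAAG is its own
reverse complement, so a single forward scan is strand-complete. N never
matches (conservative digestion).

The packaged 3q29 model stores published block/critical-region coordinates.
These are not mutually consistent: the printed analysis region ends ~0.5 Mbp
before the SDC critical region. The model keeps the union envelope of
region, critical regions and copies, and records the discrepancy as a flag
rather than erroring, since classification only needs the copies and
blocks. Per-segment copy coordinates are not published at base resolution;
the packaged BED is a synthetic reconstruction — copy counts, block
membership, and the positions of the recurrent-breakpoint cassettes are
faithful, exact coordinates are plausible placements within the published
block spans (stated in the file header).

## Sequence decomposition

Each root segment is seeded against the query with exact 16-mers (stride
k/3) on both strands; co-diagonal seeds are chained into candidate spans and
verified with edlib (infix mode). At 2% divergence a 16-mer is exact with
probability ≈ 0.72, so seeds are dense. Overlaps are resolved best-first:
higher identity, then longer hit, then leftmost — a deterministic
tie-break for the "best alignment" rule. Hits matching < 40% of the
canonical length are discarded; 40–80% are flagged partial. A partial hit is
renamed to a *derived* segment (declared via `parent_segment`) when its
matched length fits: this is how the 15-kbp cassette, a truncated copy of
the 26-kbp segment (fraction ≈ 0.58), gets its own name while keeping the
partial flag. `min_identity` defaults to 0.90 — segments are defined at
> 90% identity, and simulated paralogs sit near 98%.

## Label-map decomposition and label-blindness

Consensus maps are decomposed by greedy left-to-right matching of each
segment's inter-label distance signature, longest signature first, allowing
one label discrepancy per segment (a missing map label fuses two signature
intervals; an extra map label fuses two map intervals). Two design choices
differ from the obvious defaults and matter:

- **Detectability needs ≥ 4 labels (≥ 3 intervals).** One or two intervals
  carry no pattern: at label density ~0.24/kbp a 1–2-interval signature
  matches random unique sequence by chance many times across a 2-Mbp map.
  Short segments (the 5-kbp and 4-kbp cassettes, often the 11-kbp segment)
  are therefore reported `label_blind` rather than guessed — precisely why
  optical data alone cannot separate the two proximal breakpoint cassettes.
- **Sizing tolerance defaults to 4%**, appropriate for consensus-quality
  maps. Raising it toward single-molecule sizing error (~12%) re-admits
  chance matches; noisy molecules are handled by the DP aligner in the
  support module instead, which scores rather than thresholds.

## Molecule alignment and support

The DP aligns a molecule's labels to a candidate map: global on the
molecule, free end-gaps on the map, evaluated in both orientations. A
matched interval pays `((Δc−Δm)/σ)²` with `σ = max(500 bp, 0.03·Δc)`;
unmatched map labels inside the span pay `C_miss`, unmatched molecule
labels `C_false`; a match earns `C_match`. Defaults `C_match=3, C_miss=1,
C_false=1`, margin `δ=3`; at most 3 consecutive labels may be skipped or
merged between matched neighbours (optical resolution handling). The
scoring model is this package's definition — the published pipeline's
internals are not restated anywhere — so it is pinned by an exhaustive
enumeration oracle on small instances rather than by an external reference.
The kernel is numba-compiled; molecules with < 5 labels or < 150 kbp are
unassignable and skipped.

Support is deliberately conservative: a molecule supports candidate *h*
only if its best alignment is to *h* by ≥ δ over the runner-up *and* its
inferred footprint fully contains one of *h*'s critical regions; ties
support nothing. Genotypes are the top two candidates with ≥ 3 supporting
molecules (one → homozygous reading; more than two → MULTI, flagged for
review rather than force-called).

## Breakpoint localization and the five classes

Comparing the proband token string against the reference token string
yields one of three parsimony patterns: a *fused* token claimed by both the
reference prefix and suffix (NAHR through paralogous copies — the two host
copies are read off directly), a clean token gap (deleted copies plus
flanking uncertainty), or identical tokens with a span change (event wholly
in unique sequence; the uncertainty is the whole gap). When identical
cassettes in a row admit several junction placements, the prefix-maximal
one is taken; the alternatives differ by less than the cassette spacing, so
the size error stays below the breakpoint-interval width. Event size is the
start-to-start distance of the host copies, which for equal-length paralogs
equals the engineered paralog offset exactly.

Classes are context rules, not coordinates: deletion through the first
proximal-SDB cassette copy → I, through the second → II, no SD contact →
III; duplication through the Class-II cassettes → IV, wholly unique → V;
anything else UNCLASSIFIED. Published archetype coordinates are rounded to
0.01–0.1 Mbp, so fixture events carry an uncertainty interval of ± half the
printed precision; context is *any overlapping copy*, preferring a
paralogous proximal/distal pair (the NAHR prerequisite). When the proximal
interval also overlaps a truncated-paralog cassette the call is qualified
`cassette-level`. Mechanism from sequence: NAHR requires paralogous
same-orientation contexts at ≥ 98% identity; < 80% or unique contexts is
OTHER; between is AMBIGUOUS, reported not masked.

## Trio resolution

A parent can be the origin if one of their haplotypes (or a single
crossover between their two) explains both flanks of the rearranged
chromosome; the other parent must carry the proband's intact haplotype.
Exactly one consistent assignment → resolved; zero or two → UNRESOLVED.
The frequent genuinely symmetric case is intact haplotype = origin
haplotype (probability Σfₕ² ≈ 13% under the default frequencies): both
parents then carry the same haplotype and no structure-level method can
decide. Recovery experiments therefore score an abstention as correct only
when the simulated parental genotypes are verifiably symmetric; an
abstention on a resolvable trio, or any wrong call, is an error.

## PSV refinement

Paralog alignment uses edlib for speed with a normalization pass: edit
distance ties can scatter an indel run or trade substitutions for indel
pairs, so dirty windows of the path are locally re-aligned with affine gap
costs (match 2, mismatch −1, open −4, extend −0.5), which prefers
substitutions and consolidates runs. Substitution columns emit one PSV
each; an indel run collapses to one PSV at its start. The junction is
genotyped P/D/N through its alignment to the proximal copy; the crossover
is the minimal-conflict switch (ties leftmost) and the interval runs from
the last P before it to the first D after it, exclusive of both PSV sites.
With clean assignments this is the unique maximal P-prefix/D-suffix
boundary; its width is the PSV gap containing the crossover —
length-biased, hence expected width ≈ 2/ρ at PSV density ρ.

## Statistics

Per-cell association uses the two-sided Fisher exact test on the collapsed
2×2 table (in/out of haplotype × in/out of population), which is exactly
hypergeometric enumeration; Benjamini–Hochberg q-values are reported
alongside raw p (the per-cell tests are many). The overall r×c p-value is
Monte-Carlo: tables sampled from the fixed-margin null
(`scipy.stats.random_table`), chi-square statistic, `(1+#{T≥T_obs})/(1+N)`.
Pearson residuals (obs−exp)/√exp are the association-plot quantity and
conserve margins exactly.

## The synthetic generator: what it emulates, what it does not

The generator reproduces the study conditions at desk scale: the
seven-segment three-block layout with a 1.48-Mbp spacer (the two 80-kbp
unique shoulders flanking the spacer match the published block-to-cassette
distances, making SDA→SDC inverted spans exceed 2 Mbp as required for
Type I inversions); paralog copies independently mutated at (1−p)/2 so any
two copies sit at pairwise identity p = 0.98; molecules with floored
exponential lengths tuned to N50 300 kbp (floor 150 kbp), i.i.d. 10% label
dropout, Poisson false labels at 0.8/100 kbp, 3% per-interval Gaussian
sizing error, and sub-500-bp label merging. Coverage defaults to 20× per
haplotype — the full-study ~100× adds nothing at this locus size and keeps
the end-to-end suite within minutes; the cohort defaults to 161 samples
over five populations with one enriched haplotype each, and trio
simulations place Class-I/II-template deletions on one transmitted
haplotype.

Not emulated: chimeric molecules, fragile-site breakage, stretch-factor
miscalibration, assembly errors, or reference-bias effects. Passing
recovery tests therefore demonstrates the pipeline's correctness under the
declared noise model, not robustness to instrument artefacts beyond it.
The eight default haplotype variants are constructed so every pair differs
within both SD-block critical regions, which is what makes 20× genotyping
near-perfect; real cohorts contain closer haplotype pairs, and accuracy on
them is bounded by the critical-region design, not by this code path.

## Numerical and degenerate-input choices

Digestion is deterministic and strictly increasing by construction.
Decomposition tie-breaks are fixed (identity, length, leftmost). The DP is
deterministic given parameters; candidate ties yield no support. Empty
structures are valid decompositions (anchors-only); unanchored probands
yield UNRESOLVED events with a reason; all-P or all-D PSV windows raise
"no crossover in window". Monte-Carlo association p-values are seeded and
never exactly zero. Problem sizes in tests and the acceptance script (50
samples, 50 trios, 500 PSV replicates, 200 oracle instances) were chosen as
the smallest runs whose binomial noise stays well inside the asserted
margins.

## Known limitations

Catalogue identity is exact token-string equality: sub-segment variation
(SNVs, small indels) within a haplotype does not create a new haplotype.
Label-map decomposition is greedy and will not recover nested or
interleaved rearrangements of label-blind segments. The breakpoint
localizer explains a structure with at most one event; compound probands
are reported unreconcilable rather than decomposed. Trio resolution is
structure-level only — molecule-level phasing could resolve some
configurations reported UNRESOLVED here.
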