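"""Single-molecule DP alignment, support counting and diploid genotyping."""

import numpy as np
import pytest

from sdhap.locus import LabelMap, Molecule, digest_sequence
from sdhap.simulate import (SimulationConfig, default_haplotypes,
                            genotyping_inputs, simulate_locus,
                            simulate_molecules)
from sdhap.support import (MULTI, NO_CALL, AlignParams, align_molecule,
                           count_support, genotype_sample)

PARAMS = AlignParams()


def brute_force_score(mol: np.ndarray, cmap: np.ndarray,
                      p: AlignParams = PARAMS) -> float:
    """Exhaustive enumeration over monotone label matchings (the scoring
    model's step cap included); independent of the DP implementation."""
    n, m = len(mol), len(cmap)
    best = [-np.inf]

    def step_score(i0, j0, i1, j1):
        dc = cmap[j1] - cmap[j0]
        dm = mol[i1] - mol[i0]
        sigma = max(p.sigma_min, p.sigma_rel * dc)
        return (p.c_match - ((dc - dm) / sigma) ** 2
                - p.c_false * (i1 - i0 - 1) - p.c_miss * (j1 - j0 - 1))

    def extend(i, j, score):
        total = score - p.c_false * (n - 1 - i)
        if total > best[0]:
            best[0] = total
        for i2 in range(i + 1, min(i + p.max_step + 1, n)):
            for j2 in range(j + 1, min(j + p.max_step + 1, m)):
                extend(i2, j2, score + step_score(i, j, i2, j2))

    for i in range(n):
        for j in range(m):
            extend(i, j, p.c_match - p.c_false * i)
    return best[0]


def _mol(labels, length, mid="mol"):
    return Molecule(map_id=mid, length=length, labels=np.asarray(labels, float))


class TestAlignment:
    def test_perfect_submap_scores_match_times_labels(self):
        cmap = LabelMap("c", 200_000, np.arange(5_000, 195_000, 7_000.0))
        sub = cmap.labels[4:14] - 30_000.0
        aln = align_molecule(_mol(sub, 170_000), cmap)
        assert aln.score == pytest.approx(PARAMS.c_match * 10)
        assert len(aln.pairs) == 10
        assert aln.orientation == "+"

    def test_dp_equals_brute_force_on_random_instances(self, rng):
        for _ in range(60):
            m = rng.integers(5, 9)
            n = rng.integers(5, 13)
            mol = np.sort(rng.uniform(0, 120_000, m))
            cmap = np.sort(rng.uniform(0, 260_000, n))
            got = align_molecule(_mol(mol, 130_000),
                                 LabelMap("c", 270_000, cmap)).score
            fwd = brute_force_score(mol, cmap)
            rev = brute_force_score(np.sort(130_000 - mol), cmap)
            assert got == pytest.approx(max(fwd, rev), abs=1e-6)

    def test_orientation_symmetry(self, rng):
        cmap = LabelMap("c", 300_000, np.sort(rng.uniform(0, 300_000, 40)))
        labels = np.sort(rng.uniform(0, 150_000, 12))
        fwd = align_molecule(_mol(labels, 150_000), cmap)
        rev = align_molecule(_mol(np.sort(150_000 - labels), 150_000), cmap)
        assert fwd.score == pytest.approx(rev.score)
        assert {fwd.orientation, rev.orientation} == {"+", "-"}

    def test_input_validation(self):
        cmap = LabelMap("c", 10_000, np.array([1_000.0]))
        with pytest.raises(ValueError, match="< 2 labels"):
            align_molecule(_mol([1, 2, 3, 4, 5], 10_000), cmap)
        good = LabelMap("c", 10_000, np.array([1_000.0, 5_000.0]))
        with pytest.raises(ValueError, match="< 5"):
            align_molecule(_mol([1.0], 10_000), good)

    def test_true_haplotype_outscores_alternative(self):
        cfg = SimulationConfig(seed=5)
        loc = simulate_locus(cfg)
        haps = default_haplotypes(loc, ["H1", "H2"])  # differ by 33-kbp segment
        maps = {h: digest_sequence(v.sequence[slice(*v.sd_window())], map_id=h)
                for h, v in haps.items()}
        rng = np.random.default_rng(5)
        mols = simulate_molecules(
            {"H1": haps["H1"].sequence[slice(*haps["H1"].sd_window())]},
            cfg, rng, sample="x")
        informative = 0
        wins = 0
        sda_end = 150_000
        for mol in mols:
            if mol.n_labels < PARAMS.min_mol_labels:
                continue
            if not (mol.origin_offset < 30_000
                    and mol.origin_offset + mol.length > sda_end):
                continue  # must overlap the segment that distinguishes H1/H2
            informative += 1
            a = align_molecule(mol, maps["H1"], PARAMS)
            b = align_molecule(mol, maps["H2"], PARAMS)
            wins += a.score > b.score
        assert informative >= 3
        assert wins == informative


@pytest.fixture(scope="module")
def diploid_run():
    cfg = SimulationConfig(seed=9)
    loc = simulate_locus(cfg)
    haps = default_haplotypes(loc, ["H1", "H3", "H5"])
    cands, crits = genotyping_inputs(haps)
    rng = np.random.default_rng(9)
    mols = simulate_molecules(
        {h: haps[h].sequence[slice(*haps[h].sd_window())]
         for h in ("H3", "H5")}, cfg, rng, sample="s")
    return count_support(mols, cands, crits, sample="s")


class TestSupportCounting:
    def test_single_candidate_perfect_molecules(self):
        cmap = LabelMap("h", 400_000, np.arange(2_000, 398_000, 4_000.0))
        crits = {"h": [(50_000.0, 150_000.0)]}
        mols = [Molecule(map_id=f"m{i}", length=200_000,
                         labels=cmap.labels[(cmap.labels >= s)
                                            & (cmap.labels < s + 200_000)] - s)
                for i, s in enumerate((0.0, 20_000.0, 40_000.0))]
        call = count_support(mols, [cmap], crits)
        assert call.support["h"] == 3

    def test_molecule_spanning_half_the_region_contributes_nothing(self):
        rng = np.random.default_rng(4)
        cmap = LabelMap("h", 400_000, np.sort(rng.uniform(0, 400_000, 90)))
        crits = {"h": [(50_000.0, 150_000.0)]}
        labels = cmap.labels[(cmap.labels >= 100_000) & (cmap.labels < 260_000)]
        mol = Molecule(map_id="m", length=160_000, labels=labels - 100_000)
        call = count_support([mol], [cmap], crits)
        assert call.support["h"] == 0
        assert call.spanning["h"] == 0

    def test_diploid_true_haplotypes_supported_decoy_not(self, diploid_run):
        assert diploid_run.support["H3"] >= 3
        assert diploid_run.support["H5"] >= 3
        assert diploid_run.support["H1"] <= 1

    def test_candidate_without_critical_region_rejected(self):
        cmap = LabelMap("h", 10_000, np.array([1_000.0, 2_000.0]))
        with pytest.raises(ValueError, match="critical region"):
            count_support([], [cmap], {})

    def test_support_monotone_in_coverage(self):
        cfg_lo = SimulationConfig(seed=11, coverage=10.0)
        cfg_hi = SimulationConfig(seed=11, coverage=20.0)
        loc = simulate_locus(SimulationConfig(seed=11))
        haps = default_haplotypes(loc, ["H1", "H2"])
        cands, crits = genotyping_inputs(haps)
        win = haps["H1"].sequence[slice(*haps["H1"].sd_window())]
        mols_lo = simulate_molecules({"H1": win}, cfg_lo,
                                     np.random.default_rng(11))
        mols_hi = simulate_molecules({"H1": win}, cfg_hi,
                                     np.random.default_rng(11))
        # same seed composition: the low-coverage draw is a prefix
        assert [m.map_id for m in mols_hi[:len(mols_lo)]] == \
               [m.map_id for m in mols_lo]
        lo = count_support(mols_lo, cands, crits).support["H1"]
        hi = count_support(mols_hi, cands, crits).support["H1"]
        assert hi >= lo


class TestGenotyping:
    @pytest.mark.parametrize("counts,expected", [
        ({"H3": 12, "H5": 9, "H1": 1}, ("H3", "H5")),
        ({"H3": 2}, NO_CALL),
        ({"H3": 7}, ("H3",)),
        ({"H1": 5, "H2": 4, "H3": 3}, MULTI),
    ])
    def test_thresholding(self, counts, expected):
        assert genotype_sample(counts, min_support=3) == expected
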