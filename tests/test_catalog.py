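"""Haplotype naming, inversion typing and population statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdhap.catalog import (NOVEL, HaplotypeRecord, PopulationTable,
                           classify_inversions, fisher_2x2, match_structure,
                           population_association, read_catalog_tsv,
                           summarize_catalog, write_catalog_tsv)
from sdhap.simulate import SimulatedHaplotype, _edit_parts


def _fisher_oracle(table: np.ndarray) -> float:
    """Independent two-sided Fisher p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row = a + b
    col = a + c
    rv = stats.hypergeom(n, row, col)
    support = range(max(0, row + col - n), min(row, col) + 1)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-9)))


class TestMatching:
    def test_identity_and_empty_catalog(self, sim_catalog, sim_haplotypes):
        q = sim_haplotypes["H3"].structure
        res = match_structure(q, sim_catalog)
        assert res.haplotype_id == "H3" and res.similarity == 1.0
        assert match_structure(q, []).haplotype_id == NOVEL

    def test_insertion_then_matching_round_trips(self, sim_catalog, sim_haplotypes):
        for hid, hap in sim_haplotypes.items():
            assert match_structure(hap.structure, sim_catalog).haplotype_id == hid

    def test_reversed_query_still_matches(self, sim_catalog, sim_haplotypes):
        q = sim_haplotypes["H2"].structure.reversed()
        assert match_structure(q, sim_catalog).haplotype_id == "H2"

    def test_novel_reports_nearest_neighbour(self, sim_catalog, sim_haplotypes):
        st = sim_haplotypes["H1"].structure
        trimmed = type(st)(st.tokens[:-1], st.total_span, st.anchors)
        res = match_structure(trimmed, sim_catalog)
        assert res.haplotype_id == NOVEL
        assert res.nearest_id == "H1"
        assert 0 < res.similarity < 1

    def test_empty_query_is_an_error(self, sim_catalog):
        from sdhap.decompose import HaplotypeStructure
        with pytest.raises(ValueError):
            match_structure(HaplotypeStructure([], 1000), sim_catalog)


class TestInversionTyping:
    def test_all_forward_structure_has_no_inversions(self, sim_locus, sim_haplotypes):
        assert classify_inversions(sim_haplotypes["H1"].structure,
                                   sim_locus.model) == set()

    def test_289kb_inversion_between_sda_and_sdb_is_type_ii(
            self, sim_locus, sim_haplotypes):
        assert classify_inversions(sim_haplotypes["H4"].structure,
                                   sim_locus.model) == {"II"}

    def test_sda_to_sdc_inversion_over_2mbp_is_type_i(self, sim_locus):
        inv1 = SimulatedHaplotype(
            "INV1", _edit_parts(sim_locus.parts, invert=("SDA.blue", "SDC.blue")))
        assert "I" in classify_inversions(inv1.structure, sim_locus.model)

    def test_inverted_duplication_is_type_iii(self, sim_locus):
        parts = _edit_parts(sim_locus.parts, duplicate=("SDA.maroon",))
        flip = _edit_parts(parts, invert=("SDA.maroon.dup", "SDA.maroon.dup"))
        hap = SimulatedHaplotype("invdup", flip)
        assert "III" in classify_inversions(hap.structure, sim_locus.model)

    def test_typing_invariant_under_whole_structure_reversal(
            self, sim_locus, sim_haplotypes):
        for hid in ("H1", "H4"):
            st = sim_haplotypes[hid].structure
            assert classify_inversions(st, sim_locus.model) == \
                classify_inversions(st.reversed(), sim_locus.model)


class TestFisher:
    def test_printed_2x2_example(self):
        assert fisher_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)

    def test_agrees_with_enumeration_on_all_small_tables(self):
        # every 2x2 table with grand total <= 30 (margins >= 1)
        checked = 0
        for n in range(4, 31, 2):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0 or (a + b) == 0 or (c + d) == 0 or (a + c) == 0 \
                        or (b + d) == 0:
                    continue
                t = np.array([[a, b], [c, d]])
                assert fisher_2x2(t) == pytest.approx(_fisher_oracle(t), abs=1e-9)
                checked += 1
        assert checked > 1000


class TestAssociation:
    def test_null_table_has_zero_residuals(self):
        counts = pd.DataFrame(np.full((3, 5), 4),
                              index=list("abc"), columns=list("vwxyz"))
        res = population_association(PopulationTable(counts), n_permutations=200)
        assert np.allclose(res.residuals.values, 0.0)
        assert res.overall_p > 0.5

    def test_residual_margins_sum_to_zero(self, rng):
        counts = pd.DataFrame(rng.integers(0, 20, (6, 5)).astype(int))
        counts.iloc[0, 0] += 5
        table = PopulationTable(counts)
        diff = counts.values - table.expected().values
        assert np.allclose(diff.sum(axis=0), 0.0)
        assert np.allclose(diff.sum(axis=1), 0.0)

    def test_enriched_cell_is_detected(self, rng):
        counts = pd.DataFrame(np.full((4, 5), 6))
        counts.iloc[1, 2] = 40    # strong enrichment
        res = population_association(PopulationTable(counts),
                                     n_permutations=500, seed=3)
        assert res.p_values.iloc[1, 2] < 0.001
        assert res.residuals.iloc[1, 2] > 2
        assert res.overall_p < 0.01

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            population_association(PopulationTable(pd.DataFrame([[1, 2]])))
        with pytest.raises(ValueError):
            population_association(
                PopulationTable(pd.DataFrame(np.zeros((2, 2), dtype=int))))


class TestSummaries:
    def test_small_call_list_arithmetic(self):
        s = summarize_catalog(["H1", "H1", "H2"])
        assert s.frequencies["H1"] == pytest.approx(200 / 3)
        assert s.frequencies["H2"] == pytest.approx(100 / 3)
        assert s.singletons == ["H2"]
        assert s.n_chromosomes == 3

    def test_reconstructed_cohort_headline_tallies(self):
        from sdhap.fixtures import reference_cohort_calls
        calls = reference_cohort_calls()["haplotype_id"].tolist()
        s = summarize_catalog(calls)
        assert s.n_chromosomes == 322
        assert s.frequencies["H3"] == pytest.approx(14.91, abs=0.01)
        assert s.frequencies["H1"] == pytest.approx(14.29, abs=0.01)
        assert s.frequencies["H2"] == pytest.approx(12.42, abs=0.01)
        assert len(s.singletons) == 14
        assert len(s.counts) == 33

    def test_sampled_cohort_frequencies_within_3_sigma(self, rng):
        freqs = {"H1": 0.5, "H2": 0.3, "H3": 0.2}
        n = 322
        draws = rng.choice(list(freqs), size=n, p=list(freqs.values()))
        s = summarize_catalog(list(draws))
        for h, f in freqs.items():
            sigma = 100 * np.sqrt(f * (1 - f) / n)
            assert abs(s.frequencies.get(h, 0.0) - 100 * f) <= 3 * sigma

    def test_inversion_carrier_fraction_uses_catalog(self, sim_catalog):
        s = summarize_catalog(["H4", "H4", "H1", "H2"], sim_catalog)
        assert s.inversion_carrier_fraction == pytest.approx(0.5)


def test_catalog_tsv_round_trip(tmp_path, sim_catalog):
    path = tmp_path / "catalog.tsv"
    write_catalog_tsv(sim_catalog, path)
    back = read_catalog_tsv(path)
    assert [r.haplotype_id for r in back] == [r.haplotype_id for r in sim_catalog]
    for a, b in zip(sim_catalog, back):
        assert a.token_keys == b.token_keys
        assert a.inversion_types == b.inversion_types
        assert a.size_bp == b.size_bp
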