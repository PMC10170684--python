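"""Breakpoint localization, class assignment, mechanism and trios."""

import numpy as np
import pytest

from sdhap.breakpoints import (AMBIGUOUS, NAHR, OTHER, UNRESOLVED, TrioInput,
                               classify_event, event_from_coords,
                               infer_mechanism, localize_breakpoints,
                               parent_of_origin)
from sdhap.simulate import (SimulatedHaplotype, _edit_parts, _mutate,
                            _random_seq, rearranged_flanks,
                            simulate_nahr_event, simulate_trios,
                            SimulationConfig)


@pytest.fixture(scope="module")
def h1(sim_haplotypes):
    return sim_haplotypes["H1"]


class TestLocalization:
    def test_reference_structure_yields_no_event(self, sim_locus):
        from sdhap.simulate import parts_structure
        st = parts_structure(sim_locus.parts)
        assert localize_breakpoints(st, sim_locus.model) is None

    def test_engineered_class_ii_size_recovered_exactly(self, sim_locus, h1):
        re_, truth = simulate_nahr_event(h1, "SDB.blue2", "SDC.blue",
                                         1_234, "deletion")
        ev = localize_breakpoints(re_.structure, sim_locus.model)
        assert ev.event_type == "deletion"
        assert ev.size_bp == truth.size_bp

    def test_unanchored_structure_unresolved(self, sim_locus, h1):
        st = h1.structure
        st2 = type(st)(st.tokens, st.total_span, anchors=(True, False))
        ev = localize_breakpoints(st2, sim_locus.model)
        assert not ev.resolved and "anchored" in ev.reason

    def test_unique_spacer_deletion_localizes_to_unique_context(self, sim_locus):
        # remove 400 kbp from the middle of the spacer
        parts = []
        for p in sim_locus.parts:
            if p.name == "spacer":
                parts.append(type(p)(p.name, p.seq[:500_000] + p.seq[900_000:]))
            else:
                parts.append(p)
        hap = SimulatedHaplotype("spacer_del", parts)
        ev = localize_breakpoints(hap.structure, sim_locus.model)
        assert ev.event_type == "deletion"
        assert ev.size_bp == pytest.approx(400_000, abs=1)
        call = classify_event(ev, sim_locus.model)
        assert call.proximal_context == ["unique"]
        assert call.class_label == "III"


class TestClassification:
    @pytest.mark.parametrize("prox,dist,etype,unc,expected", [
        (195.94e6, 197.64e6, "deletion", 5e3, "I"),
        (195.99e6, 197.64e6, "deletion", 5e3, "II"),
        (196.01e6, 197.30e6, "deletion", 5e3, "III"),
        (196.00e6, 197.60e6, "duplication", 50e3, "IV"),
        (196.25e6, 197.20e6, "duplication", 5e3, "V"),
    ])
    def test_printed_class_coordinates_on_packaged_model(
            self, grch38_model, prox, dist, etype, unc, expected):
        ev = event_from_coords(prox, dist, etype, uncertainty=unc)
        call = classify_event(ev, grch38_model)
        assert call.class_label == expected
        if expected in ("I", "II", "IV"):
            assert call.mechanism == NAHR
        else:
            assert call.mechanism == OTHER

    def test_class_i_carries_cassette_level_qualifier(self, grch38_model):
        # the 15-kbp truncated-paralog cassette abuts the first 5-kbp copy,
        # so breakpoint resolution is cassette-level only
        ev = event_from_coords(195.94e6, 197.64e6, "deletion", uncertainty=5e3)
        assert classify_event(ev, grch38_model).confidence == "cassette-level"

    def test_simulated_templates_classify_i_ii_iv(self, sim_locus, h1):
        for prox, etype, expected in [("SDB.blue1", "deletion", "I"),
                                      ("SDB.blue2", "deletion", "II"),
                                      ("SDB.blue2", "duplication", "IV")]:
            re_, _ = simulate_nahr_event(h1, prox, "SDC.blue", 2_000, etype)
            ev = localize_breakpoints(re_.structure, sim_locus.model)
            assert classify_event(ev, sim_locus.model).class_label == expected

    def test_reciprocal_duplication_of_class_ii_is_class_iv(self, sim_locus, h1):
        del_, _ = simulate_nahr_event(h1, "SDB.blue2", "SDC.blue", 900, "deletion")
        dup_, _ = simulate_nahr_event(h1, "SDB.blue2", "SDC.blue", 900, "duplication")
        cd = classify_event(localize_breakpoints(del_.structure, sim_locus.model),
                            sim_locus.model)
        cu = classify_event(localize_breakpoints(dup_.structure, sim_locus.model),
                            sim_locus.model)
        assert (cd.class_label, cu.class_label) == ("II", "IV")

    def test_every_resolved_event_gets_exactly_one_label(self, sim_locus, h1):
        labels = set()
        for prox, etype in [("SDB.blue1", "deletion"), ("SDB.blue2", "deletion"),
                            ("SDB.blue2", "duplication")]:
            re_, _ = simulate_nahr_event(h1, prox, "SDC.blue", 100, etype)
            ev = localize_breakpoints(re_.structure, sim_locus.model)
            call = classify_event(ev, sim_locus.model)
            assert call.class_label in {"I", "II", "III", "IV", "V", "UNCLASSIFIED"}
            labels.add(call.class_label)
        assert labels == {"I", "II", "IV"}


class TestMechanism:
    def test_engineered_identity_bands(self, sim_locus, h1, rng):
        re_, _ = simulate_nahr_event(h1, "SDB.blue2", "SDC.blue", 500, "deletion")
        ev = localize_breakpoints(re_.structure, sim_locus.model)
        call = classify_event(ev, sim_locus.model)
        base = _random_seq(rng, 10_000)

        high = infer_mechanism(call, base, _mutate(np.random.default_rng(1), base, 0.015 / 2))
        assert high.mechanism == NAHR and high.identity_at_breakpoints >= 0.98

        mid = infer_mechanism(call, base, _mutate(np.random.default_rng(2), base, 0.10 / 2 * 2))
        assert mid.mechanism == AMBIGUOUS

    def test_unique_context_low_identity_is_other(self, sim_locus, rng):
        parts = []
        for p in sim_locus.parts:
            if p.name == "spacer":
                parts.append(type(p)(p.name, p.seq[:200_000] + p.seq[700_000:]))
            else:
                parts.append(p)
        ev = localize_breakpoints(SimulatedHaplotype("d", parts).structure,
                                  sim_locus.model)
        call = classify_event(ev, sim_locus.model)
        a, b = _random_seq(rng, 5_000), _random_seq(rng, 5_000)
        call = infer_mechanism(call, a, b)
        assert call.mechanism == OTHER
        assert call.identity_at_breakpoints < 0.80

    def test_missing_sequence_falls_back_to_context(self, sim_locus, h1):
        re_, _ = simulate_nahr_event(h1, "SDB.blue1", "SDC.blue", 0, "deletion")
        ev = localize_breakpoints(re_.structure, sim_locus.model)
        call = infer_mechanism(classify_event(ev, sim_locus.model), None, None)
        assert call.mechanism == NAHR and call.low_confidence


class TestTrios:
    def test_family15_like_trio_resolves_to_father(self, sim_haplotypes,
                                                   sim_catalog):
        # father H6/H2, mother H6/H4, proband: deletion on H6 + intact H4
        re_, _ = simulate_nahr_event(sim_haplotypes["H6"], "SDB.blue2",
                                     "SDC.blue", 1_500, "deletion")
        prox, dist = rearranged_flanks(re_)
        trio = TrioInput("F15", "H4", prox, dist,
                         mother=("H6", "H4"), father=("H6", "H2"))
        res = parent_of_origin(trio, sim_catalog)
        assert res.parent_of_origin == "father"
        assert res.origin_haplotype == "H6"
        assert res.intact_haplotype == "H4"
        assert res.transmitting_parent_of_intact == "mother"

    def test_symmetric_parents_are_unresolved(self, sim_haplotypes, sim_catalog):
        re_, _ = simulate_nahr_event(sim_haplotypes["H1"], "SDB.blue2",
                                     "SDC.blue", 1_500, "deletion")
        prox, dist = rearranged_flanks(re_)
        trio = TrioInput("amb", "H2", prox, dist,
                         mother=("H1", "H2"), father=("H1", "H2"))
        assert parent_of_origin(trio, sim_catalog).parent_of_origin == UNRESOLVED

    def test_missing_parent_partial_inference(self, sim_haplotypes, sim_catalog):
        re_, _ = simulate_nahr_event(sim_haplotypes["H1"], "SDB.blue1",
                                     "SDC.blue", 700, "deletion")
        prox, dist = rearranged_flanks(re_)
        trio = TrioInput("single", "H2", prox, dist,
                         mother=None, father=("H1", "H3"))
        res = parent_of_origin(trio, sim_catalog)
        assert res.parent_of_origin == "father"
        assert res.reason == "single-parent inference"
        trio2 = TrioInput("none", "H2", prox, dist, mother=None, father=None)
        assert parent_of_origin(trio2, sim_catalog).parent_of_origin == UNRESOLVED

    def test_recovery_over_simulated_trios(self, sim_locus, sim_haplotypes,
                                           sim_catalog):
        cfg = SimulationConfig(seed=21)
        trios = simulate_trios(sim_locus, sim_haplotypes, cfg,
                               np.random.default_rng(21), n_trios=50)
        correct = 0
        for t in trios:
            res = parent_of_origin(t.trio_input, sim_catalog)
            if res.parent_of_origin == t.origin_parent:
                assert res.origin_haplotype == t.origin_haplotype
                assert res.transmitting_parent_of_intact != t.origin_parent
                correct += 1
            else:
                # abstention is only acceptable when the trio is genuinely
                # symmetric (no method could resolve it)
                assert res.parent_of_origin == UNRESOLVED and t.ambiguous
                correct += 1
        assert correct / len(trios) >= 0.95

    def test_origin_chromosomes_without_inversions_never_flagged_as_carriers(
            self, sim_locus, sim_haplotypes, sim_catalog):
        freqs = {p: [0.15, 0.15, 0.20, 0.0, 0.15, 0.15, 0.10, 0.10]
                 for p in ("AFR", "AMR", "EAS", "EUR", "SAS")}
        cfg = SimulationConfig(seed=33, population_freqs=freqs)
        trios = simulate_trios(sim_locus, sim_haplotypes, cfg,
                               np.random.default_rng(33), n_trios=25)
        inv_ids = {r.haplotype_id for r in sim_catalog if r.inversion_types}
        for t in trios:
            assert t.origin_haplotype not in inv_ids
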