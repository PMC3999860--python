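"""Mechanistic generator: template choice, exposure geometry, deaminations."""

import math

import numpy as np
import pytest

from repairmut.reference import LesionSpec
from repairmut.simulate import (
    SimParams,
    event_substitutions,
    realize_clone,
    simulate_experiment,
    simulate_random_nick_event,
    simulate_repair_event,
    simulate_transfection,
)


def three_se(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


class TestRepairEvent:
    def test_tg_template_choice_sets_conversion_rate(self, reference, catalog, params):
        """T/G repair converts to T/A when the T strand is the template,
        ~25% of events under the default template-choice probability."""
        rng = np.random.default_rng(101)
        n = 10_000
        converted = sum(
            simulate_repair_event(catalog["TG_top"], params, rng, reference).fate
            == "converted"
            for _ in range(n)
        )
        assert converted / n == pytest.approx(0.25, abs=three_se(0.25, n))

    def test_restored_events_use_g_strand_template(self, reference, catalog, params):
        rng = np.random.default_rng(102)
        for _ in range(200):
            ev = simulate_repair_event(catalog["UG_top"], params, rng, reference)
            if ev.fate == "restored":
                assert ev.template_strand == "bottom"
            else:
                assert ev.template_strand == "top"

    @pytest.mark.parametrize("condition", ["UG_top", "TG_top", "UG_bottom", "SSB_near"])
    def test_deaminations_hit_template_c_inside_exposure(
        self, reference, catalog, params, condition
    ):
        rng = np.random.default_rng(103)
        n = reference.length
        for _ in range(500):
            ev = simulate_repair_event(
                catalog[condition], params, rng, reference, condition=condition
            )
            template = reference.strand_sequence(ev.template_strand)
            for pos, outcome in ev.deaminations:
                assert template[pos] == "C"
                assert outcome in ("T", "G", "A")
                assert ev.exposure_contains(pos, n)

    def test_ber_mmr_never_mutates_3prime_of_lesion(self, reference, catalog, params):
        """Resection runs 5' of the lesion on the lesion strand, so induced
        mutations never appear on its 3' side (unless resection wraps the
        whole plasmid, which the geometric length makes vanishingly rare)."""
        rng = np.random.default_rng(104)
        n = reference.length
        anchor = min(catalog["UG_top"].lesion_positions)
        for _ in range(2000):
            ev = simulate_repair_event(catalog["UG_top"], params, rng, reference)
            span = ev.exposure[1]
            for pos, _ref, _alt in event_substitutions(ev, reference):
                # physical position must be within [anchor-span, anchor)
                assert (anchor - 1 - pos) % n < span
                if span < n - 1:
                    assert not (0 < (pos - anchor) % n < n - span)

    def test_dloop_reaches_whole_episome(self, reference, catalog, params):
        rng = np.random.default_rng(105)
        anchor = min(catalog["TG_top"].lesion_positions)
        n = reference.length
        downstream = 0
        for _ in range(2000):
            ev = simulate_repair_event(catalog["TG_top"], params, rng, reference)
            assert ev.exposure == (0, n)
            for pos, _ref, _alt in event_substitutions(ev, reference):
                if 0 < (pos - anchor) % n < n // 2:
                    downstream += 1
        assert downstream > 0  # mutations do appear 3' of a T/G

    def test_zero_cluster_size_gives_bare_fate(self, reference, catalog):
        p = SimParams(seed=1, cluster_size_pmf={0: 1.0}, restore_prob={"UG": 1.0})
        rng = np.random.default_rng(106)
        ev = simulate_repair_event(catalog["UG_top"], p, rng, reference)
        assert ev.deaminations == ()
        clone = realize_clone(ev, reference, rng)
        b_start, b_end = reference.regions["barcode"]
        stripped = clone.sequence[:b_start] + clone.sequence[b_end:]
        ref_stripped = (
            reference.top_sequence[:b_start] + reference.top_sequence[b_end:]
        )
        assert stripped == ref_stripped  # restored fate: only the bar code differs
        assert clone.color == "blue"

    def test_ssb_and_none_rejections(self, reference, catalog, params):
        rng = np.random.default_rng(107)
        with pytest.raises(ValueError, match="random_nick"):
            simulate_repair_event(catalog["noMM"], params, rng, reference)


class TestRandomNick:
    def test_g_and_c_readout_balance(self, reference, params):
        """Random nicks on both strands give equal G and C readout mutations."""
        rng = np.random.default_rng(108)
        g = c = 0
        for _ in range(10_000):
            ev = simulate_random_nick_event(params, reference, rng)
            for _pos, ref_base, _alt in event_substitutions(ev, reference):
                if ref_base == "G":
                    g += 1
                elif ref_base == "C":
                    c += 1
        assert abs(g - c) <= 3 * math.sqrt(g + c)

    def test_strand_override_fixes_readout(self, reference, params):
        rng = np.random.default_rng(109)
        for _ in range(300):
            ev = simulate_random_nick_event(params, reference, rng, strand="top")
            for _pos, ref_base, _alt in event_substitutions(ev, reference):
                assert ref_base == "G"  # bottom-template C reads out as top G


class TestRealizeClone:
    def test_bottom_template_deamination_reads_as_top_g(
        self, reference, catalog, params
    ):
        rng = np.random.default_rng(110)
        while True:
            ev = simulate_repair_event(catalog["UG_top"], params, rng, reference)
            if ev.fate == "restored" and ev.deaminations:
                break
        clone = realize_clone(ev, reference, rng)
        n = reference.length
        for template_pos, outcome in ev.deaminations:
            top_pos = n - 1 - template_pos
            assert reference.top_sequence[top_pos] == "G"
            if outcome == "T":  # template C->T is a top-strand G->A transition
                assert clone.sequence[top_pos] == "A"

    def test_two_deaminations_make_a_cluster(self, reference, catalog, params):
        rng = np.random.default_rng(111)
        while True:
            ev = simulate_repair_event(catalog["UG_top"], params, rng, reference)
            if len(ev.deaminations) == 2:
                break
        clone = realize_clone(ev, reference, rng)
        diffs = [
            i
            for i, (a, b) in enumerate(zip(clone.sequence, reference.top_sequence))
            if a != b
        ]
        b_start, b_end = reference.regions["barcode"]
        diffs = [
            i for i in diffs
            if not (b_start <= i < b_end) and i not in ev.lesion.lesion_positions
        ]
        assert len(diffs) == 2


class TestTransfection:
    def test_zero_rate_gives_no_whites(self, reference, catalog):
        p = SimParams(seed=1, per_colony_mut_prob={"UG_top": 0.0})
        ds = simulate_transfection(
            "UG_top", 5000, catalog["UG_top"], reference, p,
            np.random.default_rng(112),
        )
        assert ds.transfections[0].n_white_undeleted == 0

    def test_frequency_recovery_ug_top(self, reference, catalog, params):
        """White-undeleted frequency matches the calibrated per-colony rate."""
        ds = simulate_transfection(
            "UG_top", 100_000, catalog["UG_top"], reference, params,
            np.random.default_rng(113),
        )
        t = ds.transfections[0]
        freq = t.n_white_undeleted / t.total_colonies
        assert freq == pytest.approx(0.00726, abs=three_se(0.00726, 100_000))
        assert t.n_blue + t.n_white == t.total_colonies
        assert all(c.color == "white" for c in ds.clones)

    def test_unknown_condition_lists_known(self, reference, catalog, params):
        with pytest.raises(ValueError, match="UG_top"):
            simulate_transfection(
                "mystery", 100, catalog["UG_top"], reference, params,
                np.random.default_rng(114),
            )

    def test_clone_classes_injected(self, reference, catalog, params):
        ds = simulate_transfection(
            "UG_top", 200_000, catalog["UG_top"], reference, params,
            np.random.default_rng(115),
        )
        classes = {c.clone_class for c in ds.clones}
        assert "ok" in classes and "small_indel" in classes and "deleted" in classes
        t = ds.transfections[0]
        assert t.n_white_deleted == sum(
            1 for c in ds.clones if c.clone_class == "deleted"
        )

    def test_same_seed_reproduces_dataset(self, reference, catalog):
        runs = []
        for _ in range(2):
            ds = simulate_experiment(
                ["UG_top", "noMM"],
                catalog,
                reference,
                SimParams(seed=7),
                n_transfections=2,
                n_colonies=5000,
            )
            runs.append(
                (
                    [(c.clone_id, c.sequence, c.barcode) for c in ds.clones],
                    [(t.transfection_id, t.n_white) for t in ds.transfections],
                    {cid: ev.deaminations for cid, ev in ds.events.items()},
                )
            )
        assert runs[0] == runs[1]


class TestParams:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SimParams(tg_template_choice=1.5)

    def test_pmf_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            SimParams(cluster_size_pmf={1: 0.5, 2: 0.4})
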