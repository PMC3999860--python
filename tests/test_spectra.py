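"""Spectrum, context and cluster summaries."""

import math

import numpy as np
import pytest

from repairmut.calling import MutationRecord, call_mutations
from repairmut.simulate import event_substitutions, simulate_repair_event
from repairmut.spectra import (
    cluster_partition,
    identity_fate_summary,
    kmer_context_spectrum,
    per_base_spectrum,
    trinucleotide_of_G,
)


def make_record(pos, ref, alt, c5="A", c3="A", clone="c1", lesion=False):
    return MutationRecord(clone, pos, ref, alt, "supf", c5, c3, lesion)


class TestPerBaseSpectrum:
    def test_fraction_example(self, reference):
        records = [
            make_record(10, "G", "A"),
            make_record(10, "G", "A", clone="c2"),
            make_record(12, "G", "T", clone="c3"),
        ]
        table = per_base_spectrum(records, reference)
        fractions = table.position_fractions()
        assert fractions[10] == pytest.approx(2 / 3)
        assert fractions[12] == pytest.approx(1 / 3)
        row10 = table.table.set_index("position").loc[10]
        assert row10.to_A == pytest.approx(2 / 3)
        assert row10.to_T == 0.0

    def test_single_position_fraction_one(self, reference):
        records = [make_record(10, "G", "A")] * 4
        table = per_base_spectrum(records, reference)
        assert table.position_fractions()[10] == pytest.approx(1.0)

    def test_lesion_sites_excluded(self, reference):
        records = [make_record(10, "G", "A"), make_record(11, "C", "T", lesion=True)]
        table = per_base_spectrum(records, reference)
        assert table.n_mutations == 1

    def test_zero_mutations_empty(self, reference):
        table = per_base_spectrum([], reference)
        assert table.n_mutations == 0 and table.table.empty

    def test_fractions_sum_to_one(self, small_dataset, reference, catalog):
        records = []
        for clone in small_dataset.clones:
            if clone.clone_class == "ok":
                records.extend(
                    call_mutations(clone.sequence, reference,
                                   catalog[clone.condition], clone.clone_id)
                )
        table = per_base_spectrum(records, reference)
        assert table.table.fraction.sum() == pytest.approx(1.0, abs=1e-9)
        # per-position alt-base split sums to that position's fraction
        split = table.table[["to_A", "to_C", "to_G", "to_T"]].sum(axis=1)
        assert np.allclose(split, table.table.fraction, atol=1e-12)


class TestIdentityFate:
    def test_single_mutation_is_hundred_percent(self):
        table = identity_fate_summary([make_record(5, "G", "T")])
        assert len(table) == 1
        assert table.iloc[0].percent == 100.0

    def test_modal_class_top_restored_is_g_to_a(self, reference, catalog, params):
        """Bottom-template TpC deamination makes G->A the modal outcome of
        top-strand lesions restored to C/G."""
        rng = np.random.default_rng(301)
        records = []
        for _ in range(3000):
            ev = simulate_repair_event(catalog["UG_top"], params, rng, reference)
            if ev.fate != "restored":
                continue
            for pos, ref, alt in event_substitutions(ev, reference):
                records.append(make_record(pos, ref, alt))
        table = identity_fate_summary(records)
        top = table.sort_values("percent", ascending=False).iloc[0]
        assert (top.ref, top.alt) == ("G", "A")

    def test_modal_class_bottom_restored_is_c_to_t(self, reference, catalog, params):
        rng = np.random.default_rng(302)
        records = []
        for _ in range(3000):
            ev = simulate_repair_event(catalog["UG_bottom"], params, rng, reference)
            if ev.fate != "restored":
                continue
            for pos, ref, alt in event_substitutions(ev, reference):
                records.append(make_record(pos, ref, alt))
        table = identity_fate_summary(records)
        top = table.sort_values("percent", ascending=False).iloc[0]
        assert (top.ref, top.alt) == ("C", "T")

    def test_percentages_sum_to_hundred_per_group(self):
        records = [make_record(1, "G", "A"), make_record(2, "G", "T"),
                   make_record(3, "C", "T")]
        table = identity_fate_summary(records)
        assert table.percent.sum() == pytest.approx(100.0)


class TestKmerContext:
    def test_dinucleotide_examples(self, reference):
        record = make_record(10, "G", "A", c5="T", c3="A")
        three = kmer_context_spectrum([record], reference, k=2, side="three_prime")
        five = kmer_context_spectrum([record], reference, k=2, side="five_prime")
        assert three.fractions == {"GA": 1.0}
        assert five.fractions == {"TG": 1.0}

    def test_identical_contexts_pool(self, reference):
        records = [make_record(10, "G", "A", c3="A"),
                   make_record(20, "G", "T", c3="A", clone="c2")]
        table = kmer_context_spectrum(records, reference, k=2, side="three_prime")
        assert table.fractions == {"GA": 1.0}
        assert table.n == 2

    def test_edge_mutations_excluded(self, reference):
        records = [make_record(0, "G", "A", c5=None, c3="A")]
        table = kmer_context_spectrum(records, reference, k=2, side="five_prime")
        assert table.n == 0

    def test_unsupported_k_rejected(self, reference):
        with pytest.raises(ValueError, match="unsupported k"):
            kmer_context_spectrum([], reference, k=4)

    def test_trinucleotide_of_g(self, reference):
        record = make_record(10, "G", "A", c5="A", c3="A")
        spectrum, background = trinucleotide_of_G([record], reference)
        assert spectrum.fractions == {"AGA": 1.0}
        assert all(k[1] == "G" for k in background.fractions)
        assert sum(background.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_preference_tracks_availability(self, reference, catalog):
        """With the TpC preference disabled, deaminated Cs are drawn
        uniformly from the exposed non-TpC pool, so the trinucleotide
        spectrum of mutated Gs tracks the direct count of available
        contexts (3 SE)."""
        from repairmut.simulate import SimParams, _candidates_in_exposure

        flat = SimParams(seed=1, p_five_prime_T=0.0)
        rng = np.random.default_rng(303)
        n = reference.length
        observed: dict[str, int] = {}
        expected: dict[str, float] = {}
        total = 0
        for _ in range(3000):
            ev = simulate_repair_event(catalog["UG_top"], flat, rng, reference)
            if ev.fate != "restored" or not ev.deaminations:
                continue
            template = reference.bottom_sequence
            cpos, is_tpc = _candidates_in_exposure(template, ev.exposure)
            pool = cpos[~is_tpc]
            if len(pool) == 0:
                continue

            def trinuc(template_pos):
                i = n - 1 - template_pos
                return reference.top_sequence[i - 1 : i + 2]

            k = len(ev.deaminations)
            avail: dict[str, int] = {}
            for p in pool:
                key = trinuc(int(p))
                avail[key] = avail.get(key, 0) + 1
            for key, count in avail.items():
                expected[key] = expected.get(key, 0.0) + k * count / len(pool)
            for p, _outcome in ev.deaminations:
                key = trinuc(p)
                observed[key] = observed.get(key, 0) + 1
                total += 1
        for key in ("AGT", "CGT", "GGT", "AGG", "CGG"):
            f_exp = expected.get(key, 0.0) / total
            f_obs = observed.get(key, 0) / total
            se = math.sqrt(max(f_exp * (1 - f_exp), 1e-9) / total)
            assert abs(f_obs - f_exp) <= 3 * se + 1e-9


class TestClusterPartition:
    def test_labels_and_fraction(self):
        by_clone = {
            "a": [make_record(1, "G", "A"), make_record(2, "G", "A")],
            "b": [make_record(3, "G", "A")],
            "c": [make_record(4, "G", "A")],
            "d": [make_record(5, "G", "A")],
        }
        part = cluster_partition(by_clone)
        assert part.labels["a"] == "clustered"
        assert part.labels["b"] == "unclustered"
        assert part.fraction_clustered == pytest.approx(0.25)

    def test_lesion_only_clone_not_labelled(self):
        by_clone = {"a": [make_record(1, "C", "T", lesion=True)]}
        part = cluster_partition(by_clone)
        assert part.labels == {}

    def test_partitioned_spectra_recombine_to_pooled(
        self, small_dataset, reference, catalog
    ):
        """Clustered + unclustered spectra, weighted by mutation counts,
        reproduce the pooled spectrum exactly."""
        by_clone = {}
        for clone in small_dataset.clones:
            if clone.clone_class != "ok" or clone.condition != "UG_top":
                continue
            by_clone[clone.clone_id] = call_mutations(
                clone.sequence, reference, catalog["UG_top"], clone.clone_id
            )
        part = cluster_partition(by_clone, regions=None)
        pooled_records = [m for recs in by_clone.values() for m in recs]
        split = {"clustered": [], "unclustered": []}
        for cid, records in by_clone.items():
            if cid in part.labels:
                split[part.labels[cid]].extend(records)
        pooled = per_base_spectrum(pooled_records, reference)
        parts = {k: per_base_spectrum(v, reference) for k, v in split.items()}
        total = pooled.n_mutations
        for pos, fraction in pooled.position_fractions().items():
            combined = sum(
                t.position_fractions().get(pos, 0.0) * t.n_mutations / total
                for t in parts.values()
            )
            assert combined == pytest.approx(fraction, abs=1e-12)

    def test_mostly_g_mutations_for_top_lesions(self, small_dataset, reference, catalog):
        refs = []
        for clone in small_dataset.clones:
            if clone.clone_class != "ok" or clone.condition != "UG_top":
                continue
            refs.extend(
                m.ref_base
                for m in call_mutations(clone.sequence, reference,
                                        catalog["UG_top"], clone.clone_id)
                if not m.is_lesion_site
            )
        assert refs.count("G") / len(refs) > 0.5
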