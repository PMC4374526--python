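"""Ground-truth generators."""

import numpy as np
import pytest

from genoscreen.effects import CdsModel
from genoscreen.hgvs import HgvsVariant, parse_hgvs_c
from genoscreen.synthetic import (
    ReferenceBundle,
    make_reference,
    mutate_protein,
    plant_mutations,
    simulate_depth,
    table_fixture_cds,
)
from genoscreen.triage import run_triage


class TestMakeReference:
    def test_cds_translates_to_99_aa(self):
        ref = make_reference(1, genome_length=10_000, cds_length=300, cds_start=2001)
        cds = ref.cds_model()
        assert len(cds.protein) == 99  # 300/3 - 1 (stop not counted)

    def test_deterministic(self):
        a = make_reference(123)
        b = make_reference(123)
        assert a.genome == b.genome

    def test_different_seeds_differ(self):
        assert make_reference(1).genome != make_reference(2).genome

    def test_non_codon_multiple_rejected(self):
        with pytest.raises(ValueError):
            make_reference(1, cds_length=301)

    def test_cds_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            make_reference(1, genome_length=1000, cds_length=300, cds_start=900)

    def test_cds_model_valid(self):
        # CdsModel constructor enforces ATG start / stop end / no internal stop
        ref = make_reference(99)
        assert isinstance(ref.cds_model(), CdsModel)

    def test_invalid_bundle_rejected(self):
        with pytest.raises(ValueError):
            ReferenceBundle("ACGT" * 100, cds_start=1, cds_length=7, upstream_len=0)


class TestTableFixture:
    def test_planted_codons(self, long_cds):
        assert len(long_cds.cds_seq) == 7146
        assert long_cds.cds_seq[1014] == "A"          # c.1015
        assert long_cds.cds_seq[3 * 1370: 3 * 1371] == "AAG"  # codon 1371
        assert long_cds.upstream_len >= 1954


class TestPlantMutations:
    def _specs(self, ref, n_strains, rng):
        specs, used = [], set()
        for _ in range(n_strains):
            while True:
                pos = int(rng.integers(4, ref.cds_length - 5))
                if pos not in used:
                    used.add(pos)
                    break
            base = ref.cds_seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            specs.append([HgvsVariant("substitution", pos, None, base, alt)])
        return specs

    def test_four_strains_one_private_each(self):
        ref = make_reference(3)
        rng = np.random.default_rng(0)
        truths = plant_mutations(ref, self._specs(ref, 4, rng), n_shared=10, n_noise=5, seed=1)
        surviving, _ = run_triage([t.call_set() for t in truths])
        for t, s in zip(truths, surviving):
            assert s.keys() == {r.key for r in t.private_records}
            assert len(s) == 1

    def test_shared_identical_across_strains(self):
        ref = make_reference(4)
        rng = np.random.default_rng(1)
        truths = plant_mutations(ref, self._specs(ref, 3, rng), n_shared=8, n_noise=2, seed=2)
        first = {r.key for r in truths[0].shared_parental_variants}
        for t in truths[1:]:
            assert {r.key for r in t.shared_parental_variants} == first

    def test_noise_only_filtered_sets_empty(self):
        ref = make_reference(5)
        truths = plant_mutations(ref, [[], []], n_shared=0, n_noise=5, seed=3)
        from genoscreen.triage import filter_calls

        for t in truths:
            assert len(filter_calls(t.call_set())) == 0

    def test_empty_spec_list_rejected(self):
        ref = make_reference(6)
        with pytest.raises(ValueError):
            plant_mutations(ref, [], seed=1)

    def test_spec_outside_cds_rejected(self):
        ref = make_reference(7)
        bad = HgvsVariant("substitution", 9999, None, "A", "T")
        with pytest.raises(ValueError):
            plant_mutations(ref, [[bad]], seed=1)

    def test_deletion_and_inversion_records(self):
        ref = make_reference(8)
        specs = [[parse_hgvs_c("c.10_16del")], [parse_hgvs_c("c.30_50inv")]]
        truths = plant_mutations(ref, specs, n_shared=5, n_noise=3, seed=4)
        surviving, _ = run_triage([t.call_set() for t in truths], cds=ref.cds_interval())
        for t, s in zip(truths, surviving):
            assert s.keys() == {r.key for r in t.private_records}
            assert all(r.coding for r in s.records)

    def test_truth_roundtrip_99_of_100_seeds(self):
        """Filtering + subtraction recovers exactly the planted privates in
        >= 99/100 seeded replicates (it is 100/100 by construction)."""
        n_ok = 0
        for seed in range(100):
            ref = make_reference(seed)
            rng = np.random.default_rng(seed)
            truths = plant_mutations(ref, self._specs(ref, 4, rng), seed=seed)
            surviving, _ = run_triage([t.call_set() for t in truths])
            if all(
                s.keys() == {r.key for r in t.private_records}
                for t, s in zip(truths, surviving)
            ):
                n_ok += 1
        assert n_ok >= 99


class TestSimulateDepth:
    def test_mean_within_clt_band(self):
        track = simulate_depth(1_000_000, [], 20.0, seed=1)
        # 3-sigma band for the mean of 1e6 Poisson(20) draws:
        # 3 * sqrt(20 / 1e6) = 0.0134 < 0.05
        assert abs(track.depths.mean() - 20) < 0.05

    def test_whole_genome_duplication_doubles_mean(self):
        track = simulate_depth(200_000, [(1, 200_000)], 20.0, seed=2)
        assert track.depths.mean() == pytest.approx(40, abs=0.3)

    def test_inside_vs_outside_factor_two(self):
        track = simulate_depth(400_000, [(100_001, 300_000)], 20.0, seed=3)
        inside = track.depths[100_000:300_000]
        outside = np.concatenate([track.depths[:100_000], track.depths[300_000:]])
        assert inside.mean() / outside.mean() == pytest.approx(2.0, abs=0.02)
        assert inside.var() / outside.var() == pytest.approx(2.0, abs=0.05)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            simulate_depth(1000, [], 0.0, seed=1)

    def test_overlapping_duplications_rejected(self):
        with pytest.raises(ValueError):
            simulate_depth(1000, [(10, 100), (50, 200)], 20.0, seed=1)

    def test_deterministic(self):
        a = simulate_depth(10_000, [(100, 200)], 17.0, seed=9)
        b = simulate_depth(10_000, [(100, 200)], 17.0, seed=9)
        assert np.array_equal(a.depths, b.depths)

    def test_negative_binomial_overdispersion(self):
        nb = simulate_depth(500_000, [], 20.0, seed=4, dispersion=5.0)
        po = simulate_depth(500_000, [], 20.0, seed=4)
        assert nb.depths.var() > 1.5 * po.depths.var()


class TestMutateProtein:
    def test_zero_rates_identity(self):
        assert mutate_protein("MKWVTF", 0.0, 0.0, seed=1) == "MKWVTF"

    def test_full_substitution_no_residue_retained(self):
        p = "MKWVTFISLLLLFSSAYS"
        m = mutate_protein(p, 1.0, 0.0, seed=2)
        assert len(m) == len(p)
        assert all(a != b for a, b in zip(p, m))

    def test_substitution_count_binomial(self):
        rng = np.random.default_rng(0)
        p = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=1000))
        counts = []
        for seed in range(100):
            m = mutate_protein(p, 0.1, 0.0, seed=seed)
            counts.append(sum(a != b for a, b in zip(p, m)))
        assert np.mean(counts) == pytest.approx(100, abs=10)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            mutate_protein("", 0.1, 0.0, seed=1)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            mutate_protein("MKW", 1.5, 0.0, seed=1)

    def test_deterministic(self):
        assert mutate_protein("MKWVTF" * 20, 0.3, 0.1, seed=7) == mutate_protein(
            "MKWVTF" * 20, 0.3, 0.1, seed=7
        )


class TestSubstreamIndependence:
    def test_generators_do_not_perturb_each_other(self):
        """Named substreams: the same seed gives the same genome regardless of
        what other generators ran."""
        a = make_reference(42)
        _ = simulate_depth(1000, [], 20.0, seed=42)
        _ = mutate_protein("MKWVTF", 0.5, 0.1, seed=42)
        b = make_reference(42)
        assert a.genome == b.genome
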