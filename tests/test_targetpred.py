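"""SOM training, fragment projection, tail dissimilarity, duplex energy, full predictor."""

import itertools

import numpy as np
import pytest

from _oracles import duplex_energy_enum, perfect_site_pairs, random_rna, tail_cost_enum
from cerna_weaver.records import MiRNARecord, TranscriptRecord
from cerna_weaver.sequences import revcomp
from cerna_weaver.targetpred import (
    PredictParams,
    decode_seed,
    duplex_energy,
    encode_seed,
    load_energy_model,
    predict,
    project_fragments,
    tail_dissimilarity,
    train_som,
)


class TestEncoding:
    def test_homopolymer_one_hot(self):
        v = encode_seed("AAAAAAA")
        assert v.shape == (28,)
        assert all(v[4 * i] == 1.0 for i in range(7))
        assert v.sum() == 7

    def test_round_trip(self, rng):
        for _ in range(20):
            s = random_rna(rng, 7)
            assert decode_seed(encode_seed(s)) == s

    def test_distance_is_sqrt_2_hamming(self, rng):
        """Euclidean distance between encodings = sqrt(2 * Hamming distance)."""
        base = random_rna(rng, 7)
        for h in range(1, 8):
            other = list(base)
            for p in rng.choice(7, size=h, replace=False):
                other[p] = {"A": "C", "C": "G", "G": "U", "U": "A"}[other[p]]
            d = np.linalg.norm(encode_seed(base) - encode_seed("".join(other)))
            assert d == pytest.approx(np.sqrt(2 * h))


class TestTrainSom:
    def test_single_seed_converges_to_fixed_point(self):
        lat = train_som(["GAGGUAG"], rows=1, cols=1)
        assert np.linalg.norm(lat.weights[0] - encode_seed("GAGGUAG")) < 1e-6

    def test_duplicate_seeds_share_bmu(self):
        lat = train_som(["GAGGUAG", "GAGGUAG", "AAAAAAA"], rows=2, cols=2)
        assert lat.bmu(encode_seed("GAGGUAG")) == lat.bmu_map["GAGGUAG"]

    def test_weights_in_unit_interval(self, rng):
        seeds = [random_rna(rng, 7) for _ in range(12)]
        lat = train_som(seeds, rng_seed=3)
        assert (lat.weights >= 0).all() and (lat.weights <= 1).all()

    def test_deterministic_and_order_independent(self, rng):
        seeds = [random_rna(rng, 7) for _ in range(10)]
        a = train_som(seeds, rng_seed=5)
        b = train_som(list(reversed(seeds)), rng_seed=5)
        assert np.array_equal(a.weights, b.weights)
        assert a.bmu_map == b.bmu_map

    def test_separated_clusters_recovered(self):
        """Two clusters (Hamming >= 6 apart, <= 1 within) map to distinct BMU groups."""
        rng = np.random.default_rng(9)
        c1, c2 = "AAAAAAA", "GGGGGGG"

        def variant(center):
            s = list(center)
            p = rng.integers(7)
            s[p] = "CU"[rng.integers(2)]
            return "".join(s)

        wins = 0
        for restart in range(20):
            seeds1 = [c1] + [variant(c1) for _ in range(3)]
            seeds2 = [c2] + [variant(c2) for _ in range(3)]
            lat = train_som(seeds1 + seeds2, rows=2, cols=2, rng_seed=restart)
            b1 = {lat.bmu_map[s] for s in seeds1}
            b2 = {lat.bmu_map[s] for s in seeds2}
            if not (b1 & b2):
                wins += 1
        assert wins > 10  # majority of restarts separate the planted clusters


class TestProjectFragments:
    def test_exact_seed_complement_is_candidate(self):
        mir = MiRNARecord(id="m1", mature="UGAGGUAGUAGGUUGUAUAGUU")
        site = revcomp(mir.seed)
        target = TranscriptRecord(
            id="t1", biotype="protein_coding", sequence="A" * 30 + site + "A" * 30, utr3=(21, 67)
        )
        lat = train_som([mir.seed], rows=2, cols=2)
        cands = project_fragments(lat, target, {mir.seed: ["m1"]})
        assert ("m1", mir.seed, 31, 37) in cands

    def test_short_target_gives_empty(self):
        mir = MiRNARecord(id="m1", mature="UGAGGUAGUAGGUUGUAUAGUU")
        lat = train_som([mir.seed], rows=1, cols=1)
        target = TranscriptRecord(id="t1", biotype="pseudogene", sequence="ACGUA")
        assert project_fragments(lat, target, {mir.seed: ["m1"]}) == []

    def test_superset_of_exhaustive_seed_matches(self, ref_bundle):
        """Candidates always include every exact seed complement in a searchable region."""
        transcripts, mirnas, _ = ref_bundle
        mrnas = [t for t in transcripts if t.biotype == "protein_coding"]
        seed_to_ids = {}
        for m in mirnas:
            seed_to_ids.setdefault(m.seed, []).append(m.id)
        lat = train_som(sorted(seed_to_ids), rng_seed=42)
        expected = perfect_site_pairs(mirnas, mrnas)
        got = set()
        for t in mrnas:
            for mid, _, s, _ in project_fragments(lat, t, seed_to_ids):
                got.add((mid, t.id, s))
        assert expected <= got


class TestTailDissimilarity:
    def test_perfect_complement_extension(self, rng):
        tail = random_rna(rng, 14)
        assert tail_dissimilarity(tail, revcomp(tail)) == 0.0

    def test_self_extension_of_A_tail_is_one(self):
        # extension AAAA reverse-complements to UUUU: no position matches an A tail
        assert tail_dissimilarity("AAAA", "AAAA") == 1.0

    def test_empty_tail_is_zero(self):
        assert tail_dissimilarity("", "ACGU") == 0.0

    def test_matches_exhaustive_budget_alignment(self, rng):
        for _ in range(100):
            tail = random_rna(rng, int(rng.integers(1, 9)))
            ext = random_rna(rng, int(rng.integers(1, 13)))
            d = tail_dissimilarity(tail, ext, max_bulge=4)
            assert d == pytest.approx(tail_cost_enum(tail, revcomp(ext), 4))

    def test_bulge_absorbs_insertion(self, rng):
        tail = random_rna(rng, 10)
        ext = revcomp(tail)
        bulged = ext[:5] + "A" + ext[5:]  # one extra nt in the site
        assert tail_dissimilarity(tail, bulged, max_bulge=4) <= 1.0 / 10


class TestDuplexEnergy:
    def test_no_pairing_returns_initiation(self):
        model = load_energy_model()
        # A pairs only U, so an all-A site offers no pair at all
        assert duplex_energy("AAAA", "AAAA", model) == model.initiation

    def test_perfect_duplex_equals_hand_summed_stacks(self, rng):
        model = load_energy_model()
        q = random_rna(rng, 22)
        ctx = revcomp(q)
        expected = model.initiation
        rc = ctx[::-1]
        for i in range(1, 22):
            expected += model.stack(q[i - 1] + rc[i - 1], q[i] + rc[i])
        assert duplex_energy(q, ctx, model) == pytest.approx(expected)

    def test_dp_matches_exhaustive_enumeration(self, rng):
        model = load_energy_model()
        for _ in range(25):
            q = random_rna(rng, int(rng.integers(4, 9)))
            t = random_rna(rng, int(rng.integers(4, 9)))
            assert duplex_energy(q, t, model) == pytest.approx(duplex_energy_enum(q, t, model))

    def test_more_complementarity_is_more_stable(self, rng):
        model = load_energy_model()
        q = random_rna(rng, 15)
        full = duplex_energy(q, revcomp(q), model)
        half = duplex_energy(q, revcomp(q[:8]) , model)
        assert full <= half


class TestPredict:
    def test_empty_targets(self, ref_bundle):
        _, mirnas, _ = ref_bundle
        interactions, stats = predict(mirnas, [])
        assert interactions == [] and stats.candidates == 0

    def test_all_retained_below_cut(self, ref_predictions):
        interactions, _ = ref_predictions
        assert interactions
        assert all(x.delta_g < -12.0 for x in interactions)

    def test_sites_inside_searchable_region(self, ref_bundle, ref_predictions):
        transcripts, _, _ = ref_bundle
        by_id = {t.id: t for t in transcripts}
        for x in ref_predictions[0]:
            lo, hi = by_id[x.target_id].searchable_region
            assert lo <= x.site_start <= x.site_end <= hi

    def test_planted_site_sensitivity_at_reference_config(self, ref_bundle, ref_predictions):
        transcripts, mirnas, truth = ref_bundle
        interactions, _ = ref_predictions
        truth_pairs = {(m, t) for m, t, _, _ in truth.planted_interactions}
        pred_pairs = {(x.mirna_id, x.target_id) for x in interactions}
        sensitivity = len(truth_pairs & pred_pairs) / len(truth_pairs)
        assert sensitivity >= 0.9

    def test_filter_monotonicity(self, ref_bundle):
        """Tightening the deltaG cut or the dissimilarity threshold never adds interactions."""
        transcripts, mirnas, _ = ref_bundle
        mrnas = [t for t in transcripts if t.biotype == "protein_coding"][:30]
        base, _ = predict(mirnas, mrnas, PredictParams(som_seed=42))
        tighter_dg, _ = predict(mirnas, mrnas, PredictParams(dg_cut=-16.0, som_seed=42))
        tighter_tau, _ = predict(mirnas, mrnas, PredictParams(tau=0.15, som_seed=42))
        pairs = lambda xs: {(x.mirna_id, x.target_id) for x in xs}
        assert pairs(tighter_dg) <= pairs(base)
        assert pairs(tighter_tau) <= pairs(base)

    def test_output_sorted_by_energy(self, ref_predictions):
        interactions, _ = ref_predictions
        dgs = [x.delta_g for x in interactions]
        assert dgs == sorted(dgs)
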