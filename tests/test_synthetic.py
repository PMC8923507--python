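"""Tests of the ground-truth synthetic proteome generator."""

import json

import numpy as np
import pytest

from idphub.annotations import read_annotation_table, read_fasta, read_pllps_table
from idphub.disorder_profiles import (
    DisorderClass,
    binarize_track,
    group_tracks_by_protein,
    read_score_table,
)
from idphub.synthetic_data import (
    SpecValidationError,
    SyntheticSpec,
    generate_ppi,
    generate_proteome,
    generate_score_tracks,
    write_dataset,
)


def dataset_fingerprint(ds):
    """Serialize everything randomness touches, for determinism checks."""
    return (
        ds.protein_ids,
        tuple(sorted(ds.sequences.items())),
        tuple((pid, m.tobytes()) for pid, m in sorted(ds.truth_masks.items())),
        tuple((t.protein_id, t.predictor_id, t.scores.tobytes()) for t in ds.tracks),
        tuple(ds.edges),
        tuple((k, tuple(sorted(v))) for k, v in sorted(ds.term_map.items())),
        tuple((p.protein_id, p.is_tf, p.pllps, tuple(sorted(p.pathways))) for p in ds.proteins),
    )


class TestGenerateProteome:
    def test_empty_proteome_is_valid(self):
        ds = generate_proteome(SyntheticSpec(n_proteins=0))
        assert ds.proteins == [] and ds.tracks == [] and ds.edges == []

    def test_same_seed_gives_identical_datasets(self):
        spec = SyntheticSpec(n_proteins=60, seed=1)
        assert dataset_fingerprint(generate_proteome(spec)) == dataset_fingerprint(
            generate_proteome(spec)
        )

    def test_different_seeds_differ(self):
        a = generate_proteome(SyntheticSpec(n_proteins=60, seed=1))
        b = generate_proteome(SyntheticSpec(n_proteins=60, seed=2))
        assert dataset_fingerprint(a) != dataset_fingerprint(b)

    def test_planted_dratio_falls_in_assigned_interval(self):
        spec = SyntheticSpec(
            n_proteins=40,
            dratio_mixture=((1.0, (0.6, 0.8)),),
            predictor_noise_sd=0.0,
            predictor_agreement=1.0,
            seed=3,
        )
        ds = generate_proteome(spec)
        for pid, mask in ds.truth_masks.items():
            assert 0.6 <= mask.mean() <= 0.8, pid

    def test_planted_blocks_respect_min_length_and_gap(self, small_dataset):
        for pid, intervals in small_dataset.truth_intervals.items():
            for iv in intervals:
                assert len(iv) >= small_dataset.spec.idr_block_min
            for a, b in zip(intervals, intervals[1:]):
                assert b.start - a.end - 1 >= small_dataset.spec.min_block_gap

    def test_truth_mask_matches_truth_intervals_and_class(self, small_dataset):
        for pid, mask in small_dataset.truth_masks.items():
            total = sum(len(iv) for iv in small_dataset.truth_intervals[pid])
            assert total == int(mask.sum())
            assert small_dataset.truth_dratio[pid] == pytest.approx(mask.mean())

    def test_tf_count_is_floor_of_fraction(self):
        ds = generate_proteome(SyntheticSpec(n_proteins=97, frac_tf=0.1, seed=4))
        assert sum(p.is_tf for p in ds.proteins) == 9

    def test_track_lengths_match_protein_lengths(self, small_dataset):
        lengths = {p.protein_id: p.length for p in small_dataset.proteins}
        for t in small_dataset.tracks:
            assert len(t) == lengths[t.protein_id]

    def test_planted_enrichment_oversamples_idps(self):
        # with odds 5, IDP representation inside the planted pathway should
        # exceed the proteome-wide IDP rate in essentially every draw
        spec = SyntheticSpec(n_proteins=800, n_predictors=0, seed=5)
        ds = generate_proteome(spec)
        idps = {pid for pid, c in ds.truth_class.items() if c is DisorderClass.HD}
        base_rate = len(idps) / 800
        planted = ds.term_map["heat_shock"]  # odds 5 by default
        assert len(planted & idps) / len(planted) > base_rate

    def test_invalid_spec_names_field(self):
        with pytest.raises(SpecValidationError, match="frac_tf"):
            SyntheticSpec(frac_tf=1.5).validate()
        with pytest.raises(SpecValidationError, match="weights"):
            SyntheticSpec(dratio_mixture=((0.5, (0.0, 0.1)),)).validate()
        with pytest.raises(SpecValidationError, match="pathway_sizes"):
            SyntheticSpec(n_proteins=10, pathway_sizes=(50, 1, 1, 1, 1)).validate()


class TestScoreTracks:
    def test_noiseless_full_agreement_reproduces_truth(self):
        rng = np.random.default_rng(0)
        masks = {f"P{i}": rng.random(200) < 0.3 for i in range(5)}
        tracks = generate_score_tracks(masks, 2, noise_sd=0.0, agreement=1.0, rng=1)
        for t in tracks:
            assert (binarize_track(t).states == masks[t.protein_id]).all()

    def test_observed_concordance_matches_agreement_parameter(self):
        rng = np.random.default_rng(1)
        masks = {"P1": rng.random(10_000) < 0.5}
        agreement = 0.9
        tracks = generate_score_tracks(masks, 1, noise_sd=0.1, agreement=agreement, rng=2)
        observed = np.mean(binarize_track(tracks[0]).states == masks["P1"])
        se = np.sqrt(agreement * (1 - agreement) / 10_000)
        assert abs(observed - agreement) <= 3 * se

    def test_one_predictor_yields_one_track_per_protein(self):
        masks = {f"P{i}": np.ones(50, dtype=bool) for i in range(3)}
        tracks = generate_score_tracks(masks, 1, 0.05, 0.9, rng=3)
        grouped = group_tracks_by_protein(tracks)
        assert all(len(v) == 1 for v in grouped.values()) and len(grouped) == 3

    def test_scores_stay_inside_unit_interval(self, small_dataset):
        for t in small_dataset.tracks:
            assert t.scores.min() >= 0.0 and t.scores.max() <= 1.0

    def test_agreement_out_of_range_rejected(self):
        with pytest.raises(SpecValidationError):
            generate_score_tracks({"P1": np.ones(10, dtype=bool)}, 1, 0.1, 1.5)


class TestGeneratePpi:
    @staticmethod
    def _tf_proteins(n, seed, effect):
        spec = SyntheticSpec(
            n_proteins=n,
            frac_tf=1.0,
            dratio_mixture=((0.5, (0.12, 0.28)), (0.5, (0.52, 0.88))),
            n_predictors=0,
            degree_disorder_effect=effect,
            seed=seed,
        )
        return generate_proteome(spec)

    def test_zero_means_give_empty_edge_list(self):
        ds = self._tf_proteins(50, 0, 0.0)
        edges = generate_ppi(ds.proteins, ds.truth_class, 0.0, 0.0, rng=1)
        assert edges == []

    def test_planted_degree_effect_recovered_within_three_se(self):
        effect = 5.0
        ds = self._tf_proteins(500, 7, effect)
        edges = generate_ppi(ds.proteins, ds.truth_class, 8.0, effect, rng=8)
        degree = {p.protein_id: 0 for p in ds.proteins}
        for a, b in edges:
            degree[a] += 1
            if a != b:
                degree[b] += 1
        hd = [degree[pid] for pid, c in ds.truth_class.items() if c is DisorderClass.HD]
        ld = [degree[pid] for pid, c in ds.truth_class.items() if c is DisorderClass.LD]
        diff = np.mean(hd) - np.mean(ld)
        se = np.sqrt(np.var(hd, ddof=1) / len(hd) + np.var(ld, ddof=1) / len(ld))
        assert abs(diff - effect) <= 3 * se

    def test_same_seed_gives_identical_edges(self):
        ds = self._tf_proteins(80, 9, 5.0)
        e1 = generate_ppi(ds.proteins, ds.truth_class, 6.0, 5.0, rng=10)
        e2 = generate_ppi(ds.proteins, ds.truth_class, 6.0, 5.0, rng=10)
        assert e1 == e2

    def test_edges_are_deduplicated_unordered_pairs(self, small_dataset):
        canon = {tuple(sorted(e)) for e in small_dataset.edges}
        assert len(canon) == len(small_dataset.edges)


class TestWriteDataset:
    def test_round_trip_through_readers(self, tmp_path, small_dataset):
        paths = write_dataset(small_dataset, tmp_path)
        proteome = read_fasta(paths["fasta"])
        assert list(proteome) == small_dataset.protein_ids
        assert {k: len(v) for k, v in proteome.items()} == {
            p.protein_id: p.length for p in small_dataset.proteins
        }
        tracks = read_score_table(paths["scores"])
        assert len(tracks) == len(small_dataset.tracks)
        by_key = {(t.protein_id, t.predictor_id): t for t in tracks}
        for t in small_dataset.tracks:
            np.testing.assert_array_equal(by_key[(t.protein_id, t.predictor_id)].scores, t.scores)
        records, unmatched = read_annotation_table(paths["annotations"], proteome)
        assert unmatched == [] and len(records) == len(small_dataset.proteins)
        by_id = {r.protein_id: r for r in records}
        for p in small_dataset.proteins:
            r = by_id[p.protein_id]
            assert r.is_tf == p.is_tf
            assert r.pathways == p.pathways
            assert r.localizations == p.localizations
        pllps = read_pllps_table(paths["pllps"])
        for p in small_dataset.proteins:
            assert pllps[p.protein_id] == p.pllps
        truth = json.loads(paths["truth"].read_text())
        assert truth["class"] == {k: v.name for k, v in small_dataset.truth_class.items()}

    def test_empty_dataset_writes_well_formed_files(self, tmp_path):
        ds = generate_proteome(SyntheticSpec(n_proteins=0))
        paths = write_dataset(ds, tmp_path)
        assert read_fasta(paths["fasta"]) == {}
        records, unmatched = read_annotation_table(paths["annotations"], {})
        assert records == [] and unmatched == []

    def test_fasta_preserves_input_order(self, tmp_path):
        ds = generate_proteome(SyntheticSpec(n_proteins=3, seed=11))
        paths = write_dataset(ds, tmp_path)
        headers = [l[1:].strip() for l in paths["fasta"].read_text().splitlines()
                   if l.startswith(">")]
        assert headers == ds.protein_ids
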