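"""Combined predictor training, protein scanning, and serialization."""

import numpy as np
import pytest

import ubimdd as u
from ubimdd import phmm, predictor


@pytest.fixture(scope="module")
def trained(benchmark):
    positives, negatives, _ = benchmark
    config = u.TrainConfig(min_cluster_size=80, seed=5)
    return u.train_combined(positives, negatives, config)


class TestTraining:
    def test_unsplittable_data_degenerates_to_single_hmm(
        self, small_positives, small_negatives
    ):
        # 120 positives cannot produce two clusters of 80: one model
        config = u.TrainConfig(min_cluster_size=80, seed=2)
        combined = u.train_combined(small_positives, small_negatives, config)
        assert len(combined.models) == 1
        single = phmm.build_profile_hmm(
            small_positives, background=phmm.smoothed_background(small_positives)
        )
        assert np.allclose(
            combined.models[0].model.match_emissions, single.match_emissions
        )

    def test_benchmark_yields_one_model_per_motif(self, trained):
        assert len(trained.models) == 2
        assert sum(trained.cluster_sizes) == 400
        assert all(size >= 80 for size in trained.cluster_sizes)

    def test_same_seed_gives_byte_identical_predictor(self, benchmark):
        positives, negatives, _ = benchmark
        config = u.TrainConfig(min_cluster_size=80, seed=5)
        first = predictor.predictor_to_text(
            u.train_combined(positives, negatives, config)
        )
        second = predictor.predictor_to_text(
            u.train_combined(positives, negatives, config)
        )
        assert first == second

    def test_mislabeled_inputs_rejected(self, small_positives, small_negatives):
        with pytest.raises(u.ValidationError, match="mislabeled"):
            u.train_combined(small_negatives, small_positives, u.TrainConfig())


class TestScanning:
    def test_protein_without_lysine_yields_no_sites(self, trained):
        assert u.predict_sites(trained, u.Protein(id="p", sequence="AGAGA")) == []

    def test_every_scored_site_addresses_a_lysine(self, trained):
        fasta, sites = u.generate_annotated_proteins(
            n_proteins=3,
            length=120,
            positive_motif=u.MotifSpec(weight=1.0, biases=((+1, "aromatic", 1.0),)),
            sites_per_protein=2,
            seed=17,
        )
        proteins = self._load(fasta, sites)
        for protein in proteins:
            for site in u.predict_sites(trained, protein):
                assert protein.sequence[site.position - 1] == "K"
                assert site.prediction == any(
                    s > tm.threshold for s, tm in zip(site.scores, trained.models)
                )

    @staticmethod
    def _load(fasta, sites, tmp_dir=None):
        import io

        from Bio import SeqIO

        records = list(SeqIO.parse(io.StringIO(fasta), "fasta"))
        table = [
            line.split("\t")
            for line in sites.splitlines()
            if line and not line.startswith("#")
        ]
        by_id = {}
        for pid, pos in table:
            by_id.setdefault(pid, set()).add(int(pos))
        return [
            u.Protein(
                id=r.id, sequence=str(r.seq), validated_sites=by_id.get(r.id, set())
            )
            for r in records
        ]

    def test_planted_motif_site_ranks_first(self):
        # one strongly planted site per protein; a three-position motif
        # is specific enough that a uniform background essentially never
        # reproduces it, so the planted site should top the per-protein
        # ranking by best bit score almost always
        motif = u.MotifSpec(
            weight=1.0,
            biases=((-1, "acidic", 1.0), (+1, "aromatic", 1.0), (+2, "basic", 1.0)),
        )
        positives, _ = u.generate_fragments([motif], 300, seed=601)
        negatives, _ = u.generate_fragments(
            [u.MotifSpec(weight=1.0)], 624, seed=602, label=u.NEGATIVE
        )
        scanner = u.train_combined(positives, negatives, u.TrainConfig(seed=5))
        hits = 0
        n_proteins = 100
        fasta, sites = u.generate_annotated_proteins(
            n_proteins=n_proteins,
            length=80,
            positive_motif=motif,
            sites_per_protein=1,
            seed=23,
        )
        for protein in self._load(fasta, sites):
            scored = u.predict_sites(scanner, protein)
            best = max(scored, key=lambda s: s.best_score)
            hits += best.position in protein.validated_sites
        assert hits >= 0.95 * n_proteins

    def test_score_exactly_at_threshold_is_negative(self, trained, benchmark):
        positives, _, _ = benchmark
        scores = predictor.score_fragments(trained, positives)
        pinned = predictor.CombinedPredictor(
            models=[
                phmm.ThresholdedModel(
                    model=tm.model,
                    threshold=float(scores[0, i]),
                    cluster_id=tm.cluster_id,
                )
                for i, tm in enumerate(trained.models)
            ],
            config=trained.config,
        )
        decisions = predictor.predict_fragments(pinned, positives[:1])
        assert decisions[0] == False  # noqa: E712  — strict '>' rule


class TestSitePrecision:
    def test_case_study_style_overlap(self):
        assert u.site_precision({27, 29, 33, 48, 63}, {11, 29, 33, 48, 63}) == 80.0

    def test_identical_sets_give_hundred(self):
        assert u.site_precision({1, 2}, {1, 2}) == 100.0

    def test_disjoint_sets_give_zero(self):
        assert u.site_precision({1}, {2}) == 0.0

    def test_empty_prediction_rejected(self):
        with pytest.raises(u.ValidationError):
            u.site_precision(set(), {1})


def test_predictor_serialization_preserves_scores_bitwise(
    tmp_path, trained, benchmark
):
    positives, negatives, _ = benchmark
    path = tmp_path / "predictor.txt"
    u.save_predictor(trained, path)
    restored = u.load_predictor(path)
    assert restored.config == trained.config
    assert restored.cluster_sizes == trained.cluster_sizes
    query = u.FragmentSet(list(positives[:50]) + list(negatives[:50]))
    assert np.array_equal(
        predictor.score_fragments(trained, query),
        predictor.score_fragments(restored, query),
    )
    assert [tm.threshold for tm in restored.models] == [
        tm.threshold for tm in trained.models
    ]


def test_combined_outperforms_single_on_one_replicate(benchmark):
    positives, negatives, _ = benchmark
    config = u.TrainConfig(seed=5)
    single = u.cross_validate_single(positives, negatives, config)
    reports, macro = u.cross_validate_combined(positives, negatives, config)
    assert len(reports) == 2
    assert macro.acc > single.acc
    assert macro.auc > single.auc
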