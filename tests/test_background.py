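import numpy as np
import pytest

from rnaloci.background import (
    EnsembleMember,
    HardNegativeSet,
    InsufficientBackgroundError,
    TrainingRun,
    collect_hard_negatives,
    sample_random_negatives,
    select_best_model,
)
from rnaloci.intervals import GenomicInterval, is_hit, make_windows


class _StubModel:
    """Stands in for a trained model when scores are precomputed."""


def _positives(n=10, length=80, chrom="chrA", spacing=500):
    return [
        GenomicInterval(chrom, 1000 + i * spacing, 1000 + i * spacing + length,
                        "+" if i % 2 == 0 else "-", f"pos_{i}")
        for i in range(n)
    ]


class TestSampleRandomNegatives:
    CANDIDATES = [GenomicInterval("chrA", 10_000, 60_000, "+", "bg")]

    def test_one_to_four_ratio_and_length_match(self):
        pos = _positives(10)
        negs = sample_random_negatives(pos, self.CANDIDATES, ratio=4, seed=1)
        assert len(negs) == 40
        assert all(n.length == 80 for n in negs)

    def test_deterministic_per_seed(self):
        pos = _positives(5)
        a = sample_random_negatives(pos, self.CANDIDATES, ratio=4, seed=7)
        b = sample_random_negatives(pos, self.CANDIDATES, ratio=4, seed=7)
        assert a == b
        c = sample_random_negatives(pos, self.CANDIDATES, ratio=4, seed=8)
        assert a != c

    def test_no_overlap_with_positives_or_each_other(self):
        pos = _positives(8)
        candidates = [GenomicInterval("chrA", 0, 20_000, "+", "bg")]  # overlaps pos
        negs = sample_random_negatives(pos, candidates, ratio=4, seed=2)
        for n in negs:
            assert all(not is_hit(n, p) for p in pos)
            assert all(n.same_strand_overlap(p) == 0 for p in pos)
        for i, a in enumerate(negs):
            for b in negs[i + 1:]:
                assert a.same_strand_overlap(b) == 0

    def test_candidate_too_short_errors(self):
        pos = [GenomicInterval("chrA", 0, 100, "+")]
        with pytest.raises(InsufficientBackgroundError):
            sample_random_negatives(
                pos, [GenomicInterval("chrB", 0, 50, "+")], ratio=1, seed=0
            )

    def test_exhausted_space_errors(self):
        pos = [GenomicInterval("chrA", 0, 100, "+")]
        # room for at most ~2 non-overlapping negatives, ask for 50
        tight = [GenomicInterval("chrB", 0, 220, "+")]
        with pytest.raises(InsufficientBackgroundError):
            sample_random_negatives(pos, tight, ratio=50, seed=0)

    def test_training_run_invariants(self):
        pos = _positives(6)
        negs = sample_random_negatives(pos, self.CANDIDATES, ratio=4, seed=3)
        run = TrainingRun(positives=pos, negatives=negs, split={}, seed=3)
        run.validate(ratio=4)  # raises on violation


def _window_grid(chrom="chrA", n=20, width=100, step=50):
    region = GenomicInterval(chrom, 0, width + (n - 1) * step, "+")
    wins = make_windows(region, width=width, step=step)
    assert len(wins) == n
    return wins


class TestCollectHardNegatives:
    def brute_force_supports(self, windows, scores, targets, thr):
        """Independent recount from the raw per-model flag table."""
        from rnaloci.intervals import cluster_by_overlap

        n_models = scores.shape[0]
        flags = {}
        for mi in range(n_models):
            for wi, w in enumerate(windows):
                if scores[mi, wi] >= thr and not any(is_hit(w, t) for t in targets):
                    flags.setdefault(w.key(), set()).add(mi)
        clusters = cluster_by_overlap(
            [w for w in windows if w.key() in flags]
        )
        out = []
        for cl in clusters:
            models = set()
            for w in cl:
                models |= flags[w.key()]
            out.append(len(models))
        return sorted(out)

    def test_toy_flag_table(self):
        # non-overlapping windows, 3 models, threshold support 2
        wins = _window_grid(n=4, step=200)
        scores = np.array([
            [0.9, 0.1, 0.9, 0.1],
            [0.8, 0.9, 0.1, 0.1],
            [0.1, 0.1, 0.1, 0.9],
        ])
        models = [_StubModel()] * 3
        hard = collect_hard_negatives(
            models, [], [], None, support_threshold=2,
            precomputed=(wins, scores),
        )
        # window 0 flagged by models {0,1} -> support 2; others support 1
        assert len(hard) == 1
        assert hard.support[hard.intervals[0].key()] == 2
        assert hard.intervals[0].start == wins[0].start

    def test_support_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        wins = _window_grid(n=150, step=30)  # overlapping windows
        targets = [GenomicInterval("chrA", 1000, 1100, "+")]
        for n_models in (2, 3, 5):
            scores = rng.random((n_models, len(wins)))
            hard = collect_hard_negatives(
                [_StubModel()] * n_models, [], targets, None,
                support_threshold=1, precomputed=(wins, scores),
                score_threshold=0.7,
            )
            assert sorted(hard.support.values()) == self.brute_force_supports(
                wins, scores, targets, 0.7
            )

    def test_boundary_at_least_25_of_50(self):
        wins = _window_grid(n=2, step=300)
        scores = np.zeros((50, 2))
        scores[:24, 0] = 0.9   # window 0: 24 models -> excluded
        scores[:25, 1] = 0.9   # window 1: 25 models -> included
        hard = collect_hard_negatives(
            [_StubModel()] * 50, [], [], None, support_threshold=25,
            precomputed=(wins, scores),
        )
        assert len(hard) == 1
        assert hard.intervals[0].start == wins[1].start
        assert hard.support[hard.intervals[0].key()] == 25

    def test_target_overlap_never_false_positive(self):
        wins = _window_grid(n=3, step=300)
        targets = [GenomicInterval("chrA", wins[1].start, wins[1].end, "+")]
        scores = np.ones((3, 3))  # every model maximally confident everywhere
        hard = collect_hard_negatives(
            [_StubModel()] * 3, [], targets, None, support_threshold=1,
            precomputed=(wins, scores),
        )
        starts = {h.start for h in hard.intervals}
        assert wins[1].start not in starts
        assert starts == {wins[0].start, wins[2].start}

    def test_support_exceeding_models_rejected(self):
        with pytest.raises(ValueError):
            collect_hard_negatives(
                [_StubModel()] * 3, [], [], None, support_threshold=4,
                precomputed=(_window_grid(n=1), np.zeros((3, 1))),
            )

    def test_empty_when_no_flags(self):
        wins = _window_grid(n=5, step=300)
        hard = collect_hard_negatives(
            [_StubModel()] * 3, [], [], None, support_threshold=1,
            precomputed=(wins, np.zeros((3, 5))),
        )
        assert len(hard) == 0 and hard.intervals == []

    def test_score_column_is_support_fraction(self):
        wins = _window_grid(n=1)
        scores = np.array([[0.9], [0.9], [0.0], [0.0]])
        hard = collect_hard_negatives(
            [_StubModel()] * 4, [], [], None, support_threshold=2,
            precomputed=(wins, scores),
        )
        assert hard.intervals[0].score == pytest.approx(0.5)


class TestSelectBestModel:
    def _member(self, i, f1):
        return EnsembleMember(index=i, seed=i, model=None, negatives=[],
                              metrics={"f1": f1})

    def test_argmax(self):
        members = [self._member(i, f1) for i, f1 in enumerate([0.3, 0.7, 0.5])]
        assert select_best_model(members).index == 1

    def test_tie_goes_to_lower_index(self):
        members = [self._member(i, 0.5) for i in range(2)]
        assert select_best_model(members).index == 0

    def test_single_member(self):
        members = [self._member(0, 0.1)]
        assert select_best_model(members) is members[0]

    def test_missing_metric(self):
        bad = EnsembleMember(index=0, seed=0, model=None, negatives=[], metrics={})
        with pytest.raises(ValueError):
            select_best_model([bad])


class TestIterateTrain:
    def test_scaled_down_pipeline(self):
        from rnaloci.background import iterate_train
        from rnaloci.model import ModelConfig
        from rnaloci.synthetic import SyntheticGenomeSpec, benchmark_suite, simulate_genome

        spec = SyntheticGenomeSpec(
            n_chroms=3, chrom_length=8_000, n_positives=9,
            n_decoys_per_class=3, seed=0,
        )
        genome = simulate_genome(spec)
        suite = benchmark_suite(genome)
        cfg = ModelConfig(branches=("S", "C"), conv_filters=(4, 4, 8), kernel=3,
                          dense_units=(8,), epochs=2, seed=0)
        final, hard, prov = iterate_train(
            suite.run.positives, suite.candidate_regions, suite.scan_regions,
            genome.sequences, genome.track,
            config=cfg, targets=suite.run.positives,
            n_models=2, ratio=2, support_threshold=1, step=50, seed=0,
            split=suite.run.split,
        )
        assert final.trained
        assert prov["n_models"] == 2 and len(prov["members"]) == 2
        assert prov["best_index"] in (0, 1)
        enhanced = prov["enhanced_set"]
        assert enhanced["n_negatives_total"] == (
            enhanced["n_random_negatives"] + enhanced["n_hard_negatives"]
        )
        assert enhanced["n_hard_negatives"] == len(hard.intervals)
        # every emitted hard negative carries its support
        assert all(
            hard.support[iv.key()] >= 1 for iv in hard.intervals
        )
        # left-out chromosome excluded from everything by construction
        assert all(p.chrom != suite.left_out_chrom for p in suite.run.positives)
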