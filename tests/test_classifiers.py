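"""Training, scoring, the Vote rule, grid search, and persistence."""

import itertools

import numpy as np
import pytest

import pripper as pp
from pripper.classifiers import (
    ClassifierConfig,
    SiteClassifier,
    VoteClassifier,
    combine_votes,
    grid_search,
    load_model,
    save_model,
    train,
)
from pripper.encoding import (
    CandidateSite,
    PaddingPolicy,
    WindowGeometry,
    encode_windows,
)
from pripper.evaluation import leave_one_out
from pripper.sequence_io import ProteinRecord

ALGORITHMS = ("svm", "random_forest", "decision_tree")


class TestConfigDefaults:
    def test_svm_table_values(self):
        cfg = ClassifierConfig.default("svm")
        assert cfg.geometry == WindowGeometry(6, 4)
        hp = cfg.hyperparameters
        assert hp["nu"] == 0.536
        assert hp["gamma"] == pytest.approx(2.0 ** -5.5)
        assert hp["tol"] == 1e-5
        assert hp["kernel"] == "rbf"
        assert cfg.name == "SVM-6-4"

    def test_rf_table_values(self):
        cfg = ClassifierConfig.default("random_forest")
        assert cfg.geometry == WindowGeometry(12, 12)
        est = cfg.build_estimator()
        assert est.n_estimators == 143
        assert est.max_features == 4
        assert est.max_depth is None

    def test_tree_table_values(self):
        cfg = ClassifierConfig.default("decision_tree")
        assert cfg.geometry == WindowGeometry(4, 2)
        est = cfg.build_estimator()
        assert est.min_samples_leaf == 5
        # J48-only options are carried as advisory metadata
        assert cfg.hyperparameters["confidence_factor"] == 0.285

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig.default("perceptron")


class TestTrain:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_set_fits_perfectly(self, separable_toyset, algorithm):
        cfg = ClassifierConfig.default(
            algorithm, geometry=separable_toyset.geometry, seed=0
        )
        clf = train(separable_toyset, cfg)
        assert np.array_equal(clf.classify(separable_toyset.X), separable_toyset.y)

    def test_rf_same_seed_identical_predictions(self, separable_toyset):
        cfg = ClassifierConfig.default(
            "random_forest", geometry=separable_toyset.geometry, seed=7
        )
        a = train(separable_toyset, cfg)
        b = train(separable_toyset, cfg)
        assert np.array_equal(
            a.decision_scores(separable_toyset.X),
            b.decision_scores(separable_toyset.X),
        )

    def test_single_class_dataset_rejected(self, separable_toyset):
        pos = separable_toyset.subset(np.flatnonzero(separable_toyset.y == 1))
        cfg = ClassifierConfig.default("svm", geometry=pos.geometry)
        with pytest.raises(ValueError, match="both classes"):
            train(pos, cfg)

    def test_geometry_mismatch_rejected(self, separable_toyset):
        cfg = ClassifierConfig.default("svm")  # (6,4) != toyset's (4,2)
        with pytest.raises(ValueError, match="geometry"):
            train(separable_toyset, cfg)

    def test_loo_beats_nearest_neighbour_baseline(self, small_corpus):
        """Each algorithm's LOO accuracy matches or beats a brute-force
        1-NN on the same one-hot encoding."""
        proteins, positive_sites = small_corpus
        for algorithm in ALGORITHMS:
            cfg = ClassifierConfig.default(
                algorithm, geometry=WindowGeometry(4, 2), seed=0
            )
            ds = pp.build_dataset(proteins, positive_sites, cfg.geometry, seed=0)
            counts = leave_one_out(ds, cfg)
            acc = (counts.tp + counts.tn) / counts.total
            # independent baseline: leave-one-out 1-nearest-neighbour
            X, y = ds.X, ds.y
            hits = 0
            for i in range(len(ds)):
                d = np.abs(X - X[i]).sum(axis=1)
                d[i] = np.inf
                hits += y[int(np.argmin(d))] == y[i]
            nn_acc = hits / len(ds)
            assert acc >= nn_acc, (algorithm, acc, nn_acc)


class TestDecisionScore:
    def test_rf_unanimous_training_point_scores_one(self, separable_toyset):
        cfg = ClassifierConfig.default(
            "random_forest", geometry=separable_toyset.geometry, seed=0
        )
        clf = train(separable_toyset, cfg)
        scores = clf.decision_scores(separable_toyset.X)
        assert scores.max() == pytest.approx(1.0)
        assert scores.min() == pytest.approx(0.0)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_threshold_infinities_are_roc_endpoints(
        self, separable_toyset, algorithm
    ):
        cfg = ClassifierConfig.default(
            algorithm, geometry=separable_toyset.geometry, seed=0
        )
        clf = train(separable_toyset, cfg)
        assert (clf.classify(separable_toyset.X, threshold=np.inf) == -1).all()
        assert (clf.classify(separable_toyset.X, threshold=-np.inf) == 1).all()

    def test_classify_consistent_with_score_and_threshold(self, separable_toyset):
        cfg = ClassifierConfig.default(
            "svm", geometry=separable_toyset.geometry, seed=0
        )
        clf = train(separable_toyset, cfg)
        scores = clf.decision_scores(separable_toyset.X)
        labels = clf.classify(separable_toyset.X)
        assert np.array_equal(labels, np.where(scores >= clf.threshold, 1, -1))

    def test_geometry_mismatch_raises(self, separable_toyset):
        cfg = ClassifierConfig.default(
            "svm", geometry=separable_toyset.geometry, seed=0
        )
        clf = train(separable_toyset, cfg)
        with pytest.raises(ValueError, match="geometry"):
            clf.decision_scores(np.zeros((1, 200)))


class _StubMember:
    """Fixed-answer member for exercising the majority rule."""

    class config:
        name = "stub"

    def __init__(self, answer):
        self.answer = answer

    def predict_site(self, protein, site, padding_policy=PaddingPolicy.PAD):
        return self.answer


class TestVote:
    @pytest.mark.parametrize("n_members", [1, 2, 3])
    def test_truth_table_matches_strict_majority(self, n_members):
        """All vote patterns (including abstentions) for 1-3 members."""
        protein = ProteinRecord(id="p", sequence="AAADAA")
        site = CandidateSite("p", 4)
        for pattern in itertools.product((1, -1, None), repeat=n_members):
            vc = VoteClassifier([_StubMember(v) for v in pattern])
            got = vc.predict_site(protein, site)
            n_pos = sum(1 for v in pattern if v == 1)
            expected = 1 if n_pos > n_members / 2 else -1
            assert got == expected, pattern
            assert combine_votes(pattern, n_members) == expected

    def test_two_members_require_agreement(self):
        protein = ProteinRecord(id="p", sequence="AAADAA")
        site = CandidateSite("p", 4)
        both = VoteClassifier([_StubMember(1), _StubMember(1)])
        split = VoteClassifier([_StubMember(1), _StubMember(-1)])
        assert both.predict_site(protein, site) == 1
        assert split.predict_site(protein, site) == -1

    def test_single_member_vote_equals_member(self, small_corpus):
        proteins, positive_sites = small_corpus
        cfg = ClassifierConfig.default("decision_tree", seed=0)
        ds = pp.build_dataset(proteins, positive_sites, cfg.geometry, seed=0)
        clf = train(ds, cfg)
        vc = VoteClassifier([clf])
        protein = proteins[0]
        sites = pp.scan_candidates(protein)
        direct = [clf.predict_site(protein, s) for s in sites]
        voted = vc.predict_sites(protein, sites)
        assert np.array_equal(np.asarray(direct), voted)

    def test_members_use_their_own_geometries(self, small_corpus):
        proteins, positive_sites = small_corpus
        geoms = [WindowGeometry(4, 2), WindowGeometry(6, 4)]
        members = []
        for geom in geoms:
            cfg = ClassifierConfig.default("decision_tree", geometry=geom, seed=0)
            ds = pp.build_dataset(proteins, positive_sites, geom, seed=0)
            members.append(train(ds, cfg))
        vc = VoteClassifier(members)
        protein = proteins[0]
        sites = pp.scan_candidates(protein)
        voted = vc.predict_sites(protein, sites)
        manual = []
        for s in sites:
            votes = [m.predict_site(protein, s) for m in members]
            manual.append(combine_votes(votes, len(members)))
        assert np.array_equal(voted, np.asarray(manual))

    def test_abstention_counts_as_negative_vote(self):
        # site so close to the N-terminus that a (6,4) member must abstain
        protein = ProteinRecord(id="p", sequence="AADEVDGSAAAA")
        site = CandidateSite("p", 3)
        always_yes = _StubMember(1)
        vc = VoteClassifier([always_yes, _StubMember(None)])
        assert vc.predict_site(protein, site) == -1

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            VoteClassifier([])


class TestPermutationInvariance:
    """Relabeling the residue→index table permutes one-hot columns and
    must not change what any classifier learns."""

    @staticmethod
    def _permute_columns(X, perm):
        cols = np.concatenate([20 * b + perm for b in range(X.shape[1] // 20)])
        return X[:, cols]

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_predictions_invariant_under_table_permutation(
        self, small_corpus, algorithm
    ):
        proteins, positive_sites = small_corpus
        cfg = ClassifierConfig.default(
            algorithm, geometry=WindowGeometry(4, 2), seed=0
        )
        ds = pp.build_dataset(proteins, positive_sites, cfg.geometry, seed=0)
        perm = np.random.default_rng(99).permutation(20)
        Xp = self._permute_columns(ds.X, perm)
        dsp = pp.LabeledDataset(X=Xp, y=ds.y, geometry=ds.geometry)
        a = train(ds, cfg)
        b = train(dsp, cfg)
        assert np.array_equal(a.classify(ds.X), b.classify(Xp))
        if algorithm == "svm":
            # the RBF kernel depends only on pairwise distances, which a
            # column permutation preserves exactly
            np.testing.assert_allclose(
                a.decision_scores(ds.X), b.decision_scores(Xp), atol=1e-9
            )


def test_tree_never_splits_on_the_constant_p1_slot(small_corpus):
    """With negatives drawn at Asp positions, every training sample has D
    at P1, so the P1 block is constant and carries no split information."""
    proteins, positive_sites = small_corpus
    cfg = ClassifierConfig.default("decision_tree", seed=0)
    ds = pp.build_dataset(proteins, positive_sites, cfg.geometry, seed=0)
    clf = train(ds, cfg)
    p1_block = slice(20 * (cfg.geometry.n_left - 1), 20 * cfg.geometry.n_left)
    assert clf.estimator.feature_importances_[p1_block].sum() == 0.0


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self, small_corpus):
        proteins, positive_sites = small_corpus
        geom = WindowGeometry(4, 2)
        best, cells = grid_search(
            proteins, positive_sites, "decision_tree",
            geometries=[geom], seed=0,
        )
        assert best.geometry == geom
        assert len(cells) == 1

    def test_right_context_signal_prefers_wider_window(self):
        """A cut signal living entirely in P1' (G after the cut) is invisible
        to a (4,0) window but trivial for (6,4)."""
        rng = np.random.default_rng(21)
        alphabet = "ACEFHIKLMNPQRSTVWY"  # no D, no G in the background
        proteins, positive_sites = [], {}
        for k in range(30):
            seq = list(rng.choice(list(alphabet), size=60))
            pos_p1, neg_p1 = 20, 40
            seq[pos_p1 - 1] = "D"
            seq[pos_p1] = "G"  # the only informative residue
            seq[neg_p1 - 1] = "D"
            pid = f"g{k}"
            proteins.append(ProteinRecord(id=pid, sequence="".join(seq)))
            positive_sites[pid] = [pos_p1]
        best, cells = grid_search(
            proteins, positive_sites, "decision_tree",
            geometries=[WindowGeometry(4, 0), WindowGeometry(6, 4)],
            negative_policy="exhaustive", seed=0,
        )
        accs = {str(c.geometry): c.accuracy for c in cells}
        assert accs["6-4"] > accs["4-0"]
        assert best.geometry == WindowGeometry(6, 4)

    def test_per_cell_accuracy_matches_independent_recomputation(
        self, small_corpus
    ):
        proteins, positive_sites = small_corpus
        from pripper.dataset import assemble_sites

        geometries = [WindowGeometry(4, 2), WindowGeometry(6, 4)]
        best, cells = grid_search(
            proteins, positive_sites, "decision_tree",
            geometries=geometries, seed=3,
        )
        sites = assemble_sites(proteins, positive_sites, seed=3)
        for cell in cells:
            ds = pp.build_dataset(
                proteins, positive_sites, cell.geometry, sites=sites
            )
            cfg = ClassifierConfig(
                "decision_tree", cell.geometry, cell.hyperparameters, seed=3
            )
            counts = leave_one_out(ds, cfg)
            assert cell.accuracy == pytest.approx(
                (counts.tp + counts.tn) / counts.total
            )

    def test_tie_breaks_toward_smaller_window(self, separable_toyset):
        """Identical accuracies must resolve to the smaller total window."""
        # single protein corpus where both geometries achieve equal accuracy
        protein = ProteinRecord(
            id="p", sequence="AAAAAAADEVDGSAAAAAAADAAAAAAA"
        )
        best, cells = grid_search(
            [protein], {"p": [11]}, "decision_tree",
            geometries=[WindowGeometry(6, 4), WindowGeometry(4, 2)],
            negative_policy="exhaustive", seed=0,
        )
        accs = [c.accuracy for c in cells]
        if accs[0] == accs[1]:
            assert best.geometry == WindowGeometry(4, 2)
        else:
            assert best.geometry == cells[int(np.argmax(accs))].geometry


class TestPersistence:
    def test_roundtrip_identical_predictions_and_scores(
        self, tmp_path, separable_toyset, rng
    ):
        cfg = ClassifierConfig.default(
            "random_forest", geometry=separable_toyset.geometry, seed=0
        )
        clf = train(separable_toyset, cfg)
        path = tmp_path / "rf.joblib"
        save_model(clf, path)
        back = load_model(path)
        X = (rng.random((100, separable_toyset.geometry.n_features)) < 0.05).astype(
            float
        )
        assert np.array_equal(clf.classify(X), back.classify(X))
        np.testing.assert_allclose(
            clf.decision_scores(X), back.decision_scores(X), atol=1e-12
        )

    def test_metadata_sidecar_written(self, tmp_path, separable_toyset):
        import json

        cfg = ClassifierConfig.default(
            "svm", geometry=separable_toyset.geometry, seed=0
        )
        clf = train(separable_toyset, cfg)
        path = tmp_path / "svm.joblib"
        save_model(clf, path)
        meta = json.loads((tmp_path / "svm.joblib.json").read_text())
        assert meta["algorithm"] == "svm"
        assert meta["geometry"] == {"n_left": 4, "n_right": 2}

    def test_vote_roundtrip(self, tmp_path, separable_toyset):
        cfg1 = ClassifierConfig.default(
            "svm", geometry=separable_toyset.geometry, seed=0
        )
        cfg2 = ClassifierConfig.default(
            "decision_tree", geometry=separable_toyset.geometry, seed=0
        )
        vc = VoteClassifier(
            [train(separable_toyset, cfg1), train(separable_toyset, cfg2)]
        )
        path = tmp_path / "vote.joblib"
        save_model(vc, path)
        back = load_model(path)
        assert isinstance(back, VoteClassifier)
        protein = ProteinRecord(id="p", sequence="AAAADEVDGSAAAA")
        sites = pp.scan_candidates(protein)
        assert np.array_equal(
            vc.predict_sites(protein, sites), back.predict_sites(protein, sites)
        )

    def test_wrong_geometry_input_errors_after_load(
        self, tmp_path, separable_toyset
    ):
        cfg = ClassifierConfig.default(
            "svm", geometry=separable_toyset.geometry, seed=0
        )
        clf = train(separable_toyset, cfg)
        path = tmp_path / "m.joblib"
        save_model(clf, path)
        back = load_model(path)
        with pytest.raises(ValueError, match="geometry"):
            back.classify(np.zeros((2, 200)))

    def test_bad_format_version_rejected(self, tmp_path, separable_toyset):
        import joblib

        path = tmp_path / "m.joblib"
        joblib.dump({"format_version": 99, "kind": "single"}, path)
        with pytest.raises(ValueError, match="format version"):
            load_model(path)
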