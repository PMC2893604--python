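"""Site classifiers: ν-SVM, random forest, decision tree, and the Vote ensemble.

The three base learners mirror the published tool's optimized
configurations:

* ``svm`` — ν-SVC with an RBF kernel (γ = 2^−5.5, ν = 0.536, stopping
  tolerance 1e−5), window 6 residues before / 4 after the cut.
* ``random_forest`` — 143 trees, 4 features considered per split,
  unlimited depth, window 12/12.
* ``decision_tree`` — a CART-style stand-in for Weka's J48 (C4.5):
  entropy splits, minimum 5 objects per leaf, binary splits (CART is
  inherently binary), pruning strength exposed as ``ccp_alpha``.  The
  J48-only options (confidence factor, subtree raising, Laplace
  smoothing, reduced-error-pruning folds) are accepted and recorded but
  advisory: error-based C4.5 pruning has no exact CART equivalent, so
  bit-identical trees are out of reach and results may differ in detail.

The Vote ensemble labels a site positive only when a strict majority of
its members do; with the default two members (SVM + RF) both must
agree.  Each member extracts and encodes the site with its *own* window
geometry.  A member that cannot resolve a site (window overruns a
terminus under the skip policy) abstains, and abstentions count as
negative votes — conservative, which is the point of the ensemble.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import NuSVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import LabeledDataset, build_dataset
from .encoding import (
    CandidateSite,
    PaddingPolicy,
    WindowGeometry,
    encode,
    extract_window,
)
from .sequence_io import ProteinRecord

ALGORITHMS = ("svm", "random_forest", "decision_tree")

DEFAULT_SEED = 0

#: Advisory J48 options: accepted in decision_tree hyperparameters and
#: stored in model metadata, but without a CART counterpart.
ADVISORY_TREE_KEYS = frozenset(
    {
        "confidence_factor",
        "num_folds",
        "reduced_error_pruning",
        "subtree_raising",
        "use_laplace",
        "unpruned",
        "binary_splits",
    }
)

_DEFAULTS: dict[str, tuple[WindowGeometry, dict]] = {
    "svm": (
        WindowGeometry(6, 4),
        {"nu": 0.536, "gamma": 2.0 ** -5.5, "tol": 1e-5, "kernel": "rbf"},
    ),
    "random_forest": (
        WindowGeometry(12, 12),
        {"n_estimators": 143, "max_features": 4, "max_depth": None},
    ),
    "decision_tree": (
        WindowGeometry(4, 2),
        {
            "min_samples_leaf": 5,
            "ccp_alpha": 0.0,
            "criterion": "entropy",
            "confidence_factor": 0.285,
            "num_folds": 3,
            "binary_splits": True,
            "reduced_error_pruning": False,
            "subtree_raising": True,
            "use_laplace": False,
            "unpruned": False,
        },
    ),
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Algorithm + window geometry + hyperparameters + seed.

    :meth:`default` reproduces the published optimized configuration
    for each algorithm; pass overrides to depart from it.
    """

    algorithm: str
    geometry: WindowGeometry
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )

    @classmethod
    def default(
        cls,
        algorithm: str,
        *,
        geometry: Optional[WindowGeometry] = None,
        seed: int = DEFAULT_SEED,
        **overrides,
    ) -> "ClassifierConfig":
        if algorithm not in _DEFAULTS:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        geom, hp = _DEFAULTS[algorithm]
        params = dict(hp)
        params.update(overrides)
        return cls(
            algorithm=algorithm,
            geometry=geometry if geometry is not None else geom,
            hyperparameters=params,
            seed=seed,
        )

    @property
    def name(self) -> str:
        """Short display name, e.g. ``SVM-6-4`` / ``RF-12-12`` / ``DT-4-2``."""
        tag = {"svm": "SVM", "random_forest": "RF", "decision_tree": "DT"}
        return f"{tag[self.algorithm]}-{self.geometry.n_left}-{self.geometry.n_right}"

    def build_estimator(self):
        """Construct the (unfitted) scikit-learn estimator."""
        hp = dict(self.hyperparameters)
        if self.algorithm == "svm":
            return NuSVC(
                nu=float(hp.get("nu", 0.536)),
                gamma=float(hp.get("gamma", 2.0 ** -5.5)),
                tol=float(hp.get("tol", 1e-5)),
                kernel=str(hp.get("kernel", "rbf")),
            )
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=int(hp.get("n_estimators", 143)),
                max_features=hp.get("max_features", 4),
                max_depth=hp.get("max_depth", None),
                random_state=self.seed,
                n_jobs=1,
            )
        for key in hp:
            if key in ADVISORY_TREE_KEYS:
                continue
            if key not in ("min_samples_leaf", "ccp_alpha", "criterion", "max_depth"):
                raise ValueError(f"unknown decision_tree hyperparameter {key!r}")
        return DecisionTreeClassifier(
            criterion=str(hp.get("criterion", "entropy")),
            min_samples_leaf=int(hp.get("min_samples_leaf", 5)),
            ccp_alpha=float(hp.get("ccp_alpha", 0.0)),
            max_depth=hp.get("max_depth", None),
            random_state=self.seed,
        )

    @property
    def default_threshold(self) -> float:
        """Native decision point: 0 for the SVM margin, 0.5 for tree votes."""
        return 0.0 if self.algorithm == "svm" else 0.5


class SiteClassifier:
    """A fitted cut-site classifier bound to one window geometry.

    Scores are monotone in cut-site confidence: the signed margin for
    the SVM, the fraction of trees voting positive for the forest, and
    the positive leaf-class proportion for the single tree.  A site is
    called positive when its score is >= ``threshold``.
    """

    def __init__(self, config: ClassifierConfig, estimator, threshold: Optional[float] = None):
        self.config = config
        self.estimator = estimator
        self.threshold = (
            config.default_threshold if threshold is None else float(threshold)
        )

    @property
    def geometry(self) -> WindowGeometry:
        return self.config.geometry

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.geometry.n_features:
            raise ValueError(
                f"feature width {X.shape[1]} does not match classifier geometry "
                f"{self.geometry} ({self.geometry.n_features} features)"
            )
        return X

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous decision score per row (used for ROC construction)."""
        X = self._check_X(X)
        if self.config.algorithm == "svm":
            scores = self.estimator.decision_function(X)
            # orient so larger = more cut-site-like regardless of class order
            if self.estimator.classes_[-1] != 1:
                scores = -scores
            return np.asarray(scores, dtype=np.float64)
        proba = self.estimator.predict_proba(X)
        pos_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return np.asarray(proba[:, pos_col], dtype=np.float64)

    def decision_score(self, v: np.ndarray) -> float:
        return float(self.decision_scores(np.atleast_2d(v))[0])

    def classify(self, X: np.ndarray, threshold: Optional[float] = None) -> np.ndarray:
        """Label rows ±1 by comparing scores against the threshold."""
        thr = self.threshold if threshold is None else threshold
        scores = self.decision_scores(X)
        return np.where(scores >= thr, 1, -1).astype(np.int64)

    def predict_site(
        self,
        protein: ProteinRecord,
        site: CandidateSite,
        padding_policy: PaddingPolicy = PaddingPolicy.PAD,
    ) -> Optional[int]:
        """Classify one site; ``None`` means the member abstains (window
        overran a terminus under the skip policy)."""
        window = extract_window(protein, site, self.geometry, padding_policy)
        if window is None:
            return None
        return int(self.classify(encode(window, self.geometry))[0])

    def __repr__(self) -> str:
        return f"SiteClassifier({self.config.name}, threshold={self.threshold})"


def train(ds: LabeledDataset, config: ClassifierConfig) -> SiteClassifier:
    """Fit a site classifier on a labeled dataset.

    The dataset geometry must equal the config geometry and both classes
    must be present.  Tree methods are reproducible under
    ``config.seed``; the ν-SVM solver is deterministic.
    """
    if ds.geometry != config.geometry:
        raise ValueError(
            f"dataset geometry {ds.geometry} != config geometry {config.geometry}"
        )
    classes = set(np.unique(ds.y))
    if classes != {-1, 1}:
        raise ValueError(
            f"training requires both classes; got labels {sorted(classes)}"
        )
    est = config.build_estimator()
    try:
        est.fit(ds.X, ds.y)
    except ValueError as exc:
        # NuSVC raises when nu is infeasible for the class balance
        raise RuntimeError(
            f"training {config.name} failed: {exc}"
        ) from exc
    return SiteClassifier(config, est)


class VoteClassifier:
    """Strict-majority ensemble over fitted site classifiers.

    A site is positive only when strictly more than half of the members
    vote positive; abstentions (unresolvable windows under skip
    padding) count as negative votes.  With one member the Vote is that
    member; with the default SVM+RF pair both must agree.
    """

    def __init__(self, members: Sequence[SiteClassifier]):
        if not members:
            raise ValueError("VoteClassifier needs at least one member")
        self.members = list(members)

    @property
    def name(self) -> str:
        return "Vote(" + "+".join(m.config.name for m in self.members) + ")"

    def predict_site(
        self,
        protein: ProteinRecord,
        site: CandidateSite,
        padding_policy: PaddingPolicy = PaddingPolicy.PAD,
    ) -> int:
        votes = [m.predict_site(protein, site, padding_policy) for m in self.members]
        return combine_votes(votes, len(self.members))

    def predict_sites(
        self,
        protein: ProteinRecord,
        sites: Sequence[CandidateSite],
        padding_policy: PaddingPolicy = PaddingPolicy.PAD,
    ) -> np.ndarray:
        """Vectorized majority vote over many sites of one protein."""
        if not sites:
            return np.zeros(0, dtype=np.int64)
        n = len(sites)
        positive_votes = np.zeros(n, dtype=np.int64)
        for member in self.members:
            rows = []
            resolved = []
            for j, site in enumerate(sites):
                window = extract_window(protein, site, member.geometry, padding_policy)
                if window is None:
                    continue  # abstain -> no positive vote
                rows.append(window)
                resolved.append(j)
            if rows:
                from .encoding import encode_windows

                labels = member.classify(encode_windows(rows))
                for j, lab in zip(resolved, labels):
                    if lab == 1:
                        positive_votes[j] += 1
        majority = len(self.members) / 2.0
        return np.where(positive_votes > majority, 1, -1).astype(np.int64)

    def __repr__(self) -> str:
        return self.name


def combine_votes(votes: Sequence[Optional[int]], n_members: int) -> int:
    """Strict-majority rule; ``None`` (abstention) counts as a negative vote."""
    positive = sum(1 for v in votes if v == 1)
    return 1 if positive > n_members / 2.0 else -1


def vote_predict(
    vc: VoteClassifier,
    protein: ProteinRecord,
    site: CandidateSite,
    padding_policy: PaddingPolicy = PaddingPolicy.PAD,
) -> int:
    """Functional wrapper: strict-majority label for one site."""
    return vc.predict_site(protein, site, padding_policy)


@dataclass
class GridCell:
    geometry: WindowGeometry
    hyperparameters: dict
    accuracy: float
    n_samples: int


def grid_search(
    proteins: Sequence[ProteinRecord],
    positive_sites: Mapping[str, Sequence[int]],
    algorithm: str,
    *,
    geometries: Optional[Sequence[WindowGeometry]] = None,
    param_grid: Optional[Sequence[Mapping[str, object]]] = None,
    seed: int = DEFAULT_SEED,
    negative_policy: str = "balanced",
    padding_policy: PaddingPolicy = PaddingPolicy.SKIP,
) -> tuple[ClassifierConfig, list[GridCell]]:
    """Select window geometry + hyperparameters by leave-one-out accuracy.

    Every (geometry, hyperparameter) cell is scored by LOO accuracy on
    the dataset rebuilt at that geometry (the site list and negative
    sample are fixed once, so cells differ only in their windows).
    Returns the argmax config and the full per-cell table.  Ties break
    toward the smaller total window, then grid order.
    """
    from .dataset import assemble_sites
    from .evaluation import leave_one_out

    if geometries is None:
        from .encoding import GRID_N_LEFT, GRID_N_RIGHT

        geometries = [
            WindowGeometry(l, r) for l in GRID_N_LEFT for r in GRID_N_RIGHT
        ]
    if param_grid is None:
        param_grid = [dict(_DEFAULTS[algorithm][1])]
    if not geometries or not param_grid:
        raise ValueError("grid must be nonempty")

    sites = assemble_sites(
        proteins, positive_sites, negative_policy=negative_policy, seed=seed
    )
    cells: list[GridCell] = []
    best: Optional[tuple] = None
    best_config: Optional[ClassifierConfig] = None
    for gi, geom in enumerate(geometries):
        ds = build_dataset(
            proteins,
            positive_sites,
            geom,
            sites=sites,
            padding_policy=padding_policy,
            provenance="grid-search",
        )
        for pi, params in enumerate(param_grid):
            config = ClassifierConfig(
                algorithm=algorithm,
                geometry=geom,
                hyperparameters=dict(params),
                seed=seed,
            )
            counts = leave_one_out(ds, config)
            acc = (counts.tp + counts.tn) / counts.total
            cells.append(GridCell(geom, dict(params), acc, len(ds)))
            # maximize accuracy; ties -> smaller window, then grid order
            key = (-acc, geom.width, gi, pi)
            if best is None or key < best:
                best = key
                best_config = config
    assert best_config is not None
    return best_config, cells


_FORMAT_VERSION = 1


def save_model(
    clf: Union[SiteClassifier, VoteClassifier], path: Union[str, Path]
) -> None:
    """Persist a classifier (joblib bundle + JSON metadata sidecar)."""
    path = Path(path)

    def config_meta(c: ClassifierConfig) -> dict:
        return {
            "algorithm": c.algorithm,
            "geometry": {"n_left": c.geometry.n_left, "n_right": c.geometry.n_right},
            "hyperparameters": {
                k: (v if isinstance(v, (int, float, str, bool, type(None))) else repr(v))
                for k, v in dict(c.hyperparameters).items()
            },
            "seed": c.seed,
        }

    if isinstance(clf, VoteClassifier):
        payload = {
            "format_version": _FORMAT_VERSION,
            "kind": "vote",
            "members": [
                {"config": m.config, "estimator": m.estimator, "threshold": m.threshold}
                for m in clf.members
            ],
        }
        meta = {
            "kind": "vote",
            "members": [config_meta(m.config) for m in clf.members],
        }
    else:
        payload = {
            "format_version": _FORMAT_VERSION,
            "kind": "single",
            "config": clf.config,
            "estimator": clf.estimator,
            "threshold": clf.threshold,
        }
        meta = {"kind": "single", **config_meta(clf.config), "threshold": clf.threshold}
    meta["format_version"] = _FORMAT_VERSION
    meta["sklearn_version"] = sklearn.__version__
    joblib.dump(payload, path)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: Union[str, Path]) -> Union[SiteClassifier, VoteClassifier]:
    """Load a persisted classifier; predictions are identical to pre-save."""
    path = Path(path)
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(
            f"model file {path} has format version {version!r}, expected "
            f"{_FORMAT_VERSION}"
        )
    meta_path = path.with_suffix(path.suffix + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("sklearn_version") != sklearn.__version__:
            warnings.warn(
                f"model {path.name} was saved with scikit-learn "
                f"{meta.get('sklearn_version')}, running {sklearn.__version__}"
            )
    if payload["kind"] == "vote":
        return VoteClassifier(
            [
                SiteClassifier(m["config"], m["estimator"], m["threshold"])
                for m in payload["members"]
            ]
        )
    return SiteClassifier(payload["config"], payload["estimator"], payload["threshold"])
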