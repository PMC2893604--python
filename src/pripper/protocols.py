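"""End-to-end evaluation protocols on the synthetic benchmark corpus.

`run_benchmark` reproduces the full study design in one call: build a
balanced cut-site collection (default 400 positives + 400 negatives,
mirroring the scale of curated caspase substrate sets), run the
leave-one-out protocol for each classifier at its published
configuration, combine the SVM and RF into the strict-majority Vote,
compute LOO-score ROC curves, and run the fixed-threshold bootstrap
comparison.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classifiers import ClassifierConfig, SiteClassifier, VoteClassifier, train
from .dataset import (
    LabeledDataset,
    assemble_sites,
    build_dataset,
    generate_synthetic_corpus,
)
from .encoding import CandidateSite, Label
from .evaluation import (
    BootstrapPoint,
    ConfusionCounts,
    LooResult,
    QualityMeasures,
    bootstrap_compare,
    loo_predict,
    quality_measures,
    roc_from_scores,
)
from .sequence_io import ProteinRecord

DEFAULT_ALGORITHMS = ("svm", "random_forest", "decision_tree")


def benchmark_sites(
    seed: int,
    n_per_class: int = 400,
    n_proteins: int = 380,
) -> tuple[list[ProteinRecord], list[CandidateSite]]:
    """Synthetic corpus plus a balanced labeled site list.

    Generates planted-motif proteins, truncates the positives to
    ``n_per_class`` (in protein order) and samples the same number of
    non-cut Asp negatives.  The corpus size is chosen so the expected
    positive yield comfortably exceeds the target.
    """
    proteins, positive_sites = generate_synthetic_corpus(
        n_proteins=n_proteins, seed=seed
    )
    kept: dict[str, list[int]] = {}
    total = 0
    for protein in proteins:
        if protein.id not in positive_sites:
            continue
        take = positive_sites[protein.id][: max(0, n_per_class - total)]
        if take:
            kept[protein.id] = take
            total += len(take)
        if total >= n_per_class:
            break
    if total < n_per_class:
        raise RuntimeError(
            f"corpus yielded only {total} positive sites; increase n_proteins"
        )
    sites = assemble_sites(proteins, kept, negative_policy="balanced", seed=seed)
    return proteins, sites


def align_loo_predictions(
    results: dict[str, tuple[LabeledDataset, LooResult]]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Restrict per-classifier LOO predictions to their shared sites.

    Classifiers use different window geometries, so each dataset may
    have dropped different near-terminal or duplicate sites; the
    intersection (keyed by protein and P1 position) makes their
    predictions comparable sample-by-sample.
    """
    common: Optional[set] = None
    for ds, _ in results.values():
        keys = {(s.protein_id, s.p1_position) for s in ds.sites}
        common = keys if common is None else common & keys
    assert common is not None
    aligned: dict[str, np.ndarray] = {}
    y_ref: Optional[np.ndarray] = None
    for name, (ds, result) in results.items():
        order = sorted(
            (i for i, s in enumerate(ds.sites)
             if (s.protein_id, s.p1_position) in common),
            key=lambda i: (ds.sites[i].protein_id, ds.sites[i].p1_position),
        )
        aligned[name] = result.predictions[order]
        y = ds.y[order]
        if y_ref is None:
            y_ref = y
        elif not np.array_equal(y_ref, y):
            raise AssertionError("aligned labels disagree between classifiers")
    return y_ref, aligned


@dataclass
class BenchmarkResult:
    proteins: list[ProteinRecord]
    sites: list[CandidateSite]
    datasets: dict[str, LabeledDataset]
    loo: dict[str, LooResult]
    measures: dict[str, QualityMeasures]
    auc: dict[str, float]
    vote_measures: Optional[QualityMeasures]
    n_aligned: int = 0
    bootstrap: dict[str, BootstrapPoint] = field(default_factory=dict)
    fitted: dict[str, SiteClassifier] = field(default_factory=dict)
    vote: Optional[VoteClassifier] = None

    def accuracy(self, name: str) -> float:
        return self.measures[name].acc


def run_benchmark(
    seed: int,
    *,
    n_per_class: int = 400,
    algorithms: Sequence[str] = DEFAULT_ALGORITHMS,
    n_boot: int = 10_000,
    vote_members: Sequence[str] = ("svm", "random_forest"),
) -> BenchmarkResult:
    """LOO-evaluate every classifier and the Vote on one balanced corpus."""
    proteins, sites = benchmark_sites(seed, n_per_class=n_per_class)
    datasets: dict[str, LabeledDataset] = {}
    loo: dict[str, LooResult] = {}
    measures: dict[str, QualityMeasures] = {}
    auc: dict[str, float] = {}
    fitted: dict[str, SiteClassifier] = {}
    for algorithm in algorithms:
        config = ClassifierConfig.default(algorithm, seed=seed % (2**31))
        ds = build_dataset(
            proteins, {}, config.geometry, sites=sites,
            provenance=f"benchmark(seed={seed})",
        )
        result = loo_predict(ds, config)
        datasets[algorithm] = ds
        loo[algorithm] = result
        measures[algorithm] = quality_measures(result.counts)
        auc[algorithm] = roc_from_scores(result.y_true, result.scores).auc
        fitted[algorithm] = train(ds, config)

    vote_measures = None
    bootstrap: dict[str, BootstrapPoint] = {}
    vote = None
    n_aligned = 0
    members_present = [a for a in vote_members if a in loo]
    if len(members_present) >= 2:
        y_ref, aligned = align_loo_predictions(
            {a: (datasets[a], loo[a]) for a in members_present}
        )
        votes = np.sum([aligned[a] == 1 for a in members_present], axis=0)
        vote_pred = np.where(votes > len(members_present) / 2, 1, -1)
        n_aligned = int(y_ref.shape[0])
        vote_measures = quality_measures(
            ConfusionCounts.from_labels(y_ref, vote_pred)
        )
        if n_boot:
            # bootstrap over the aligned sites, LOO predictions fixed
            ref = datasets[members_present[0]]
            common_keys = set.intersection(*[
                {(s.protein_id, s.p1_position) for s in datasets[a].sites}
                for a in members_present
            ])
            sel = sorted(
                (i for i, s in enumerate(ref.sites)
                 if (s.protein_id, s.p1_position) in common_keys),
                key=lambda i: (ref.sites[i].protein_id, ref.sites[i].p1_position),
            )
            ds_aligned = ref.subset(sel, provenance="benchmark-aligned")
            preds = dict(aligned)
            preds["vote"] = vote_pred
            bootstrap = bootstrap_compare(
                {name: None for name in preds},
                ds_aligned,
                n_boot=n_boot,
                seed=seed,
                predictions=preds,
            )
        vote = VoteClassifier([fitted[a] for a in members_present])
    return BenchmarkResult(
        proteins=proteins,
        sites=sites,
        datasets=datasets,
        loo=loo,
        measures=measures,
        auc=auc,
        vote_measures=vote_measures,
        n_aligned=n_aligned,
        bootstrap=bootstrap,
        fitted=fitted,
        vote=vote,
    )
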