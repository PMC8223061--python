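"""Independent-cohort validation of a fixed gene set, plus 2-D embeddings.

A gene set selected on one cohort is only useful if the committee it defines
transfers to data it has never seen. ``evaluate_independent`` trains the
one-vs-one linear-SVM committee once on the training matrix restricted to
the panel and applies it to every sample of the test matrix
(``mode="transfer"``); ``mode="refit_cv"`` instead cross-validates the fixed
panel inside the test cohort, for comparison with pipelines that re-fit.

Because training and validation cohorts typically come from different array
platforms, per-gene z-scoring of each dataset independently
(``harmonize="zscore"``, the default) removes platform-level location/scale
shifts before the committee is applied.

t-SNE embeddings are quality control only: no classification decision is
made from the coordinates. A silhouette score of the embedding against the
labels turns "clearly separated clusters" into an objective scalar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .expression_io import ExpressionMatrix, SubgroupLabels, align_to_gene_set
from .sarc_core import (
    DEFAULT_C,
    EvaluationResult,
    _empty_confusion,
    _fit_committee,
    _predict_committee,
    confusion_metrics,
    cross_validate,
)

__all__ = [
    "EmbeddingResult",
    "evaluate_independent",
    "compute_metrics",
    "tsne_embed",
    "DEFAULT_PERPLEXITY",
    "DEFAULT_TSNE_ITERATIONS",
]

#: t-SNE defaults for cohort-scale QC plots.
DEFAULT_PERPLEXITY: float = 30.0
DEFAULT_TSNE_ITERATIONS: int = 1000


def _zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    values = m.data.to_numpy()
    center = values.mean(axis=1, keepdims=True)
    scale = values.std(axis=1, ddof=0, keepdims=True)
    scale = np.where(scale == 0.0, 1.0, scale)
    return ExpressionMatrix(
        pd.DataFrame((values - center) / scale, index=m.gene_ids, columns=m.sample_ids)
    )


def evaluate_independent(
    train_m: ExpressionMatrix,
    train_labels: SubgroupLabels,
    genes,
    test_m: ExpressionMatrix,
    test_labels: SubgroupLabels,
    C: float = DEFAULT_C,
    *,
    mode: str = "transfer",
    harmonize: str | None = "zscore",
    folds: int = 10,
    seed: int = 0,
) -> EvaluationResult:
    """Apply a fixed gene set trained on one cohort to an independent one.

    Both matrices are aligned strictly to ``genes``. Every class present in
    the test labels must also be present in training. The confusion matrix
    rows are test-set truth, columns committee predictions.
    """
    if mode not in {"transfer", "refit_cv"}:
        raise ValueError("mode must be 'transfer' or 'refit_cv'")
    if harmonize not in {None, "zscore"}:
        raise ValueError("harmonize must be None or 'zscore'")

    test_sub = align_to_gene_set(test_m, list(genes), policy="strict")
    test_ids = [s for s in test_sub.sample_ids if s in test_labels.assignments]
    test_sub = ExpressionMatrix(test_sub.data[test_ids])
    test_lab = test_labels.subset(test_ids)

    if mode == "refit_cv":
        return cross_validate(test_sub, test_lab, list(genes), folds=folds, seed=seed, C=C)

    train_sub = align_to_gene_set(train_m, list(genes), policy="strict")
    train_ids = [s for s in train_sub.sample_ids if s in train_labels.assignments]
    train_sub = ExpressionMatrix(train_sub.data[train_ids])
    train_lab = train_labels.subset(train_ids)

    missing_classes = set(test_lab.classes) - set(train_lab.classes)
    if missing_classes:
        raise ValueError(
            f"test classes absent from training data: {sorted(missing_classes)}"
        )

    if harmonize == "zscore":
        train_sub = _zscore_rows(train_sub)
        test_sub = _zscore_rows(test_sub)
        standardize = False  # each cohort already on a common per-gene scale
    else:
        standardize = True

    models = _fit_committee(train_sub, train_lab, C, standardize)
    pred = _predict_committee(models, test_sub)
    classes = train_lab.classes
    confusion = _empty_confusion(classes)
    for s in test_ids:
        confusion.loc[test_lab.assignments[s], pred[s]] += 1
    return EvaluationResult.from_confusion(confusion, folds=1, seed=seed)


def compute_metrics(confusion: pd.DataFrame):
    """Accuracy and per-class (sensitivity, specificity) from a confusion
    matrix (truth in rows, prediction in columns).

    ``sensitivity(c) = TP_c / (TP_c + FN_c)``,
    ``specificity(c) = TN_c / (TN_c + FP_c)``; a class with zero truth
    samples reports sensitivity as NaN rather than 0.
    """
    return confusion_metrics(confusion)


@dataclass
class EmbeddingResult:
    """A 2-D t-SNE embedding with the parameters actually used."""

    sample_ids: list[str]
    coordinates: np.ndarray  # n x 2
    parameters: dict[str, object]
    silhouette: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates, index=self.sample_ids, columns=["tsne1", "tsne2"]
        )


def tsne_embed(
    m: ExpressionMatrix,
    genes,
    labels: SubgroupLabels,
    perplexity: float = DEFAULT_PERPLEXITY,
    iterations: int = DEFAULT_TSNE_ITERATIONS,
    seed: int = 0,
) -> EmbeddingResult:
    """Embed samples in 2-D with t-SNE on a gene panel, for visual QC.

    Genes are z-scored before embedding so panels mixing bright and dim
    genes are not dominated by absolute intensity. The requested perplexity
    is clamped to ``(n_samples - 1) / 3`` (t-SNE's feasibility bound) with a
    warning recorded in the returned parameters; the run is deterministic
    given ``seed``. The silhouette of the embedded coordinates against the
    labels summarizes class separation (NaN when fewer than 2 classes).
    """
    sub = align_to_gene_set(m, list(genes), policy="strict")
    ids = [s for s in sub.sample_ids if s in labels.assignments]
    sub = ExpressionMatrix(sub.data[ids])
    n = sub.n_samples
    if n < 4:
        raise ValueError(f"t-SNE needs at least 4 samples, got {n}")
    effective = min(float(perplexity), (n - 1) / 3.0)
    clamped = effective < perplexity
    if clamped:
        warnings.warn(
            f"perplexity {perplexity} infeasible for n={n}; clamped to {effective:.3g}",
            stacklevel=2,
        )
    x = _zscore_rows(sub).values.T  # samples x genes
    tsne = TSNE(
        n_components=2,
        perplexity=effective,
        max_iter=iterations,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(x)
    y = [labels.assignments[s] for s in ids]
    sil = (
        float(silhouette_score(coords, y)) if len(set(y)) >= 2 else float("nan")
    )
    return EmbeddingResult(
        sample_ids=ids,
        coordinates=np.asarray(coords, dtype=float),
        parameters={
            "perplexity_requested": float(perplexity),
            "perplexity_used": float(effective),
            "perplexity_clamped": clamped,
            "iterations": int(iterations),
            "seed": int(seed),
        },
        silhouette=sil,
    )
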