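"""SVM attribute ranking and combinations (SARC) for minimal gene-set selection.

The method distinguishes the four medulloblastoma subgroups with as few
genes as possible. It runs in five steps:

1. train one linear soft-margin SVM per unordered subgroup pair (six models
   for four classes);
2. score every gene in each pairwise model by its squared weight ``w**2``
   and rank genes per model (rank 1 = largest squared weight);
3. for each subgroup, aggregate by summing the gene's ranks over the
   pairwise models involving that subgroup — the ascending order of these
   rank sums is the subgroup's top-attribute list;
4. enumerate candidate gene sets as the union of the top-``k`` genes of each
   subgroup, over a grid of per-subgroup ``k`` values (default 0..12);
5. evaluate every candidate with stratified k-fold cross-validation of a
   one-vs-one linear-SVM committee and keep, per attained accuracy level,
   the smallest set — the accuracy/size frontier.

Attribute ranks are recomputed inside every cross-validation training split
by default (``rank_scope="per_fold"``) so the reported accuracy is not
inflated by selecting genes on the very samples used to test them; a
``"global"`` scope (rank once on the full matrix) is also available for
comparison with pipelines that rank up front.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .expression_io import (
    CLASS_ORDER,
    ExpressionMatrix,
    SubgroupLabels,
    align_to_gene_set,
)

__all__ = [
    "PairwiseModel",
    "AttributeRanking",
    "AggregatedRanking",
    "GeneSetCandidate",
    "EvaluationResult",
    "SarcReport",
    "train_pairwise",
    "squared_weight_scores",
    "rank_attributes",
    "aggregate_ranks",
    "enumerate_combinations",
    "cross_validate",
    "select_frontier",
    "run_sarc",
    "confusion_metrics",
    "load_panel",
    "NANOSTRING_22_PANEL",
    "SIX_GENE_PANEL",
]

#: Default soft-margin regularization, matching the common default of
#: sequential-minimal-optimization SVM implementations.
DEFAULT_C: float = 1.0

#: Default cross-validation fold count.
DEFAULT_FOLDS: int = 10

#: Default per-subgroup top-attribute range for the combination grid.
DEFAULT_K_MAX: int = 12


def load_panel(name: str) -> list[str]:
    """Load a packaged gene panel ("nanostring22" or "six_gene")."""
    fname = {"nanostring22": "nanostring22_panel.txt", "six_gene": "six_gene_panel.txt"}
    if name not in fname:
        raise KeyError(f"unknown panel {name!r}; available: {sorted(fname)}")
    text = resources.files("mbsarc.data").joinpath(fname[name]).read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def _panel_or_empty(name: str) -> list[str]:
    try:
        return load_panel(name)
    except (FileNotFoundError, ModuleNotFoundError):  # pragma: no cover
        return []


NANOSTRING_22_PANEL: tuple[str, ...] = tuple(_panel_or_empty("nanostring22"))
SIX_GENE_PANEL: tuple[str, ...] = tuple(_panel_or_empty("six_gene"))


# ---------------------------------------------------------------------------
# step 1: pairwise linear SVMs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseModel:
    """One linear maximum-margin model for one subgroup pair.

    The decision value for a sample ``x`` is ``w . z(x) + b`` where ``z`` is
    the identity when ``standardize`` is off and the per-gene z-score (with
    the stored training mean/scale) when it is on. Positive decision values
    vote for the *second* class of the canonically sorted pair.
    """

    class_pair: tuple[str, str]
    gene_ids: tuple[str, ...]
    weights: np.ndarray
    bias: float
    C: float
    standardize: bool
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def decision_values(self, m: ExpressionMatrix) -> pd.Series:
        """w.x + b per sample of ``m`` (genes aligned strictly)."""
        sub = align_to_gene_set(m, list(self.gene_ids), policy="strict")
        x = sub.values.T  # samples x genes
        if self.standardize:
            x = (x - self.center) / self.scale
        return pd.Series(x @ self.weights + self.bias, index=sub.sample_ids)


def _sort_pair(pair: Sequence[str]) -> tuple[str, str]:
    a, b = pair
    for c in (a, b):
        if c not in CLASS_ORDER:
            raise ValueError(f"unknown class {c!r}")
    if a == b:
        raise ValueError("a pairwise model needs two distinct classes")
    first, second = sorted((a, b), key=CLASS_ORDER.index)
    return first, second


def train_pairwise(
    m: ExpressionMatrix,
    labels: SubgroupLabels,
    pair: Sequence[str],
    C: float = DEFAULT_C,
    *,
    standardize: bool = True,
) -> PairwiseModel:
    """Fit the linear soft-margin SVM separating one subgroup pair.

    Features are optionally z-scored per gene using the training samples
    only (constant genes get unit scale so they contribute nothing). The
    solution is the deterministic libsvm optimum at regularization ``C``.
    """
    first, second = _sort_pair(pair)
    cols_first = [s for s in m.sample_ids if labels.assignments.get(s) == first]
    cols_second = [s for s in m.sample_ids if labels.assignments.get(s) == second]
    if not cols_first or not cols_second:
        empty = first if not cols_first else second
        raise ValueError(f"class {empty!r} has no samples in the matrix")

    x = m.data[cols_first + cols_second].to_numpy().T  # samples x genes
    y = np.array([0] * len(cols_first) + [1] * len(cols_second))
    if np.allclose(x, x[0]):
        raise ValueError("all samples are identical; no separating information")

    center = scale = None
    if standardize:
        center = x.mean(axis=0)
        scale = x.std(axis=0, ddof=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        x = (x - center) / scale

    svc = SVC(kernel="linear", C=C)
    svc.fit(x, y)
    return PairwiseModel(
        class_pair=(first, second),
        gene_ids=tuple(m.gene_ids),
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        standardize=standardize,
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# step 2: squared-weight scoring and ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeRanking:
    """Per-pair gene ranking by squared SVM weight (rank 1 = largest)."""

    class_pair: tuple[str, str]
    scores: dict[str, float]
    ranks: dict[str, int]

    @property
    def ordered_genes(self) -> list[str]:
        return sorted(self.ranks, key=self.ranks.__getitem__)


def squared_weight_scores(model: PairwiseModel) -> dict[str, float]:
    """Gene -> w**2 for one pairwise model (sign-free discriminative score)."""
    return {g: float(w) ** 2 for g, w in zip(model.gene_ids, model.weights)}


def rank_attributes(
    scores: Mapping[str, float], class_pair: tuple[str, str] = ("WNT", "SHH")
) -> AttributeRanking:
    """Rank genes by descending score; ties broken by lexicographic gene ID.

    The result is always a permutation of ``1..n``.
    """
    if not scores:
        raise ValueError("cannot rank an empty score map")
    order = sorted(scores, key=lambda g: (-scores[g], g))
    ranks = {g: i + 1 for i, g in enumerate(order)}
    return AttributeRanking(class_pair=class_pair, scores=dict(scores), ranks=ranks)


# ---------------------------------------------------------------------------
# step 3: per-subgroup rank aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregatedRanking:
    """Rank sums for one subgroup over the pairwise models involving it."""

    subgroup: str
    total_rank: dict[str, int]
    top_list: list[str]


def aggregate_ranks(
    subgroup: str, rankings: Sequence[AttributeRanking]
) -> AggregatedRanking:
    """Sum a gene's ranks over the pairwise models involving ``subgroup``.

    With four classes each subgroup appears in exactly three pairs; with
    ``n`` classes, in ``n - 1``. Lower rank sums mark genes that are
    consistently discriminative for the subgroup; the top list is ordered by
    ascending rank sum, ties by gene ID.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    universe = set(rankings[0].ranks)
    for r in rankings:
        if subgroup not in r.class_pair:
            raise ValueError(
                f"ranking for pair {r.class_pair} does not involve {subgroup!r}"
            )
        if set(r.ranks) != universe:
            raise ValueError("rankings do not share one gene universe")
    pairs = {r.class_pair for r in rankings}
    if len(pairs) != len(rankings):
        raise ValueError("duplicate pairwise rankings supplied")
    total = {g: sum(r.ranks[g] for r in rankings) for g in universe}
    top = sorted(total, key=lambda g: (total[g], g))
    return AggregatedRanking(subgroup=subgroup, total_rank=total, top_list=top)


# ---------------------------------------------------------------------------
# step 4: combination enumeration
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCandidate:
    """One k-vector over subgroups with the union of their top-k genes."""

    k_per_subgroup: dict[str, int]
    genes: tuple[str, ...]
    evaluation: "EvaluationResult | None" = None

    @property
    def size(self) -> int:
        return len(self.genes)


def _union_top_k(
    top_lists: Mapping[str, Sequence[str]], k_vec: Mapping[str, int]
) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for cls in (c for c in CLASS_ORDER if c in top_lists):
        for g in top_lists[cls][: k_vec.get(cls, 0)]:
            seen.setdefault(g, None)
    return tuple(seen)


def enumerate_combinations(
    top_lists: Mapping[str, Sequence[str]],
    k_grid: Mapping[str, Iterable[int]] | None = None,
    k_max: int = DEFAULT_K_MAX,
    *,
    max_candidates: int | None = None,
) -> list[GeneSetCandidate]:
    """Enumerate candidate gene sets over the per-subgroup top-k grid.

    One candidate per element of the Cartesian product of the allowed ``k``
    values, excluding the all-zero vector; each candidate's gene set is the
    de-duplicated union of the top-``k`` genes of each subgroup. The list is
    deterministic (classes in canonical order, ``k`` ascending) and
    duplicate-free by k-vector.
    """
    classes = [c for c in CLASS_ORDER if c in top_lists]
    if not classes:
        raise ValueError("top_lists is empty")
    if k_grid is None:
        k_grid = {c: range(k_max + 1) for c in classes}
    grids: list[list[int]] = []
    for cls in classes:
        ks = sorted(set(k_grid.get(cls, (0,))))
        for k in ks:
            if k < 0:
                raise ValueError(f"negative k for {cls}")
            if k > k_max:
                raise ValueError(f"k={k} for {cls} exceeds k_max={k_max}")
            if k > len(top_lists[cls]):
                raise ValueError(
                    f"k={k} for {cls} exceeds its top-list length {len(top_lists[cls])}"
                )
        grids.append(ks)
    n_total = int(np.prod([len(g) for g in grids]))
    if max_candidates is not None and n_total - 1 > max_candidates:
        raise ValueError(
            f"{n_total - 1} candidates exceed max_candidates={max_candidates}; "
            "shrink the k grid"
        )
    candidates = []
    for combo in itertools.product(*grids):
        if all(k == 0 for k in combo):
            continue
        k_vec = dict(zip(classes, combo))
        candidates.append(
            GeneSetCandidate(k_per_subgroup=k_vec, genes=_union_top_k(top_lists, k_vec))
        )
    return candidates


# ---------------------------------------------------------------------------
# committee prediction and metrics
# ---------------------------------------------------------------------------

def _fit_committee(
    m: ExpressionMatrix,
    labels: SubgroupLabels,
    C: float,
    standardize: bool,
) -> list[PairwiseModel]:
    classes = labels.classes
    if len(classes) < 2:
        raise ValueError("committee needs at least 2 classes")
    return [
        train_pairwise(m, labels, (a, b), C, standardize=standardize)
        for a, b in itertools.combinations(classes, 2)
    ]


def _predict_committee(
    models: Sequence[PairwiseModel], m: ExpressionMatrix
) -> pd.Series:
    """One-vs-one majority vote; ties by largest summed signed margin, then
    canonical class order."""
    classes = sorted(
        {c for md in models for c in md.class_pair}, key=CLASS_ORDER.index
    )
    votes = pd.DataFrame(0, index=m.sample_ids, columns=classes, dtype=int)
    margin = pd.DataFrame(0.0, index=m.sample_ids, columns=classes)
    for md in models:
        first, second = md.class_pair
        d = md.decision_values(m)
        winner = np.where(d > 0, second, first)
        for cls in (first, second):
            votes.loc[winner == cls, cls] += 1
        # signed margin toward each class of the pair
        margin[second] += d
        margin[first] -= d
    predictions = []
    for s in m.sample_ids:
        v = votes.loc[s]
        best = v.max()
        tied = [c for c in classes if v[c] == best]
        if len(tied) > 1:
            mg = margin.loc[s, tied]
            tied = [c for c in tied if mg[c] == mg.max()]
        predictions.append(tied[0])  # canonical order settles residual ties
    return pd.Series(predictions, index=m.sample_ids)


def confusion_metrics(
    confusion: pd.DataFrame,
) -> tuple[float, dict[str, tuple[float, float]]]:
    """Accuracy and per-class (sensitivity, specificity) from a confusion
    matrix with truth in rows and prediction in columns.

    Classes with zero truth samples report sensitivity as NaN (undefined),
    never 0.
    """
    conf = confusion.to_numpy()
    if conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (conf < 0).any():
        raise ValueError("confusion matrix entries must be >= 0")
    total = conf.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    accuracy = float(np.trace(conf)) / float(total)
    per_class: dict[str, tuple[float, float]] = {}
    for i, cls in enumerate(confusion.index):
        tp = conf[i, i]
        fn = conf[i, :].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = float(tp) / float(tp + fn) if (tp + fn) > 0 else float("nan")
        spec = float(tn) / float(tn + fp) if (tn + fp) > 0 else float("nan")
        per_class[str(cls)] = (sens, spec)
    return accuracy, per_class


@dataclass
class EvaluationResult:
    """Cross-validated (or held-out) committee performance."""

    confusion: pd.DataFrame  # rows = truth, columns = prediction
    accuracy: float
    per_class: dict[str, tuple[float, float]]
    folds: int
    seed: int

    @classmethod
    def from_confusion(
        cls, confusion: pd.DataFrame, folds: int, seed: int
    ) -> "EvaluationResult":
        accuracy, per_class = confusion_metrics(confusion)
        return cls(
            confusion=confusion,
            accuracy=accuracy,
            per_class=per_class,
            folds=folds,
            seed=seed,
        )


def _stratified_folds(
    labels: SubgroupLabels, sample_ids: Sequence[str], folds: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    y = [labels.assignments[s] for s in sample_ids]
    counts = pd.Series(y).value_counts()
    too_small = counts[counts < folds]
    if len(too_small):
        raise ValueError(
            f"class {too_small.index[0]!r} has {int(too_small.iloc[0])} samples, "
            f"fewer than folds={folds}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ids = np.asarray(sample_ids)
    return [
        (list(ids[tr]), list(ids[te]))
        for tr, te in skf.split(np.zeros(len(ids)), np.asarray(y))
    ]


def _empty_confusion(classes: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)


class _FoldWorkspace:
    """Precomputed fold split views for fast repeated committee evaluation.

    Candidate evaluation trains thousands of tiny SVMs; going through the
    DataFrame-based public API for each would dominate the runtime, so this
    workspace holds the expression values as one ndarray plus per-fold
    train/test index arrays, and evaluates any gene set (possibly a
    different one per fold, for per-fold rank scope) straight on slices.
    The arithmetic (per-pair z-scoring on the pair's training samples,
    libsvm linear fit, vote/margin tie-breaking) mirrors
    :func:`train_pairwise` / the committee predictor exactly.
    """

    def __init__(
        self,
        m: ExpressionMatrix,
        labels: SubgroupLabels,
        folds: int,
        seed: int,
    ) -> None:
        self.classes = labels.classes
        self.gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
        self.values = np.ascontiguousarray(m.data.to_numpy().T)  # samples x genes
        sample_ids = list(m.sample_ids)
        y = np.array([self.classes.index(labels.assignments[s]) for s in sample_ids])
        self.y = y
        self.folds = folds
        self.seed = seed
        splits = _stratified_folds(labels, sample_ids, folds, seed)
        pos = {s: j for j, s in enumerate(sample_ids)}
        self.fold_train_by_class: list[list[np.ndarray]] = []
        self.fold_test: list[np.ndarray] = []
        for train_ids, test_ids in splits:
            tr = np.array([pos[s] for s in train_ids])
            self.fold_train_by_class.append(
                [tr[y[tr] == ci] for ci in range(len(self.classes))]
            )
            self.fold_test.append(np.array([pos[s] for s in test_ids]))

    def evaluate(
        self,
        genes_per_fold: Sequence[Sequence[str]],
        C: float,
        standardize: bool,
    ) -> pd.DataFrame:
        """Accumulate the one-vs-one committee confusion over all folds."""
        n_cls = len(self.classes)
        confusion = np.zeros((n_cls, n_cls), dtype=int)
        for f, genes in enumerate(genes_per_fold):
            cols = np.array([self.gene_pos[g] for g in genes])
            test_idx = self.fold_test[f]
            x_test = self.values[np.ix_(test_idx, cols)]
            votes = np.zeros((len(test_idx), n_cls), dtype=int)
            margin = np.zeros((len(test_idx), n_cls))
            for ia, ib in itertools.combinations(range(n_cls), 2):
                rows_a = self.fold_train_by_class[f][ia]
                rows_b = self.fold_train_by_class[f][ib]
                x = self.values[np.ix_(np.concatenate([rows_a, rows_b]), cols)]
                xt = x_test
                if standardize:
                    center = x.mean(axis=0)
                    scale = x.std(axis=0, ddof=0)
                    scale = np.where(scale == 0.0, 1.0, scale)
                    x = (x - center) / scale
                    xt = (x_test - center) / scale
                y01 = np.concatenate(
                    [np.zeros(len(rows_a), dtype=int), np.ones(len(rows_b), dtype=int)]
                )
                svc = SVC(kernel="linear", C=C)
                svc.fit(x, y01)
                d = xt @ svc.coef_.ravel() + svc.intercept_[0]
                win_b = d > 0
                votes[:, ib] += win_b
                votes[:, ia] += ~win_b
                margin[:, ib] += d
                margin[:, ia] -= d
            for t, si in enumerate(test_idx):
                v = votes[t]
                best = v.max()
                tied = np.flatnonzero(v == best)
                if len(tied) > 1:
                    mg = margin[t, tied]
                    tied = tied[mg == mg.max()]
                confusion[self.y[si], tied[0]] += 1
        return pd.DataFrame(
            confusion, index=list(self.classes), columns=list(self.classes)
        )


def cross_validate(
    m: ExpressionMatrix,
    labels: SubgroupLabels,
    genes: Sequence[str],
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    C: float = DEFAULT_C,
    *,
    standardize: bool = True,
) -> EvaluationResult:
    """Stratified k-fold CV of the one-vs-one committee on a fixed gene set.

    Fold assignment is stratified by class and seeded; within each fold the
    committee (all pairwise linear SVMs over the classes present) is fit on
    the training split restricted to ``genes`` and applied to the held-out
    fold. The confusion matrix accumulates over folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    sub = align_to_gene_set(m, list(genes), policy="strict")
    sample_ids = [s for s in sub.sample_ids if s in labels.assignments]
    sub = ExpressionMatrix(sub.data[sample_ids])
    lab = labels.subset(sample_ids)
    ws = _FoldWorkspace(sub, lab, folds, seed)
    confusion = ws.evaluate([list(genes)] * folds, C, standardize)
    return EvaluationResult.from_confusion(confusion, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# step 5: frontier selection
# ---------------------------------------------------------------------------

#: Accuracy is grouped into levels at 2 decimal places in percent (the
#: reporting precision of the underlying study design, e.g. 98.56%).
ACCURACY_DECIMALS: int = 2


def _rounded_pct(accuracy: float) -> float:
    return round(100.0 * accuracy, ACCURACY_DECIMALS)


def select_frontier(candidates: Sequence[GeneSetCandidate]) -> list[GeneSetCandidate]:
    """Smallest best-performing candidate(s) per attained accuracy level.

    Accuracy levels are the distinct CV accuracies rounded to 2 decimals in
    percent; per level only candidates of minimal gene-set size are kept,
    then any candidate dominated by another frontier member (<= size with >
    accuracy, or < size with >= accuracy) is removed. Ordered by accuracy
    descending, then size ascending, then k-vector.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    for c in candidates:
        if c.evaluation is None:
            raise ValueError("all candidates must be evaluated before selection")
    by_level: dict[float, list[GeneSetCandidate]] = {}
    for c in candidates:
        by_level.setdefault(_rounded_pct(c.evaluation.accuracy), []).append(c)
    per_level: list[GeneSetCandidate] = []
    for level, group in by_level.items():
        smallest = min(c.size for c in group)
        per_level.extend(c for c in group if c.size == smallest)

    def dominated(c: GeneSetCandidate) -> bool:
        ca = _rounded_pct(c.evaluation.accuracy)
        for o in per_level:
            if o is c:
                continue
            oa = _rounded_pct(o.evaluation.accuracy)
            if (o.size <= c.size and oa > ca) or (o.size < c.size and oa >= ca):
                return True
        return False

    frontier = [c for c in per_level if not dominated(c)]
    frontier.sort(
        key=lambda c: (
            -_rounded_pct(c.evaluation.accuracy),
            c.size,
            tuple(c.k_per_subgroup.get(cls, 0) for cls in CLASS_ORDER),
        )
    )
    return frontier


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

@dataclass
class SarcReport:
    """Everything a SARC run produces.

    ``pairwise_rankings`` and ``aggregated`` are computed once on the full
    matrix (they are the interpretable output); candidate *evaluation* uses
    per-fold re-ranking when ``rank_scope`` is ``"per_fold"``.
    """

    pairwise_rankings: dict[tuple[str, str], AttributeRanking]
    aggregated: dict[str, AggregatedRanking]
    candidates: list[GeneSetCandidate]
    frontier: list[GeneSetCandidate]
    config: dict[str, object]

    def rankings_frame(self, top_n: int | None = 50) -> pd.DataFrame:
        rows = []
        for cls, agg in self.aggregated.items():
            genes = agg.top_list if top_n is None else agg.top_list[:top_n]
            for pos, g in enumerate(genes, start=1):
                rows.append(
                    {
                        "subgroup": cls,
                        "position": pos,
                        "gene": g,
                        "rank_sum": agg.total_rank[g],
                    }
                )
        return pd.DataFrame.from_records(rows)

    def frontier_frame(self) -> pd.DataFrame:
        return _candidates_frame(self.frontier)

    def candidates_frame(self) -> pd.DataFrame:
        return _candidates_frame(self.candidates)

    @property
    def best(self) -> GeneSetCandidate:
        return self.frontier[0]


def _candidates_frame(candidates: Sequence[GeneSetCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        ev = c.evaluation
        row = {
            **{f"k_{cls}": c.k_per_subgroup.get(cls, 0) for cls in CLASS_ORDER},
            "n_genes": c.size,
            "genes": ",".join(c.genes),
            "accuracy_pct": _rounded_pct(ev.accuracy) if ev else float("nan"),
        }
        if ev:
            for cls, (sens, spec) in ev.per_class.items():
                row[f"sens_{cls}"] = round(sens, 4)
                row[f"spec_{cls}"] = round(spec, 4)
        rows.append(row)
    return pd.DataFrame.from_records(rows)


def _rank_top_lists(
    m: ExpressionMatrix,
    labels: SubgroupLabels,
    C: float,
    standardize: bool,
) -> tuple[dict[tuple[str, str], AttributeRanking], dict[str, AggregatedRanking]]:
    """Steps 1-3 on one (sub)matrix: pairwise models -> rankings -> rank sums."""
    classes = labels.classes
    rankings: dict[tuple[str, str], AttributeRanking] = {}
    for pair in itertools.combinations(classes, 2):
        model = train_pairwise(m, labels, pair, C, standardize=standardize)
        rankings[model.class_pair] = rank_attributes(
            squared_weight_scores(model), model.class_pair
        )
    aggregated = {
        cls: aggregate_ranks(cls, [r for p, r in rankings.items() if cls in p])
        for cls in classes
    }
    return rankings, aggregated


def run_sarc(
    m: ExpressionMatrix,
    labels: SubgroupLabels,
    *,
    k_max: int = DEFAULT_K_MAX,
    k_grid: Mapping[str, Iterable[int]] | None = None,
    C: float = DEFAULT_C,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    rank_scope: str = "per_fold",
    standardize: bool = True,
    restrict_to: Sequence[str] | None = None,
    max_candidates: int | None = None,
) -> SarcReport:
    """Run SARC steps 1-5 and return the full report.

    ``restrict_to`` subsets the matrix to a fixed input panel first (the
    mode used when the search starts from an established signature such as
    the 22-gene panel). The run is a pure function of its inputs and
    configuration; rerunning with the same seed reproduces the report
    exactly.
    """
    if rank_scope not in {"per_fold", "global"}:
        raise ValueError("rank_scope must be 'per_fold' or 'global'")
    if restrict_to is not None:
        m = align_to_gene_set(m, list(restrict_to), policy="strict")
    sample_ids = [s for s in m.sample_ids if s in labels.assignments]
    m = ExpressionMatrix(m.data[sample_ids])
    lab = labels.subset(sample_ids)
    classes = lab.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes with samples")
    eff_k_max = min(k_max, m.n_genes)

    # interpretable global rankings (steps 1-3 on the full matrix)
    pairwise_rankings, aggregated = _rank_top_lists(m, lab, C, standardize)
    global_top = {cls: aggregated[cls].top_list for cls in classes}

    # step 4: the candidate grid comes from the global lists
    candidates = enumerate_combinations(
        global_top, k_grid, eff_k_max, max_candidates=max_candidates
    )

    # step 5: seeded stratified folds, shared by every candidate
    fold_splits = _stratified_folds(lab, sample_ids, folds, seed)
    fold_top: list[dict[str, list[str]]] = []
    if rank_scope == "per_fold":
        for train_ids, _ in fold_splits:
            _, agg = _rank_top_lists(
                ExpressionMatrix(m.data[train_ids]), lab.subset(train_ids), C, standardize
            )
            fold_top.append({cls: agg[cls].top_list for cls in classes})

    ws = _FoldWorkspace(m, lab, folds, seed)
    for cand in candidates:
        genes_per_fold = [
            _union_top_k(fold_top[f] if rank_scope == "per_fold" else global_top,
                         cand.k_per_subgroup)
            for f in range(folds)
        ]
        confusion = ws.evaluate(genes_per_fold, C, standardize)
        cand.evaluation = EvaluationResult.from_confusion(confusion, folds, seed)

    frontier = select_frontier(candidates)
    config = {
        "k_max": eff_k_max,
        "k_grid": {c: sorted(set(k_grid[c])) for c in k_grid} if k_grid else None,
        "C": C,
        "folds": folds,
        "seed": seed,
        "rank_scope": rank_scope,
        "standardize": standardize,
        "restrict_to": list(restrict_to) if restrict_to is not None else None,
        "classes": list(classes),
        "n_candidates": len(candidates),
    }
    return SarcReport(
        pairwise_rankings=pairwise_rankings,
        aggregated=aggregated,
        candidates=candidates,
        frontier=frontier,
        config=config,
    )
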