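"""Ranking and classification metrics for recruitment prediction.

Covers the full evaluation harness: ROC AUC (Mann–Whitney formulation)
with a stratified-bootstrap percentile confidence interval and standard
quality bands; a sensitivity+specificity cut-off sweep; the
information-retrieval metrics P@5, P@10, average precision and reciprocal
rank with best-possible (Upper) and random-list (Lower) reference values;
and the top-50 overlap with the database-identified candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.stats import rankdata

QUALITY_BANDS = (
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "fair"),
    (0.6, "poor"),
    (0.5, "fail"),
    (0.0, "worse_than_random"),
)


@dataclass
class RankedList:
    """Test-set persons ordered by descending prediction score.

    Ties in score are broken by a seeded random shuffle applied before the
    (stable) sort, so the order is deterministic given ``tie_seed`` but
    unbiased with respect to the original person order.
    """

    person_ids: np.ndarray
    scores: np.ndarray
    relevance: np.ndarray
    db_flags: np.ndarray
    tie_seed: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.relevance = np.asarray(self.relevance, dtype=np.int64)
        self.db_flags = np.asarray(self.db_flags, dtype=np.int64)
        self.person_ids = np.asarray(self.person_ids)
        n = len(self.person_ids)
        if not (len(self.scores) == len(self.relevance) == len(self.db_flags) == n):
            raise ValueError("all ranked-list fields must have equal length")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing along the list")
        if len(np.unique(self.person_ids)) != n:
            raise ValueError("every person must appear exactly once")

    def __len__(self) -> int:
        return len(self.person_ids)


def rank_people(
    person_ids, scores, relevance, db_flags, tie_seed: int = 0
) -> RankedList:
    """Build a :class:`RankedList` by descending score with seeded tie-break."""
    person_ids = np.asarray(person_ids)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(tie_seed)
    perm = rng.permutation(len(scores))
    order = perm[np.argsort(-scores[perm], kind="stable")]
    return RankedList(
        person_ids=person_ids[order],
        scores=scores[order],
        relevance=np.asarray(relevance)[order],
        db_flags=np.asarray(db_flags)[order],
        tie_seed=tie_seed,
    )


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative.

    Mann–Whitney formulation: the mean over all (positive, negative)
    pairs of 1 if the positive scores higher, 0.5 on a tie, else 0; this
    equals the trapezoidal area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_quality_label(auc: float) -> str:
    """Standard interpretation band for an ROC AUC value.

    Half-open bands: [0.9, 1] excellent, [0.8, 0.9) good, [0.7, 0.8) fair,
    [0.6, 0.7) poor, [0.5, 0.6) fail, below 0.5 worse than random.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc must lie in [0, 1], got {auc}")
    for lo, label in QUALITY_BANDS:
        if auc >= lo:
            return label
    return "worse_than_random"


def _auc_matrix(score_rows: np.ndarray, n_pos: int) -> np.ndarray:
    """Row-wise AUC where the first ``n_pos`` columns are the positives."""
    ranks = rankdata(score_rows, axis=1)
    n_neg = score_rows.shape[1] - n_pos
    return (ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def bootstrap_ci(
    scores,
    labels,
    n_replicates: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the ROC AUC.

    By default positives and negatives are resampled separately
    (stratified), so every replicate retains both classes. When either
    stratum has fewer than 2 members the interval is unstable and
    ``(nan, nan)`` is returned as an NA marker rather than raising.
    Deterministic given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels != 1]
    if len(pos_scores) < 2 or len(neg_scores) < 2:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    aucs = np.empty(n_replicates)
    if stratified:
        chunk = max(1, int(2e6 // (n_pos + n_neg)))
        done = 0
        while done < n_replicates:
            m = min(chunk, n_replicates - done)
            p = pos_scores[rng.integers(0, n_pos, size=(m, n_pos))]
            q = neg_scores[rng.integers(0, n_neg, size=(m, n_neg))]
            aucs[done : done + m] = _auc_matrix(np.hstack([p, q]), n_pos)
            done += m
    else:
        n = len(scores)
        filled = 0
        while filled < n_replicates:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if (lab == 1).all() or (lab != 1).all():
                continue  # degenerate replicate, redraw
            aucs[filled] = roc_auc(scores[idx], lab)
            filled += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))


def cutoff_sweep(scores, labels, grid_step: float = 0.01) -> pd.DataFrame:
    """Scaled sensitivity+specificity at each threshold of a [0, 1] grid.

    The performance metric is (sensitivity + specificity) / 2, scaled to
    [0, 1]; any positive affine rescaling leaves the argmax unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cut-off sweep needs both classes present")
    thresholds = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    pred = scores[None, :] >= thresholds[:, None]
    sens = (pred & pos[None, :]).sum(axis=1) / n_pos
    spec = (~pred & ~pos[None, :]).sum(axis=1) / n_neg
    return pd.DataFrame(
        {"threshold": thresholds, "metric": (sens + spec) / 2.0,
         "sensitivity": sens, "specificity": spec}
    )


def optimal_cutoff(
    scores, labels, grid_step: float = 0.01
) -> tuple[float, float]:
    """Smallest grid threshold maximizing scaled sensitivity+specificity."""
    sweep = cutoff_sweep(scores, labels, grid_step)
    i = int(sweep["metric"].to_numpy().argmax())  # argmax takes the first max
    return (float(sweep["threshold"].iloc[i]), float(sweep["metric"].iloc[i]))


def precision_at_k(ranked: RankedList, k: int) -> float:
    """Fraction of the top-k ranked persons who are relevant (recruited)."""
    if len(ranked) < k:
        raise ValueError(f"ranked list of length {len(ranked)} is shorter than k={k}")
    return float(ranked.relevance[:k].sum() / k)


def average_precision(ranked: RankedList) -> float:
    """Mean, over relevant items, of the precision at each relevant rank."""
    rel = ranked.relevance
    n_rel = int(rel.sum())
    if n_rel == 0:
        raise ValueError("average precision is undefined with zero relevant items")
    ranks = np.nonzero(rel)[0] + 1
    hits = np.arange(1, n_rel + 1)
    return float(np.mean(hits / ranks))


def reciprocal_rank(ranked: RankedList) -> float:
    """Reciprocal of the rank of the first relevant person retrieved."""
    rel_positions = np.nonzero(ranked.relevance)[0]
    if len(rel_positions) == 0:
        raise ValueError("reciprocal rank is undefined with zero relevant items")
    return float(1.0 / (rel_positions[0] + 1))


def _metrics_from_ranks(ranks: np.ndarray, list_length: int) -> dict[str, float]:
    """P5/P10/AP/RR from the 1-based ranks of the relevant items."""
    ranks = np.sort(np.asarray(ranks))
    n_rel = len(ranks)
    hits = np.arange(1, n_rel + 1)
    return {
        "p5": float((ranks <= 5).sum() / 5),
        "p10": float((ranks <= 10).sum() / 10),
        "map": float(np.mean(hits / ranks)),
        "mrr": float(1.0 / ranks[0]),
    }


def reference_bounds(
    n_relevant: int, list_length: int, seed: int = 0, n_random_refs: int = 1
) -> dict[str, float]:
    """Upper and Lower reference values for the ranking metrics.

    Upper: the best possible list, with all relevant items at ranks
    1..n_relevant (closed forms: MAP = MRR = 1, P@k = min(n_relevant, k)/k).
    Lower: the metrics of a seeded uniformly random list (averaged over
    ``n_random_refs`` independent realizations).
    """
    if not 1 <= n_relevant <= list_length:
        raise ValueError("need 1 <= n_relevant <= list_length")
    upper = _metrics_from_ranks(np.arange(1, n_relevant + 1), list_length)
    rng = np.random.default_rng(seed)
    lowers = []
    for _ in range(n_random_refs):
        ranks = rng.choice(list_length, size=n_relevant, replace=False) + 1
        lowers.append(_metrics_from_ranks(ranks, list_length))
    lower = {k: float(np.mean([d[k] for d in lowers])) for k in lowers[0]}
    out = {f"upper_{k}": v for k, v in upper.items()}
    out.update({f"lower_{k}": v for k, v in lower.items()})
    return out


def top_k_overlap(ranked: RankedList, k: int = 50) -> float:
    """Proportion of the top-k ranked persons flagged database-identified."""
    if len(ranked) < k:
        raise ValueError(f"ranked list of length {len(ranked)} is shorter than k={k}")
    return float(ranked.db_flags[:k].sum() / k)


@dataclass
class FoldEvaluation:
    """All evaluation metrics for one cross-validation fold."""

    roc_auc: float
    auc_quality: str
    ci_low: float
    ci_high: float
    p5: float
    p10: float
    map: float
    mrr: float
    upper_p5: float
    upper_p10: float
    upper_map: float
    upper_mrr: float
    lower_p5: float
    lower_p10: float
    lower_map: float
    lower_mrr: float
    top50_overlap: float
    optimal_cutoff: float
    cutoff_metric: float
    n_test: int
    n_relevant: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def evaluate_ranked_list(
    ranked: RankedList,
    n_bootstrap: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
    grid_step: float = 0.01,
    n_random_refs: int = 1,
    stratified: bool = True,
) -> FoldEvaluation:
    """Compute every fold metric from one ranked test list."""
    auc = roc_auc(ranked.scores, ranked.relevance)
    ci_low, ci_high = bootstrap_ci(
        ranked.scores,
        ranked.relevance,
        n_replicates=n_bootstrap,
        level=ci_level,
        seed=seed,
        stratified=stratified,
    )
    cutoff, cutoff_metric = optimal_cutoff(ranked.scores, ranked.relevance, grid_step)
    n_rel = int(ranked.relevance.sum())
    refs = reference_bounds(
        n_rel, len(ranked), seed=seed, n_random_refs=n_random_refs
    )
    return FoldEvaluation(
        roc_auc=auc,
        auc_quality=auc_quality_label(auc),
        ci_low=ci_low,
        ci_high=ci_high,
        p5=precision_at_k(ranked, 5),
        p10=precision_at_k(ranked, 10),
        map=average_precision(ranked),
        mrr=reciprocal_rank(ranked),
        top50_overlap=top_k_overlap(ranked, 50),
        optimal_cutoff=cutoff,
        cutoff_metric=cutoff_metric,
        n_test=len(ranked),
        n_relevant=n_rel,
        **refs,
    )


def plot_cutoff_sweep(sweep: pd.DataFrame, path) -> None:
    """Plot scaled sensitivity+specificity against the score cut-off."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep["threshold"], sweep["metric"], lw=1.5)
    best = sweep.loc[sweep["metric"].idxmax()]
    ax.axvline(best["threshold"], color="grey", ls="--", lw=1)
    ax.set_xlabel("prediction score cut-off")
    ax.set_ylabel("scaled sensitivity + specificity")
    ax.set_title(f"optimal cut-off {best['threshold']:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
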