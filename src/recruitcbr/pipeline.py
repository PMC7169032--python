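"""Per-project two-fold cross-validation orchestration and reporting.

For each project the recruited participants are split in half. Each half
in turn trains the target profile and the entity-weight regression; the
other half is hidden inside a large test pool assembled from randomly
drawn registrants plus the database-identified candidates, scored,
ranked, and evaluated. Fold metrics are averaged per project and across
the suite, and predictions are pooled for the cut-off sweep.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .case_profile import build_target_profile
from .evaluation import (
    FoldEvaluation,
    cutoff_sweep,
    evaluate_ranked_list,
    optimal_cutoff,
    rank_people,
)
from .records import apply_inclusion_filter, frame_to_events, group_by_person
from .scoring import (
    SCORE_COLUMNS,
    EntityWeights,
    final_score,
    fit_entity_weights,
    scale_scores,
    score_population,
)

AVERAGED_METRICS = (
    "roc_auc", "ci_low", "ci_high", "p5", "p10", "map", "mrr",
    "upper_p5", "upper_p10", "upper_map", "upper_mrr",
    "lower_p5", "lower_p10", "lower_map", "lower_mrr", "top50_overlap",
)


def derive_seed(master: int, *tokens) -> int:
    """Stable per-stage sub-seed from the master seed and context tokens."""
    h = zlib.crc32("|".join(str(t) for t in tokens).encode())
    return int((master * 1_000_003 + h) % (2**31 - 1))


@dataclass
class PipelineConfig:
    """All analysis knobs in one place; loadable from YAML.

    Defaults mirror the reference analysis: strict four-entity inclusion,
    80% support with a minimum of 10 featured codes per entity, mean
    central tendency, 30,000 randomly drawn registrants per test fold,
    500 regression negatives, 2000 bootstrap replicates, a 0.01 cut-off
    grid, and one seeded random list for the Lower reference.
    """

    inclusion_mode: str = "all_four"
    support_threshold: float = 0.8
    min_codes: int = 10
    tendency: str = "mean"
    binary_counts: bool = False
    top_up: bool = True
    n_random: int = 30_000
    n_negatives: int = 500
    n_bootstrap: int = 2000
    ci_level: float = 0.95
    grid_step: float = 0.01
    n_random_refs: int = 1
    stratified_bootstrap: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class FoldResult:
    """One fold's evaluation plus the artefacts needed for reporting."""

    fold: int
    evaluation: FoldEvaluation
    scores: pd.DataFrame            # person_id, s_*, final_raw, final_scaled, label, db_identified
    weights: EntityWeights
    train_ids: tuple[str, ...]
    test_participant_ids: tuple[str, ...]


@dataclass
class ProjectResult:
    """Two fold evaluations, their per-metric mean, and pooled predictions."""

    project_id: str
    folds: list[FoldResult]
    averaged: dict[str, float]
    pooled_scores: np.ndarray = field(repr=False, default=None)
    pooled_labels: np.ndarray = field(repr=False, default=None)

    def fold_frame(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            row = {"project_id": self.project_id, "fold": fr.fold}
            row.update(fr.evaluation.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def split_two_fold(participants, seed: int = 0) -> tuple[list[str], list[str]]:
    """Seeded random halving of the participant ids (sizes differ by <= 1)."""
    participants = list(participants)
    if len(participants) < 2:
        raise ValueError("two-fold split needs at least 2 participants")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(participants))
    half = (len(participants) + 1) // 2
    fold_a = [participants[i] for i in perm[:half]]
    fold_b = [participants[i] for i in perm[half:]]
    return fold_a, fold_b


def assemble_test_set(
    test_fold_participants,
    registrant_pool,
    db_identified_not_recruited,
    n_random: int = 30_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Build one fold's test set: participants + random registrants + candidates.

    The test set is the union of (i) the held-out fold participants
    (label 1), (ii) ``n_random`` registrants drawn without replacement
    from the pool, and (iii) every database-identified person not
    recruited, de-duplicated (a drawn registrant already in the candidate
    set appears once and keeps its flag). The returned ``db_identified``
    column marks membership of group (iii) only; callers overlay the
    participants' own flags.
    """
    pool = list(registrant_pool)
    if n_random > len(pool):
        raise ValueError(
            f"cannot draw {n_random} registrants from a pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    drawn = [pool[i] for i in rng.choice(len(pool), size=n_random, replace=False)]
    db_set = set(db_identified_not_recruited)
    participants = list(test_fold_participants)
    overlap = db_set & set(participants)
    if overlap:
        raise ValueError(
            f"db_identified_not_recruited overlaps test participants: {sorted(overlap)[:5]}"
        )
    seen = set(participants)
    ids = list(participants)
    for pid in drawn:
        if pid not in seen:
            ids.append(pid)
            seen.add(pid)
    for pid in sorted(db_set):
        if pid not in seen:
            ids.append(pid)
            seen.add(pid)
    part_set = set(participants)
    return pd.DataFrame(
        {
            "person_id": ids,
            "label": [1 if p in part_set else 0 for p in ids],
            "db_identified": [1 if p in db_set else 0 for p in ids],
        }
    )


def run_fold(
    events: pd.DataFrame,
    labels: pd.DataFrame,
    train_ids,
    test_participant_ids,
    registrant_pool,
    config: PipelineConfig,
    fold_seed: int,
    fold: int = 1,
) -> FoldResult:
    """Train on one participant half, score and evaluate the assembled test set."""
    train_ids = list(train_ids)
    db_flag_of = dict(zip(labels["person_id"], labels["db_identified"]))
    recruited = set(labels.loc[labels["recruited"] == 1, "person_id"])
    pool_set = set(registrant_pool)
    db_not_recruited = [
        pid for pid, f in db_flag_of.items()
        if f == 1 and pid not in recruited and pid in pool_set
    ]

    test_df = assemble_test_set(
        test_participant_ids,
        registrant_pool,
        db_not_recruited,
        n_random=config.n_random,
        seed=derive_seed(fold_seed, "test_sample"),
    )
    # overlay the held-out participants' own database-identified flags
    test_df["db_identified"] = np.maximum(
        test_df["db_identified"],
        test_df["person_id"].map(db_flag_of).fillna(0).astype(np.int64),
    )

    # profile from the training participants alone
    train_events = events[events["person_id"].isin(train_ids)]
    train_persons = group_by_person(frame_to_events(train_events))
    profile = build_target_profile(
        train_persons,
        support_threshold=config.support_threshold,
        min_codes=config.min_codes,
        tendency=config.tendency,
        binary=config.binary_counts,
        top_up=config.top_up,
    )

    # regression negatives: registrants kept out of this fold's test set
    test_members = set(test_df["person_id"])
    candidates = sorted(set(registrant_pool) - test_members)
    if len(candidates) < config.n_negatives:
        raise ValueError(
            f"only {len(candidates)} registrants left outside the test set; "
            f"cannot draw {config.n_negatives} training negatives"
        )
    rng = np.random.default_rng(derive_seed(fold_seed, "negatives"))
    negatives = [
        candidates[i]
        for i in rng.choice(len(candidates), size=config.n_negatives, replace=False)
    ]

    overlap = (set(train_ids) | set(negatives)) & test_members
    assert not overlap, f"training/test leakage: {sorted(overlap)[:5]}"

    train_rows = score_population(
        events, train_ids + negatives, profile, binary=config.binary_counts
    )
    train_labels = np.array([1] * len(train_ids) + [0] * len(negatives))
    weights = fit_entity_weights(train_rows, train_labels)

    scores = score_population(
        events, test_df["person_id"], profile, binary=config.binary_counts
    )
    scores = scores.merge(test_df, on="person_id", how="left", validate="1:1")
    scores["final_raw"] = final_score(scores, weights)
    scores["final_scaled"] = scale_scores(scores["final_raw"])

    ranked = rank_people(
        scores["person_id"].to_numpy(),
        scores["final_scaled"].to_numpy(),
        scores["label"].to_numpy(),
        scores["db_identified"].to_numpy(),
        tie_seed=derive_seed(fold_seed, "ties"),
    )
    evaluation = evaluate_ranked_list(
        ranked,
        n_bootstrap=config.n_bootstrap,
        ci_level=config.ci_level,
        seed=derive_seed(fold_seed, "eval"),
        grid_step=config.grid_step,
        n_random_refs=config.n_random_refs,
        stratified=config.stratified_bootstrap,
    )
    score_cols = ["person_id", *SCORE_COLUMNS.values(),
                  "final_raw", "final_scaled", "label", "db_identified"]
    return FoldResult(
        fold=fold,
        evaluation=evaluation,
        scores=scores[score_cols],
        weights=weights,
        train_ids=tuple(train_ids),
        test_participant_ids=tuple(test_participant_ids),
    )


def run_project(
    events: pd.DataFrame,
    labels: pd.DataFrame,
    config: PipelineConfig,
    project_id: str | None = None,
) -> ProjectResult:
    """Two-fold cross-validation of one project, fully seeded.

    ``labels`` holds one row per person with the project's recruited and
    database-identified flags. Persons failing the inclusion filter are
    dropped before analysis.
    """
    if project_id is None:
        project_id = str(labels["project_id"].iloc[0])
    labels = labels[labels["project_id"] == project_id]

    included = set(apply_inclusion_filter(events, config.inclusion_mode))
    labels = labels[labels["person_id"].isin(included)]
    events = events[events["person_id"].isin(included)]

    participants = sorted(labels.loc[labels["recruited"] == 1, "person_id"])
    pool = sorted(set(labels["person_id"]) - set(participants))
    if len(participants) < 2:
        raise ValueError(
            f"project {project_id}: need >= 2 recruited participants, "
            f"got {len(participants)}"
        )

    fold_a, fold_b = split_two_fold(
        participants, seed=derive_seed(config.seed, project_id, "split")
    )
    folds = []
    for fold, (train, test) in enumerate([(fold_a, fold_b), (fold_b, fold_a)], start=1):
        try:
            folds.append(
                run_fold(
                    events,
                    labels,
                    train,
                    test,
                    pool,
                    config,
                    fold_seed=derive_seed(config.seed, project_id, "fold", fold),
                    fold=fold,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"project {project_id}, fold {fold}: {exc}") from exc

    averaged = {
        m: float(np.mean([getattr(fr.evaluation, m) for fr in folds]))
        for m in AVERAGED_METRICS
    }
    pooled_scores = np.concatenate(
        [fr.scores["final_scaled"].to_numpy() for fr in folds]
    )
    pooled_labels = np.concatenate([fr.scores["label"].to_numpy() for fr in folds])
    return ProjectResult(
        project_id=project_id,
        folds=folds,
        averaged=averaged,
        pooled_scores=pooled_scores,
        pooled_labels=pooled_labels,
    )


@dataclass
class SuiteResult:
    """All projects' results with grand means and the pooled cut-off sweep."""

    projects: list[ProjectResult]
    grand_means: dict[str, float]
    pooled_cutoff: float
    pooled_cutoff_metric: float
    sweep: pd.DataFrame = field(repr=False, default=None)

    def fold_frame(self) -> pd.DataFrame:
        return pd.concat(
            [p.fold_frame() for p in self.projects], ignore_index=True
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.projects:
            row = {"project_id": p.project_id}
            row.update(p.averaged)
            rows.append(row)
        grand = {"project_id": "ALL"}
        grand.update(self.grand_means)
        rows.append(grand)
        return pd.DataFrame(rows)


def run_suite(
    project_data: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    config: PipelineConfig,
) -> SuiteResult:
    """Run every project and aggregate: grand fold means and pooled sweep.

    ``project_data`` maps project id to its ``(events, labels)`` pair.
    Grand means are taken across all fold evaluations (two per project),
    matching per-project averaging when every project has two folds.
    """
    if not project_data:
        raise ValueError("need at least one project")
    projects = [
        run_project(events, labels, config, project_id=pid)
        for pid, (events, labels) in project_data.items()
    ]
    all_folds = [fr.evaluation for p in projects for fr in p.folds]
    grand_means = {
        m: float(np.mean([getattr(ev, m) for ev in all_folds]))
        for m in AVERAGED_METRICS
    }
    pooled_scores = np.concatenate([p.pooled_scores for p in projects])
    pooled_labels = np.concatenate([p.pooled_labels for p in projects])
    sweep = cutoff_sweep(pooled_scores, pooled_labels, config.grid_step)
    cutoff, metric = optimal_cutoff(pooled_scores, pooled_labels, config.grid_step)
    return SuiteResult(
        projects=projects,
        grand_means=grand_means,
        pooled_cutoff=cutoff,
        pooled_cutoff_metric=metric,
        sweep=sweep,
    )


_FLOAT_FMT = "%.10g"


def write_report(suite: SuiteResult, outdir, plot: bool = True) -> None:
    """Write the evaluation report: per-fold and summary CSVs, sweep data/plot.

    Output is byte-stable: identical config and seeds give identical files.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suite.fold_frame().to_csv(outdir / "folds.csv", index=False, float_format=_FLOAT_FMT)
    suite.summary_frame().to_csv(
        outdir / "summary.csv", index=False, float_format=_FLOAT_FMT
    )
    suite.sweep.to_csv(outdir / "cutoff_sweep.csv", index=False, float_format=_FLOAT_FMT)
    for p in suite.projects:
        for fr in p.folds:
            fr.scores.to_csv(
                outdir / f"scores_{p.project_id}_fold{fr.fold}.csv",
                index=False,
                float_format=_FLOAT_FMT,
            )
    if plot:
        from .evaluation import plot_cutoff_sweep

        plot_cutoff_sweep(suite.sweep, outdir / "cutoff_sweep.png")
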