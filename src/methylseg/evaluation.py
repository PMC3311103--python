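"""Cross-validated AUC evaluation of the three modeling resolutions.

Ten-fold cross validation with the amplicon as the fold unit (all of an
amplicon's sites and segments share a fold, so overlapping sequence never
leaks across the train/test split).  k-mer features are selected from the
training folds only, regression coefficients are computed in the training
stage only, and performance is the rank-based area under the ROC curve on
the held-out units.

Segment resolution reports two AUCs per fold: on the test data's initial
(label-change) configuration, and on the final configuration found by the
merge search run with the frozen training model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .io_data import Dataset
from .kmer_features import (
    DegenerateClassError,
    LabeledInstance,
    balance_classes,
    count_kmers,
    extract_site_flank,
    instance_matrix,
    select_rf_consensus,
    select_ttest,
)
from .mixture_logistic import decision_scores, fit
from .segment_search import (
    KmerOccurrenceIndex,
    build_site_table,
    hill_climbing_search,
    initial_configuration,
    segment_feature_matrix,
)

__all__ = [
    "ExperimentConfig",
    "FoldResult",
    "ExperimentReport",
    "UndefinedAUCError",
    "kfold_split",
    "auc",
    "run_segment_experiment",
    "run_site_experiment",
    "run_promoter_experiment",
    "kmer_count_sweep",
]


class UndefinedAUCError(ValueError):
    """AUC is undefined because only one class is present."""


@dataclass
class ExperimentConfig:
    """Settings for one cross-validated experiment."""

    k: int = 6
    selection: str = "ttest"  # or "rf_consensus"
    n_kmers: int = 30
    folds: int = 10
    seed: int = 0
    cell_type: str = ""
    resolution: str = "segment"  # site | promoter | segment
    delta: float = 1e-6
    restarts: int = 10
    site_threshold: float = 0.5
    flank_length: int = 100
    ridge: float = 1e-6
    init_mode: str = "label-change"
    rf_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.resolution not in ("site", "promoter", "segment"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        if self.selection not in ("ttest", "rf_consensus"):
            raise ValueError(f"unknown selection method {self.selection!r}")


@dataclass
class FoldResult:
    """Per-fold test AUCs (auc_final is segment resolution only)."""

    fold: int
    auc_initial: float
    auc_final: Optional[float] = None
    n_test_units: int = 0


@dataclass
class ExperimentReport:
    """All folds of one experiment, with summary statistics."""

    config: ExperimentConfig
    folds: list[FoldResult]
    skipped: list[int] = field(default_factory=list)
    traces: list = field(default_factory=list)
    selected_kmers: list[list[str]] = field(default_factory=list)

    @property
    def mean_auc_initial(self) -> float:
        return float(np.mean([f.auc_initial for f in self.folds]))

    @property
    def sd_auc_initial(self) -> float:
        return float(np.std([f.auc_initial for f in self.folds], ddof=1))

    @property
    def mean_auc_final(self) -> Optional[float]:
        vals = [f.auc_final for f in self.folds if f.auc_final is not None]
        return float(np.mean(vals)) if vals else None

    def to_dict(self) -> dict:
        return {
            "config": vars(self.config).copy(),
            "folds": [vars(f).copy() for f in self.folds],
            "skipped": list(self.skipped),
            "mean_auc_initial": self.mean_auc_initial,
            "mean_auc_final": self.mean_auc_final,
        }


def kfold_split(
    units: Sequence[str], n_folds: int, seed: int
) -> list[list[str]]:
    """Seeded random partition of unit ids into near-equal folds."""
    units = list(units)
    if len(units) < n_folds:
        raise ValueError(
            f"{len(units)} units cannot fill {n_folds} folds; "
            "use a smaller n_folds"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(units)))
    return [
        [units[i] for i in chunk] for chunk in np.array_split(order, n_folds)
    ]


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (Mann-Whitney with ties contributing 1/2)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise UndefinedAUCError("both classes are required for AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _fold_seeds(seed: int, folds: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(3 * folds) % (2**31)


def _site_instances(
    dataset: Dataset, amp_ids: Sequence[str], cell_type: str, config: ExperimentConfig
) -> list[LabeledInstance]:
    instances = []
    amp_ids = set(amp_ids)
    for amp in dataset.amplicons:
        if amp.id not in amp_ids:
            continue
        for offset, level in dataset.sites_for(amp.id, cell_type):
            flank = extract_site_flank(amp, offset, config.flank_length)
            instances.append(
                LabeledInstance(
                    features=count_kmers(flank, config.k),
                    label="+" if level > config.site_threshold else "-",
                    source_id=f"{amp.id}:{offset}",
                )
            )
    return instances


def _promoter_instances(
    dataset: Dataset, amp_ids: Sequence[str], cell_type: str, config: ExperimentConfig
) -> list[LabeledInstance]:
    instances = []
    amp_ids = set(amp_ids)
    for amp in dataset.amplicons:
        if amp.id not in amp_ids:
            continue
        sites = dataset.sites_for(amp.id, cell_type)
        if not sites:
            continue
        frac = np.mean([lvl > config.site_threshold for _, lvl in sites])
        instances.append(
            LabeledInstance(
                features=count_kmers(amp.sequence, config.k),
                label="+" if frac > 0.5 else "-",
                source_id=amp.id,
            )
        )
    return instances


def _select_features(
    dataset: Dataset,
    train_ids: Sequence[str],
    cell_type: str,
    config: ExperimentConfig,
    seed: int,
) -> list[str]:
    """Select k-mers from training amplicons only (balanced site flanks)."""
    instances = _site_instances(dataset, train_ids, cell_type, config)
    balanced = balance_classes(instances, seed=seed)
    if config.selection == "ttest":
        result = select_ttest(balanced, m=config.n_kmers)
    else:
        result = select_rf_consensus(balanced, seed=seed, **config.rf_params)
    if not result.selected:
        raise ValueError("feature selection returned no k-mers")
    return result.selected


def _cv_units(dataset: Dataset, cell_type: str) -> list[str]:
    return sorted(
        {amp for (amp, ct) in dataset.sites if ct == cell_type}
    )


def run_segment_experiment(
    dataset: Dataset, config: ExperimentConfig
) -> ExperimentReport:
    """10-fold CV of segment-resolution modeling: initial vs. final AUC.

    Per fold: select k-mers on the training amplicons, fit model and run
    the hill-climbing search on training data, then score the test
    amplicons' initial configuration and the final configuration found by
    the frozen-model search.
    """
    ct = config.cell_type
    units = _cv_units(dataset, ct)
    folds = kfold_split(units, config.folds, config.seed)
    seeds = _fold_seeds(config.seed, config.folds)
    results, skipped, traces, selected_all = [], [], [], []
    for f, test_ids in enumerate(folds):
        train_ids = [u for u in units if u not in set(test_ids)]
        sel_seed, train_seed, test_seed = (int(s) for s in seeds[3 * f : 3 * f + 3])
        kmers = _select_features(dataset, train_ids, ct, config, sel_seed)
        selected_all.append(kmers)
        train_table = [
            t
            for t in build_site_table(dataset, ct, config.site_threshold)
            if t.amplicon.id in set(train_ids)
        ]
        try:
            train_res = hill_climbing_search(
                train_table,
                kmers,
                N_restarts=config.restarts,
                delta=config.delta,
                seed=train_seed,
                stage="train",
                init_mode=config.init_mode,
                ridge=config.ridge,
                cell_type=ct,
            )
        except DegenerateClassError:
            skipped.append(f)
            continue
        model = train_res.model
        traces.append(train_res.trace)

        test_table = [
            t
            for t in build_site_table(dataset, ct, config.site_threshold)
            if t.amplicon.id in set(test_ids)
        ]
        test_amps = [t.amplicon for t in test_table]
        index = KmerOccurrenceIndex(test_amps, kmers)
        init_cfg = initial_configuration(test_table, config.init_mode, ct)
        X_init = segment_feature_matrix(init_cfg, kmers, test_amps, index)
        final_res = hill_climbing_search(
            test_table,
            kmers,
            N_restarts=config.restarts,
            delta=config.delta,
            seed=test_seed,
            stage="test",
            frozen_model=model,
            init_mode=config.init_mode,
            ridge=config.ridge,
            cell_type=ct,
        )
        final_cfg = final_res.configuration
        X_final = segment_feature_matrix(final_cfg, kmers, test_amps, index)
        try:
            auc_i = auc(decision_scores(model, X_init), init_cfg.labels01())
            auc_f = auc(decision_scores(model, X_final), final_cfg.labels01())
        except UndefinedAUCError:
            skipped.append(f)
            continue
        results.append(
            FoldResult(
                fold=f,
                auc_initial=auc_i,
                auc_final=auc_f,
                n_test_units=len(test_ids),
            )
        )
    return ExperimentReport(config, results, skipped, traces, selected_all)


def _run_instance_experiment(
    dataset: Dataset,
    config: ExperimentConfig,
    make_instances,
) -> ExperimentReport:
    ct = config.cell_type
    units = _cv_units(dataset, ct)
    all_instances = make_instances(dataset, units, ct, config)
    labels = {inst.label for inst in all_instances}
    if len(labels) < 2:
        raise DegenerateClassError(
            f"all {config.resolution} instances share one class"
        )
    folds = kfold_split(units, config.folds, config.seed)
    seeds = _fold_seeds(config.seed, config.folds)
    results, skipped, selected_all = [], [], []
    for f, test_ids in enumerate(folds):
        test_set = set(test_ids)
        train_ids = [u for u in units if u not in test_set]
        sel_seed = int(seeds[3 * f])
        try:
            kmers = _select_features(dataset, train_ids, ct, config, sel_seed)
        except DegenerateClassError:
            skipped.append(f)
            continue
        selected_all.append(kmers)
        train_inst = make_instances(dataset, train_ids, ct, config)
        test_inst = make_instances(dataset, test_ids, ct, config)
        X_tr, y_tr, _ = instance_matrix(train_inst, kmers=kmers)
        X_te, y_te, _ = instance_matrix(test_inst, kmers=kmers)
        try:
            model = fit(X_tr, y_tr, kmers=kmers, ridge=config.ridge)
            score = auc(decision_scores(model, X_te), y_te)
        except (DegenerateClassError, UndefinedAUCError, ValueError):
            skipped.append(f)
            continue
        results.append(
            FoldResult(fold=f, auc_initial=score, n_test_units=len(test_ids))
        )
    return ExperimentReport(config, results, skipped, [], selected_all)


def run_site_experiment(
    dataset: Dataset, config: ExperimentConfig
) -> ExperimentReport:
    """CpG-site resolution: one instance per site, features from its
    l=100 flank, logistic model, per-fold test AUC."""
    return _run_instance_experiment(dataset, config, _site_instances)


def run_promoter_experiment(
    dataset: Dataset, config: ExperimentConfig
) -> ExperimentReport:
    """Promoter resolution: one instance per amplicon, features from the
    whole sequence, label + iff the fraction of + sites exceeds 0.5."""
    return _run_instance_experiment(dataset, config, _promoter_instances)


def kmer_count_sweep(
    dataset: Dataset,
    k: int,
    counts: Sequence[int] = tuple(range(10, 101, 10)),
    folds: int = 10,
    seed: int = 0,
    cell_type: str = "",
    **kw,
) -> dict[tuple[str, int], ExperimentReport]:
    """The feature-count sweep: all three resolutions at each number of
    t-test-selected k-mers, emitting a (resolution, count) grid."""
    runners = {
        "site": run_site_experiment,
        "promoter": run_promoter_experiment,
        "segment": run_segment_experiment,
    }
    grid: dict[tuple[str, int], ExperimentReport] = {}
    for resolution, runner in runners.items():
        for m in counts:
            config = ExperimentConfig(
                k=k,
                selection="ttest",
                n_kmers=m,
                folds=folds,
                seed=seed,
                cell_type=cell_type,
                resolution=resolution,
                **kw,
            )
            grid[(resolution, m)] = runner(dataset, config)
    return grid
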