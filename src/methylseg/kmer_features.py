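"""k-mer feature extraction and selection.

Instances are sequences (CpG-site flanks, segments or whole promoters)
labeled +/- by methylation status.  Features are overlapping k-mer
occurrence counts; a small subset of k-mers is selected either by a Welch
two-sample t-test on counts between classes, or by consensus over repeated
random-forest importance runs (k runs of n trees each; k-mers among the
top-N positive-z-score importances in at least p% of runs are kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "KmerCountVector",
    "LabeledInstance",
    "FeatureSelectionResult",
    "DegenerateClassError",
    "count_kmers",
    "extract_site_flank",
    "balance_classes",
    "instance_matrix",
    "select_ttest",
    "rf_importance_run",
    "select_rf_consensus",
]

DNA = set("ACGT")


class DegenerateClassError(ValueError):
    """Both +/- classes are required but only one is present."""


@dataclass(frozen=True)
class KmerCountVector:
    """Occurrence counts of the k-mers observed in one sequence."""

    k: int
    counts: dict[str, int]


@dataclass(frozen=True)
class LabeledInstance:
    """A sequence instance with a +/- methylation label."""

    features: KmerCountVector
    label: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("+", "-"):
            raise ValueError(f"label must be '+' or '-', got {self.label!r}")


@dataclass
class FeatureSelectionResult:
    """Selected k-mers with their scores and the parameters used.

    For the t-test method, ``scores`` are p-values and ``selected`` is
    ordered by ascending p-value; for RF consensus, ``scores`` are the
    fraction of runs in which each k-mer appeared.
    """

    method: str
    selected: list[str]
    scores: dict[str, float]
    params: dict = field(default_factory=dict)


def count_kmers(sequence: str, k: int) -> KmerCountVector:
    """Count every overlapping length-k window not containing N.

    A sequence shorter than k yields an empty vector.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = sequence.upper()
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        counts[w] = counts.get(w, 0) + 1
    return KmerCountVector(k=k, counts=counts)


def extract_site_flank(amplicon, cpg_offset: int, l: int = 100) -> str:
    """Window of length l centered on a CpG, truncated at amplicon ends.

    The window spans l/2 - 1 bases left of the C through l/2 - 1 bases
    right of the G; no padding is added at amplicon boundaries.
    """
    if cpg_offset not in amplicon.cpg_offsets:
        raise ValueError(
            f"offset {cpg_offset} is not a CpG site of amplicon {amplicon.id}"
        )
    if l < 2 or l % 2 != 0:
        raise ValueError(f"flank length must be even and >= 2, got {l}")
    half = l // 2 - 1
    lo = max(0, cpg_offset - half)
    hi = min(len(amplicon.sequence), cpg_offset + 2 + half)
    return amplicon.sequence[lo:hi]


def balance_classes(
    instances: Sequence[LabeledInstance], seed: int
) -> list[LabeledInstance]:
    """Down-sample the majority class to the minority size (seeded).

    The returned list is shuffled deterministically given ``seed``.
    """
    pos = [x for x in instances if x.label == "+"]
    neg = [x for x in instances if x.label == "-"]
    if not pos or not neg:
        raise DegenerateClassError("both + and - instances are required")
    rng = np.random.default_rng(seed)
    n = min(len(pos), len(neg))
    if len(pos) > n:
        pos = [pos[i] for i in rng.choice(len(pos), size=n, replace=False)]
    if len(neg) > n:
        neg = [neg[i] for i in rng.choice(len(neg), size=n, replace=False)]
    out = pos + neg
    rng.shuffle(out)  # type: ignore[arg-type]
    return list(out)


def instance_matrix(
    instances: Sequence[LabeledInstance],
    kmers: Optional[Sequence[str]] = None,
    binary: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Dense design matrix over a fixed k-mer order.

    When ``kmers`` is None the candidate universe is every k-mer observed
    in the instances (sorted).  Returns (X, y, kmers) with y in {1, 0} for
    {+, -}.
    """
    if kmers is None:
        universe: set[str] = set()
        for inst in instances:
            universe.update(inst.features.counts)
        kmers = sorted(universe)
    else:
        kmers = list(kmers)
    col = {a: j for j, a in enumerate(kmers)}
    X = np.zeros((len(instances), len(kmers)))
    for i, inst in enumerate(instances):
        for a, c in inst.features.counts.items():
            j = col.get(a)
            if j is not None:
                X[i, j] = c
    if binary:
        X = (X > 0).astype(float)
    y = np.array([1 if inst.label == "+" else 0 for inst in instances])
    return X, y, kmers


def select_ttest(
    instances: Sequence[LabeledInstance],
    m: Optional[int] = None,
    alpha: Optional[float] = None,
    binary: bool = False,
) -> FeatureSelectionResult:
    """Rank k-mers by a Welch two-sample t-test of counts between classes.

    Returns the top ``m`` by ascending p-value (ties broken
    lexicographically) or, with ``alpha``, all k-mers with p < alpha.
    """
    if (m is None) == (alpha is None):
        raise ValueError("specify exactly one of m or alpha")
    X, y, kmers = instance_matrix(instances, binary=binary)
    if len(set(y)) < 2:
        raise DegenerateClassError("both classes are required for the t-test")
    Xp, Xn = X[y == 1], X[y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(Xp, Xn, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    # zero-variance in both classes: equal means -> no evidence (p=1),
    # different means -> perfectly separated (p=0)
    nan = ~np.isfinite(pvals)
    if nan.any():
        same = np.isclose(Xp.mean(axis=0), Xn.mean(axis=0))
        pvals[nan & same] = 1.0
        pvals[nan & ~same] = 0.0
    order = sorted(range(len(kmers)), key=lambda j: (pvals[j], kmers[j]))
    if alpha is not None:
        chosen = [j for j in order if pvals[j] < alpha]
    else:
        chosen = order[: min(m, len(order))]
    selected = [kmers[j] for j in chosen]
    return FeatureSelectionResult(
        method="ttest",
        selected=selected,
        scores={kmers[j]: float(pvals[j]) for j in chosen},
        params={"m": m, "alpha": alpha, "binary": binary},
    )


def rf_importance_run(
    instances: Sequence[LabeledInstance],
    n_trees: int = 100,
    N_top: int = 100,
    seed: int = 0,
    binary: bool = False,
) -> set[str]:
    """One random-forest importance run.

    Fits a forest of ``n_trees`` trees, standardizes the Gini importances
    to z-scores across features within the run, and returns the top
    ``N_top`` features among those with z-score > 0.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, y, kmers = instance_matrix(instances, binary=binary)
    if X.shape[1] < 2:
        raise ValueError("at least 2 features are required")
    if len(set(y)) < 2:
        raise DegenerateClassError("both classes are required")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    imp = rf.feature_importances_
    sd = imp.std()
    z = (imp - imp.mean()) / sd if sd > 0 else np.zeros_like(imp)
    positive = [j for j in range(len(kmers)) if z[j] > 0]
    positive.sort(key=lambda j: (-z[j], kmers[j]))
    return {kmers[j] for j in positive[:N_top]}


def consensus_filter(
    appearances: dict[str, int], k_runs: int, p_pct: float
) -> dict[str, int]:
    """Keep k-mers appearing in at least ceil(p_pct/100 * k_runs) runs."""
    need = ceil(p_pct / 100.0 * k_runs)
    return {a: c for a, c in appearances.items() if c >= need}


def select_rf_consensus(
    instances: Sequence[LabeledInstance],
    k_runs: int = 30,
    n_trees: int = 100,
    N_top: int = 100,
    p_pct: float = 90.0,
    seed: int = 0,
    binary: bool = False,
) -> FeatureSelectionResult:
    """Consensus random-forest feature selection.

    Runs ``rf_importance_run`` ``k_runs`` times with per-run seeds derived
    from ``seed`` and keeps the k-mers collected in at least p% of runs;
    scores are appearance fractions.
    """
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s) % (2**31) for s in ss.generate_state(k_runs)]
    appearances: dict[str, int] = {}
    for rs in run_seeds:
        for a in rf_importance_run(instances, n_trees, N_top, rs, binary=binary):
            appearances[a] = appearances.get(a, 0) + 1
    kept = consensus_filter(appearances, k_runs, p_pct)
    selected = sorted(kept, key=lambda a: (-kept[a], a))
    return FeatureSelectionResult(
        method="rf_consensus",
        selected=selected,
        scores={a: kept[a] / k_runs for a in selected},
        params={
            "k_runs": k_runs,
            "n_trees": n_trees,
            "N_top": N_top,
            "p_pct": p_pct,
            "seed": seed,
            "binary": binary,
        },
    )
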