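"""Segment data model and the random binary segment-merging search.

An amplicon's measured CpG sites are partitioned into contiguous segments
by boundary variables B_i, one per gap between adjacent sites (B_i = 1
separates segments).  A complete assignment of boundary variables is a
*configuration*.  Each segment carries a methylation probability p (the
fraction of its sites labeled +), a label t (+ iff p > 0.5, strict), and an
objective weight w = S_bar / |S| where S_bar is the mean segment size of
the configuration — large segments are penalized less.

The search minimizes the weighted squared error

    O(S) = sum_i  (S_bar / |S_i|) * (yhat_i - t_i)^2

over configurations by hill climbing: starting from the finest
label-consistent segmentation, segments are repeatedly drawn (with
probability proportional to a *sampling* error e_j = (|S_j| / S_bar) *
(yhat_j - t_j)^2, whose weight is deliberately the inverse of the
objective's) and tentatively merged with their right neighbor; a merge is
accepted only if it reduces the objective, refitting the logistic model
after each tentative merge during training and reusing a frozen model at
test time.  Passes repeat until the between-pass improvement drops to
delta, and the whole procedure restarts N times from independent random
streams, keeping the best configuration found.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Optional, Sequence

import numpy as np

from .io_data import AmpliconRecord, Dataset
from .mixture_logistic import (
    DegenerateLabelsError,
    MixtureLogisticModel,
    decision_scores,
    fit,
)

__all__ = [
    "AmpliconSites",
    "Segment",
    "Configuration",
    "SearchResult",
    "KmerOccurrenceIndex",
    "label_sites",
    "build_site_table",
    "initial_configuration",
    "segment_label_and_weight",
    "segment_feature_matrix",
    "compute_error",
    "sampling_error_vector",
    "select_at_random",
    "random_binary_merging",
    "random_configuration_search",
    "hill_climbing_search",
    "enumerate_all_configurations",
    "parenthesization_count",
]


# ---------------------------------------------------------------- data model


@dataclass
class AmpliconSites:
    """One amplicon's measured CpG sites for one cell type."""

    amplicon: AmpliconRecord
    offsets: np.ndarray  # sequence offsets of measured CpG sites, sorted
    levels: np.ndarray
    labels: np.ndarray  # '+'/'-' per site

    @property
    def n_sites(self) -> int:
        return len(self.offsets)


@dataclass
class Segment:
    """A contiguous run of CpG sites within one amplicon."""

    amplicon_id: str
    cell_type: str
    first: int  # site index range within the amplicon, inclusive
    last: int
    chrom: str
    span_start: int  # sequence offsets: first CpG's C ... last CpG's G
    span_end: int  # exclusive
    genomic_start: int
    genomic_end: int
    p: float  # fraction of sites labeled +
    n_sites: int

    @property
    def label(self) -> str:
        return "+" if self.p > 0.5 else "-"

    @property
    def t01(self) -> int:
        return 1 if self.p > 0.5 else 0


@dataclass
class Configuration:
    """A partition of every amplicon's CpG sites into contiguous segments."""

    cell_type: str
    segments: list[Segment]
    boundaries: dict[str, np.ndarray]  # per amplicon: B_i bits, len = n_sites-1

    @property
    def mean_size(self) -> float:
        """S_bar: the average count of CpG sites over all segments."""
        return float(np.mean([s.n_sites for s in self.segments]))

    def sizes(self) -> np.ndarray:
        return np.array([s.n_sites for s in self.segments], dtype=float)

    def labels01(self) -> np.ndarray:
        return np.array([s.t01 for s in self.segments], dtype=float)

    def weights(self) -> np.ndarray:
        """Objective weights w_i = S_bar / |S_i|."""
        return self.mean_size / self.sizes()


@dataclass
class SearchResult:
    """Best configuration, model and error found, with the full trace."""

    configuration: Configuration
    model: MixtureLogisticModel
    error: float
    trace: list[dict] = field(default_factory=list)


def label_sites(
    dataset: Dataset, cell_type: str, site_threshold: float = 0.5
) -> dict[str, list[str]]:
    """Per-amplicon +/- site labels: + iff level > threshold (strict)."""
    out: dict[str, list[str]] = {}
    for a in dataset.amplicons:
        sites = dataset.sites_for(a.id, cell_type)
        if sites:
            out[a.id] = ["+" if lvl > site_threshold else "-" for _, lvl in sites]
    return out


def build_site_table(
    dataset: Dataset, cell_type: str, site_threshold: float = 0.5
) -> list[AmpliconSites]:
    """Assemble the per-amplicon site arrays the search operates on."""
    table = []
    for a in dataset.amplicons:
        sites = dataset.sites_for(a.id, cell_type)
        if not sites:
            continue
        offsets = np.array([o for o, _ in sites])
        levels = np.array([lvl for _, lvl in sites])
        labels = np.where(levels > site_threshold, "+", "-")
        table.append(AmpliconSites(a, offsets, levels, labels))
    return table


def _segments_from_boundaries(
    amp_sites: Sequence[AmpliconSites],
    boundaries: dict[str, np.ndarray],
    cell_type: str,
) -> list[Segment]:
    segments: list[Segment] = []
    for asite in amp_sites:
        amp = asite.amplicon
        bits = boundaries[amp.id]
        cuts = [0] + [i + 1 for i in range(len(bits)) if bits[i]] + [asite.n_sites]
        for a, z in zip(cuts[:-1], cuts[1:]):
            span_start = int(asite.offsets[a])
            span_end = int(asite.offsets[z - 1]) + 2
            plus = sum(1 for lab in asite.labels[a:z] if lab == "+")
            segments.append(
                Segment(
                    amplicon_id=amp.id,
                    cell_type=cell_type,
                    first=a,
                    last=z - 1,
                    chrom=amp.chrom,
                    span_start=span_start,
                    span_end=span_end,
                    genomic_start=amp.start + span_start,
                    genomic_end=amp.start + span_end,
                    p=plus / (z - a),
                    n_sites=z - a,
                )
            )
    return segments


def configuration_from_boundaries(
    amp_sites: Sequence[AmpliconSites],
    boundaries: dict[str, np.ndarray],
    cell_type: str = "",
) -> Configuration:
    return Configuration(
        cell_type=cell_type,
        segments=_segments_from_boundaries(amp_sites, boundaries, cell_type),
        boundaries={k: np.asarray(v, dtype=np.int8) for k, v in boundaries.items()},
    )


def initial_configuration(
    amp_sites: Sequence[AmpliconSites],
    mode: str = "label-change",
    cell_type: str = "",
) -> Configuration:
    """The starting segmentation.

    ``label-change`` (default) sets B_i = 1 wherever adjacent site labels
    differ, giving maximal runs of identical labels — the finest
    configuration consistent with the labels.  ``all-boundaries`` sets
    every B_i = 1, one segment per CpG site.
    """
    if mode not in ("label-change", "all-boundaries"):
        raise ValueError(f"unknown initialization mode {mode!r}")
    kept = []
    boundaries: dict[str, np.ndarray] = {}
    for asite in amp_sites:
        if asite.n_sites == 0:
            warnings.warn(f"amplicon {asite.amplicon.id} has no sites; skipped")
            continue
        kept.append(asite)
        if mode == "all-boundaries":
            bits = np.ones(asite.n_sites - 1, dtype=np.int8)
        else:
            bits = np.array(
                [
                    1 if asite.labels[i] != asite.labels[i + 1] else 0
                    for i in range(asite.n_sites - 1)
                ],
                dtype=np.int8,
            )
        boundaries[asite.amplicon.id] = bits
    return configuration_from_boundaries(kept, boundaries, cell_type)


def segment_label_and_weight(
    segment: Segment, configuration: Configuration
) -> tuple[float, str, float]:
    """(p, t, w) of a segment: w = S_bar / |S| from the configuration."""
    return segment.p, segment.label, configuration.mean_size / segment.n_sites


# ------------------------------------------------------------- k-mer counts


class KmerOccurrenceIndex:
    """Sorted occurrence positions of selected k-mers per amplicon.

    Lets segment feature rows be computed with two binary searches per
    k-mer instead of rescanning sequence, which the merge loop relies on.
    """

    def __init__(self, amplicons: Sequence[AmpliconRecord], kmers: Sequence[str]):
        self.kmers = list(kmers)
        self._pos: dict[tuple[str, str], np.ndarray] = {}
        for amp in amplicons:
            seq = amp.sequence
            for kmer in self.kmers:
                hits = []
                i = seq.find(kmer)
                while i != -1:
                    hits.append(i)
                    i = seq.find(kmer, i + 1)
                self._pos[(amp.id, kmer)] = np.array(hits, dtype=np.int64)

    def count_row(self, amplicon_id: str, start: int, end: int) -> np.ndarray:
        """Occurrences fully inside sequence span [start, end)."""
        row = np.empty(len(self.kmers))
        for j, kmer in enumerate(self.kmers):
            pos = self._pos[(amplicon_id, kmer)]
            row[j] = np.searchsorted(
                pos, end - len(kmer), side="right"
            ) - np.searchsorted(pos, start, side="left")
        return row


def segment_feature_matrix(
    configuration: Configuration,
    selected_kmers: Sequence[str],
    amplicons: Sequence[AmpliconRecord],
    index: Optional[KmerOccurrenceIndex] = None,
) -> np.ndarray:
    """Design matrix: one row per segment, k-mer occurrence counts within
    the segment's span (first CpG's C through last CpG's G, inclusive)."""
    if len(selected_kmers) == 0:
        raise ValueError("selected_kmers must be nonempty")
    if index is None:
        index = KmerOccurrenceIndex(amplicons, selected_kmers)
    X = np.zeros((len(configuration.segments), len(selected_kmers)))
    for i, seg in enumerate(configuration.segments):
        X[i] = index.count_row(seg.amplicon_id, seg.span_start, seg.span_end)
    return X


# ----------------------------------------------------------------- objective


def compute_error(
    configuration: Configuration,
    model: MixtureLogisticModel,
    X: Optional[np.ndarray] = None,
    amplicons: Optional[Sequence[AmpliconRecord]] = None,
    index: Optional[KmerOccurrenceIndex] = None,
) -> float:
    """The weighted squared error  E = sum_i (S_bar/|S_i|) (yhat_i - t_i)^2."""
    if X is None:
        X = segment_feature_matrix(configuration, model.kmers, amplicons or [], index)
    yhat = decision_scores(model, X)
    resid = yhat - configuration.labels01()
    return float(np.sum(configuration.weights() * resid**2))


def sampling_error_vector(
    configuration: Configuration,
    model: MixtureLogisticModel,
    X: Optional[np.ndarray] = None,
    amplicons: Optional[Sequence[AmpliconRecord]] = None,
    index: Optional[KmerOccurrenceIndex] = None,
) -> np.ndarray:
    """Per-segment sampling errors  e_j = (|S_j|/S_bar) (yhat_j - t_j)^2.

    The weight is the inverse of the objective's w_i: sampling favors
    large, badly predicted segments as merge candidates.
    """
    if X is None:
        X = segment_feature_matrix(configuration, model.kmers, amplicons or [], index)
    yhat = decision_scores(model, X)
    resid = yhat - configuration.labels01()
    return (configuration.sizes() / configuration.mean_size) * resid**2


def select_at_random(
    e: np.ndarray, visit: Sequence[bool], rng: np.random.Generator
) -> int:
    """Draw an unvisited segment with probability proportional to e_j.

    Falls back to a uniform draw when every unvisited e_j is zero.
    """
    candidates = [j for j in range(len(e)) if not visit[j]]
    if not candidates:
        raise ValueError("no unvisited segments")
    weights = np.asarray([e[j] for j in candidates], dtype=float)
    total = weights.sum()
    if total <= 0:
        probs = np.full(len(candidates), 1.0 / len(candidates))
    else:
        probs = weights / total
    return int(candidates[rng.choice(len(candidates), p=probs)])


# -------------------------------------------------------------------- search


def _theta(model: MixtureLogisticModel) -> np.ndarray:
    return np.concatenate(([model.intercept], model.betas))


def _merge_candidate(
    config: Configuration, X: np.ndarray, j: int, index: KmerOccurrenceIndex
) -> tuple[Configuration, np.ndarray]:
    """Configuration and design matrix with segments j and j+1 merged."""
    s, t = config.segments[j], config.segments[j + 1]
    n = s.n_sites + t.n_sites
    merged = Segment(
        amplicon_id=s.amplicon_id,
        cell_type=s.cell_type,
        first=s.first,
        last=t.last,
        chrom=s.chrom,
        span_start=s.span_start,
        span_end=t.span_end,
        genomic_start=s.genomic_start,
        genomic_end=t.genomic_end,
        p=(s.p * s.n_sites + t.p * t.n_sites) / n,
        n_sites=n,
    )
    segments = config.segments[:j] + [merged] + config.segments[j + 2 :]
    boundaries = dict(config.boundaries)
    bits = boundaries[s.amplicon_id].copy()
    bits[t.first - 1] = 0  # the gap between the two segments closes
    boundaries[s.amplicon_id] = bits
    new_config = Configuration(config.cell_type, segments, boundaries)
    row = index.count_row(merged.amplicon_id, merged.span_start, merged.span_end)
    newX = np.vstack([X[:j], row, X[j + 2 :]])
    return new_config, newX


def random_binary_merging(
    config: Configuration,
    index: KmerOccurrenceIndex,
    rng: np.random.Generator,
    stage: str = "train",
    frozen_model: Optional[MixtureLogisticModel] = None,
    ridge: float = 1e-6,
) -> tuple[Configuration, MixtureLogisticModel, float, list[float]]:
    """One merging pass: consider every segment once, accepting only
    error-reducing merges.

    In the training stage the logistic model is refit after each tentative
    merge; at test time ``frozen_model`` is used throughout.  A segment
    with no right neighbor in its amplicon is merge-ineligible and is
    marked visited when drawn.  Returns the resulting (C, M, E) and the
    list of errors at each accepted merge.
    """
    if stage not in ("train", "test"):
        raise ValueError(f"stage must be 'train' or 'test', got {stage!r}")
    X = np.array(
        [index.count_row(s.amplicon_id, s.span_start, s.span_end) for s in config.segments]
    )
    if stage == "train":
        model = fit(X, config.labels01(), kmers=index.kmers, ridge=ridge)
    else:
        if frozen_model is None:
            raise ValueError("test stage requires a frozen model")
        model = frozen_model
    E = compute_error(config, model, X=X)
    visit = [False] * len(config.segments)
    accepted_errors: list[float] = []

    while not all(visit):
        e = sampling_error_vector(config, model, X=X)
        j = select_at_random(e, visit, rng)
        visit[j] = True
        seg = config.segments[j]
        last_of_amplicon = (
            j + 1 >= len(config.segments)
            or config.segments[j + 1].amplicon_id != seg.amplicon_id
        )
        if last_of_amplicon:
            continue
        cand, candX = _merge_candidate(config, X, j, index)
        if stage == "train":
            try:
                cand_model = fit(
                    candX,
                    cand.labels01(),
                    kmers=index.kmers,
                    ridge=ridge,
                    warm_start=_theta(model),
                )
            except DegenerateLabelsError:
                continue  # merge would leave one class; reject
        else:
            cand_model = model
        E_cand = compute_error(cand, cand_model, X=candX)
        if E_cand < E:
            config, X, model, E = cand, candX, cand_model, E_cand
            visit = visit[:j] + [True] + visit[j + 2 :]
            accepted_errors.append(E)
    return config, model, E, accepted_errors


def random_configuration_search(
    amp_sites: Sequence[AmpliconSites],
    selected_kmers: Sequence[str],
    delta: float = 1e-6,
    rng: Optional[np.random.Generator] = None,
    stage: str = "train",
    frozen_model: Optional[MixtureLogisticModel] = None,
    init_mode: str = "label-change",
    ridge: float = 1e-6,
    index: Optional[KmerOccurrenceIndex] = None,
    cell_type: str = "",
) -> SearchResult:
    """Repeated merging passes from the initial configuration.

    Stops when a pass improves the error by no more than ``delta`` and
    returns the last accepted state.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    if index is None:
        index = KmerOccurrenceIndex([a.amplicon for a in amp_sites], selected_kmers)
    config = initial_configuration(amp_sites, mode=init_mode, cell_type=cell_type)
    best: Optional[tuple[Configuration, MixtureLogisticModel, float]] = None
    E_prev = np.inf
    trace: list[dict] = []
    for pass_idx in itertools.count(1):
        C2, M2, E2, accepted = random_binary_merging(
            config, index, rng, stage=stage, frozen_model=frozen_model, ridge=ridge
        )
        if E_prev - E2 <= delta:
            if best is None:  # degenerate: first pass already below delta
                best = (C2, M2, E2)
                trace.append(
                    {
                        "pass": pass_idx,
                        "error": E2,
                        "n_segments": len(C2.segments),
                        "accepted_errors": accepted,
                    }
                )
            break
        best = (C2, M2, E2)
        E_prev = E2
        config = C2
        trace.append(
            {
                "pass": pass_idx,
                "error": E2,
                "n_segments": len(C2.segments),
                "accepted_errors": accepted,
            }
        )
    assert best is not None
    return SearchResult(best[0], best[1], best[2], trace)


def hill_climbing_search(
    amp_sites: Sequence[AmpliconSites],
    selected_kmers: Sequence[str],
    N_restarts: int = 10,
    delta: float = 1e-6,
    seed: int = 0,
    stage: str = "train",
    frozen_model: Optional[MixtureLogisticModel] = None,
    init_mode: str = "label-change",
    ridge: float = 1e-6,
    cell_type: str = "",
) -> SearchResult:
    """N independent restarts of the random configuration search, keeping
    the minimum-error result.  Deterministic given ``seed``."""
    if N_restarts < 1:
        raise ValueError("N_restarts must be >= 1")
    index = KmerOccurrenceIndex([a.amplicon for a in amp_sites], selected_kmers)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(N_restarts)
    best: Optional[SearchResult] = None
    trace: list[dict] = []
    for r, child in enumerate(children):
        res = random_configuration_search(
            amp_sites,
            selected_kmers,
            delta=delta,
            rng=np.random.default_rng(child),
            stage=stage,
            frozen_model=frozen_model,
            init_mode=init_mode,
            ridge=ridge,
            index=index,
            cell_type=cell_type,
        )
        trace.append(
            {
                "restart": r,
                "error": res.error,
                "n_segments": len(res.configuration.segments),
                "passes": res.trace,
            }
        )
        if best is None or res.error < best.error:
            best = res
    assert best is not None
    return SearchResult(best.configuration, best.model, best.error, trace)


# ------------------------------------------------------------- enumeration


def enumerate_all_configurations(
    amp_sites: Sequence[AmpliconSites],
    cell_type: str = "",
    max_bits: int = 20,
) -> Iterator[Configuration]:
    """All 2^m boundary settings, m = total gaps across amplicons.

    Guarded at ``max_bits`` boundary variables; intended as the exhaustive
    oracle on tiny instances.
    """
    amp_sites = [a for a in amp_sites if a.n_sites > 0]
    sizes = [a.n_sites - 1 for a in amp_sites]
    m = sum(sizes)
    if m > max_bits:
        raise ValueError(f"{m} boundary variables exceed the guard of {max_bits}")
    for bits in itertools.product((0, 1), repeat=m):
        boundaries = {}
        at = 0
        for asite, sz in zip(amp_sites, sizes):
            boundaries[asite.amplicon.id] = np.array(bits[at : at + sz], dtype=np.int8)
            at += sz
        yield configuration_from_boundaries(amp_sites, boundaries, cell_type)


@lru_cache(maxsize=None)
def parenthesization_count(n: int) -> int:
    """Number of full binary parenthesizations of n CpG sites.

    P(1) = 1;  P(n) = sum_{i=1}^{n-1} P(i) P(n-i)  for n >= 2.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        return 1
    return sum(
        parenthesization_count(i) * parenthesization_count(n - i)
        for i in range(1, n)
    )
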