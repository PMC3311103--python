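"""Synthetic bisulfite-style data with planted k-mer-driven block structure.

Each simulated amplicon carries CpG sites whose methylation levels are
block-structured along the sequence: the sites are partitioned into blocks,
and block susceptibility statuses *alternate* along the amplicon (a block
is by construction a maximal run of constant susceptibility, so adjacent
blocks always differ and ground-truth boundaries are well defined).  Copies
of planted k-mers are embedded in susceptible block spans; each block's
methylation probability comes from the logistic forward model

    q = logistic(gamma_0 + sum_c gamma_c * count of planted k-mer c in span)

with cell-type-specific effect vectors gamma over a shared sequence, and
site levels are drawn from Beta(q*kappa, (1-q)*kappa), so levels are
continuous like bisulfite-derived ratios with kappa controlling
within-block variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .io_data import AmpliconRecord, MethylationRecord
from .segment_search import Configuration

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "GenerationError",
    "generate",
    "boundary_recovery_score",
]


class GenerationError(ValueError):
    """The requested synthetic data cannot be generated."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic amplicon generator.

    ``planted`` maps each planted k-mer to its per-cell-type effect sizes
    (length ``n_cell_types``); ``gamma0`` is the background intercept of
    the logistic forward model.  ``block_mean`` is the mean number of CpG
    sites per true block; ``kappa`` the Beta concentration of site-level
    noise; ``embed_spacing`` the target bp between embedded k-mer copies
    within a susceptible block span.
    """

    n_amplicons: int = 60
    amplicon_length: int = 1000
    cpg_density: float = 0.02
    k: int = 6
    planted: dict[str, tuple[float, ...]] = field(default_factory=dict)
    gamma0: float = 0.0
    block_mean: float = 6.0
    kappa: float = 20.0
    n_cell_types: int = 2
    seed: int = 0
    embed_spacing: int = 150

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise GenerationError("kappa must be > 0")
        if self.block_mean < 1:
            raise GenerationError("block_mean must be >= 1")
        for kmer, gammas in self.planted.items():
            if set(kmer) - set("ACGT"):
                raise GenerationError(f"planted k-mer {kmer!r} not over ACGT")
            if "CG" in kmer:
                raise GenerationError(
                    f"planted k-mer {kmer!r} contains CG and would create sites"
                )
            if len(gammas) != self.n_cell_types:
                raise GenerationError(
                    f"effect vector for {kmer!r} must have {self.n_cell_types} entries"
                )
            if not all(np.isfinite(gammas)):
                raise GenerationError("effect sizes must be finite")

    @property
    def cell_types(self) -> list[str]:
        return [f"CT{c}" for c in range(self.n_cell_types)]

    @classmethod
    def strong_signal(cls, seed: int = 0, **kw) -> "SyntheticSpec":
        """Preset with |gamma| = 4 planted effects against a -2 background."""
        n_ct = kw.pop("n_cell_types", 2)
        planted = kw.pop(
            "planted",
            {
                "GATTAC": tuple(4.0 if c % 2 == 0 else 0.0 for c in range(n_ct)),
                "TCATGA": tuple(0.0 if c % 2 == 0 else 4.0 for c in range(n_ct)),
            },
        )
        return cls(
            planted=planted, gamma0=kw.pop("gamma0", -2.0),
            n_cell_types=n_ct, seed=seed, **kw,
        )

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "SyntheticSpec":
        """Zero effect sizes and zero intercept: every block's q = 0.5, so
        site labels are independent of sequence."""
        n_ct = kw.pop("n_cell_types", 2)
        planted = kw.pop("planted", {"GATTAC": tuple(0.0 for _ in range(n_ct))})
        return cls(
            planted=planted, gamma0=kw.pop("gamma0", 0.0),
            n_cell_types=n_ct, seed=seed, **kw,
        )


@dataclass
class GroundTruth:
    """Planted truth for one generated dataset.

    ``boundaries`` maps (amplicon id, cell type) to the sorted gap indices
    (0-based, between sites i and i+1) separating true blocks;
    ``block_probs`` gives each block's susceptibility probability q.
    """

    boundaries: dict[tuple[str, str], list[int]]
    block_probs: dict[tuple[str, str], list[float]]
    planted: dict[str, tuple[float, ...]]
    gamma0: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "boundaries": {f"{a}|{c}": v for (a, c), v in self.boundaries.items()},
                "block_probs": {f"{a}|{c}": v for (a, c), v in self.block_probs.items()},
                "planted": {k: list(v) for k, v in self.planted.items()},
                "gamma0": self.gamma0,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        split = lambda s: tuple(s.split("|", 1))
        return cls(
            boundaries={split(k): list(v) for k, v in d["boundaries"].items()},
            block_probs={split(k): list(v) for k, v in d["block_probs"].items()},
            planted={k: tuple(v) for k, v in d["planted"].items()},
            gamma0=d["gamma0"],
        )


def _background_sequence(rng: np.random.Generator, length: int) -> list[str]:
    """i.i.d. background with accidental CG dinucleotides removed."""
    bases = list(rng.choice(list("ACGT"), size=length))
    for i in range(length - 1):
        if bases[i] == "C" and bases[i + 1] == "G":
            bases[i + 1] = "A" if rng.random() < 0.5 else "T"
    return bases


def _block_sizes(rng: np.random.Generator, n_sites: int, mean: float) -> list[int]:
    sizes = []
    remaining = n_sites
    while remaining > 0:
        s = min(remaining, 1 + int(rng.poisson(max(mean - 1.0, 0.0))))
        sizes.append(s)
        remaining -= s
    return sizes


def _embed_kmer(
    bases: list[str],
    kmer: str,
    span: tuple[int, int],
    forbidden: list[tuple[int, int]],
    n_copies: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Overwrite background with k-mer copies inside span, never touching
    a forbidden interval (CpG sites, earlier embeds).  Returns the embedded
    intervals."""
    k = len(kmer)
    lo, hi = span
    placed: list[tuple[int, int]] = []
    starts = [
        q
        for q in range(lo, hi - k + 1)
        if all(q + k <= a or q >= b for a, b in forbidden)
    ]
    for _ in range(n_copies):
        if not starts:
            break
        q = int(rng.choice(starts))
        bases[q : q + k] = list(kmer)
        # a boundary CG can only involve background neighbors; break it
        if q > 0 and bases[q - 1] == "C" and kmer[0] == "G":
            bases[q - 1] = "A"
        if q + k < len(bases) and kmer[-1] == "C" and bases[q + k] == "G":
            bases[q + k] = "A"
        placed.append((q, q + k))
        forbidden.append((q, q + k))
        starts = [s for s in starts if s + k <= q or s >= q + k]
    return placed


def generate(
    spec: SyntheticSpec,
) -> tuple[list[AmpliconRecord], list[MethylationRecord], GroundTruth]:
    """Generate amplicons, a methylation table and the planted truth.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_cpg = int(round(spec.amplicon_length * spec.cpg_density))
    if n_cpg < 1:
        raise GenerationError("CpG density too low: no sites per amplicon")
    slot = spec.amplicon_length // n_cpg
    if slot < 6:
        raise GenerationError(
            f"infeasible CpG density {spec.cpg_density}: slots of {slot} bp "
            "cannot hold spaced CpG sites"
        )
    planted = list(spec.planted.items())
    gamma = np.array([g for _, g in planted], dtype=float)  # kmer x cell type

    amplicons: list[AmpliconRecord] = []
    records: list[MethylationRecord] = []
    boundaries: dict[tuple[str, str], list[int]] = {}
    block_probs: dict[tuple[str, str], list[float]] = {}

    for a_idx in range(spec.n_amplicons):
        amp_id = f"amp{a_idx:03d}"
        start = a_idx * (spec.amplicon_length + 100)
        bases = _background_sequence(rng, spec.amplicon_length)
        # one CpG per slot, placed away from slot edges so sites never abut
        offsets = np.array(
            [
                s * slot + 2 + int(rng.integers(0, max(slot - 5, 1)))
                for s in range(n_cpg)
            ]
        )
        forbidden = [(int(o), int(o) + 2) for o in offsets]
        # planting CG cannot create another CG with its neighbors
        for o in offsets:
            bases[o : o + 2] = ["C", "G"]
        sizes = _block_sizes(rng, n_cpg, spec.block_mean)
        cuts = np.cumsum(sizes)  # block b covers sites [cuts[b-1], cuts[b])
        gaps = [int(c - 1) for c in cuts[:-1]]  # boundary gap indices
        # block spans: first site's C .. last site's G
        block_site_ranges = [
            (int(cuts[b] - sizes[b]), int(cuts[b])) for b in range(len(sizes))
        ]
        block_spans = [
            (int(offsets[f]), int(offsets[l - 1]) + 2) for f, l in block_site_ranges
        ]

        # per cell type: alternating susceptibility with a random phase
        susceptible = np.zeros((len(sizes), spec.n_cell_types), dtype=bool)
        for c in range(spec.n_cell_types):
            phase = bool(rng.integers(0, 2))
            susceptible[:, c] = [(b % 2 == 0) == phase for b in range(len(sizes))]

        # embed each planted k-mer in the blocks susceptible for the cell
        # types it affects (positive effect sizes)
        for p_idx, (kmer, gammas) in enumerate(planted):
            active_cts = [c for c in range(spec.n_cell_types) if gammas[c] > 0]
            target_blocks = sorted(
                {
                    b
                    for c in active_cts
                    for b in range(len(sizes))
                    if susceptible[b, c]
                }
            )
            if not active_cts:  # zero-effect k-mers are embedded uniformly
                target_blocks = list(range(len(sizes)))
            for b in target_blocks:
                lo, hi = block_spans[b]
                n_copies = max(1, (hi - lo) // spec.embed_spacing)
                _embed_kmer(bases, kmer, (lo, hi), forbidden, n_copies, rng)

        sequence = "".join(bases)
        amp = AmpliconRecord(
            id=amp_id,
            chrom="synthetic",
            start=start,
            end=start + spec.amplicon_length,
            sequence=sequence,
        )
        amplicons.append(amp)

        # forward model: block q from embedded counts, site levels ~ Beta
        counts = np.array(
            [
                [sequence[lo:hi].count(kmer) for lo, hi in block_spans]
                for kmer, _ in planted
            ],
            dtype=float,
        )  # kmer x block
        for c, ct in enumerate(spec.cell_types):
            f = spec.gamma0 + (
                gamma[:, c] @ counts if planted else np.zeros(len(sizes))
            )
            q = np.clip(expit(f), 1e-9, 1 - 1e-9)
            boundaries[(amp_id, ct)] = gaps
            block_probs[(amp_id, ct)] = [float(v) for v in q]
            for b, (f_site, l_site) in enumerate(block_site_ranges):
                for s in range(f_site, l_site):
                    level = float(
                        rng.beta(q[b] * spec.kappa, (1 - q[b]) * spec.kappa)
                    )
                    records.append(
                        MethylationRecord(
                            chrom=amp.chrom,
                            pos=start + int(offsets[s]),
                            strand="+",
                            level=level,
                            coverage=30,
                            cell_type=ct,
                        )
                    )

    truth = GroundTruth(
        boundaries=boundaries,
        block_probs=block_probs,
        planted=dict(spec.planted),
        gamma0=spec.gamma0,
    )
    return amplicons, records, truth


def boundary_recovery_score(
    configuration: Configuration,
    truth: GroundTruth,
    amplicon_ids: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """Precision/recall/F1 of found boundary positions against the truth.

    Boundary positions (gaps with B = 1) are treated as a set per amplicon
    for the configuration's cell type.
    """
    ct = configuration.cell_type
    amp_ids = (
        list(amplicon_ids)
        if amplicon_ids is not None
        else sorted(configuration.boundaries)
    )
    found: set[tuple[str, int]] = set()
    true: set[tuple[str, int]] = set()
    for amp_id in amp_ids:
        if (amp_id, ct) not in truth.boundaries:
            raise ValueError(
                f"no ground truth for amplicon {amp_id!r}, cell type {ct!r}"
            )
        bits = configuration.boundaries[amp_id]
        found.update((amp_id, i) for i in range(len(bits)) if bits[i])
        true.update((amp_id, g) for g in truth.boundaries[(amp_id, ct)])
    tp = len(found & true)
    precision = tp / len(found) if found else (1.0 if not true else 0.0)
    recall = tp / len(true) if true else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}
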