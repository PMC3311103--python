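import numpy as np
import pytest
from scipy.special import logit
from scipy.stats import chisquare

import methylseg as ms
from methylseg.segment_search import (
    AmpliconSites,
    KmerOccurrenceIndex,
    configuration_from_boundaries,
    random_binary_merging,
)

from conftest import make_amplicon


def sites_fixture(labels, spacing=10, amp_id="a", seed=0, start=0):
    """An AmpliconSites with CpGs every ``spacing`` bp and given labels."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    bases = list(rng.choice(list("ACGT"), size=n * spacing + spacing))
    for i in range(len(bases) - 1):
        if bases[i] == "C" and bases[i + 1] == "G":
            bases[i + 1] = "T"
    offsets = np.arange(n) * spacing + 2
    for o in offsets:
        bases[o : o + 2] = ["C", "G"]
    amp = make_amplicon("".join(bases), amp_id=amp_id, start=start)
    levels = np.array([0.9 if lab == "+" else 0.1 for lab in labels])
    return AmpliconSites(amp, offsets, levels, np.array(labels))


def constant_model(p, kmers=("AAA",)):
    """A model predicting probability p for every segment."""
    return ms.MixtureLogisticModel(
        kmers=list(kmers), betas=[0.0] * len(kmers), intercept=float(logit(p))
    )


# ----------------------------------------------------------- labels, init


def test_label_sites_thresholds(strong_dataset):
    ds, _ = strong_dataset
    labels = ms.label_sites(ds, "CT0", 0.5)
    amp_id = ds.amplicons[0].id
    levels = [lvl for _, lvl in ds.sites_for(amp_id, "CT0")]
    assert labels[amp_id] == ["+" if lvl > 0.5 else "-" for lvl in levels]
    # threshold 0: everything above zero is +
    all_plus = ms.label_sites(ds, "CT0", 0.0)
    assert set(all_plus[amp_id]) == {"+"}


def test_initial_configuration_label_change():
    table = [sites_fixture(["+", "+", "-", "-", "+"])]
    config = ms.initial_configuration(table)
    assert [(s.first, s.last) for s in config.segments] == [(0, 1), (2, 3), (4, 4)]
    assert [s.label for s in config.segments] == ["+", "-", "+"]
    assert list(config.boundaries["a"]) == [0, 1, 0, 1]


def test_initial_configuration_uniform_labels_single_segment():
    config = ms.initial_configuration([sites_fixture(["+", "+", "+"])])
    assert len(config.segments) == 1
    assert config.segments[0].n_sites == 3


def test_initial_configuration_all_boundaries():
    config = ms.initial_configuration(
        [sites_fixture(["+", "-", "+", "-", "+"])], mode="all-boundaries"
    )
    assert len(config.segments) == 5
    assert all(s.n_sites == 1 for s in config.segments)


def test_site_label_tie_is_minus():
    amp = sites_fixture(["+", "+"]).amplicon
    recs = [
        ms.MethylationRecord("synthetic", 2, "+", 0.5, "A"),
        ms.MethylationRecord("synthetic", 12, "+", 0.8, "A"),
    ]
    ds = ms.assemble_dataset([amp], recs)
    assert ms.label_sites(ds, "A")["a"] == ["-", "+"]


# ------------------------------------------------- labels, weights, error


def test_segment_label_and_weight():
    table = [sites_fixture(["+", "+", "-", "-", "-", "-"])]
    config = ms.initial_configuration(table)  # sizes 2 and 4, S_bar = 3
    p, t, w = ms.segment_label_and_weight(config.segments[0], config)
    assert (p, t, w) == (1.0, "+", 1.5)
    p, t, w = ms.segment_label_and_weight(config.segments[1], config)
    assert (p, t, w) == (0.0, "-", 0.75)


def test_segment_majority_label_rule():
    # sites [+,+,-] -> p = 2/3, +; sites [+,-] -> p = 0.5, strict tie -> -
    table = [sites_fixture(["+", "+", "-"])]
    config = configuration_from_boundaries(table, {"a": np.zeros(2, dtype=int)})
    assert config.segments[0].p == pytest.approx(2 / 3)
    assert config.segments[0].label == "+"
    table = [sites_fixture(["+", "-"])]
    config = configuration_from_boundaries(table, {"a": np.zeros(1, dtype=int)})
    assert config.segments[0].p == 0.5
    assert config.segments[0].label == "-"


def test_segment_feature_matrix_counts_within_span():
    # CpGs at 2 and 4: one segment spanning seq[2:6] == "CGCG"
    amp = make_amplicon("TACGCGTT")
    table = [AmpliconSites(amp, np.array([2, 4]), np.array([0.9, 0.9]),
                           np.array(["+", "+"]))]
    config = ms.initial_configuration(table)
    X = ms.segment_feature_matrix(config, ["CGC", "GCG", "TTT"], [amp])
    assert X.tolist() == [[1.0, 1.0, 0.0]]


def test_merged_counts_at_least_max_of_parts():
    table = [sites_fixture(["+", "-", "+", "-"], seed=5)]
    amp = table[0].amplicon
    kmers = ["AC", "CG", "GT", "TA"]
    split = configuration_from_boundaries(table, {"a": np.array([1, 1, 1])})
    merged = configuration_from_boundaries(table, {"a": np.array([0, 1, 1])})
    Xs = ms.segment_feature_matrix(split, kmers, [amp])
    Xm = ms.segment_feature_matrix(merged, kmers, [amp])
    assert np.all(Xm[0] >= np.maximum(Xs[0], Xs[1]))


def test_compute_error_arithmetic():
    # segments of 2 and 4 sites, both +, model predicts 0.8 -> residual 0.2
    table = [sites_fixture(["+", "+", "+", "+", "+", "+"])]
    config = configuration_from_boundaries(table, {"a": np.array([0, 1, 0, 0, 0])})
    model = constant_model(0.8)
    X = np.zeros((2, 1))
    assert ms.compute_error(config, model, X=X) == pytest.approx(
        1.5 * 0.04 + 0.75 * 0.04
    )


def test_compute_error_perfect_fit_zero():
    table = [sites_fixture(["+", "+"])]
    config = ms.initial_configuration(table)
    model = constant_model(1 - 1e-12)
    assert ms.compute_error(config, model, X=np.zeros((1, 1))) < 1e-12


def test_sampling_error_vector_inverse_weighting():
    # sizes 2 and 4, residual 0.5 each, S_bar = 3 -> e = (2/3, 4/3) * 0.25
    table = [sites_fixture(["+", "+", "+", "+", "+", "+"])]
    config = configuration_from_boundaries(table, {"a": np.array([0, 1, 0, 0, 0])})
    e = ms.sampling_error_vector(config, constant_model(0.5), X=np.zeros((2, 1)))
    assert e == pytest.approx([0.25 * 2 / 3, 0.25 * 4 / 3])


def test_sampling_error_scales_quadratically():
    table = [sites_fixture(["+", "+"])]
    config = ms.initial_configuration(table)
    e1 = ms.sampling_error_vector(config, constant_model(0.9), X=np.zeros((1, 1)))
    e2 = ms.sampling_error_vector(config, constant_model(0.8), X=np.zeros((1, 1)))
    assert e2[0] == pytest.approx(4 * e1[0])


# ------------------------------------------------------------ random draws


def test_select_at_random_single_candidate():
    rng = np.random.default_rng(0)
    assert ms.select_at_random(np.array([0.7]), [False], rng) == 0


def test_select_at_random_proportional_frequencies():
    rng = np.random.default_rng(1)
    draws = [
        ms.select_at_random(np.array([1.0, 3.0]), [False, False], rng)
        for _ in range(10000)
    ]
    counts = np.bincount(draws, minlength=2)
    assert chisquare(counts, [2500, 7500]).pvalue > 0.01


def test_select_at_random_uniform_fallback():
    rng = np.random.default_rng(2)
    draws = [
        ms.select_at_random(np.zeros(3), [False, False, True], rng)
        for _ in range(3000)
    ]
    counts = np.bincount(draws, minlength=3)
    assert counts[2] == 0
    assert chisquare(counts[:2], [1500, 1500]).pvalue > 0.01


# -------------------------------------------------------------- merge pass


def _partition_ok(config, table):
    """Segments are contiguous, non-overlapping and cover all sites."""
    by_amp = {}
    for s in config.segments:
        by_amp.setdefault(s.amplicon_id, []).append((s.first, s.last))
    for asite in table:
        spans = sorted(by_amp.get(asite.amplicon.id, []))
        expected_next = 0
        for a, z in spans:
            if a != expected_next or z < a:
                return False
            expected_next = z + 1
        if expected_next != asite.n_sites:
            return False
    return True


def test_merging_pass_contract(strong_dataset):
    """After one pass every segment was considered, the count never grows,
    and segments still partition each amplicon's sites."""
    ds, _ = strong_dataset
    table = ms.build_site_table(ds, "CT0")[:6]
    kmers = ["GATTAC", "TCATGA", "ACGTAC", "TTTAAA"]
    index = KmerOccurrenceIndex([t.amplicon for t in table], kmers)
    config = ms.initial_configuration(table, cell_type="CT0")
    n0 = len(config.segments)
    out, model, E, accepted = random_binary_merging(
        config, index, np.random.default_rng(3), stage="train"
    )
    assert len(out.segments) <= n0
    assert _partition_ok(out, table)
    assert E >= 0
    # accepted-error sequence within the pass is strictly decreasing
    assert all(a > b for a, b in zip(accepted, accepted[1:]))


def _planted_sites(labels, ttt_at):
    """CpGs every 10 bp starting at offset 2, with TTT copies planted at
    the given offsets on an otherwise all-A background."""
    n = len(labels)
    bases = ["A"] * (10 * n + 10)
    for i in range(n):
        bases[10 * i + 2 : 10 * i + 4] = ["C", "G"]
    for q in ttt_at:
        bases[q : q + 3] = ["T", "T", "T"]
    amp = make_amplicon("".join(bases))
    offsets = np.arange(n) * 10 + 2
    levels = np.array([0.9 if lab == "+" else 0.1 for lab in labels])
    return [AmpliconSites(amp, offsets, levels, np.array(labels))]


def test_merge_rejected_when_model_fits_initial_perfectly():
    """A merge that flips the merged label against strong features is
    rejected and the configuration is unchanged."""
    # segments (+,+) and (-,-); TTT occurs only in the + span, and the
    # frozen model separates them perfectly, so E ~ 0.  Merging would give
    # a tie p = 0.5 -> label -, predicted ~1: error ~ 1, hence rejected.
    table = _planted_sites(["+", "+", "-", "-"], ttt_at=[5])
    config = configuration_from_boundaries(table, {"a": np.array([0, 1, 0])})
    index = KmerOccurrenceIndex([table[0].amplicon], ["TTT"])
    model = ms.MixtureLogisticModel(kmers=["TTT"], betas=[30.0], intercept=-15.0)
    assert ms.compute_error(config, model, X=np.array([[1.0], [0.0]])) < 1e-6
    out, _, E, accepted = random_binary_merging(
        config, index, np.random.default_rng(0), stage="test", frozen_model=model
    )
    assert accepted == []
    assert [(s.first, s.last) for s in out.segments] == [(0, 1), (2, 3)]


def test_merge_accepted_on_same_label_neighbors():
    """Adjacent same-label segments whose union the frozen model predicts
    better are merged, reducing the error."""
    # + block split into (+,+),(+,+); each half holds one TTT copy, the
    # union holds both; the model scores count 1 at 0.5 and count 2 at
    # 0.77, so merging the + halves lowers the objective.
    table = _planted_sites(["+", "+", "+", "+", "-", "-"], ttt_at=[5, 25])
    config = configuration_from_boundaries(
        table, {"a": np.array([0, 1, 0, 1, 0])}
    )
    index = KmerOccurrenceIndex([table[0].amplicon], ["TTT"])
    model = ms.MixtureLogisticModel(kmers=["TTT"], betas=[1.2], intercept=-1.2)
    E0 = ms.compute_error(
        config, model,
        X=ms.segment_feature_matrix(config, ["TTT"], [table[0].amplicon], index),
    )
    out, _, E, accepted = random_binary_merging(
        config, index, np.random.default_rng(1), stage="test", frozen_model=model
    )
    assert accepted, "expected at least one accepted merge"
    assert E < E0
    assert any(s.first == 0 and s.last >= 3 for s in out.segments)


# ------------------------------------------------------------- full search


def test_random_configuration_search_stops_with_huge_delta(strong_dataset):
    ds, _ = strong_dataset
    table = ms.build_site_table(ds, "CT0")[:5]
    res = ms.random_configuration_search(
        table, ["GATTAC", "ACGTAC"], delta=1.0, rng=np.random.default_rng(0)
    )
    assert len(res.trace) == 1  # returns after the first pass


def test_search_error_nonincreasing_across_passes(strong_dataset):
    ds, _ = strong_dataset
    table = ms.build_site_table(ds, "CT0")[:8]
    res = ms.random_configuration_search(
        table, ["GATTAC", "ACGTAC"], delta=1e-9, rng=np.random.default_rng(5)
    )
    errors = [p["error"] for p in res.trace]
    assert all(a > b for a, b in zip(errors, errors[1:]))


def test_hill_climbing_keeps_minimum_and_beats_initial(strong_dataset):
    ds, _ = strong_dataset
    table = ms.build_site_table(ds, "CT0")[:8]
    kmers = ["GATTAC", "ACGTAC", "TCATGA"]
    res = ms.hill_climbing_search(table, kmers, N_restarts=3, seed=4)
    assert res.error <= min(r["error"] for r in res.trace)
    # hill-climbing guarantee: no worse than the initial configuration
    config0 = ms.initial_configuration(table)
    X0 = ms.segment_feature_matrix(config0, kmers, [t.amplicon for t in table])
    model0 = ms.fit(X0, config0.labels01(), kmers=kmers)
    assert res.error <= ms.compute_error(config0, model0, X=X0) + 1e-12


def test_hill_climbing_deterministic(strong_dataset):
    ds, _ = strong_dataset
    table = ms.build_site_table(ds, "CT0")[:6]
    kmers = ["GATTAC", "ACGTAC"]
    a = ms.hill_climbing_search(table, kmers, N_restarts=2, seed=11)
    b = ms.hill_climbing_search(table, kmers, N_restarts=2, seed=11)
    assert a.error == b.error
    assert np.array_equal(a.model.betas, b.model.betas)
    for amp_id in a.configuration.boundaries:
        assert np.array_equal(
            a.configuration.boundaries[amp_id], b.configuration.boundaries[amp_id]
        )


def test_merging_only_clears_boundary_bits(strong_dataset):
    ds, _ = strong_dataset
    table = ms.build_site_table(ds, "CT0")[:6]
    res = ms.hill_climbing_search(table, ["GATTAC", "ACGTAC"], N_restarts=1, seed=2)
    init = ms.initial_configuration(table)
    for amp_id, bits in res.configuration.boundaries.items():
        assert np.all(init.boundaries[amp_id] >= bits)  # only 1 -> 0 moves


# -------------------------------------------------------------- enumeration


def test_enumerate_counts_and_invariants():
    single = [sites_fixture(["+"])]
    assert len(list(ms.enumerate_all_configurations(single))) == 1
    table = [sites_fixture(["+", "-", "+", "-"])]  # m = 3
    configs = list(ms.enumerate_all_configurations(table))
    assert len(configs) == 8
    seen = set()
    for c in configs:
        assert _partition_ok(c, table)
        seen.add(tuple(c.boundaries["a"]))
    assert len(seen) == 8


def test_enumerate_guard():
    table = [sites_fixture(["+"] * 25)]
    with pytest.raises(ValueError):
        list(ms.enumerate_all_configurations(table))


# --------------------------------------------------------- parenthesization


def _brute_parenthesizations(n):
    """Count full binary parenthesizations of n leaves by explicit
    construction (independent of the recurrence)."""
    if n == 1:
        return ["x"]
    out = []
    for i in range(1, n):
        for left in _brute_parenthesizations(i):
            for right in _brute_parenthesizations(n - i):
                out.append(f"({left}{right})")
    return out


@pytest.mark.parametrize("n,expected", [(1, 1), (2, 1), (4, 5)])
def test_parenthesization_printed_values(n, expected):
    assert ms.parenthesization_count(n) == expected


def test_parenthesization_matches_enumerator():
    for n in range(1, 11):
        distinct = set(_brute_parenthesizations(n))
        assert ms.parenthesization_count(n) == len(distinct)


def test_parenthesization_domain():
    with pytest.raises(ValueError):
        ms.parenthesization_count(0)
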