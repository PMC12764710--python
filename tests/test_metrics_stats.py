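import numpy as np
import pytest
from scipy import stats

from slicesurv.metrics_stats import (
    ModelPredictions,
    PairedRuns,
    acceptable_pairs,
    ctd_index,
    effect_size_r,
    permutation_paired_test,
    wilcoxon_exact,
)
from slicesurv.survival_head import T_MAX, SurvivalDistribution, SurvivalRecord

from conftest import random_distribution, random_record


def _preds(dists, records, ids=None):
    n = len(dists)
    ids = ids or tuple(f"p{i}" for i in range(n))
    return ModelPredictions(tuple(ids), tuple(dists), tuple(records))


def _dist_with_cif(points: dict[int, float]) -> SurvivalDistribution:
    """Build a distribution whose CIF passes through the given (t, F) points."""
    F = np.zeros(T_MAX + 1)
    for t, v in points.items():
        F[t] = v
    for t in range(1, T_MAX + 1):
        F[t] = max(F[t], F[t - 1])
    F[T_MAX] = 1.0
    return SurvivalDistribution(np.diff(F))


# ---------------------------------------------------------------------------
# acceptable_pairs
# ---------------------------------------------------------------------------

def test_acceptable_pairs_definition():
    records = [SurvivalRecord(2, 1), SurvivalRecord(4, 0)]
    assert acceptable_pairs(records) == {(0, 1)}


def test_acceptable_pairs_all_censored_empty():
    records = [SurvivalRecord(2, 0), SurvivalRecord(4, 0), SurvivalRecord(9, 0)]
    assert acceptable_pairs(records) == set()


def test_acceptable_pairs_matches_bruteforce(rng):
    records = [random_record(rng) for _ in range(5)]
    expected = {
        (i, j)
        for i, ri in enumerate(records)
        for j, rj in enumerate(records)
        if i != j and ri.k == 1 and ri.s < rj.s
    }
    assert acceptable_pairs(records) == expected


# ---------------------------------------------------------------------------
# ctd_index
# ---------------------------------------------------------------------------

def test_ctd_perfect_concordance():
    records = [SurvivalRecord(2, 1), SurvivalRecord(5, 1), SurvivalRecord(7, 1)]
    dists = [_dist_with_cif({2: 0.9, 5: 0.95}), _dist_with_cif({2: 0.5, 5: 0.8}),
             _dist_with_cif({2: 0.1, 5: 0.2})]
    assert ctd_index(_preds(dists, records)) == 1.0


def test_ctd_fully_reversed():
    records = [SurvivalRecord(2, 1), SurvivalRecord(5, 1), SurvivalRecord(7, 1)]
    dists = [_dist_with_cif({2: 0.1, 5: 0.2}), _dist_with_cif({2: 0.5, 5: 0.3}),
             _dist_with_cif({2: 0.9, 5: 0.95})]
    assert ctd_index(_preds(dists, records)) == 0.0


def test_ctd_hand_worked_example():
    # times (2, 5, 7), all events; pairwise CIF comparisons give 2 of 3 concordant
    records = [SurvivalRecord(2, 1), SurvivalRecord(5, 1), SurvivalRecord(7, 1)]
    dists = [_dist_with_cif({2: 0.9}), _dist_with_cif({2: 0.3, 5: 0.4}),
             _dist_with_cif({2: 0.2, 5: 0.6})]
    assert ctd_index(_preds(dists, records)) == pytest.approx(2 / 3)


def test_ctd_no_pairs_raises():
    records = [SurvivalRecord(5, 0), SurvivalRecord(7, 0)]
    dists = [_dist_with_cif({5: 0.4}), _dist_with_cif({5: 0.6})]
    with pytest.raises(ValueError, match="acceptable"):
        ctd_index(_preds(dists, records))


def _brute_force_ctd(dists, records, tie_weight=0.0):
    num = den = 0.0
    for i, ri in enumerate(records):
        for j, rj in enumerate(records):
            if i == j or ri.k != 1 or not ri.s < rj.s:
                continue
            den += 1
            fi = dists[i].cif()[ri.s]
            fj = dists[j].cif()[ri.s]
            if fi > fj:
                num += 1
            elif fi == fj:
                num += tie_weight
    return num / den


@pytest.mark.parametrize("trial", range(20))
def test_ctd_matches_bruteforce_oracle(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(4, 51))
    dists = [random_distribution(rng) for _ in range(n)]
    records = [random_record(rng) for _ in range(n)]
    if not acceptable_pairs(records):
        records[0] = SurvivalRecord(1, 1)
    preds = _preds(dists, records)
    assert ctd_index(preds) == pytest.approx(_brute_force_ctd(dists, records), abs=1e-12)


def test_ctd_invariant_under_reordering(rng):
    n = 20
    dists = [random_distribution(rng) for _ in range(n)]
    records = [random_record(rng) for _ in range(n)]
    records[0] = SurvivalRecord(1, 1)
    base = ctd_index(_preds(dists, records))
    perm = rng.permutation(n)
    shuffled = ctd_index(_preds([dists[i] for i in perm], [records[i] for i in perm],
                                ids=tuple(f"p{i}" for i in perm)))
    assert shuffled == pytest.approx(base)


def test_ctd_complement_sums_to_one(rng):
    # with continuous CIFs (no ties), C(F) + C(1 - F at comparison points) = 1
    n = 15
    dists = [random_distribution(rng) for _ in range(n)]
    records = [random_record(rng) for _ in range(n)]
    records[0] = SurvivalRecord(1, 1)
    forward = ctd_index(_preds(dists, records))
    # fraction of pairs with F_i < F_j, i.e. the complement model's concordance
    complement = 1.0 - _brute_force_ctd(dists, records, tie_weight=1.0)
    assert forward + complement == pytest.approx(1.0)


def test_ctd_tie_weight_option():
    records = [SurvivalRecord(2, 1), SurvivalRecord(5, 0)]
    d = _dist_with_cif({2: 0.4})
    preds = _preds([d, d], records)
    assert ctd_index(preds) == 0.0
    assert ctd_index(preds, tie_weight=0.5) == 0.5


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _random_preds_pair(rng, n=20):
    records = [random_record(rng) for _ in range(n)]
    records[0] = SurvivalRecord(1, 1)
    a = [random_distribution(rng) for _ in range(n)]
    b = [random_distribution(rng) for _ in range(n)]
    ids = tuple(f"p{i}" for i in range(n))
    return (_preds(a, records, ids), _preds(b, records, ids))


def test_permutation_identical_predictions_give_p_one(rng):
    a, _ = _random_preds_pair(rng)
    result = permutation_paired_test(a, a, n_perm=200, rng=rng)
    assert result["observed_diff"] == 0.0
    assert result["p_value"] == 1.0


def test_permutation_zero_permutations_rejected(rng):
    a, b = _random_preds_pair(rng)
    with pytest.raises(ValueError, match="n_perm"):
        permutation_paired_test(a, b, n_perm=0, rng=rng)


def test_permutation_patient_mismatch_rejected(rng):
    a, _ = _random_preds_pair(rng)
    b, _ = _random_preds_pair(np.random.default_rng(999), n=19)
    with pytest.raises(ValueError, match="same patients"):
        permutation_paired_test(a, b, n_perm=10, rng=rng)


def test_permutation_reproducible_under_seed(rng):
    a, b = _random_preds_pair(rng)
    r1 = permutation_paired_test(a, b, n_perm=500, rng=np.random.default_rng(5))
    r2 = permutation_paired_test(a, b, n_perm=500, rng=np.random.default_rng(5))
    assert r1 == r2


def _slow_permutation_reference(a, b, n_perm, rng):
    """Independent oracle: materialize swapped prediction sets and recompute
    the concordance difference from scratch for every permutation."""
    n = len(a)
    obs = ctd_index(a) - ctd_index(b)
    null = []
    for _ in range(n_perm):
        bits = rng.integers(0, 2, size=n)
        da = [b.distributions[i] if bits[i] else a.distributions[i] for i in range(n)]
        db = [a.distributions[i] if bits[i] else b.distributions[i] for i in range(n)]
        pa = _preds(da, list(a.records), a.patient_ids)
        pb = _preds(db, list(b.records), b.patient_ids)
        null.append(ctd_index(pa) - ctd_index(pb))
    null = np.array(null)
    return (1 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (n_perm + 1)


def test_permutation_agrees_with_high_rep_oracle():
    rng = np.random.default_rng(42)
    a, b = _random_preds_pair(rng, n=30)
    fast = permutation_paired_test(a, b, n_perm=20_000,
                                   rng=np.random.default_rng(1))["p_value"]
    slow = _slow_permutation_reference(a, b, 2_000, np.random.default_rng(2))
    assert fast == pytest.approx(slow, abs=0.02)


# ---------------------------------------------------------------------------
# Wilcoxon exact + effect size
# ---------------------------------------------------------------------------

def test_wilcoxon_six_same_sign():
    runs = PairedRuns(a=(0.57, 0.60, 0.55, 0.58, 0.61, 0.54),
                      b=(0.50, 0.52, 0.51, 0.49, 0.53, 0.48))
    stat, p = wilcoxon_exact(runs)
    assert stat == 0.0
    assert p == pytest.approx(0.03125)


def test_wilcoxon_single_difference():
    stat, p = wilcoxon_exact(PairedRuns(a=(1.0,), b=(0.5,)))
    assert stat == 0.0
    assert p == 1.0


def test_wilcoxon_all_zero_differences_rejected():
    with pytest.raises(ValueError, match="zero"):
        wilcoxon_exact(PairedRuns(a=(1.0, 2.0), b=(1.0, 2.0)))


def _enumerate_wilcoxon_p(diffs):
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w = min(w_plus, w_minus)
    total = ranks.sum()
    count = 0
    for signs in range(2**n):
        wp = sum(ranks[i] for i in range(n) if signs >> i & 1)
        if wp <= w + 1e-12 or wp >= total - w - 1e-12:
            count += 1
    return min(1.0, count / 2**n)


@pytest.mark.parametrize("diffs", [
    (1, -2, 3, -4, 5, -6),
    (0.3, 0.1, -0.2, 0.5, 0.4),
    (2, 2, -1, 3, -3, 1, 4),  # ties in |d|
])
def test_wilcoxon_matches_sign_flip_enumeration(diffs):
    runs = PairedRuns(a=tuple(diffs), b=tuple(0.0 for _ in diffs))
    stat, p = wilcoxon_exact(runs)
    assert p == pytest.approx(_enumerate_wilcoxon_p(diffs))


def test_wilcoxon_matches_scipy_exact(rng):
    for _ in range(10):
        d = rng.normal(size=8)
        _, p = wilcoxon_exact(PairedRuns(a=tuple(d), b=tuple(np.zeros(8))))
        ref = stats.wilcoxon(d, method="exact", alternative="two-sided").pvalue
        assert p == pytest.approx(ref, abs=1e-12)


def test_wilcoxon_null_cdf_n6():
    # every attainable statistic value for n = 6, against the enumerated null
    for w_obs in range(0, 11):
        counts = np.zeros(22)
        for signs in range(64):
            wp = sum(r for i, r in enumerate(range(1, 7)) if signs >> i & 1)
            counts[wp] += 1
        p_ref = min(1.0, (counts[: w_obs + 1].sum() + counts[21 - w_obs :].sum()) / 64)
        # construct differences with distinct magnitudes achieving W- = w_obs
        # (subset of ranks summing to w_obs gets negative sign)
        target, signs = w_obs, []
        for r in range(6, 0, -1):
            if target >= r:
                signs.append(-r)
                target -= r
            else:
                signs.append(r)
        assert target == 0
        stat, p = wilcoxon_exact(PairedRuns(a=tuple(signs), b=tuple(np.zeros(6))))
        assert stat == min(w_obs, 21 - w_obs)
        assert p == pytest.approx(p_ref)


def test_effect_size_printed_value():
    assert effect_size_r(0.0, 6) == pytest.approx(0.899, abs=5e-4)


def test_effect_size_null_mean_is_zero():
    n = 6
    assert effect_size_r(n * (n + 1) / 4, n) == 0.0


def test_effect_size_hand_computation():
    # (10.5 - 1) / sqrt(22.75) / sqrt(6)
    expected = (10.5 - 1) / np.sqrt(6 * 7 * 13 / 24) / np.sqrt(6)
    assert effect_size_r(1.0, 6) == pytest.approx(expected)
    assert effect_size_r(1.0, 6) == pytest.approx(0.8131, abs=5e-4)
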