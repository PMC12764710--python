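"""Evaluation metric and model-comparison statistics.

* time-dependent concordance index over admissible patient pairs,
* a permutation-based paired comparison that swaps the two models'
  predictions patient-by-patient with probability 0.5,
* an exact Wilcoxon signed-rank test (full enumeration of sign assignments)
  with its normal-approximation effect size r = |Z| / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival_head import SurvivalDistribution, SurvivalRecord

__all__ = [
    "ModelPredictions",
    "PairedRuns",
    "acceptable_pairs",
    "ctd_index",
    "permutation_paired_test",
    "wilcoxon_exact",
    "effect_size_r",
]


@dataclass(frozen=True)
class ModelPredictions:
    """Per-patient predicted distributions aligned with observed records."""

    patient_ids: tuple[str, ...]
    distributions: tuple[SurvivalDistribution, ...]
    records: tuple[SurvivalRecord, ...]

    def __post_init__(self):
        if not (len(self.patient_ids) == len(self.distributions) == len(self.records)):
            raise ValueError("ids, distributions and records must have equal length")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("patient identifiers must be unique")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def cif_matrix(self) -> np.ndarray:
        """(N, T_MAX + 1) matrix of cumulative incidence values, F(0) = 0."""
        return np.stack([d.cif() for d in self.distributions])


@dataclass(frozen=True)
class PairedRuns:
    """Two equal-length sequences of per-run performance values."""

    a: tuple[float, ...]
    b: tuple[float, ...]

    def __post_init__(self):
        if len(self.a) != len(self.b) or len(self.a) == 0:
            raise ValueError("paired runs must be nonempty and of equal length")
        if not all(np.isfinite(self.a)) or not all(np.isfinite(self.b)):
            raise ValueError("run values must be finite")

    @property
    def n(self) -> int:
        return len(self.a)

    def differences(self) -> np.ndarray:
        return np.asarray(self.a, dtype=float) - np.asarray(self.b, dtype=float)


def acceptable_pairs(records: list[SurvivalRecord]) -> set[tuple[int, int]]:
    """Ordered pairs (i, j) with k_i = 1 and s_i < s_j (j may be censored)."""
    if not records:
        raise ValueError("records must be nonempty")
    s = np.array([r.s for r in records])
    k = np.array([r.k for r in records])
    ii, jj = np.nonzero((k[:, None] == 1) & (s[:, None] < s[None, :]))
    return set(zip(ii.tolist(), jj.tolist()))


def _pair_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    s = np.array([r.s for r in records])
    k = np.array([r.k for r in records])
    return np.nonzero((k[:, None] == 1) & (s[:, None] < s[None, :]))


def ctd_index(preds: ModelPredictions, tie_weight: float = 0.0) -> float:
    """Fraction of admissible pairs whose CIFs at the earlier patient's event
    time are strictly correctly ordered. Ties contribute ``tie_weight``
    (0 as printed in the defining indicator; 0.5 optionally)."""
    pair_i, pair_j = _pair_arrays(preds.records)
    if len(pair_i) == 0:
        raise ValueError(
            "no acceptable pairs: need at least one uncensored patient whose "
            "event time precedes another patient's observed time"
        )
    cif = preds.cif_matrix()
    s = np.array([r.s for r in preds.records])
    f_i = cif[pair_i, s[pair_i]]
    f_j = cif[pair_j, s[pair_i]]
    concordant = (f_i > f_j).sum() + tie_weight * (f_i == f_j).sum()
    return float(concordant / len(pair_i))


def permutation_paired_test(
    preds_a: ModelPredictions,
    preds_b: ModelPredictions,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    tie_weight: float = 0.0,
) -> dict:
    """Two-sided paired comparison of two models' concordance.

    The observed statistic is ``ctd(a) - ctd(b)``; the null distribution is
    built by swapping the two models' predictions independently per patient
    with probability 0.5. The p-value uses add-one smoothing:
    ``(1 + #{|perm| >= |obs|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if preds_a.patient_ids != preds_b.patient_ids or preds_a.records != preds_b.records:
        raise ValueError("both prediction sets must cover the same patients and records")
    rng = rng if rng is not None else np.random.default_rng()

    pair_i, pair_j = _pair_arrays(preds_a.records)
    if len(pair_i) == 0:
        raise ValueError("no acceptable pairs for the concordance statistic")
    n = len(preds_a)
    s = np.array([r.s for r in preds_a.records])
    cif_a, cif_b = preds_a.cif_matrix(), preds_b.cif_matrix()

    def _conc(fi, fj):
        return ((fi > fj) + tie_weight * (fi == fj)).astype(float)

    npairs = len(pair_i)
    observed = float(
        _conc(cif_a[pair_i, s[pair_i]], cif_a[pair_j, s[pair_i]]).sum() / npairs
        - _conc(cif_b[pair_i, s[pair_i]], cif_b[pair_j, s[pair_i]]).sum() / npairs
    )

    # Precompute, per pair, the concordance contribution for the four
    # (model of i, model of j) combinations in both the a-side and b-side
    # statistic; a swap bit of 1 means the patient's a/b predictions traded.
    fa_i, fb_i = cif_a[pair_i, s[pair_i]], cif_b[pair_i, s[pair_i]]
    fa_j, fb_j = cif_a[pair_j, s[pair_i]], cif_b[pair_j, s[pair_i]]
    # a-side combo table indexed by code 2*bit_i + bit_j
    a_tab = np.stack(
        [_conc(fa_i, fa_j), _conc(fa_i, fb_j), _conc(fb_i, fa_j), _conc(fb_i, fb_j)]
    )
    b_tab = np.stack(
        [_conc(fb_i, fb_j), _conc(fb_i, fa_j), _conc(fa_i, fb_j), _conc(fa_i, fa_j)]
    )
    diff_tab = (a_tab - b_tab) / npairs  # (4, npairs)

    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, 20_000_000 // max(npairs, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        bits = rng.integers(0, 2, size=(m, n))
        codes = 2 * bits[:, pair_i] + bits[:, pair_j]  # (m, npairs)
        null[done : done + m] = np.take_along_axis(
            diff_tab.T[None, :, :], codes[:, :, None], axis=2
        )[:, :, 0].sum(axis=1)
        done += m

    p = (1.0 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (n_perm + 1.0)
    return {"observed_diff": observed, "p_value": float(p), "n_perm": n_perm}


def wilcoxon_exact(runs: PairedRuns, alternative: str = "two-sided") -> tuple[float, float]:
    """Exact Wilcoxon signed-rank test.

    Zero differences are dropped; |differences| are ranked with average ranks
    for ties; the statistic is the smaller of the two signed-rank sums. The
    p-value enumerates all 2^n sign assignments (n <= 25), no continuity
    correction. ``alternative`` is 'two-sided' or 'greater' (a tends to exceed
    b, i.e. the negative-rank sum is small).
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    d = runs.differences()
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25")
    order = np.abs(d).argsort(kind="stable")
    ranks = np.empty(n)
    # average ranks over ties
    sorted_abs = np.abs(d)[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)

    # exact null distribution of W+ via subset-sum counting on doubled ranks
    r2 = np.round(ranks * 2).astype(np.int64)
    total2 = int(r2.sum())
    counts = np.zeros(total2 + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total2 + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    if alternative == "greater":
        w2m = int(round(w_minus * 2))
        p = counts[: w2m + 1].sum()  # P(W- <= observed) under the null
    else:
        w2 = int(round(statistic * 2))
        p = counts[: w2 + 1].sum() + counts[total2 - w2 :].sum()
    return statistic, float(min(1.0, p))


def effect_size_r(statistic: float, n: int) -> float:
    """r = |Z| / sqrt(n) with the no-continuity-correction standardization
    Z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (statistic - mean) / sd
    return float(abs(z) / np.sqrt(n))
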