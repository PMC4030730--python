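"""Per-instance two-group tests with BH correction and expected values.

Each Monte Carlo instance of the clr ensemble is tested feature-by-feature
between the two conditions with Welch's unequal-variance t-test and the
Wilcoxon rank-sum test.  P values are Benjamini-Hochberg corrected across
features *within* each instance, and the per-feature expected value (mean
across instances) of both the raw and corrected values is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ConditionDesign
from .mc_clr_core import ClrEnsemble

#: p-value reported for complete separation with zero variance in both groups
TINY_P = np.finfo(float).tiny

#: largest total sample size for which the exact rank-sum null is used
WILCOXON_EXACT_MAX_N = 20

VALID_TESTS = ("welch", "wilcoxon")


@dataclass(frozen=True)
class InstanceStatistics:
    """Per-instance, per-feature p-values and BH values; shape (n_instances, n_features)."""

    feature_ids: tuple[str, ...]
    welch_p: np.ndarray | None = None
    welch_bh: np.ndarray | None = None
    wilcoxon_p: np.ndarray | None = None
    wilcoxon_bh: np.ndarray | None = None


def welch_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch unequal-variance t-test p-value.

    Zero variance in both groups is degenerate: returns 1.0 when the group
    means are equal (no evidence) and the smallest positive float when they
    differ (complete separation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(_welch_p_rows(a[None, :], b[None, :])[0])


def wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the pooled sample size is at most
    20 and there are no ties; otherwise the normal approximation with tie
    and continuity corrections.  Degenerate all-equal input gives 1.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(_wilcoxon_p_rows(a[None, :], b[None, :])[0])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    adjusted_(r) = min_{s >= r} p_(s) * m / s, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    np.minimum(adj, 1.0, out=adj)
    out = np.empty_like(adj)
    out[order] = adj
    # guard against ULP rounding in p * m / s dipping below p itself
    np.maximum(out, p, out=out)
    return out


def instance_statistics(
    ensemble: ClrEnsemble,
    design: ConditionDesign,
    tests: tuple[str, ...] = VALID_TESTS,
) -> InstanceStatistics:
    """Test every feature in every Monte Carlo instance and BH-correct.

    BH correction is applied across features within each instance, never
    after averaging.
    """
    for t in tests:
        if t not in VALID_TESTS:
            raise ValueError(f"unknown test {t!r}; choose from {VALID_TESTS}")
    idx_a, idx_b, _, _ = design.group_indices(ensemble.sample_ids)
    k, f, _ = ensemble.clr.shape
    fields: dict[str, np.ndarray | None] = {
        "welch_p": None, "welch_bh": None, "wilcoxon_p": None, "wilcoxon_bh": None
    }
    for test in tests:
        p = np.empty((k, f))
        bh = np.empty((k, f))
        rows = _welch_p_rows if test == "welch" else _wilcoxon_p_rows
        for i in range(k):
            a = ensemble.clr[i][:, idx_a]
            b = ensemble.clr[i][:, idx_b]
            p[i] = rows(a, b)
            bh[i] = bh_adjust(p[i])
        fields[f"{test}_p"] = p
        fields[f"{test}_bh"] = bh
    return InstanceStatistics(ensemble.feature_ids, **fields)


def expected_statistics(
    stats_: InstanceStatistics, method: str = "mean"
) -> pd.DataFrame:
    """Summarise instance statistics per feature across instances.

    ``method='mean'`` gives the expected value (the default); ``'median'``
    is available as a robust alternative.  Columns follow the result-table
    naming: we_ep / we_eBH for Welch, wi_ep / wi_eBH for Wilcoxon; a test
    that was not run yields NaN columns.
    """
    if method == "mean":
        agg = lambda x: x.mean(axis=0)  # noqa: E731
    elif method == "median":
        agg = lambda x: np.median(x, axis=0)  # noqa: E731
    else:
        raise ValueError("method must be 'mean' or 'median'")
    n = len(stats_.feature_ids)
    nan = np.full(n, np.nan)
    cols = {
        "we_ep": stats_.welch_p,
        "we_eBH": stats_.welch_bh,
        "wi_ep": stats_.wilcoxon_p,
        "wi_eBH": stats_.wilcoxon_bh,
    }
    data = {name: (nan if arr is None else agg(arr)) for name, arr in cols.items()}
    return pd.DataFrame({"feature_id": list(stats_.feature_ids), **data})


def _welch_p_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised Welch p-values for row-aligned groups a (F, na), b (F, nb)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1), rtol=0, atol=0)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = TINY_P
    p[np.isnan(p)] = 1.0
    return p


def _wilcoxon_p_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised rank-sum p-values; exact where the null can be enumerated."""
    f = a.shape[0]
    n_total = a.shape[1] + b.shape[1]
    pooled = np.sort(np.concatenate([a, b], axis=1), axis=1)
    has_ties = np.any(np.diff(pooled, axis=1) == 0, axis=1)
    p = np.empty(f)
    exact = (~has_ties) if n_total <= WILCOXON_EXACT_MAX_N else np.zeros(f, bool)
    if exact.any():
        res = stats.mannwhitneyu(
            a[exact], b[exact], axis=1, alternative="two-sided", method="exact"
        )
        p[exact] = res.pvalue
    approx = ~exact
    if approx.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.mannwhitneyu(
                a[approx],
                b[approx],
                axis=1,
                alternative="two-sided",
                method="asymptotic",
                use_continuity=True,
            )
        pv = np.asarray(res.pvalue, dtype=float)
        pv[np.isnan(pv)] = 1.0  # all-tied rows: rank variance 0, no evidence
        p[approx] = pv
    return np.clip(p, 0.0, 1.0)
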