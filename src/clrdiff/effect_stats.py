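"""Between/within-condition difference distributions and effect sizes.

For every Monte Carlo instance a set of random sample pairings is drawn:
the between-condition difference is the clr value of a random sample of
condition B minus that of a random sample of A; the within-condition
dispersion is, per draw, the larger of the two groups' absolute differences
between two distinct random samples.  Medians of these distributions give
diff_btw, diff_win and the per-feature effect size (median of the paired
between/within ratios).

Pairing indices for each group are drawn from a substream keyed by the
group's sample-identifier set, so exchanging the two condition labels
negates every between-condition draw exactly (effect antisymmetry).
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .io_tables import ConditionDesign
from .mc_clr_core import ClrEnsemble

#: floor applied to within-condition dispersions before forming ratios
DIFF_WIN_FLOOR = 1e-3


def abundance_medians(
    ensemble: ClrEnsemble, design: ConditionDesign
) -> pd.DataFrame:
    """Median clr relative abundance per feature: overall and per condition."""
    idx_a, idx_b, _, _ = design.group_indices(ensemble.sample_ids)
    clr = ensemble.clr
    return pd.DataFrame(
        {
            "feature_id": list(ensemble.feature_ids),
            "rab_all": np.median(clr, axis=(0, 2)),
            "rab_condA": np.median(clr[:, :, idx_a], axis=(0, 2)),
            "rab_condB": np.median(clr[:, :, idx_b], axis=(0, 2)),
        }
    )


def difference_distributions(
    ensemble: ClrEnsemble,
    design: ConditionDesign,
    seed: int | None = None,
    n_draws: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo draws of between-differences and within-dispersions.

    Returns ``(between, within)`` arrays of shape
    (n_instances, n_features, n_draws), paired along the draw axis; the
    default number of draws per instance is the larger group size.
    """
    idx_a, idx_b, _, _ = design.group_indices(ensemble.sample_ids)
    n_a, n_b = len(idx_a), len(idx_b)
    if min(n_a, n_b) < 2:
        raise ValueError("each condition needs >= 2 samples to form within-pairs")
    if n_draws is None:
        n_draws = max(n_a, n_b)
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0])
    k = ensemble.n_instances
    ids_a = [ensemble.sample_ids[i] for i in idx_a]
    ids_b = [ensemble.sample_ids[i] for i in idx_b]
    rng_a = _group_rng(seed, ids_a)
    rng_b = _group_rng(seed, ids_b)
    arr_a = ensemble.clr[:, :, idx_a]  # (k, f, n_a)
    arr_b = ensemble.clr[:, :, idx_b]

    win_a, btw_a = _group_draws(rng_a, arr_a, n_a, k, n_draws)
    win_b, btw_b = _group_draws(rng_b, arr_b, n_b, k, n_draws)
    between = btw_b - btw_a
    within = np.maximum(win_a, win_b)
    return between, within


def effect_size(
    between: np.ndarray,
    within: np.ndarray,
    win_floor: float = DIFF_WIN_FLOOR,
) -> pd.DataFrame:
    """Summarise paired difference draws into diff_btw, diff_win and effect.

    diff_btw and diff_win are medians over all draws; effect is the median
    of the per-draw ratios between / max(within, win_floor), which keeps
    the sign of the between-differences while scaling by within-condition
    dispersion.
    """
    if between.shape != within.shape:
        raise ValueError("between and within draws must be paired (same shape)")
    # collapse (instances, draws) onto one axis per feature
    btw = np.moveaxis(between, 1, 0).reshape(between.shape[1], -1)
    win = np.moveaxis(within, 1, 0).reshape(within.shape[1], -1)
    diff_btw = np.median(btw, axis=1)
    diff_win = np.maximum(np.median(win, axis=1), win_floor)
    ratios = btw / np.maximum(win, win_floor)
    effect = np.median(ratios, axis=1)
    return pd.DataFrame(
        {"diff_btw": diff_btw, "diff_win": diff_win, "effect": effect}
    )


def summarize(
    ensemble: ClrEnsemble,
    design: ConditionDesign,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-feature abundance medians plus difference/effect summaries."""
    medians = abundance_medians(ensemble, design)
    between, within = difference_distributions(ensemble, design, seed=seed)
    eff = effect_size(between, within)
    return pd.concat([medians, eff], axis=1)


def _group_rng(seed: int, sample_ids: list[str]) -> np.random.Generator:
    # keyed by the group's sample set so draws follow the samples, not the label
    digest = hashlib.sha256("\x1f".join(sorted(sample_ids)).encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _group_draws(
    rng: np.random.Generator,
    arr: np.ndarray,
    n: int,
    k: int,
    n_draws: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-pair absolute differences and between-candidate picks for one group."""
    i = rng.integers(n, size=(k, 1, n_draws))
    off = rng.integers(1, n, size=(k, 1, n_draws))
    j = (i + off) % n
    pick = rng.integers(n, size=(k, 1, n_draws))
    within = np.abs(
        np.take_along_axis(arr, i, axis=2) - np.take_along_axis(arr, j, axis=2)
    )
    between = np.take_along_axis(arr, pick, axis=2)
    return within, between
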