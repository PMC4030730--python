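"""Monte Carlo sampling of per-sample proportions and clr transformation.

Counts for each sample are converted to posterior proportion instances by
drawing from a Dirichlet distribution whose concentration vector is the
count vector plus a uniform prior (default 1/2).  Each instance is then
centred log-ratio transformed in base 2, so differences between features
read as log2 fold changes in relative abundance.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .io_tables import CountTable

log = logging.getLogger(__name__)

DEFAULT_N_INSTANCES = 128
DEFAULT_PRIOR = 0.5


@dataclass(frozen=True)
class ClrEnsemble:
    """clr-transformed proportion instances, indexed [instance, feature, sample]."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    clr: np.ndarray  # (n_instances, n_features, n_samples), log2 units
    proportions: np.ndarray | None = None  # same shape, optional

    def __post_init__(self) -> None:
        if self.clr.ndim != 3:
            raise ValueError("clr array must be 3-D [instance, feature, sample]")
        k, f, s = self.clr.shape
        if k < 1:
            raise ValueError("at least one Monte Carlo instance is required")
        if (f, s) != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("clr array shape does not match identifier lists")

    @property
    def n_instances(self) -> int:
        return self.clr.shape[0]

    @property
    def n_features(self) -> int:
        return self.clr.shape[1]

    @property
    def n_samples(self) -> int:
        return self.clr.shape[2]


def filter_features(table: CountTable) -> CountTable:
    """Drop features whose counts are zero in every sample.

    Feature order is preserved; the removed identifiers are logged.  Raises
    if nothing survives the filter.
    """
    keep = table.counts.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("all features have zero counts in every sample")
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    if removed:
        log.info(
            "removed %d all-zero feature(s): %s",
            len(removed),
            ", ".join(removed[:10]) + ("..." if len(removed) > 10 else ""),
        )
    if not removed:
        return table
    return table.subset_features(keep)


def clr_transform(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centred log-ratio transform in base 2 along ``axis``.

    ``out = log2(x) - mean(log2(x))``, i.e. each part expressed relative to
    the geometric mean of all parts.  Scale invariant: closing ``x`` to
    proportions first changes nothing.  All entries must be strictly
    positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("clr_transform requires strictly positive values")
    lx = np.log2(x)
    return lx - lx.mean(axis=axis, keepdims=True)


def sample_dirichlet_instances(
    table: CountTable,
    n_instances: int = DEFAULT_N_INSTANCES,
    prior: float = DEFAULT_PRIOR,
    seed: int | None = None,
) -> np.ndarray:
    """Draw posterior proportion instances for every sample.

    For sample j with count vector n_j, each instance is one draw from
    Dirichlet(n_j + prior); zero counts therefore always yield strictly
    positive proportions.  Each sample gets an independent substream keyed
    by (seed, sample identifier), so a sample's draws do not depend on its
    column position or on processing order.

    Returns an array of shape (n_instances, n_features, n_samples).
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if not prior > 0:
        raise ValueError("prior must be a positive real")
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0])
    counts = table.counts
    n_features, n_samples = counts.shape
    out = np.empty((n_instances, n_features, n_samples))
    tiny = np.finfo(float).tiny
    for j in range(n_samples):
        rng = _sample_rng(seed, table.sample_ids[j])
        alpha = counts[:, j].astype(float) + prior
        draws = rng.dirichlet(alpha, size=n_instances)
        # guard against representable-zero underflow for very small alpha
        np.maximum(draws, tiny, out=draws)
        draws /= draws.sum(axis=1, keepdims=True)
        out[:, :, j] = draws
    return out


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    digest = hashlib.sha256(sample_id.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def build_ensemble(
    table: CountTable,
    n_instances: int = DEFAULT_N_INSTANCES,
    prior: float = DEFAULT_PRIOR,
    seed: int | None = None,
    keep_proportions: bool = False,
) -> ClrEnsemble:
    """Sample Dirichlet instances and clr-transform each one per sample.

    The table must already be free of all-zero features (see
    :func:`filter_features`).  Deterministic for a fixed seed.
    """
    if np.any(table.counts.sum(axis=1) == 0):
        raise ValueError(
            "table contains all-zero features; apply filter_features first"
        )
    props = sample_dirichlet_instances(table, n_instances, prior, seed)
    clr = clr_transform(props, axis=1)
    return ClrEnsemble(
        table.feature_ids,
        table.sample_ids,
        clr,
        proportions=props if keep_proportions else None,
    )
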