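"""Simulated count tables with known ground truth.

Three generators share a common recipe: a baseline composition is drawn
once from a log-normal abundance model, optionally perturbed per condition,
and every sample is a multinomial draw at roughly the requested depth
(uniform +/-10% jitter emulates unequal sequencing effort).  Per-sample
log-normal overdispersion (``sample_log2_sigma``) adds biological
between-replicate variation on top of counting noise.

* ``generate_null``     - no differential features.
* ``generate_selex``    - a minority of features enriched in condition B,
                          nothing depleted (selective-growth design).
* ``generate_shift``    - symmetric design, half the differential features
                          up in B and half down.

Truth labels are returned as an integer vector per feature: +1 enriched in
B, -1 depleted in B, 0 unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_tables import ConditionDesign, CountTable

DEPTH_JITTER = 0.10


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a simulated two-condition experiment."""

    n_features: int
    n_per_group: int
    depth: float
    enriched_fraction: float = 0.0
    log2_fold_change: float = 0.0
    abundance_log_sigma: float = 2.0  # spread of the baseline log-normal
    sample_log2_sigma: float = 0.0  # per-sample biological overdispersion
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3 (minimum group size)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.enriched_fraction < 1:
            raise ValueError("enriched_fraction must lie in [0, 1)")
        if self.log2_fold_change != 0 and self.enriched_fraction > 0:
            if round(self.enriched_fraction * self.n_features) < 1:
                raise ValueError(
                    "enriched_fraction * n_features must be >= 1 for a "
                    "non-zero fold change"
                )
        if self.depth < self.n_features:
            warnings.warn(
                "sequencing depth below the number of features; most "
                "features will have zero counts",
                stacklevel=3,
            )

    @property
    def n_enriched(self) -> int:
        return int(round(self.enriched_fraction * self.n_features))


def generate_null(
    spec: SyntheticSpec,
) -> tuple[CountTable, ConditionDesign, np.ndarray]:
    """Two groups sampled from one shared composition (no true differences)."""
    rng_base, _, rng_sample = _rngs(spec)
    base = _baseline(rng_base, spec)
    counts = np.concatenate(
        [
            _sample_group(rng_sample, base, spec),
            _sample_group(rng_sample, base, spec),
        ],
        axis=1,
    )
    table, design = _package(counts, spec)
    return table, design, np.zeros(spec.n_features, dtype=np.int8)


def generate_selex(
    spec: SyntheticSpec,
) -> tuple[CountTable, ConditionDesign, np.ndarray]:
    """Selective-growth design: enriched features rise in B, none fall.

    The enriched features are chosen among the *less* abundant half of the
    baseline so the bulk composition is only mildly distorted by closure.
    """
    if spec.enriched_fraction <= 0:
        raise ValueError("generate_selex requires enriched_fraction > 0")
    rng_base, rng_choice, rng_sample = _rngs(spec)
    base = _baseline(rng_base, spec)
    truth = np.zeros(spec.n_features, dtype=np.int8)
    candidates = np.argsort(base)[: max(spec.n_enriched, spec.n_features // 2)]
    chosen = rng_choice.choice(candidates, size=spec.n_enriched, replace=False)
    truth[chosen] = 1
    boosted = base.copy()
    boosted[chosen] *= 2.0 ** spec.log2_fold_change
    boosted /= boosted.sum()
    counts = np.concatenate(
        [
            _sample_group(rng_sample, base, spec),
            _sample_group(rng_sample, boosted, spec),
        ],
        axis=1,
    )
    table, design = _package(counts, spec)
    return table, design, truth


def generate_shift(
    spec: SyntheticSpec,
) -> tuple[CountTable, ConditionDesign, np.ndarray]:
    """Symmetric two-group design: half the differential features up, half down."""
    rng_base, rng_choice, rng_sample = _rngs(spec)
    base = _baseline(rng_base, spec)
    truth = np.zeros(spec.n_features, dtype=np.int8)
    n_diff = spec.n_enriched
    chosen = rng_choice.choice(spec.n_features, size=n_diff, replace=False)
    truth[chosen[: n_diff // 2]] = 1
    truth[chosen[n_diff // 2 :]] = -1
    shifted = base * 2.0 ** (spec.log2_fold_change * truth)
    shifted /= shifted.sum()
    counts = np.concatenate(
        [
            _sample_group(rng_sample, base, spec),
            _sample_group(rng_sample, shifted, spec),
        ],
        axis=1,
    )
    table, design = _package(counts, spec)
    return table, design, truth


def write_truth(truth: np.ndarray, feature_ids: tuple[str, ...], path) -> None:
    """Write truth labels as a two-column TSV (feature_id, direction)."""
    with open(path, "w") as fh:
        for fid, t in zip(feature_ids, truth):
            fh.write(f"{fid}\t{int(t)}\n")


def _rngs(
    spec: SyntheticSpec,
) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    # independent substreams so e.g. the choice of enriched features does not
    # perturb the count sampling (zero fold change then reduces to the null)
    base, choice, sampling = np.random.SeedSequence(spec.seed).spawn(3)
    return (
        np.random.default_rng(base),
        np.random.default_rng(choice),
        np.random.default_rng(sampling),
    )


def _baseline(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    logs = rng.normal(0.0, spec.abundance_log_sigma, size=spec.n_features)
    props = np.exp(logs)
    return props / props.sum()


def _sample_group(
    rng: np.random.Generator, props: np.ndarray, spec: SyntheticSpec
) -> np.ndarray:
    cols = []
    ln2 = np.log(2.0)
    for _ in range(spec.n_per_group):
        p = props
        if spec.sample_log2_sigma > 0:
            jitter = rng.normal(0.0, spec.sample_log2_sigma, size=p.size)
            p = p * np.exp(ln2 * jitter)
            p = p / p.sum()
        depth = int(round(spec.depth * rng.uniform(1 - DEPTH_JITTER, 1 + DEPTH_JITTER)))
        cols.append(rng.multinomial(depth, p))
    return np.stack(cols, axis=1)


def _package(
    counts: np.ndarray, spec: SyntheticSpec
) -> tuple[CountTable, ConditionDesign]:
    width = len(str(spec.n_features))
    feature_ids = tuple(f"F{i:0{width}d}" for i in range(1, spec.n_features + 1))
    sample_ids = tuple(
        [f"A{i}" for i in range(1, spec.n_per_group + 1)]
        + [f"B{i}" for i in range(1, spec.n_per_group + 1)]
    )
    table = CountTable(feature_ids, sample_ids, counts)
    design = ConditionDesign(
        {s: ("A" if s.startswith("A") else "B") for s in sample_ids}
    )
    return table, design
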