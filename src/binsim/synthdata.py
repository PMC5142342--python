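"""Synthetic formula × ingredient matrices.

Three generators cover every input the pipeline needs:

* ``random_matrix`` — i.i.d. Bernoulli cells at a fixed density (the 1%, 5%
  and 10% random controls);
* ``row_count_matrix`` — every row gets an exact prescribed number of ones at
  uniformly random positions; row counts may be drawn from a truncated
  discrete normal (the Jamu-like profile: mean 4.904, sd 2.969, range 1–26,
  or the Kampo-like profile: mean 8.923, sd 3.885, range 3–19);
* ``structured_dataset`` — class-labeled formulas whose ingredients
  concentrate in a per-class pool, so same-class pairs genuinely overlap
  more than cross-class pairs and the ROC analysis has signal to recover.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .dataset_io import BinaryDataset

__all__ = [
    "RowCountDistribution",
    "JAMU_ROW_COUNTS",
    "KAMPO_ROW_COUNTS",
    "SynthConfig",
    "random_matrix",
    "row_count_matrix",
    "structured_dataset",
]


@dataclass(frozen=True)
class RowCountDistribution:
    """Truncated discrete normal over [min_count, max_count].

    Draws are normal(mean, sd) rounded to the nearest integer; values
    outside the range are redrawn.  Only the mean, sd and range of the
    emulated per-formula ingredient counts are pinned down; the family is a
    modelling choice.
    """

    mean: float
    sd: float
    min_count: int
    max_count: int

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(size, dtype=np.int64)
        filled = 0
        while filled < size:
            draw = np.rint(rng.normal(self.mean, self.sd, size=size - filled))
            keep = draw[(draw >= self.min_count) & (draw <= self.max_count)]
            out[filled:filled + keep.size] = keep.astype(np.int64)
            filled += keep.size
        return out


# Per-formula ingredient-count profiles of the two herbal-medicine corpora.
JAMU_ROW_COUNTS = RowCountDistribution(4.904, 2.969, 1, 26)
KAMPO_ROW_COUNTS = RowCountDistribution(8.923, 3.885, 3, 19)


@dataclass
class SynthConfig:
    """Parameters of the class-structured generator.

    Defaults are the package's desk-scale stand-in for a labeled
    herbal-medicine corpus: 200 formulas over 101 ingredients in 4 efficacy
    classes, each class owning a 20-ingredient pool; every ingredient pick
    lands in the formula's class pool with probability ``p_in`` and is
    uniform over all ingredients otherwise; per-formula ingredient counts
    follow the Kampo-like profile.
    """

    n_formulas: int = 200
    n_ingredients: int = 101
    n_classes: int = 4
    pool_size: int = 20
    p_in: float = 0.5
    row_counts: RowCountDistribution = field(
        default_factory=lambda: KAMPO_ROW_COUNTS)
    multilabel_fraction: float = 0.0
    seed: int | None = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 <= self.p_in <= 1.0:
            raise ValueError("p_in must lie in [0, 1]")
        if not 0.0 <= self.multilabel_fraction <= 1.0:
            raise ValueError("multilabel_fraction must lie in [0, 1]")
        if self.pool_size < self.row_counts.max_count:
            raise ValueError(
                f"pool_size {self.pool_size} smaller than the maximum row "
                f"count {self.row_counts.max_count}"
            )
        if self.pool_size * 1 > self.n_ingredients:
            raise ValueError("pool_size exceeds the ingredient universe")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "row_counts" in raw:
            raw["row_counts"] = RowCountDistribution(**raw["row_counts"])
        return cls(**raw)


def _ids(prefix: str, count: int) -> list[str]:
    width = len(str(count))
    return [f"{prefix}{k + 1:0{width}d}" for k in range(count)]


def random_matrix(n_formulas: int, n_ingredients: int, density: float,
                  seed=None) -> BinaryDataset:
    """Uniform-density random matrix: i.i.d. Bernoulli(density) cells."""
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    rng = np.random.default_rng(seed)
    matrix = (rng.random((n_formulas, n_ingredients)) < density).astype(np.int8)
    return BinaryDataset(_ids("F", n_formulas), _ids("I", n_ingredients),
                         matrix)


def row_count_matrix(row_counts, n_ingredients: int,
                     seed=None, n_formulas: int | None = None) -> BinaryDataset:
    """Matrix with exact per-row ones counts at uniform random positions.

    ``row_counts`` is either an explicit integer sequence (one entry per
    formula) or a :class:`RowCountDistribution` (requires ``n_formulas``).
    """
    rng = np.random.default_rng(seed)
    if isinstance(row_counts, RowCountDistribution):
        if n_formulas is None:
            raise ValueError("n_formulas required with a distribution")
        counts = row_counts.sample(n_formulas, rng)
    else:
        counts = np.asarray(row_counts, dtype=np.int64)
    if (counts < 0).any() or (counts > n_ingredients).any():
        raise ValueError("row counts must lie in [0, n_ingredients]")
    matrix = np.zeros((counts.size, n_ingredients), dtype=np.int8)
    for row, k in enumerate(counts):
        matrix[row, rng.choice(n_ingredients, size=k, replace=False)] = 1
    return BinaryDataset(_ids("F", counts.size), _ids("I", n_ingredients),
                         matrix)


def structured_dataset(config: SynthConfig | None = None,
                       seed=None) -> BinaryDataset:
    """Class-structured labeled dataset with recoverable ROC signal.

    Classes own contiguous, disjoint ingredient pools (wrapping if pools
    exhaust the universe).  Each formula belongs to one class; each of its
    ingredient picks is uniform over the class pool with probability
    ``p_in`` and uniform over all ingredients otherwise, so
    E[within-class overlap] > E[between-class overlap] whenever p_in
    exceeds the baseline density.  A ``multilabel_fraction`` of formulas
    receives a second class code (label only, not ingredients) to exercise
    multi-label match rules.
    """
    if config is None:
        config = SynthConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    v = config.n_ingredients
    pools = [
        np.arange(g * config.pool_size, (g + 1) * config.pool_size) % v
        for g in range(config.n_classes)
    ]
    classes = rng.integers(config.n_classes, size=config.n_formulas)
    counts = config.row_counts.sample(config.n_formulas, rng)
    matrix = np.zeros((config.n_formulas, v), dtype=np.int8)
    base = np.full(v, (1.0 - config.p_in) / v)
    weights_per_class = []
    for g in range(config.n_classes):
        w = base.copy()
        w[pools[g]] += config.p_in / len(pools[g])
        weights_per_class.append(w / w.sum())
    for row in range(config.n_formulas):
        picks = rng.choice(v, size=counts[row], replace=False,
                           p=weights_per_class[classes[row]])
        matrix[row, picks] = 1
    formula_ids = _ids("F", config.n_formulas)
    labels = {}
    second = rng.random(config.n_formulas) < config.multilabel_fraction
    for row, fid in enumerate(formula_ids):
        codes = {f"E{classes[row] + 1}"}
        if second[row]:
            other = (classes[row] + 1 + rng.integers(config.n_classes - 1)
                     ) % config.n_classes
            codes.add(f"E{other + 1}")
        labels[fid] = frozenset(codes)
    return BinaryDataset(formula_ids, _ids("I", v), matrix, labels)
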