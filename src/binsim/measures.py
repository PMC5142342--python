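"""The catalogue of 79 binary similarity and dissimilarity measures.

Every measure is a function of the four OTU (Operational Taxonomic Unit)
quantities obtained by cross-tabulating two equal-length binary vectors x, y:

    a = |{m : x_m = 1, y_m = 1}|   positive matches
    b = |{m : x_m = 1, y_m = 0}|   absence mismatches
    c = |{m : x_m = 0, y_m = 1}|
    d = |{m : x_m = 0, y_m = 0}|   negative matches

with a + b + c + d = n, the vector length (a per-dataset constant).  The b/c
orientation above is a convention; every catalogued measure is symmetric
under the swap b <-> c, so the choice is immaterial (property-tested).

Evaluation never raises on mathematically undefined inputs: a division by
zero yields status ``nonfinite`` (signed infinity), and a 0/0, log of a
nonpositive argument after cancellation, or square root of a negative yields
status ``indeterminate`` (NaN).  The downstream validity screen eliminates
measures on exactly this behaviour.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .dataset_io import BinaryDataset, enumerate_pairs

__all__ = [
    "OTUQuantities",
    "MeasureSpec",
    "MeasureValue",
    "Annotation",
    "CoefficientMatrix",
    "REGISTRY",
    "REDUNDANT_IDS",
    "INVALID_IDS",
    "CLUSTERED_IDS",
    "RETAINED_IDS",
    "compute_otu",
    "evaluate",
    "evaluate_vectorized",
    "evaluate_all_pairs",
    "export_registry",
]


# ---------------------------------------------------------------------------
# OTU quantities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OTUQuantities:
    """The 2×2 match/mismatch counts for one pair of binary vectors.

    Derived scalars reused by several catalogue entries are exposed as
    properties: ``n`` (= a+b+c+d, the constant M), the chi-squared statistic,
    the phi-style correlation ``rho``, and the ``sigma``/``sigma_prime``
    row/column maxima sums of the Goodman & Kruskal family.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"OTU count {name}={v!r} must be a "
                                 "nonnegative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def chi2(self) -> float:
        a, b, c, d, n = map(float, (self.a, self.b, self.c, self.d, self.n))
        denom = (a + b) * (a + c) * (c + d) * (b + d)
        if denom == 0.0:
            return float("nan")
        return n * (a * d - b * c) ** 2 / denom

    @property
    def rho(self) -> float:
        a, b, c, d = map(float, (self.a, self.b, self.c, self.d))
        denom = np.sqrt((a + b) * (a + c) * (b + d) * (c + d))
        if denom == 0.0:
            return float("nan")
        return (a * d - b * c) / denom

    @property
    def sigma(self) -> int:
        a, b, c, d = self.a, self.b, self.c, self.d
        return max(a, b) + max(c, d) + max(a, c) + max(b, d)

    @property
    def sigma_prime(self) -> int:
        a, b, c, d = self.a, self.b, self.c, self.d
        return max(a + c, b + d) + max(a + b, c + d)

    def swapped(self) -> "OTUQuantities":
        """The OTU table of the pair taken in the other order (b <-> c)."""
        return OTUQuantities(self.a, self.c, self.b, self.d)


def compute_otu(x, y) -> OTUQuantities:
    """Cross-tabulate two equal-length binary vectors into (a, b, c, d)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"vectors must be 1-D of equal length, got {x.shape} vs {y.shape}"
        )
    if x.size < 1:
        raise ValueError("vectors must have length >= 1")
    for name, v in (("x", x), ("y", y)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary entries")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return OTUQuantities(a, b, c, d)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

class Annotation(str, Enum):
    """Catalogue annotation deciding an equation's fate in the reduction.

    ``redundant``  — identical to a retained equation by algebra alone.
    ``invalid``    — produces infinite/NaN or indeterminate coefficients.
    ``clustered``  — a positive affine transform of a retained equation;
                     removed at the zero-distance clustering stage.
    ``retained``   — one of the 45 unique equations kept for ROC ranking.
    """

    REDUNDANT = "redundant"
    INVALID = "invalid"
    CLUSTERED = "clustered"
    RETAINED = "retained"


@dataclass(frozen=True)
class MeasureSpec:
    eq_id: int
    name: str
    polarity: str          # "S" similarity | "D" dissimilarity
    uses_d: bool           # value depends on d (directly or through n)
    annotation: Annotation


@dataclass(frozen=True)
class MeasureValue:
    eq_id: int
    value: float
    status: str            # "finite" | "nonfinite" | "indeterminate"


# Sets copied from the catalogue's annotation column and checked by tests.
REDUNDANT_IDS = frozenset({5, 11, 17, 18, 19, 21, 22, 28, 33, 38, 60, 65})
INVALID_IDS = frozenset({32, 37, 53, 56, 58, 64, 69, 70, 73, 75, 76})
CLUSTERED_IDS = frozenset({3, 13, 14, 20, 23, 30, 41, 42, 43, 67, 72})

# Equations whose value does not involve d, neither directly nor through the
# constant n = a+b+c+d.  The complement (46 equations) has uses_d = True.
_NO_D_IDS = frozenset({
    1, 2, 3, 4, 5, 6, 12, 15, 16, 17, 18, 19, 21, 22, 27, 28, 29, 30, 31,
    33, 36, 37, 38, 39, 41, 42, 43, 45, 46, 47, 64, 65, 78,
})

_CATALOGUE: list[tuple[int, str, str]] = [
    (1, "Jaccard", "S"),
    (2, "Dice-2", "S"),
    (3, "Dice-1/Czekanowski", "S"),
    (4, "3W-Jaccard", "S"),
    (5, "Nei & Li", "S"),
    (6, "Sokal & Sneath-1", "S"),
    (7, "Sokal & Michener", "S"),
    (8, "Sokal & Sneath-2", "S"),
    (9, "Roger & Tanimoto", "S"),
    (10, "Faith", "S"),
    (11, "Gower & Legendre", "S"),
    (12, "Intersection", "S"),
    (13, "Innerproduct", "S"),
    (14, "Russell & Rao", "S"),
    (15, "Hamming", "D"),
    (16, "Euclid", "D"),
    (17, "Squared-euclid", "D"),
    (18, "Canberra", "D"),
    (19, "Manhattan", "D"),
    (20, "Mean-Manhattan", "D"),
    (21, "Cityblock", "D"),
    (22, "Minkowski", "D"),
    (23, "Vari", "D"),
    (24, "Size Difference", "D"),
    (25, "Shape Difference", "D"),
    (26, "Pattern Difference", "D"),
    (27, "Lance & Williams", "D"),
    (28, "Bray & Curtis", "D"),
    (29, "Hellinger", "D"),
    (30, "Chord", "D"),
    (31, "Cosine", "S"),
    (32, "Gilbert & Wells", "S"),
    (33, "Ochiai-1", "S"),
    (34, "Forbes-1", "S"),
    (35, "Fossum", "S"),
    (36, "Sorgenfrei", "S"),
    (37, "Mountford", "S"),
    (38, "Otsuka", "S"),
    (39, "McConnaughey", "S"),
    (40, "Tarwid", "S"),
    (41, "Kulczynski-2", "S"),
    (42, "Driver & Kroeber", "S"),
    (43, "Johnson", "S"),
    (44, "Dennis", "S"),
    (45, "Simpson", "S"),
    (46, "Braun & Banquet", "S"),
    (47, "Fager & McGowan", "S"),
    (48, "Forbes-2", "S"),
    (49, "Sokal & Sneath-4", "S"),
    (50, "Gower", "S"),
    (51, "Pearson-1", "S"),
    (52, "Pearson-2", "S"),
    (53, "Pearson-3", "S"),
    (54, "Pearson & Heron-1", "S"),
    (55, "Pearson & Heron-2", "S"),
    (56, "Sokal & Sneath-3", "S"),
    (57, "Sokal & Sneath-5", "S"),
    (58, "Cole", "S"),
    (59, "Stiles", "S"),
    (60, "Ochiai-2", "S"),
    (61, "Yuleq", "S"),
    (62, "Yuleq (distance)", "D"),
    (63, "Yulew", "S"),
    (64, "Kulczynski-1", "S"),
    (65, "Tanimoto", "S"),
    (66, "Disperson", "S"),
    (67, "Hamann", "S"),
    (68, "Michael", "S"),
    (69, "Goodman & Kruskal", "S"),
    (70, "Anderberg", "S"),
    (71, "Baroni-Urbani & Buser-1", "S"),
    (72, "Baroni-Urbani & Buser-2", "S"),
    (73, "Peirce", "S"),
    (74, "Eyraud", "S"),
    (75, "Tarantula", "S"),
    (76, "Ample", "S"),
    (77, "Derived Russell & Rao", "S"),
    (78, "Derived Jaccard", "S"),
    (79, "Variant of Correlation", "S"),
]


def _annotation(eq_id: int) -> Annotation:
    if eq_id in REDUNDANT_IDS:
        return Annotation.REDUNDANT
    if eq_id in INVALID_IDS:
        return Annotation.INVALID
    if eq_id in CLUSTERED_IDS:
        return Annotation.CLUSTERED
    return Annotation.RETAINED


REGISTRY: dict[int, MeasureSpec] = {
    eq_id: MeasureSpec(eq_id, name, pol, eq_id not in _NO_D_IDS,
                       _annotation(eq_id))
    for eq_id, name, pol in _CATALOGUE
}

RETAINED_IDS = frozenset(
    k for k, s in REGISTRY.items() if s.annotation is Annotation.RETAINED
)


# ---------------------------------------------------------------------------
# Formulas (vectorized over float arrays a, b, c, d; n = a+b+c+d)
# ---------------------------------------------------------------------------

def _rho(a, b, c, d):
    return (a * d - b * c) / np.sqrt((a + b) * (a + c) * (b + d) * (c + d))


def _chi2(a, b, c, d, n):
    return n * (a * d - b * c) ** 2 / ((a + b) * (a + c) * (c + d) * (b + d))


def _sigma(a, b, c, d):
    return (np.maximum(a, b) + np.maximum(c, d)
            + np.maximum(a, c) + np.maximum(b, d))


def _sigma_prime(a, b, c, d):
    return np.maximum(a + c, b + d) + np.maximum(a + b, c + d)


_FORMULAS = {
    1: lambda a, b, c, d, n: a / (a + b + c),
    2: lambda a, b, c, d, n: a / (2 * a + b + c),
    3: lambda a, b, c, d, n: 2 * a / (2 * a + b + c),
    4: lambda a, b, c, d, n: 3 * a / (3 * a + b + c),
    5: lambda a, b, c, d, n: 2 * a / ((a + b) + (a + c)),
    6: lambda a, b, c, d, n: a / (a + 2 * b + 2 * c),
    7: lambda a, b, c, d, n: (a + d) / n,
    8: lambda a, b, c, d, n: 2 * (a + d) / (2 * a + b + c + 2 * d),
    9: lambda a, b, c, d, n: (a + d) / (a + 2 * (b + c) + d),
    10: lambda a, b, c, d, n: (a + 0.5 * d) / n,
    11: lambda a, b, c, d, n: (a + d) / (a + 0.5 * (b + c) + d),
    12: lambda a, b, c, d, n: a + 0.0,
    13: lambda a, b, c, d, n: a + d,
    14: lambda a, b, c, d, n: a / n,
    15: lambda a, b, c, d, n: b + c,
    16: lambda a, b, c, d, n: np.sqrt(b + c),
    17: lambda a, b, c, d, n: np.sqrt((b + c) ** 2),
    18: lambda a, b, c, d, n: (b + c) ** (2 / 2),
    19: lambda a, b, c, d, n: b + c,
    20: lambda a, b, c, d, n: (b + c) / n,
    21: lambda a, b, c, d, n: b + c,
    22: lambda a, b, c, d, n: (b + c) ** (1 / 1),
    23: lambda a, b, c, d, n: (b + c) / (4 * n),
    24: lambda a, b, c, d, n: (b + c) ** 2 / n ** 2,
    25: lambda a, b, c, d, n: (n * (b + c) - (b - c) ** 2) / n ** 2,
    26: lambda a, b, c, d, n: 4 * b * c / n ** 2,
    27: lambda a, b, c, d, n: (b + c) / (2 * a + b + c),
    28: lambda a, b, c, d, n: (b + c) / (2 * a + b + c),
    29: lambda a, b, c, d, n: 2 * np.sqrt(1 - a / np.sqrt((a + b) * (a + c))),
    30: lambda a, b, c, d, n: np.sqrt(2 * (1 - a / np.sqrt((a + b) * (a + c)))),
    31: lambda a, b, c, d, n: a / np.sqrt((a + b) * (a + c)),
    32: lambda a, b, c, d, n: (np.log(a) - np.log(n)
                               - np.log((a + b) / n) - np.log((a + c) / n)),
    33: lambda a, b, c, d, n: a / np.sqrt((a + b) * (a + c)),
    34: lambda a, b, c, d, n: n * a / ((a + b) * (a + c)),
    35: lambda a, b, c, d, n: n * (a - 0.5) ** 2 / ((a + b) * (a + c)),
    36: lambda a, b, c, d, n: a ** 2 / ((a + b) * (a + c)),
    37: lambda a, b, c, d, n: a / (0.5 * (a * b + a * c) + b * c),
    38: lambda a, b, c, d, n: a / ((a + b) * (a + c)) ** 0.5,
    39: lambda a, b, c, d, n: (a ** 2 - b * c) / ((a + b) * (a + c)),
    40: lambda a, b, c, d, n: ((n * a - (a + b) * (a + c))
                               / (n * a + (a + b) * (a + c))),
    41: lambda a, b, c, d, n: (a / 2) * (2 * a + b + c) / ((a + b) * (a + c)),
    42: lambda a, b, c, d, n: (a / 2) * (1 / (a + b) + 1 / (a + c)),
    43: lambda a, b, c, d, n: a / (a + b) + a / (a + c),
    44: lambda a, b, c, d, n: ((a * d - b * c)
                               / np.sqrt(n * (a + b) * (a + c))),
    45: lambda a, b, c, d, n: a / np.minimum(a + b, a + c),
    46: lambda a, b, c, d, n: a / np.maximum(a + b, a + c),
    47: lambda a, b, c, d, n: (a / np.sqrt((a + b) * (a + c))
                               - np.maximum(a + b, a + c) / 2),
    48: lambda a, b, c, d, n: ((n * a - (a + b) * (a + c))
                               / (n * np.minimum(a + b, a + c)
                                  - (a + b) * (a + c))),
    49: lambda a, b, c, d, n: (a / (a + b) + a / (a + c)
                               + d / (b + d) + d / (c + d)) / 4,
    50: lambda a, b, c, d, n: ((a + d)
                               / np.sqrt((a + b) * (a + c) * (b + d) * (c + d))),
    51: _chi2,
    52: lambda a, b, c, d, n: np.sqrt(
        _chi2(a, b, c, d, n) / (n + _chi2(a, b, c, d, n))),
    53: lambda a, b, c, d, n: np.sqrt(
        _rho(a, b, c, d) / (n + _rho(a, b, c, d))),
    54: lambda a, b, c, d, n: _rho(a, b, c, d),
    55: lambda a, b, c, d, n: np.cos(
        np.pi * np.sqrt(b * c) / (np.sqrt(a * d) + np.sqrt(b * c))),
    56: lambda a, b, c, d, n: (a + d) / (b + c),
    # Literature form: the 0.5 exponent applies to the whole margin product,
    # making this entry coincide with Ochiai-2 (its catalogued duplicate).
    57: lambda a, b, c, d, n: (a * d
                               / np.sqrt((a + b) * (a + c) * (b + d) * (c + d))),
    58: lambda a, b, c, d, n: (np.sqrt(2.0) * (a * d - b * c)
                               / np.sqrt((a * d - b * c) ** 2
                                         - (a + b) * (a + c) * (b + d) * (c + d))),
    59: lambda a, b, c, d, n: np.log10(
        n * (np.abs(a * d - b * c) - n / 2) ** 2
        / ((a + b) * (a + c) * (b + d) * (c + d))),
    60: lambda a, b, c, d, n: (a * d
                               / np.sqrt((a + b) * (a + c) * (b + d) * (c + d))),
    61: lambda a, b, c, d, n: (a * d - b * c) / (a * d + b * c),
    62: lambda a, b, c, d, n: 2 * b * c / (a * d + b * c),
    63: lambda a, b, c, d, n: ((np.sqrt(a * d) - np.sqrt(b * c))
                               / (np.sqrt(a * d) + np.sqrt(b * c))),
    64: lambda a, b, c, d, n: a / (b + c),
    65: lambda a, b, c, d, n: a / ((a + b) + (a + c) - a),
    66: lambda a, b, c, d, n: (a * d - b * c) / n ** 2,
    67: lambda a, b, c, d, n: ((a + d) - (b + c)) / n,
    68: lambda a, b, c, d, n: (4 * (a * d - b * c)
                               / ((a + d) ** 2 + (b + c) ** 2)),
    69: lambda a, b, c, d, n: ((_sigma(a, b, c, d) - _sigma_prime(a, b, c, d))
                               / (2 * n - _sigma_prime(a, b, c, d))),
    70: lambda a, b, c, d, n: ((_sigma(a, b, c, d) - _sigma_prime(a, b, c, d))
                               / (2 * n)),
    71: lambda a, b, c, d, n: ((np.sqrt(a * d) + a)
                               / (np.sqrt(a * d) + a + b + c)),
    72: lambda a, b, c, d, n: ((np.sqrt(a * d) + a - (b + c))
                               / (np.sqrt(a * d) + a + b + c)),
    73: lambda a, b, c, d, n: ((a * b + b * c)
                               / (a * b + 2 * b * c + c * d)),
    74: lambda a, b, c, d, n: (n ** 2 * (n * a - (a + b) * (a + c))
                               / ((a + b) * (a + c) * (b + d) * (c + d))),
    75: lambda a, b, c, d, n: a * (c + d) / (c * (a + b)),
    76: lambda a, b, c, d, n: np.abs(a * (c + d) / (c * (a + b))),
    77: lambda a, b, c, d, n: np.log(1 + a) / np.log(1 + n),
    78: lambda a, b, c, d, n: np.log(1 + a) / np.log(1 + a + b + c),
    79: lambda a, b, c, d, n: ((np.log(1 + a * d) - np.log(1 + b * c))
                               / np.log(1 + n ** 2 / 4)),
}


def evaluate_vectorized(eq_id: int, a, b, c, d) -> np.ndarray:
    """Evaluate one equation over arrays of OTU counts; NaN/inf pass through."""
    if eq_id not in _FORMULAS:
        raise KeyError(f"unknown equation id {eq_id}")
    a, b, c, d = (np.asarray(v, dtype=np.float64) for v in (a, b, c, d))
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.asarray(_FORMULAS[eq_id](a, b, c, d, n), dtype=np.float64)


def _status(value: float) -> str:
    if np.isnan(value):
        return "indeterminate"
    if np.isinf(value):
        return "nonfinite"
    return "finite"


def evaluate(eq_id: int, otu: OTUQuantities) -> MeasureValue:
    """Evaluate one catalogue equation on a single OTU quadruple."""
    value = float(evaluate_vectorized(eq_id, otu.a, otu.b, otu.c, otu.d))
    return MeasureValue(eq_id, value, _status(value))


# ---------------------------------------------------------------------------
# Dataset-wide evaluation
# ---------------------------------------------------------------------------

@dataclass
class CoefficientMatrix:
    """Pairs × measures table of raw coefficients.

    ``values[p, k]`` is equation ``eq_ids[k]`` on pair ``p`` in the row-major
    upper-triangle pair order.  ``finite`` is the elementwise validity mask.
    """

    eq_ids: list[int]
    pair_index: tuple[np.ndarray, np.ndarray]
    values: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def finite(self) -> np.ndarray:
        return np.isfinite(self.values)

    def column(self, eq_id: int) -> np.ndarray:
        return self.values[:, self.eq_ids.index(eq_id)]


def pair_otu_arrays(dataset: BinaryDataset):
    """Vectorized OTU counts (a, b, c, d) for all upper-triangle pairs."""
    x = dataset.matrix.astype(np.int64)
    ii, jj = enumerate_pairs(dataset)
    inter = x @ x.T  # a for every ordered pair
    row = x.sum(axis=1)
    a = inter[ii, jj]
    b = row[ii] - a
    c = row[jj] - a
    d = dataset.n_ingredients - a - b - c
    return a, b, c, d


def evaluate_all_pairs(dataset: BinaryDataset,
                       eq_ids: list[int] | None = None) -> CoefficientMatrix:
    """Apply the catalogue to every formula pair of a dataset.

    Returns an N(N-1)/2 × |eq_ids| coefficient matrix in the deterministic
    row-major upper-triangle pair order.
    """
    if eq_ids is None:
        eq_ids = sorted(REGISTRY)
    for eq_id in eq_ids:
        if eq_id not in REGISTRY:
            raise KeyError(f"unknown equation id {eq_id}")
    a, b, c, d = pair_otu_arrays(dataset)
    values = np.empty((a.size, len(eq_ids)), dtype=np.float64)
    for k, eq_id in enumerate(eq_ids):
        values[:, k] = evaluate_vectorized(eq_id, a, b, c, d)
    return CoefficientMatrix(list(eq_ids), enumerate_pairs(dataset), values)


def export_registry(path, delimiter: str = ",") -> None:
    """Write the measure registry as a delimited table."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["eq_id", "name", "polarity", "uses_d", "annotation"])
        for eq_id in sorted(REGISTRY):
            s = REGISTRY[eq_id]
            writer.writerow([s.eq_id, s.name, s.polarity,
                             int(s.uses_d), s.annotation.value])
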