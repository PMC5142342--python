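"""Measure catalogue: OTU counting, the 79 formulas, and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binsim.dataset_io import BinaryDataset
from binsim.measures import (
    REGISTRY,
    Annotation,
    OTUQuantities,
    compute_otu,
    evaluate,
    evaluate_all_pairs,
    evaluate_vectorized,
)

# ---------------------------------------------------------------------------
# Independent scalar transcription of every formula, used as an oracle.
# Written directly from the catalogue in plain arithmetic, deliberately
# arranged differently from the vectorized implementation.
# ---------------------------------------------------------------------------

NAN = float("nan")


def _sqrt(x):
    return math.sqrt(x) if x >= 0 else NAN


def _log(x):
    if x > 0:
        return math.log(x)
    return float("-inf") if x == 0 else NAN


def _log10(x):
    if x > 0:
        return math.log10(x)
    return float("-inf") if x == 0 else NAN


def _div(num, den):
    if den != 0:
        return num / den
    if num == 0:
        return NAN
    return math.copysign(float("inf"), num)


def _hellinger_core(a, b, c, d):
    return 1.0 - _div(a, _sqrt((a + b) * (a + c)))


def _phi(a, b, c, d):
    return _div(a * d - b * c, _sqrt((a + b) * (a + c) * (b + d) * (c + d)))


def _chi_sq(a, b, c, d):
    n = a + b + c + d
    return _div(n * (a * d - b * c) ** 2,
                (a + b) * (a + c) * (b + d) * (c + d))


def _gk_sigma(a, b, c, d):
    return max(a, b) + max(c, d) + max(a, c) + max(b, d)


def _gk_sigma_prime(a, b, c, d):
    return max(a + c, b + d) + max(a + b, c + d)


ORACLE = {
    1: lambda a, b, c, d: _div(a, a + b + c),
    2: lambda a, b, c, d: _div(a, 2 * a + b + c),
    3: lambda a, b, c, d: _div(2 * a, 2 * a + b + c),
    4: lambda a, b, c, d: _div(3 * a, 3 * a + b + c),
    5: lambda a, b, c, d: _div(2 * a, (a + b) + (a + c)),
    6: lambda a, b, c, d: _div(a, a + 2 * (b + c)),
    7: lambda a, b, c, d: _div(a + d, a + b + c + d),
    8: lambda a, b, c, d: _div(2 * (a + d), 2 * a + b + c + 2 * d),
    9: lambda a, b, c, d: _div(a + d, a + 2 * (b + c) + d),
    10: lambda a, b, c, d: _div(a + d / 2, a + b + c + d),
    11: lambda a, b, c, d: _div(a + d, a + (b + c) / 2 + d),
    12: lambda a, b, c, d: float(a),
    13: lambda a, b, c, d: float(a + d),
    14: lambda a, b, c, d: _div(a, a + b + c + d),
    15: lambda a, b, c, d: float(b + c),
    16: lambda a, b, c, d: _sqrt(b + c),
    17: lambda a, b, c, d: _sqrt((b + c) * (b + c)),
    18: lambda a, b, c, d: float(b + c) ** 1.0,
    19: lambda a, b, c, d: float(b + c),
    20: lambda a, b, c, d: _div(b + c, a + b + c + d),
    21: lambda a, b, c, d: float(b + c),
    22: lambda a, b, c, d: float(b + c) ** 1.0,
    23: lambda a, b, c, d: _div(b + c, 4 * (a + b + c + d)),
    24: lambda a, b, c, d: _div((b + c) ** 2, (a + b + c + d) ** 2),
    25: lambda a, b, c, d: _div((a + b + c + d) * (b + c) - (b - c) ** 2,
                                (a + b + c + d) ** 2),
    26: lambda a, b, c, d: _div(4 * b * c, (a + b + c + d) ** 2),
    27: lambda a, b, c, d: _div(b + c, 2 * a + b + c),
    28: lambda a, b, c, d: _div(b + c, 2 * a + b + c),
    29: lambda a, b, c, d: 2 * _sqrt(_hellinger_core(a, b, c, d)),
    30: lambda a, b, c, d: _sqrt(2 * _hellinger_core(a, b, c, d)),
    31: lambda a, b, c, d: _div(a, _sqrt((a + b) * (a + c))),
    32: lambda a, b, c, d: (_log(a) - _log(a + b + c + d)
                            - _log(_div(a + b, a + b + c + d))
                            - _log(_div(a + c, a + b + c + d))),
    33: lambda a, b, c, d: _div(a, _sqrt((a + b) * (a + c))),
    34: lambda a, b, c, d: _div((a + b + c + d) * a, (a + b) * (a + c)),
    35: lambda a, b, c, d: _div((a + b + c + d) * (a - 0.5) ** 2,
                                (a + b) * (a + c)),
    36: lambda a, b, c, d: _div(a * a, (a + b) * (a + c)),
    37: lambda a, b, c, d: _div(a, (a * b + a * c) / 2 + b * c),
    38: lambda a, b, c, d: _div(a, ((a + b) * (a + c)) ** 0.5),
    39: lambda a, b, c, d: _div(a * a - b * c, (a + b) * (a + c)),
    40: lambda a, b, c, d: _div(
        (a + b + c + d) * a - (a + b) * (a + c),
        (a + b + c + d) * a + (a + b) * (a + c)),
    41: lambda a, b, c, d: _div(a * (2 * a + b + c), 2 * (a + b) * (a + c)),
    42: lambda a, b, c, d: (a / 2) * (_div(1, a + b) + _div(1, a + c))
        if a > 0 or (a + b > 0 and a + c > 0) else NAN,
    43: lambda a, b, c, d: _div(a, a + b) + _div(a, a + c),
    44: lambda a, b, c, d: _div(a * d - b * c,
                                _sqrt((a + b + c + d) * (a + b) * (a + c))),
    45: lambda a, b, c, d: _div(a, min(a + b, a + c)),
    46: lambda a, b, c, d: _div(a, max(a + b, a + c)),
    47: lambda a, b, c, d: (_div(a, _sqrt((a + b) * (a + c)))
                            - max(a + b, a + c) / 2),
    48: lambda a, b, c, d: _div(
        (a + b + c + d) * a - (a + b) * (a + c),
        (a + b + c + d) * min(a + b, a + c) - (a + b) * (a + c)),
    49: lambda a, b, c, d: (_div(a, a + b) + _div(a, a + c)
                            + _div(d, b + d) + _div(d, c + d)) / 4,
    50: lambda a, b, c, d: _div(a + d,
                                _sqrt((a + b) * (a + c) * (b + d) * (c + d))),
    51: _chi_sq,
    52: lambda a, b, c, d: _sqrt(_div(_chi_sq(a, b, c, d),
                                      a + b + c + d + _chi_sq(a, b, c, d))),
    53: lambda a, b, c, d: _sqrt(_div(_phi(a, b, c, d),
                                      a + b + c + d + _phi(a, b, c, d))),
    54: _phi,
    55: lambda a, b, c, d: math.cos(
        math.pi * _div(_sqrt(b * c), _sqrt(a * d) + _sqrt(b * c)))
        if _sqrt(a * d) + _sqrt(b * c) > 0 else NAN,
    56: lambda a, b, c, d: _div(a + d, b + c),
    57: lambda a, b, c, d: _div(a * d,
                                _sqrt((a + b) * (a + c) * (b + d) * (c + d))),
    58: lambda a, b, c, d: _div(
        math.sqrt(2) * (a * d - b * c),
        _sqrt((a * d - b * c) ** 2
              - (a + b) * (a + c) * (b + d) * (c + d))),
    59: lambda a, b, c, d: _log10(_div(
        (a + b + c + d) * (abs(a * d - b * c) - (a + b + c + d) / 2) ** 2,
        (a + b) * (a + c) * (b + d) * (c + d))),
    60: lambda a, b, c, d: _div(a * d,
                                _sqrt((a + b) * (a + c) * (b + d) * (c + d))),
    61: lambda a, b, c, d: _div(a * d - b * c, a * d + b * c),
    62: lambda a, b, c, d: _div(2 * b * c, a * d + b * c),
    63: lambda a, b, c, d: _div(_sqrt(a * d) - _sqrt(b * c),
                                _sqrt(a * d) + _sqrt(b * c)),
    64: lambda a, b, c, d: _div(a, b + c),
    65: lambda a, b, c, d: _div(a, a + b + c),
    66: lambda a, b, c, d: _div(a * d - b * c, (a + b + c + d) ** 2),
    67: lambda a, b, c, d: _div((a + d) - (b + c), a + b + c + d),
    68: lambda a, b, c, d: _div(4 * (a * d - b * c),
                                (a + d) ** 2 + (b + c) ** 2),
    69: lambda a, b, c, d: _div(
        _gk_sigma(a, b, c, d) - _gk_sigma_prime(a, b, c, d),
        2 * (a + b + c + d) - _gk_sigma_prime(a, b, c, d)),
    70: lambda a, b, c, d: _div(
        _gk_sigma(a, b, c, d) - _gk_sigma_prime(a, b, c, d),
        2 * (a + b + c + d)),
    71: lambda a, b, c, d: _div(_sqrt(a * d) + a, _sqrt(a * d) + a + b + c),
    72: lambda a, b, c, d: _div(_sqrt(a * d) + a - (b + c),
                                _sqrt(a * d) + a + b + c),
    73: lambda a, b, c, d: _div(a * b + b * c, a * b + 2 * b * c + c * d),
    74: lambda a, b, c, d: _div(
        (a + b + c + d) ** 2 * ((a + b + c + d) * a - (a + b) * (a + c)),
        (a + b) * (a + c) * (b + d) * (c + d)),
    75: lambda a, b, c, d: _div(a * (c + d), c * (a + b)),
    76: lambda a, b, c, d: abs(_div(a * (c + d), c * (a + b))),
    77: lambda a, b, c, d: _div(_log(1 + a), _log(1 + a + b + c + d)),
    78: lambda a, b, c, d: _div(_log(1 + a), _log(1 + a + b + c)),
    79: lambda a, b, c, d: _div(_log(1 + a * d) - _log(1 + b * c),
                                _log(1 + (a + b + c + d) ** 2 / 4)),
}

# Equations that are not symmetric under swapping the two vectors; all three
# are eliminated by the validity screen before any downstream use.
ASYMMETRIC_IDS = {73, 75, 76}


def _close(x, y, rtol=1e-12):
    if math.isnan(x) or math.isnan(y):
        return math.isnan(x) and math.isnan(y)
    if math.isinf(x) or math.isinf(y):
        return x == y
    return abs(x - y) <= rtol * max(abs(x), abs(y), 1.0)


# ---------------------------------------------------------------------------
# OTU counting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, y, expected", [
    ((1, 1, 0, 0, 0), (1, 0, 1, 0, 0), (1, 1, 1, 2)),
    ((1, 0, 1), (1, 0, 1), (2, 0, 0, 1)),
    ((0, 0, 0), (0, 0, 0), (0, 0, 0, 3)),
])
def test_compute_otu_counts(x, y, expected):
    otu = compute_otu(x, y)
    assert (otu.a, otu.b, otu.c, otu.d) == expected
    assert otu.a + otu.b + otu.c + otu.d == len(x)


def test_compute_otu_rejects_bad_input():
    with pytest.raises(ValueError, match="equal length"):
        compute_otu([1, 0], [1, 0, 1])
    with pytest.raises(ValueError, match="non-binary"):
        compute_otu([1, 2], [0, 1])
    with pytest.raises(ValueError, match="length"):
        compute_otu([], [])


@given(st.lists(st.integers(0, 1), min_size=1, max_size=40),
       st.data())
@settings(max_examples=100, deadline=None)
def test_otu_swap_exchanges_b_and_c(x, data):
    y = data.draw(st.lists(st.integers(0, 1), min_size=len(x),
                           max_size=len(x)))
    otu_xy = compute_otu(x, y)
    otu_yx = compute_otu(y, x)
    assert (otu_xy.a, otu_xy.d) == (otu_yx.a, otu_yx.d)
    assert (otu_xy.b, otu_xy.c) == (otu_yx.c, otu_yx.b)
    assert otu_xy.swapped() == otu_yx


def test_otu_derived_scalars():
    otu = OTUQuantities(2, 1, 1, 3)
    assert otu.n == 7
    assert otu.chi2 == pytest.approx(7 * 25 / (3 * 3 * 4 * 4))
    assert otu.rho == pytest.approx(5 / math.sqrt(144))
    # sigma = max(a,b)+max(c,d)+max(a,c)+max(b,d) = 2+3+2+3
    assert otu.sigma == 10
    assert otu.sigma_prime == max(3, 4) + max(3, 4)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def test_registry_covers_1_to_79():
    assert sorted(REGISTRY) == list(range(1, 80))
    assert len({s.name for s in REGISTRY.values()}) == 79


def test_registry_annotation_counts():
    by_annotation = {}
    for s in REGISTRY.values():
        by_annotation.setdefault(s.annotation, []).append(s.eq_id)
    assert len(by_annotation[Annotation.REDUNDANT]) == 12
    assert len(by_annotation[Annotation.INVALID]) == 11
    assert len(by_annotation[Annotation.CLUSTERED]) == 11
    assert len(by_annotation[Annotation.RETAINED]) == 45


def test_registry_d_usage_count():
    assert sum(s.uses_d for s in REGISTRY.values()) == 46


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("eq_id, otu, expected", [
    (1, (1, 1, 1, 2), 1 / 3),
    (7, (1, 1, 1, 2), 0.6),
    (1, (3, 0, 0, 2), 1.0),
    (2, (1, 1, 1, 2), 0.25),
    (15, (0, 2, 3, 0), 5.0),
    (61, (2, 1, 1, 3), (6 - 1) / (6 + 1)),
])
def test_evaluate_hand_examples(eq_id, otu, expected):
    result = evaluate(eq_id, OTUQuantities(*otu))
    assert result.status == "finite"
    assert result.value == pytest.approx(expected, rel=1e-12)


def test_evaluate_undefined_inputs_carry_status():
    # Kulczynski-1 on an identical pair divides by b + c = 0
    assert evaluate(64, OTUQuantities(2, 0, 0, 1)).status == "nonfinite"
    # Gilbert & Wells on a disjoint pair takes log(0)
    assert evaluate(32, OTUQuantities(0, 2, 3, 4)).status == "nonfinite"
    # Peirce on an identical pair is 0/0
    assert evaluate(73, OTUQuantities(2, 0, 0, 1)).status == "indeterminate"


def test_evaluate_unknown_eq_id():
    with pytest.raises(KeyError):
        evaluate(99, OTUQuantities(1, 1, 1, 1))


def test_oracle_equivalence_all_formulas(rng):
    """Every formula matches an independent scalar transcription to 1e-12
    relative tolerance on 1,000 random quadruples."""
    quads = rng.integers(0, 21, size=(1000, 4))
    quads = quads[quads.sum(axis=1) > 0]
    for eq_id in sorted(REGISTRY):
        values = evaluate_vectorized(eq_id, *quads.T)
        for (a, b, c, d), got in zip(quads.tolist(), values):
            want = ORACLE[eq_id](a, b, c, d)
            assert _close(got, want), (
                f"Eq {eq_id} on {(a, b, c, d)}: {got} vs oracle {want}"
            )


@given(st.tuples(st.integers(0, 30), st.integers(0, 30),
                 st.integers(0, 30), st.integers(0, 30))
       .filter(lambda q: sum(q) > 0))
@settings(max_examples=200, deadline=None)
def test_symmetry_under_vector_swap(quad):
    """Swapping the two vectors (b <-> c) leaves every symmetric measure's
    value unchanged, statuses included."""
    a, b, c, d = quad
    otu, swapped = OTUQuantities(a, b, c, d), OTUQuantities(a, c, b, d)
    for eq_id in sorted(REGISTRY):
        if eq_id in ASYMMETRIC_IDS:
            continue
        v1, v2 = evaluate(eq_id, otu), evaluate(eq_id, swapped)
        assert v1.status == v2.status, f"Eq {eq_id} status differs on {quad}"
        if v1.status == "finite":
            assert _close(v1.value, v2.value, 1e-12), f"Eq {eq_id} on {quad}"


def test_documented_asymmetric_measures():
    """Peirce, Tarantula and Ample are direction-dependent as printed; all
    three are screened out before ranking."""
    otu, swapped = OTUQuantities(1, 2, 3, 4), OTUQuantities(1, 3, 2, 4)
    for eq_id in ASYMMETRIC_IDS:
        assert REGISTRY[eq_id].annotation is Annotation.INVALID
        v1, v2 = evaluate(eq_id, otu), evaluate(eq_id, swapped)
        assert not _close(v1.value, v2.value)


def test_bounded_measures_stay_in_range(rng):
    quads = rng.integers(0, 21, size=(500, 4))
    quads = quads[quads.sum(axis=1) > 0]
    unit_interval = [1, 2, 3, 4, 7, 10, 14]    # Jaccard/Dice/SM/Faith/RR...
    signed_unit = [54, 61, 63]                 # correlation-style
    for eq_id in unit_interval:
        v = evaluate_vectorized(eq_id, *quads.T)
        v = v[np.isfinite(v)]
        assert ((v >= 0) & (v <= 1)).all()
    for eq_id in signed_unit:
        v = evaluate_vectorized(eq_id, *quads.T)
        v = v[np.isfinite(v)]
        assert ((v >= -1 - 1e-12) & (v <= 1 + 1e-12)).all()


# ---------------------------------------------------------------------------
# Dataset-wide evaluation
# ---------------------------------------------------------------------------

def test_evaluate_all_pairs_matches_scalar_route():
    matrix = np.array([
        [1, 1, 0, 0, 0],
        [1, 0, 1, 0, 0],
        [0, 1, 1, 1, 0],
    ])
    ds = BinaryDataset(["J1", "J2", "J3"], list("vwxyz"), matrix)
    coeffs = evaluate_all_pairs(ds, [1, 7, 15])
    assert coeffs.values.shape == (3, 3)
    ii, jj = coeffs.pair_index
    assert list(zip(ii.tolist(), jj.tolist())) == [(0, 1), (0, 2), (1, 2)]
    for p, (i, j) in enumerate(zip(ii, jj)):
        otu = compute_otu(matrix[i], matrix[j])
        for k, eq_id in enumerate([1, 7, 15]):
            assert coeffs.values[p, k] == pytest.approx(
                evaluate(eq_id, otu).value)


def test_jaccard_column_bounded(structured_ds):
    coeffs = evaluate_all_pairs(structured_ds, [1])
    finite = coeffs.values[np.isfinite(coeffs.values)]
    assert ((finite >= 0) & (finite <= 1)).all()
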