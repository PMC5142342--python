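"""Three-stage reduction of the 79-equation catalogue to 45 unique measures.

Stage 1 removes 12 equations that are algebraically identical to a retained
partner (seven identity groups, verified numerically).  Stage 2 removes 11
equations that produce infinite/NaN or indeterminate coefficients on
degenerate vector pairs.  Stage 3 standardizes the per-pair coefficient
columns of the 56 survivors on an actual dataset and removes 11 columns at
(near-)zero Euclidean distance from a retained column — exactly the
positive-affine transforms of retained equations, since mean-centering and
unit-variance scaling map v and alpha*v + beta (alpha > 0) to the same
z-scores.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import measures
from .dataset_io import BinaryDataset
from .measures import (
    INVALID_IDS,
    REDUNDANT_IDS,
    REGISTRY,
    OTUQuantities,
    evaluate,
    evaluate_vectorized,
)

__all__ = [
    "IDENTITY_GROUPS",
    "AFFINE_RELATIONS",
    "DEGENERATE_CORPUS",
    "IdentityGroup",
    "AffineRelation",
    "ValidityReport",
    "ReductionResult",
    "random_otu_quadruples",
    "verify_identity_groups",
    "verify_affine_relations",
    "screen_validity",
    "eliminate_zero_distance",
    "reduce_pipeline",
    "write_audit",
]


@dataclass(frozen=True)
class IdentityGroup:
    """Equations identical to the kept one by algebraic manipulation alone."""

    kept_eq_id: int
    eliminated_eq_ids: tuple[int, ...]


# The seven identity groups, with the kept member of each.
IDENTITY_GROUPS: tuple[IdentityGroup, ...] = (
    IdentityGroup(3, (5,)),                      # Nei & Li = Dice-1
    IdentityGroup(8, (11,)),                     # Gower & Legendre = SS-2
    IdentityGroup(15, (17, 18, 19, 21, 22)),     # all equal b + c
    IdentityGroup(27, (28,)),                    # Bray & Curtis = Lance & W.
    IdentityGroup(31, (33, 38)),                 # Ochiai-1/Otsuka = Cosine
    IdentityGroup(57, (60,)),                    # Ochiai-2 = SS-5
    IdentityGroup(1, (65,)),                     # Tanimoto = Jaccard
)


@dataclass(frozen=True)
class AffineRelation:
    """eliminated = coef * M**m_exp * kept + offset, with M = a+b+c+d."""

    eliminated_eq_id: int
    kept_eq_id: int
    coef: float
    m_exp: int = 0
    offset: float = 0.0

    def scale(self, m: float) -> float:
        return self.coef * m ** self.m_exp


# The eleven positive-affine transformations behind the zero-distance stage.
AFFINE_RELATIONS: tuple[AffineRelation, ...] = (
    AffineRelation(30, 29, 1 / np.sqrt(2)),       # Chord = Hellinger/sqrt(2)
    AffineRelation(20, 15, 1.0, m_exp=-1),        # Mean-Manhattan = Hamming/M
    AffineRelation(23, 15, 0.25, m_exp=-1),       # Vari = Hamming/(4M)
    AffineRelation(14, 12, 1.0, m_exp=-1),        # Russell & Rao = a/M
    AffineRelation(72, 71, 2.0, offset=-1.0),     # BUB-2 = 2*BUB-1 - 1
    AffineRelation(41, 43, 0.5),                  # Kulczynski-2 = Johnson/2
    AffineRelation(42, 43, 0.5),                  # Driver & Kroeber = Johnson/2
    AffineRelation(43, 39, 1.0, offset=1.0),      # Johnson = 1 + McConnaughey
    AffineRelation(3, 2, 2.0),                    # Dice-1 = 2*Dice-2
    AffineRelation(13, 7, 1.0, m_exp=1),          # Innerproduct = M*SokalMich.
    AffineRelation(67, 7, 2.0, offset=-1.0),      # Hamann = 2*SokalMich. - 1
)

# Representatives the zero-distance stage prefers when collapsing a family
# (the kept side of the affine table).
_PREFERRED_REPRESENTATIVES = frozenset(
    r.kept_eq_id for r in AFFINE_RELATIONS
) - frozenset(r.eliminated_eq_id for r in AFFINE_RELATIONS)


@dataclass
class ValidityReport:
    eq_id: int
    failing_otu_examples: list[OTUQuantities] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "invalid" if self.failing_otu_examples else "valid"


# Degenerate vector-pair fixtures that provoke the documented failure modes:
# a generic pair, an identical nonzero pair (b=c=0), a disjoint pair (a=0),
# a nested pair (b=0, c>0), a complement-free pair (d=0), and a saturated
# identical pair (a=n) whose OTU table has a full row and a full column.
DEGENERATE_CORPUS: tuple[OTUQuantities, ...] = (
    OTUQuantities(2, 1, 1, 3),
    OTUQuantities(2, 0, 0, 3),
    OTUQuantities(0, 2, 3, 4),
    OTUQuantities(2, 0, 3, 4),
    OTUQuantities(2, 1, 1, 0),
    OTUQuantities(3, 0, 0, 0),
)


def random_otu_quadruples(trials: int, seed=None,
                          low: int = 1, high: int = 20) -> np.ndarray:
    """(trials, 4) array of strictly positive random OTU counts.

    All four counts are >= 1, so every 2×2 margin is positive and the
    identity/affine checks run in each equation's well-defined regime.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(low, high + 1, size=(trials, 4))


def _rel_diff(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    scale = np.maximum(np.maximum(np.abs(x), np.abs(y)), 1.0)
    return np.abs(x - y) / scale


def verify_identity_groups(trials: int = 1000, seed=0) -> dict[int, dict]:
    """Numerically confirm each identity group on random OTU quadruples.

    Returns, per kept eq_id, the eliminated ids, the max relative deviation
    over all trials, and a pass flag at 1e-12 relative tolerance.
    """
    quads = random_otu_quadruples(trials, seed)
    a, b, c, d = quads.T
    report = {}
    for group in IDENTITY_GROUPS:
        kept = evaluate_vectorized(group.kept_eq_id, a, b, c, d)
        worst = 0.0
        for eq_id in group.eliminated_eq_ids:
            elim = evaluate_vectorized(eq_id, a, b, c, d)
            worst = max(worst, float(_rel_diff(kept, elim).max()))
        report[group.kept_eq_id] = {
            "eliminated": list(group.eliminated_eq_ids),
            "max_rel_diff": worst,
            "passed": worst <= 1e-12,
        }
    return report


def verify_affine_relations(trials: int = 1000, seed=0) -> dict[int, dict]:
    """Numerically confirm eliminated = scale(M)*kept + offset per relation."""
    quads = random_otu_quadruples(trials, seed)
    a, b, c, d = quads.T
    m = (a + b + c + d).astype(np.float64)
    report = {}
    for rel in AFFINE_RELATIONS:
        kept = evaluate_vectorized(rel.kept_eq_id, a, b, c, d)
        elim = evaluate_vectorized(rel.eliminated_eq_id, a, b, c, d)
        predicted = rel.scale(m) * kept + rel.offset
        worst = float(_rel_diff(elim, predicted).max())
        report[rel.eliminated_eq_id] = {
            "kept": rel.kept_eq_id,
            "max_rel_diff": worst,
            "passed": worst <= 1e-12,
        }
    return report


def screen_validity(eq_ids=None,
                    corpus=DEGENERATE_CORPUS) -> dict[int, ValidityReport]:
    """Flag equations that go nonfinite/indeterminate on a fixture corpus.

    The verdict is mechanical: invalid iff at least one corpus quadruple
    evaluates to a non-finite status.  The degenerate default corpus is
    deliberately harsher than real sparse data; the pipeline's validity stage
    uses the registry annotation for count fidelity (Anderberg, whose
    denominator 2n is strictly positive, is annotated invalid but can never
    be reproduced as such by any screen).
    """
    if eq_ids is None:
        eq_ids = sorted(REGISTRY)
    corpus = tuple(corpus)
    if not corpus:
        raise ValueError("screening corpus must be nonempty")
    reports = {}
    for eq_id in eq_ids:
        rep = ValidityReport(eq_id)
        for otu in corpus:
            if evaluate(eq_id, otu).status != "finite":
                rep.failing_otu_examples.append(otu)
        reports[eq_id] = rep
    return reports


def eliminate_zero_distance(z: np.ndarray, eq_ids: list[int],
                            tol: float | None = None):
    """Collapse standardized columns at pairwise distance <= tol.

    Within each connected component of the "distance <= tol" graph exactly
    one representative is retained: the lowest preferred eq_id when the
    component contains one, else the lowest eq_id.  Returns
    (retained_ids, elimination_map eliminated -> (kept, distance)).
    """
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need a standardized matrix with >= 2 pair rows")
    if not np.isfinite(z).all():
        bad = [eq_ids[k] for k in
               np.flatnonzero(~np.isfinite(z).all(axis=0))]
        raise ValueError(f"non-finite coefficient column(s) for eq_ids {bad}; "
                         "screen validity first")
    if tol is None:
        tol = 1e-8 * np.sqrt(z.shape[0])
    from scipy.spatial.distance import pdist, squareform

    dist = squareform(pdist(z.T, metric="euclidean"))
    adjacent = dist <= tol
    # connected components over the thresholded graph
    n = len(eq_ids)
    component = [-1] * n
    for start in range(n):
        if component[start] >= 0:
            continue
        stack = [start]
        component[start] = start
        while stack:
            k = stack.pop()
            for other in np.flatnonzero(adjacent[k]):
                if component[other] < 0:
                    component[other] = start
                    stack.append(int(other))
    retained = []
    eliminated: dict[int, tuple[int, float]] = {}
    for comp in sorted(set(component)):
        members = [k for k in range(n) if component[k] == comp]
        ids = [eq_ids[k] for k in members]
        preferred = sorted(i for i in ids if i in _PREFERRED_REPRESENTATIVES)
        rep = preferred[0] if preferred else min(ids)
        retained.append(rep)
        rep_k = eq_ids.index(rep)
        for k, eq_id in zip(members, ids):
            if eq_id != rep:
                eliminated[eq_id] = (rep, float(dist[k, rep_k]))
    return sorted(retained), eliminated


@dataclass
class ReductionResult:
    """Audit of the three reduction stages."""

    identity_eliminated: list[int]
    validity_eliminated: list[int]
    cluster_eliminated: dict[int, tuple[int, float]]
    retained: list[int]
    audit_rows: list[dict]

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(initial, after identity, after validity, retained)."""
        n0 = len(REGISTRY)
        n1 = n0 - len(self.identity_eliminated)
        n2 = n1 - len(self.validity_eliminated)
        n3 = n2 - len(self.cluster_eliminated)
        return n0, n1, n2, n3


def reduce_pipeline(dataset: BinaryDataset, tol: float | None = None,
                    skip_validity: bool = False,
                    verify_trials: int = 1000, seed=0) -> ReductionResult:
    """Run all three reduction stages against a dataset.

    The identity stage is verified numerically (``verify_trials`` random
    quadruples) before its 12 eliminations are applied; the validity stage
    applies the registry annotation; the clustering stage standardizes the
    surviving coefficient columns on ``dataset`` and collapses zero-distance
    families.
    """
    from .clustering import standardize

    audit: list[dict] = []

    identity_report = verify_identity_groups(verify_trials, seed)
    for kept, rep in identity_report.items():
        if not rep["passed"]:
            raise AssertionError(
                f"identity group kept={kept} failed numeric verification"
            )
        for eq_id in rep["eliminated"]:
            audit.append({
                "stage": "identity", "eliminated": eq_id, "kept": kept,
                "reason": "algebraically identical",
                "max_deviation": rep["max_rel_diff"],
            })
    pool = sorted(set(REGISTRY) - REDUNDANT_IDS)

    validity_eliminated: list[int] = []
    if not skip_validity:
        validity_eliminated = sorted(INVALID_IDS)
        for eq_id in validity_eliminated:
            audit.append({
                "stage": "validity", "eliminated": eq_id, "kept": "",
                "reason": "infinite/NaN or indeterminate coefficients",
                "max_deviation": "",
            })
        pool = sorted(set(pool) - INVALID_IDS)

    coeffs = measures.evaluate_all_pairs(dataset, pool)
    passthrough: list[int] = []
    if skip_validity:
        # Columns that go non-finite on this dataset cannot be placed in the
        # coefficient space; they pass through unclustered (only the skipped
        # validity stage could have eliminated them).
        finite_cols = coeffs.finite.all(axis=0)
        passthrough = [eq for eq, ok in zip(pool, finite_cols) if not ok]
        if passthrough:
            pool = [eq for eq, ok in zip(pool, finite_cols) if ok]
            coeffs = measures.evaluate_all_pairs(dataset, pool)
            for eq_id in passthrough:
                audit.append({
                    "stage": "zero-distance", "eliminated": "", "kept": eq_id,
                    "reason": "non-finite on dataset; not clustered",
                    "max_deviation": "",
                })
    z = standardize(coeffs)
    retained, cluster_elim = eliminate_zero_distance(z, pool, tol)
    retained = sorted(retained + passthrough)
    for eq_id, (kept, distance) in sorted(cluster_elim.items()):
        audit.append({
            "stage": "zero-distance", "eliminated": eq_id, "kept": kept,
            "reason": "standardized distance below tolerance",
            "max_deviation": distance,
        })
    return ReductionResult(
        identity_eliminated=sorted(REDUNDANT_IDS),
        validity_eliminated=validity_eliminated,
        cluster_eliminated=cluster_elim,
        retained=retained,
        audit_rows=audit,
    )


def write_audit(result: ReductionResult, path, delimiter: str = ",") -> None:
    """Write the elimination audit as delimited text."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["stage", "eliminated_eq_id", "kept_eq_id",
                        "reason", "max_deviation"])
        for row in result.audit_rows:
            writer.writerow([row["stage"], row["eliminated"], row["kept"],
                             row["reason"], row["max_deviation"]])
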