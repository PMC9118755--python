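"""The five similarity views over lncRNAs and diseases.

Disease side:
  * DSS — Wang semantic similarity on the disease-ontology DAG.  Each
    ancestor t of a disease d contributes DS_d(t), defined by DS_d(d) = 1 and
    DS_d(t) = max over children t' of t (within d's ancestor closure) of
    xi * DS_d(t'); similarity of two diseases is the summed contribution of
    their shared ancestors normalized by the two total contributions.
  * DGS — Gaussian interaction-profile (GIP) kernel on LD columns.

lncRNA side:
  * LFS — functional similarity: best-match average of DSS between the two
    lncRNAs' associated-disease sets.
  * LSS — 1 - weighted Levenshtein distance / (len_i + len_j), with
    substitution cost 2 and insertion/deletion cost 1.
  * LGS — GIP kernel on LD rows.

Every view is emitted as a symmetric matrix with entries in [0, 1] and a
diagonal forced to exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy.spatial.distance import squareform, pdist

from .io_formats import AssociationMatrix, OntologyDAG, SequenceSet

__all__ = [
    "SimilarityView",
    "EditCosts",
    "SemanticParams",
    "semantic_contributions",
    "disease_semantic_similarity",
    "lncrna_functional_similarity",
    "weighted_edit_distance",
    "lncrna_sequence_similarity",
    "gip_similarity",
    "LNCRNA_VIEW_ORDER",
    "DISEASE_VIEW_ORDER",
]

LNCRNA_VIEW_ORDER = ("LFS", "LSS", "LGS")
DISEASE_VIEW_ORDER = ("DSS", "DGS")
_VIEW_NAMES = frozenset(LNCRNA_VIEW_ORDER) | frozenset(DISEASE_VIEW_ORDER)

_SYMMETRY_TOL = 1e-12


@dataclass
class SimilarityView:
    """One symmetric [0,1] similarity matrix tagged with its view name."""

    values: np.ndarray
    entity_ids: list[str]
    view_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.view_name not in _VIEW_NAMES:
            raise ValueError(f"unknown view name {self.view_name!r}")
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match entity count")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError(f"{self.view_name} matrix is not symmetric")
        if n and (self.values.min() < -_SYMMETRY_TOL or self.values.max() > 1 + _SYMMETRY_TOL):
            raise ValueError(f"{self.view_name} entries fall outside [0, 1]")
        if n and np.any(np.diag(self.values) != 1.0):
            raise ValueError(f"{self.view_name} diagonal is not exactly 1")

    @property
    def n(self) -> int:
        return len(self.entity_ids)


def _finalize(values: np.ndarray, ids: Sequence[str], name: str) -> SimilarityView:
    values = np.asarray(values, dtype=float)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityView(values, list(ids), name)


@dataclass
class EditCosts:
    """Unit costs of the weighted Levenshtein distance."""

    substitution: float = 2.0
    insertion: float = 1.0
    deletion: float = 1.0

    def __post_init__(self) -> None:
        if min(self.substitution, self.insertion, self.deletion) < 0:
            raise ValueError("edit costs must be non-negative")


@dataclass
class SemanticParams:
    """Wang-method contribution factor xi in (0, 1]."""

    xi: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.xi <= 1:
            raise ValueError("contribution factor xi must be in (0, 1]")


# ---------------------------------------------------------------------------
# Disease semantic similarity (Wang's method)
# ---------------------------------------------------------------------------

def semantic_contributions(
    dag: OntologyDAG,
    disease: str,
    params: SemanticParams | None = None,
) -> dict[str, float]:
    """Per-ancestor semantic contributions DS_d(t) for every t in D(d).

    DS_d(d) = 1 and each strict ancestor inherits xi times the best
    contribution among its children inside the closure.  Returns an empty map
    (with a warning) when the disease is absent from the DAG, in which case
    callers fall back to identity-only similarity.
    """
    params = params or SemanticParams()
    closure = dag.ancestor_closure(disease)
    if not closure:
        warnings.warn(
            f"disease {disease!r} has no entry in the ontology DAG; "
            "semantic similarity falls back to identity",
            stacklevel=2,
        )
        return {}
    contrib: dict[str, float] = {}

    def ds(term: str) -> float:
        if term in contrib:
            return contrib[term]
        if term == disease:
            value = 1.0
        else:
            value = max(params.xi * ds(child) for child in dag.children_in(term, closure))
        contrib[term] = value
        return value

    for term in closure:
        ds(term)
    return contrib


def total_contribution(contrib: Mapping[str, float]) -> float:
    """DC(d): the summed contribution of a disease's ancestor closure."""
    return float(sum(contrib.values()))


def disease_semantic_similarity(
    dag: OntologyDAG,
    diseases: Sequence[str],
    params: SemanticParams | None = None,
) -> SimilarityView:
    params = params or SemanticParams()
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        contribs = [semantic_contributions(dag, d, params) for d in diseases]
    totals = [total_contribution(c) for c in contribs]
    n = len(diseases)
    values = np.zeros((n, n))
    for i in range(n):
        ci = contribs[i]
        for j in range(i + 1, n):
            cj = contribs[j]
            if not ci or not cj:
                continue
            shared = ci.keys() & cj.keys()
            if shared:
                values[i, j] = sum(ci[t] + cj[t] for t in shared) / (totals[i] + totals[j])
    values += values.T
    return _finalize(values, diseases, "DSS")


# ---------------------------------------------------------------------------
# lncRNA functional similarity
# ---------------------------------------------------------------------------

def lncrna_functional_similarity(ld: AssociationMatrix, dss: SimilarityView) -> SimilarityView:
    """Best-match-average DSS between the disease sets of each lncRNA pair."""
    if dss.entity_ids != ld.disease_ids:
        raise ValueError("DSS entity order does not match the association matrix diseases")
    L = len(ld.lncrna_ids)
    disease_sets = [np.flatnonzero(ld.values[i]) for i in range(L)]
    if any(len(s) == 0 for s in disease_sets):
        warnings.warn(
            "some lncRNAs have no associations; their functional similarity "
            "is 0 off-diagonal",
            stacklevel=2,
        )
    values = np.zeros((L, L))
    S = dss.values
    for i in range(L):
        di = disease_sets[i]
        for j in range(i + 1, L):
            dj = disease_sets[j]
            if len(di) == 0 or len(dj) == 0:
                continue
            block = S[np.ix_(di, dj)]
            values[i, j] = (block.max(axis=0).sum() + block.max(axis=1).sum()) / (
                len(di) + len(dj)
            )
    values += values.T
    return _finalize(values, ld.lncrna_ids, "LFS")


# ---------------------------------------------------------------------------
# lncRNA sequence similarity (weighted Levenshtein)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _edit_dp(a: np.ndarray, b: np.ndarray, sub: float, ins: float, dele: float) -> float:
    m, n = a.shape[0], b.shape[0]
    prev = np.empty(n + 1, dtype=np.float64)
    curr = np.empty(n + 1, dtype=np.float64)
    for j in range(n + 1):
        prev[j] = j * ins
    for i in range(1, m + 1):
        curr[0] = i * dele
        ai = a[i - 1]
        for j in range(1, n + 1):
            c = prev[j - 1] if ai == b[j - 1] else prev[j - 1] + sub
            d = prev[j] + dele
            if d < c:
                c = d
            e = curr[j - 1] + ins
            if e < c:
                c = e
            curr[j] = c
        prev, curr = curr, prev
    return prev[n]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def weighted_edit_distance(s1: str, s2: str, costs: EditCosts | None = None) -> float:
    """Minimum total cost of turning ``s1`` into ``s2``.

    Standard dynamic program over insertions (into s1), deletions and
    substitutions with the given unit costs; empty strings are allowed.
    """
    costs = costs or EditCosts()
    if not s1:
        return len(s2) * costs.insertion
    if not s2:
        return len(s1) * costs.deletion
    return float(
        _edit_dp(_encode(s1), _encode(s2), costs.substitution, costs.insertion, costs.deletion)
    )


def lncrna_sequence_similarity(
    seqs: SequenceSet,
    lncrnas: Sequence[str],
    costs: EditCosts | None = None,
) -> SimilarityView:
    """LSS(i, j) = 1 - dist(i, j) / (len_i + len_j), mirrored over pairs."""
    costs = costs or EditCosts()
    missing = [name for name in lncrnas if name not in seqs]
    if missing:
        raise ValueError(f"no sequence available for lncRNA {missing[0]!r}")
    n = len(lncrnas)
    encoded = [_encode(seqs[name]) for name in lncrnas]
    lengths = [len(e) for e in encoded]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = _edit_dp(
                encoded[i], encoded[j], costs.substitution, costs.insertion, costs.deletion
            )
            values[i, j] = 1.0 - dist / (lengths[i] + lengths[j])
    values += values.T
    return _finalize(values, lncrnas, "LSS")


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernel similarity
# ---------------------------------------------------------------------------

def gip_similarity(ld: AssociationMatrix, axis: str) -> SimilarityView:
    """GIP kernel over association profiles (LD rows or columns).

    The bandwidth eta is 1 over the mean squared Euclidean norm of the
    profiles, and sim(i, j) = exp(-eta * ||profile_i - profile_j||^2).
    """
    if axis == "lncrna":
        profiles = ld.values.astype(float)
        ids, name = ld.lncrna_ids, "LGS"
    elif axis == "disease":
        profiles = ld.values.T.astype(float)
        ids, name = ld.disease_ids, "DGS"
    else:
        raise ValueError("axis must be 'lncrna' or 'disease'")
    mean_sq_norm = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("GIP bandwidth undefined: the association matrix is all-zero")
    eta = 1.0 / mean_sq_norm
    if profiles.shape[0] > 1:
        sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    else:
        sq_dists = np.zeros((1, 1))
    return _finalize(np.exp(-eta * sq_dists), ids, name)
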