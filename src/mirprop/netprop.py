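"""Random-walk-with-restart propagation of miRNA perturbations.

A miRNA family perturbs its predicted targets directly; when a target is a
transcription factor the perturbation spreads to the TF's regulon, and so on
through the directed regulatory network.  The propagation operator is a
random walk with restart (RWR): starting from the uniform distribution p0
over the family's targets, iterate

    p ← (1 − α)·T p + α·p0

where T[v, u] = 1/indegree(v) for each regulation edge u → v (each gene's
incoming weights sum to 1; parentless genes receive no propagated mass).
The restart probability α keeps mass anchored on the direct targets while
(1 − α) of it diffuses downstream.  Because T's rows are sub-stochastic,
ρ((1 − α)T) < 1 and the iteration converges to the unique fixed point
α·(I − (1 − α)T)⁻¹·p0, which serves as the closed-form test oracle.

Note the total effect mass is not conserved: a hub regulator with several
single-parent children duplicates mass (each child inherits the full parent
mass), so ‖p‖₁ may exceed 1 on hub-rich networks.  Effects are compared
within a ranking, where the overall scale is irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import EdgeList, FamilyRecord, TargetTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationParams:
    """RWR parameters.

    restart_alpha: probability of restarting at the seed distribution each
        step; α = 1 reduces the effect to the direct-target profile.
    direction: "downstream" follows regulation (TF → regulated gene);
        "upstream" transposes the operator (gene → its regulators).
    """

    restart_alpha: float = 0.5
    tolerance: float = 1e-8
    max_iterations: int = 1000
    direction: str = "downstream"

    def __post_init__(self) -> None:
        if not 0 < self.restart_alpha <= 1:
            raise ValueError("restart_alpha must lie in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.direction not in ("downstream", "upstream"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class PropagationResult:
    family_id: str
    effect: dict[str, float]
    seed_genes: frozenset[str]
    iterations_used: int
    converged: bool


class SkipFamily(Exception):
    """Raised when a family has no target inside the gene universe."""


def build_transition_operator(
    edges: EdgeList, gene_universe: list[str] | tuple[str, ...]
) -> sp.csr_matrix:
    """Build T with T[v, u] = 1/indegree(v) for each edge u → v.

    *gene_universe* fixes the index order and must contain every edge
    endpoint.  Isolated genes are allowed (all-zero row and column).
    """
    index = {g: i for i, g in enumerate(gene_universe)}
    if len(index) != len(gene_universe):
        raise ValueError("gene_universe contains duplicates")
    missing = edges.node_ids() - index.keys()
    if missing:
        raise ValueError(f"edge endpoints outside gene universe: {sorted(missing)[:5]}")
    n = len(gene_universe)
    if not edges.edges:
        return sp.csr_matrix((n, n))
    rows = np.array([index[t] for _, t in edges.edges])
    cols = np.array([index[s] for s, _ in edges.edges])
    indeg = np.bincount(rows, minlength=n).astype(float)
    data = 1.0 / indeg[rows]
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def seed_vector(
    family: FamilyRecord, gene_universe: list[str] | tuple[str, ...]
) -> np.ndarray:
    """Uniform initial distribution over the family's in-universe targets."""
    index = {g: i for i, g in enumerate(gene_universe)}
    hits = [index[g] for g in family.target_gene_ids if g in index]
    if not hits:
        raise SkipFamily(family.family_id)
    p0 = np.zeros(len(gene_universe))
    p0[hits] = 1.0 / len(hits)
    return p0


def propagate(
    operator: sp.spmatrix,
    p0: np.ndarray,
    params: PropagationParams = PropagationParams(),
    *,
    family_id: str = "",
    gene_universe: list[str] | tuple[str, ...] | None = None,
) -> PropagationResult:
    """Iterate the RWR update to a fixed point (L1 change < tolerance)."""
    if not np.isclose(p0.sum(), 1.0):
        raise ValueError("p0 must sum to 1")
    T = operator.T.tocsr() if params.direction == "upstream" else operator.tocsr()
    alpha = params.restart_alpha
    p = p0.copy()
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        p_next = (1.0 - alpha) * (T @ p) + alpha * p0
        if np.abs(p_next - p).sum() < params.tolerance:
            p = p_next
            converged = True
            break
        p = p_next
    if not converged:
        logger.warning(
            "propagation for %r did not converge in %d iterations",
            family_id,
            params.max_iterations,
        )
    universe = (
        gene_universe if gene_universe is not None else [str(i) for i in range(len(p0))]
    )
    seeds = frozenset(g for g, v in zip(universe, p0) if v > 0)
    return PropagationResult(
        family_id=family_id,
        effect={g: float(v) for g, v in zip(universe, p)},
        seed_genes=seeds,
        iterations_used=it,
        converged=converged,
    )


def propagate_closed_form(
    operator: sp.spmatrix,
    p0: np.ndarray,
    params: PropagationParams = PropagationParams(),
) -> np.ndarray:
    """Dense linear-solve oracle: α·(I − (1 − α)T)⁻¹·p0."""
    T = operator.T if params.direction == "upstream" else operator
    n = len(p0)
    A = np.eye(n) - (1.0 - params.restart_alpha) * np.asarray(T.todense())
    return params.restart_alpha * np.linalg.solve(A, p0)


def propagate_all(
    target_table: TargetTable,
    edges: EdgeList,
    gene_universe: list[str] | tuple[str, ...],
    params: PropagationParams = PropagationParams(),
) -> list[PropagationResult]:
    """Propagate every family in the table; families with no in-universe
    target are skipped (logged) and omitted from the output."""
    operator = build_transition_operator(edges, gene_universe)
    results: list[PropagationResult] = []
    for rec in target_table:
        try:
            p0 = seed_vector(rec, gene_universe)
        except SkipFamily:
            logger.info("family %s has no target in universe; skipped", rec.family_id)
            continue
        results.append(
            propagate(
                operator,
                p0,
                params,
                family_id=rec.family_id,
                gene_universe=gene_universe,
            )
        )
    return results
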