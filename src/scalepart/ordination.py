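"""Correspondence-analysis machinery: chi-square transform, CCA, partial CCA,
and four-group variance partitioning on the percent-inertia scale.

The community matrix Y (cells × species counts) is converted to the matrix of
standardized chi-square residuals

    Q_ij = (p_ij − r_i c_j) / sqrt(r_i c_j),

where p = Y / N, r and c are the row and column masses.  Total inertia is
ΣQ² and equals the Pearson chi-square statistic of the table divided by its
grand total N.

Canonical correspondence analysis projects Q onto the span of the constraint
matrix X after weighted centering (row masses) and row weighting by sqrt(r);
the canonical eigenvalues are the squared singular values of the projected
matrix, and the constrained inertia is their sum.  Partial CCA first
residualizes both Q and the weighted X on the conditioning set Z; its
constrained inertia is the *exclusive* inertia of X given Z and satisfies

    pcca(Y, X | Z) = cca(Y, [X Z]) − cca(Y, Z)

exactly (orthogonal projection decomposition).

Variance partitioning divides, for each variable group G, the exclusive
inertia of G given all other groups by the total inertia and multiplies by
100; the joint percent is the same ratio for all groups together, and the
overlap is joint − Σ exclusive (it can be negative and is reported as-is,
flagged, never truncated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import VariableGroup

logger = logging.getLogger(__name__)

#: Relative singular-value tolerance for rank-revealing decompositions.
RANK_TOL = 1e-8


@dataclass
class ChiSquareDecomposition:
    Q: np.ndarray
    row_masses: np.ndarray
    col_masses: np.ndarray
    total_inertia: float


@dataclass
class CCAResult:
    eigenvalues: np.ndarray
    constrained_inertia: float
    total_inertia: float
    rank: int


@dataclass
class PartitionResult:
    """Percent-inertia partition of one grid's community variance."""

    grid_id: str
    total_inertia: float
    exclusive_pct: dict[str, float]
    joint_pct: float
    overlap_pct: float
    negative_overlap: bool = False


def drop_empty(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove all-zero rows (empty cells) and columns (absent species).

    Returns the reduced matrix and boolean masks of kept rows and columns.
    """
    Y = np.asarray(Y, dtype=float)
    rows = Y.sum(axis=1) > 0
    cols = Y.sum(axis=0) > 0
    return Y[np.ix_(rows, cols)], rows, cols


def chi_square_transform(community: np.ndarray) -> ChiSquareDecomposition:
    """Standardized chi-square residuals, masses and total inertia of a count table.

    The input must already have zero rows/columns removed (see
    :func:`drop_empty`); an all-zero matrix raises.
    """
    Y = np.asarray(community, dtype=float)
    if Y.ndim != 2 or Y.size == 0:
        raise ValueError("community must be a non-empty 2-D count matrix")
    if (Y < 0).any():
        raise ValueError("community counts must be nonnegative")
    total = Y.sum()
    if total == 0:
        raise ValueError("community matrix is all zero")
    if (Y.sum(axis=1) == 0).any() or (Y.sum(axis=0) == 0).any():
        raise ValueError("remove zero rows/columns (drop_empty) before transforming")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    return ChiSquareDecomposition(
        Q=Q, row_masses=r, col_masses=c, total_inertia=float((Q**2).sum())
    )


def _weighted_basis(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Orthonormal basis (columns) of the weighted, centered constraint space.

    Columns of X are centered by their row-mass weighted means and the rows
    scaled by sqrt(r); collinear columns are dropped by a rank-revealing SVD
    with relative tolerance RANK_TOL.  Returns an (n, rank) matrix with
    orthonormal columns (rank may be 0).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    means = r @ X  # weighted column means (Σ r_i = 1)
    Xc = X - means
    Xw = np.sqrt(r)[:, None] * Xc
    U, s, _ = np.linalg.svd(Xw, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.empty((X.shape[0], 0))
    keep = s > RANK_TOL * s[0]
    return U[:, keep]


def _eigenvalues_of_projection(Q: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Squared singular values of the projection of Q onto span(basis)."""
    if basis.shape[1] == 0:
        return np.empty(0)
    fitted = basis @ (basis.T @ Q)
    s = np.linalg.svd(fitted, compute_uv=False)
    ev = s**2
    ev = ev[ev > RANK_TOL**2 * max(ev[0], 1.0)] if ev.size else ev
    return np.sort(ev)[::-1]


def cca(community: np.ndarray, X: np.ndarray) -> CCAResult:
    """Canonical correspondence analysis of a count matrix on constraints X.

    Rows of X correspond to the (non-empty) rows of the community matrix.
    A constraint set with zero effective rank after weighted centering (e.g.
    a constant column) yields zero constrained inertia with a warning.
    """
    dec = chi_square_transform(community)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != dec.Q.shape[0]:
        raise ValueError("X rows must match community rows")
    basis = _weighted_basis(X, dec.row_masses)
    if basis.shape[1] == 0:
        logger.warning("constraint matrix has zero effective rank after centering")
    ev = _eigenvalues_of_projection(dec.Q, basis)
    return CCAResult(
        eigenvalues=ev,
        constrained_inertia=float(ev.sum()),
        total_inertia=dec.total_inertia,
        rank=int(ev.size),
    )


def pcca(community: np.ndarray, X: np.ndarray, Z: np.ndarray | None) -> CCAResult:
    """Partial CCA: exclusive inertia of X after conditioning on Z.

    Both Q and the weighted-centered X are residualized on the weighted-
    centered Z; a CCA of the residuals follows.  With Z empty this is
    identical to :func:`cca`.
    """
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        return cca(community, X)
    dec = chi_square_transform(community)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if X.shape[0] != dec.Q.shape[0] or Z.shape[0] != dec.Q.shape[0]:
        raise ValueError("X and Z rows must match community rows")
    r = dec.row_masses
    Bz = _weighted_basis(Z, r)
    Q_res = dec.Q - Bz @ (Bz.T @ dec.Q)
    # weighted-center X, then residualize the weighted matrix on span(Bz)
    Xw = np.sqrt(r)[:, None] * (X - r @ X)
    Xw_res = Xw - Bz @ (Bz.T @ Xw)
    # rank reference is the unresidualized scale: directions of X that Z
    # absorbs entirely must not resurface as numerically tiny residuals
    ref = np.linalg.norm(Xw, 2) if Xw.size else 0.0
    U, s, _ = np.linalg.svd(Xw_res, full_matrices=False)
    if s.size and ref > 0:
        basis = U[:, s > RANK_TOL * ref]
    else:
        basis = np.empty((X.shape[0], 0))
    ev = _eigenvalues_of_projection(Q_res, basis)
    return CCAResult(
        eigenvalues=ev,
        constrained_inertia=float(ev.sum()),
        total_inertia=dec.total_inertia,
        rank=int(ev.size),
    )


def partition_variance(
    community,
    environment,
    groups: list[VariableGroup],
    grid_id: str = "",
) -> PartitionResult:
    """Four-group percent-inertia variance partition for one sampling grid.

    ``community`` is the cells × species count matrix (full cell index) and
    ``environment`` the matching cells × variables DataFrame.  Empty cells
    and absent species are dropped per grid before the chi-square transform;
    environment rows follow the community rows.  For each group G the
    exclusive percent is 100 · pcca(Y, X_G | X_others) / total inertia; the
    joint percent uses all groups together, and overlap = joint − Σ exclusive.
    """
    if isinstance(community, pd.DataFrame):
        Yfull = community.to_numpy(dtype=float)
    else:
        Yfull = np.asarray(community, dtype=float)
    env = environment if isinstance(environment, pd.DataFrame) else pd.DataFrame(environment)
    if Yfull.shape[0] != env.shape[0]:
        raise ValueError("community and environment must have the same rows")
    missing = [m for g in groups for m in g.members if m not in env.columns]
    if missing:
        raise ValueError(f"environment matrix lacks group members: {missing}")

    Y, rows, _ = drop_empty(Yfull)
    envr = env.loc[np.asarray(rows)]
    # cells with any missing variable cannot enter the ordination
    finite = np.isfinite(envr.to_numpy(dtype=float)).all(axis=1)
    if not finite.all():
        logger.warning(
            "grid %s: %d cells dropped for missing environment values",
            grid_id,
            int((~finite).sum()),
        )
        Y, rows2, _ = drop_empty(Y[finite])
        envr = envr.loc[finite].loc[np.asarray(rows2)]

    Xg = {g.name: envr[list(g.members)].to_numpy(dtype=float) for g in groups}
    X_all = np.column_stack([Xg[g.name] for g in groups])
    if X_all.shape[1] >= Y.shape[0]:
        logger.warning(
            "grid %s: %d environment columns for %d usable cells; "
            "rank reduction will trim the constraint space",
            grid_id,
            X_all.shape[1],
            Y.shape[0],
        )
    total = chi_square_transform(Y).total_inertia
    joint = cca(Y, X_all).constrained_inertia
    exclusive: dict[str, float] = {}
    for g in groups:
        others = [Xg[h.name] for h in groups if h.name != g.name]
        Z = np.column_stack(others) if others else None
        exclusive[g.name] = 100.0 * pcca(Y, Xg[g.name], Z).constrained_inertia / total
    joint_pct = 100.0 * joint / total
    overlap = joint_pct - sum(exclusive.values())
    return PartitionResult(
        grid_id=grid_id,
        total_inertia=total,
        exclusive_pct=exclusive,
        joint_pct=joint_pct,
        overlap_pct=overlap,
        negative_overlap=overlap < 0,
    )


def partition_table(results: list[PartitionResult], scales: dict[str, int] | None = None) -> pd.DataFrame:
    """Flatten partition results to the analysis CSV layout."""
    rows = []
    for p in results:
        row = {
            "grid_id": p.grid_id,
            "scale": (scales or {}).get(p.grid_id),
            "total_inertia": p.total_inertia,
        }
        row.update({f"{k}_pct": v for k, v in p.exclusive_pct.items()})
        row["joint_pct"] = p.joint_pct
        row["overlap_pct"] = p.overlap_pct
        row["negative_overlap"] = p.negative_overlap
        rows.append(row)
    return pd.DataFrame(rows)
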