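"""Time-coupled optimal transport: ancestor distributions and trajectories.

For each adjacent pair of time points an entropy-regularised optimal
transport coupling is fitted by Sinkhorn scaling on the squared-
Euclidean cost in corrected PC space (cost median-normalised so the
regularisation strength is scale-free).  Endpoint fate masses - an
indicator over the terminal clusters of each fate - are pulled backward
through the couplings to give per-cell ancestor masses at every earlier
time point, and cells are allocated to the trajectory of their largest
mass, or to several trajectories when a runner-up mass is at least a
fraction ``rho`` (default 0.9) of the largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .manifold import Embedding


@dataclass
class PairCoupling:
    source_ids: np.ndarray
    target_ids: np.ndarray
    gamma: np.ndarray  # source x target, entries >= 0
    epsilon: float
    n_iter: int
    marginal_residual: float
    converged: bool


@dataclass
class TransportPlan:
    timepoints: list  # ordered stage identifiers
    couplings: dict = field(default_factory=dict)  # (t, t+1) index pair -> PairCoupling
    epsilon: float = 0.05


@dataclass
class FateMassTable:
    fates: list
    masses: dict  # stage index -> DataFrame(cell x fate)


@dataclass
class TrajectoryAssignment:
    rho: float
    table: pd.DataFrame  # cell, stage_index, per-fate masses, assigned_fates


def sinkhorn(
    cost: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    epsilon: float,
    max_iter: int = 20000,
    tol: float = 1e-9,
):
    """Log-domain Sinkhorn for the entropy-regularised OT coupling.

    Minimises <gamma, C> + eps * KL(gamma | a b^T) subject to the
    marginal constraints gamma 1 = a, gamma^T 1 = b.  The converged
    coupling is projected onto the transport polytope by the standard
    rounding step so the returned marginals are exact to machine
    precision.  Returns ``(gamma, n_iter, residual)`` where residual is
    the L1 error of both marginals after rounding.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    C = np.asarray(cost, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if C.shape != (a.size, b.size):
        raise ValueError("cost shape does not match marginals")
    if abs(a.sum() - b.sum()) > 1e-8:
        raise ValueError("marginals must have equal total mass")

    def residual(gamma):
        return float(
            np.abs(gamma.sum(axis=1) - a).sum() + np.abs(gamma.sum(axis=0) - b).sum()
        )

    def rounded(gamma):
        # project onto the transport polytope (Altschuler et al. rounding):
        # scale overfull rows/columns, then patch the deficit rank-one
        r = np.minimum(1.0, a / np.maximum(gamma.sum(axis=1), 1e-300))
        gamma = gamma * r[:, None]
        c = np.minimum(1.0, b / np.maximum(gamma.sum(axis=0), 1e-300))
        gamma = gamma * c[None, :]
        ea = a - gamma.sum(axis=1)
        eb = b - gamma.sum(axis=0)
        s = ea.sum()
        if s > 1e-300:
            gamma = gamma + np.outer(ea, eb) / s
        return np.maximum(gamma, 0.0)

    # stabilized scaling: plain u/v Sinkhorn on the rescaled kernel
    # exp((f + g - C)/eps), absorbing u, v into the log potentials f, g
    # whenever the scalings threaten double-precision range
    f = C.min(axis=1).copy()  # row shift guards against fully underflowed rows
    g = np.zeros(b.size)

    def kernel():
        return np.exp((f[:, None] + g[None, :] - C) / epsilon)

    K = kernel()
    u = np.ones(a.size)
    v = np.ones(b.size)
    gamma = K
    for it in range(1, max_iter + 1):
        u = a / np.maximum(K @ v, 1e-300)
        v = b / np.maximum(K.T @ u, 1e-300)
        if max(np.abs(np.log(u)).max(), np.abs(np.log(v)).max()) > 250.0:
            f = f + epsilon * np.log(u)
            g = g + epsilon * np.log(v)
            K = kernel()
            u.fill(1.0)
            v.fill(1.0)
        if it % 10 == 0 or it == max_iter:
            gamma = u[:, None] * K * v[None, :]
            res = residual(gamma)
            if res < tol:
                gamma = rounded(gamma)
                return gamma, it, residual(gamma)
    gamma = rounded(gamma)
    return gamma, it, residual(gamma)


def _logsumexp_rows(M: np.ndarray) -> np.ndarray:
    mx = M.max(axis=1, keepdims=True)
    return (mx + np.log(np.exp(M - mx).sum(axis=1, keepdims=True))).ravel()


def fit_couplings(
    embedding: Embedding,
    cells: pd.DataFrame,
    epsilon: float = 0.05,
    growth: np.ndarray | None = None,
    max_iter: int = 20000,
    tol: float = 1e-9,
) -> TransportPlan:
    """Sinkhorn couplings between every adjacent pair of time points.

    Cost between cells is squared Euclidean distance in the embedding,
    divided by its median so ``epsilon`` is comparable across pairs.
    Source marginals are uniform (or proportional to ``growth``), target
    marginals uniform.
    """
    if "stage_index" not in cells:
        raise ValueError("cell table lacks 'stage_index'")
    stages = sorted(cells["stage_index"].unique())
    if len(stages) < 2:
        raise ValueError("need at least two time points for transport")
    ids = np.asarray(embedding.cell_ids)
    pos = {c: i for i, c in enumerate(ids)}
    plan = TransportPlan(timepoints=stages, epsilon=epsilon)
    for t0, t1 in zip(stages[:-1], stages[1:]):
        src_cells = cells.loc[cells["stage_index"] == t0, "cell"].to_numpy()
        tgt_cells = cells.loc[cells["stage_index"] == t1, "cell"].to_numpy()
        X = embedding.coords[[pos[c] for c in src_cells]]
        Y = embedding.coords[[pos[c] for c in tgt_cells]]
        C = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
        med = np.median(C)
        if med > 0:
            C = C / med
        a = np.full(X.shape[0], 1.0 / X.shape[0])
        if growth is not None:
            g = np.asarray(growth, dtype=float)
            if g.size != X.shape[0]:
                raise ValueError("growth vector length mismatch at stage %s" % t0)
            a = g / g.sum()
        b = np.full(Y.shape[0], 1.0 / Y.shape[0])
        gamma, n_iter, res = sinkhorn(C, a, b, epsilon, max_iter=max_iter, tol=tol)
        if res >= tol:
            warnings.warn(
                f"Sinkhorn did not reach tolerance for pair ({t0}, {t1}): "
                f"residual {res:.2e} after {n_iter} iterations"
            )
        plan.couplings[(t0, t1)] = PairCoupling(
            source_ids=src_cells,
            target_ids=tgt_cells,
            gamma=gamma,
            epsilon=epsilon,
            n_iter=n_iter,
            marginal_residual=res,
            converged=res < tol,
        )
    return plan


def pull_back_mass(plan: TransportPlan, endpoint_masses: pd.DataFrame) -> FateMassTable:
    """Ancestor mass at every earlier time point by transport pull-back.

    ``endpoint_masses`` is a cells x fates frame indexed by the final
    time point's cell ids (typically an indicator of the endpoint
    cluster of each fate).  The pull-back through coupling gamma is
    a_i(f) = sum_j [gamma_ij / sum_i' gamma_i'j] d_j(f); each fate
    column is renormalised to total mass 1 at every time point.
    """
    fates = list(endpoint_masses.columns)
    if (endpoint_masses.to_numpy() < 0).any():
        raise ValueError("endpoint masses must be non-negative")
    if endpoint_masses.to_numpy().sum() == 0:
        raise ValueError("no endpoint mass supplied")
    stages = plan.timepoints
    masses: dict = {}
    d = endpoint_masses.copy()
    col_sums = d.sum(axis=0)
    if (col_sums == 0).any():
        warnings.warn(
            f"fates with zero endpoint mass: {list(col_sums.index[col_sums == 0])}"
        )
    d = d / col_sums.replace(0, np.nan)
    d = d.fillna(0.0)
    masses[stages[-1]] = d
    for k in range(len(stages) - 2, -1, -1):
        t0, t1 = stages[k], stages[k + 1]
        pc = plan.couplings[(t0, t1)]
        d_next = masses[t1].reindex(pc.target_ids).to_numpy()
        if np.isnan(d_next).any():
            raise ValueError(f"mass frame at stage {t1} missing some cells")
        gamma = pc.gamma
        col = gamma.sum(axis=0)
        dead = col <= 0
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} descendant cells carry zero coupling mass "
                f"at pair ({t0}, {t1}); their mass is dropped"
            )
        ratio = np.where(dead[None, :], 0.0, gamma / np.where(dead, 1.0, col)[None, :])
        a = ratio @ d_next
        frame = pd.DataFrame(a, index=pc.source_ids, columns=fates)
        tot = frame.sum(axis=0)
        frame = (frame / tot.replace(0, np.nan)).fillna(0.0)
        masses[t0] = frame
    return FateMassTable(fates=fates, masses=masses)


def assign_trajectories(
    masses: FateMassTable, rho: float = 0.9, floor_scale: float = 0.1
) -> TrajectoryAssignment:
    """Allocate each cell to the trajectory (or trajectories) of its mass.

    Per cell the maximal fate mass m* is found; every fate with mass
    >= rho * m* is assigned (the boundary is inclusive).  Cells whose
    m* falls below ``floor_scale / n_cells_at_that_time_point`` are left
    unassigned as carriers of numerically negligible mass.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must be in (0, 1]")
    if not masses.masses:
        raise ValueError("empty fate-mass table")
    rows = []
    for stage, frame in sorted(masses.masses.items()):
        m = frame.to_numpy()
        n_t = m.shape[0]
        floor = floor_scale / max(n_t, 1)
        mstar = m.max(axis=1)
        for i, cell in enumerate(frame.index):
            if mstar[i] <= floor or mstar[i] == 0.0:
                assigned: list = []
            else:
                assigned = [
                    f
                    for j, f in enumerate(masses.fates)
                    if m[i, j] >= rho * mstar[i] - 1e-15
                ]
            row = {"cell": cell, "stage_index": stage}
            row.update({f: m[i, j] for j, f in enumerate(masses.fates)})
            row["assigned_fates"] = ";".join(assigned)
            rows.append(row)
    return TrajectoryAssignment(rho=rho, table=pd.DataFrame(rows))


def exact_ot_cost_bruteforce(cost: np.ndarray) -> float:
    """Exact OT cost for uniform marginals by enumerating permutation couplings.

    For an n x n cost with uniform marginals the optimum sits at a
    Birkhoff vertex, i.e. a permutation matrix scaled by 1/n.  Intended
    as a small-instance oracle (n <= 8).
    """
    from itertools import permutations

    C = np.asarray(cost, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n) or n > 8:
        raise ValueError("brute force oracle is for small square problems")
    best = np.inf
    for perm in permutations(range(n)):
        val = sum(C[i, perm[i]] for i in range(n)) / n
        best = min(best, val)
    return best
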