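"""Dynamic Ollivier-Ricci curvature over graph heat diffusion.

The network is diffused with the heat semigroup D = exp(-tau * L) of the
random-walk Laplacian L = I - K^-1 C_N built from shifted edge correlations.
Each row of D is the distribution reached from a Dirac delta after
pseudotime tau.  Per-edge Ollivier-Ricci curvature

    kappa_ij(tau) = 1 - W1(p_i, p_j) / d_ij

compares endpoint distributions by exact Wasserstein-1 optimal transport
with shortest-path ground cost.  Sweeping tau over a log grid yields a
curvature trace from which the critical scale tau_crit (first tau at which
the 99th percentile of edge curvature reaches 0.75), the per-edge curvature
kappa_crit at that scale, and the time-averaged integral kappa_bar_crit are
extracted.

Wasserstein-1 is solved exactly as a linear program (HiGHS via scipy).  Two
equivalent formulations are used: the Kantorovich coupling LP restricted to
the support of p - q (exact for any metric ground cost), and a
min-cost-flow LP on the graph itself (exact because the ground cost is the
shortest-path metric of the edge weights); the smaller problem is chosen
per edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .network import CorrelationNetwork

__all__ = [
    "DiffusionOperator",
    "CurvatureTrace",
    "default_tau_grid",
    "build_laplacian",
    "diffuse",
    "truncate_distribution",
    "wasserstein_w1",
    "edge_curvature",
    "curvature_trace",
    "find_tau_crit",
    "integrate_kappa",
    "critical_curvature",
]

# coupling LP is used when |supp+| * |supp-| is below this, else the flow LP
_COUPLING_SIZE_CAP = 900
_SUPPORT_TOL = 1e-15


def default_tau_grid(tau_min: float = 1e-2, tau_max: float = 1e2, n_tau: int = 101) -> np.ndarray:
    """Log-uniform pseudotime grid, by default 101 points on [1e-2, 1e2]."""
    return np.logspace(np.log10(tau_min), np.log10(tau_max), n_tau)


@dataclass
class DiffusionOperator:
    """Random-walk Laplacian with a spectral factorization for fast expm.

    L = I - K^-1 C_N is similar to the symmetric normalized Laplacian
    I - K^-1/2 C_N K^-1/2, so exp(-tau L) is computed for all tau from one
    eigendecomposition: exp(-tau L) = K^-1/2 U exp(-tau Lam) U^T K^1/2.
    """

    nodes: list[str]
    L: np.ndarray
    _evals: np.ndarray
    _evecs: np.ndarray
    _sqrt_k: np.ndarray


def build_laplacian(network: CorrelationNetwork) -> DiffusionOperator:
    """Random-walk Laplacian of the shifted-correlation matrix.

    C_N holds rho_shifted on network edges (zero diagonal); K is the
    diagonal of its row sums.  A vertex whose incident shifted correlations
    sum to zero has no diffusion outlet and is rejected.
    """
    n = len(network.nodes)
    _, ei, ej, rs, _ = network.edge_arrays()
    C = np.zeros((n, n))
    C[ei, ej] = rs
    C[ej, ei] = rs
    k = C.sum(axis=1)
    if (k <= 0).any():
        bad = network.nodes[int(np.argmin(k))]
        raise ValueError(f"vertex {bad!r} has zero weighted degree; diffusion undefined")
    L = np.eye(n) - C / k[:, None]
    sqrt_k = np.sqrt(k)
    sym = np.eye(n) - C / np.outer(sqrt_k, sqrt_k)
    evals, evecs = np.linalg.eigh(sym)
    return DiffusionOperator(nodes=list(network.nodes), L=L,
                             _evals=evals, _evecs=evecs, _sqrt_k=sqrt_k)


def diffuse(op: DiffusionOperator, tau: float) -> np.ndarray:
    """Row-stochastic heat kernel exp(-tau L); row i is delta_i diffused to tau."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if tau == 0:
        return np.eye(len(op.nodes))
    U, lam, sk = op._evecs, op._evals, op._sqrt_k
    M = (U * np.exp(-tau * lam)) @ U.T
    D = (M / sk[:, None]) * sk[None, :]
    # spectral roundoff can leave entries at ~-1e-16; clip and renormalize
    if D.min() < -1e-8:
        raise FloatingPointError("heat kernel has a significantly negative entry")
    np.clip(D, 0.0, None, out=D)
    D /= D.sum(axis=1, keepdims=True)
    return D


def truncate_distribution(p: np.ndarray, mass_floor: float) -> np.ndarray:
    """Drop entries below ``mass_floor`` and renormalize; floor 0 is the identity."""
    p = np.asarray(p, dtype=float)
    if mass_floor == 0:
        return p
    out = np.where(p < mass_floor, 0.0, p)
    total = out.sum()
    if total == 0:
        raise ValueError("all probability mass below mass_floor")
    return out / total


def _coupling_lp(a: np.ndarray, b: np.ndarray, cost: np.ndarray) -> float:
    """Exact Kantorovich LP: transport marginal a onto b at the given cost."""
    ns, nt = len(a), len(b)
    A_eq = sp.vstack(
        [
            sp.kron(sp.eye(ns), np.ones((1, nt))),
            sp.kron(np.ones((1, ns)), sp.eye(nt)),
        ],
        format="csr",
    )
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=np.concatenate([a, b]),
                  method="highs", options={"presolve": False})
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def wasserstein_w1(p: np.ndarray, q: np.ndarray, d: np.ndarray) -> float:
    """Exact Wasserstein-1 distance between p and q with metric ground cost d.

    Because d is a metric, shared mass never moves; the LP is solved on the
    supports of the positive and negative parts of p - q only, which is
    exact and much smaller than the full coupling.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if abs(p.sum() - 1) > 1e-8 or abs(q.sum() - 1) > 1e-8:
        raise ValueError("p and q must each sum to 1 (tolerance 1e-8)")
    r = p - q
    pos = np.nonzero(r > 0)[0]
    neg = np.nonzero(r < 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        return 0.0
    return _coupling_lp(r[pos], -r[neg], d[np.ix_(pos, neg)])


def _try_highs_core():
    try:  # vendored pybind11 bindings; present in recent scipy
        import scipy.optimize._highspy._core as core
        return core
    except Exception:
        return None


class _GraphFlowSolver:
    """Min-cost-flow W1 on a fixed graph: exact for shortest-path ground cost.

    Decision variables are forward/backward flows per edge; conservation
    constraints make the divergence equal p - q.  The model is built once
    and reused across all edge pairs and tau values.  When scipy's bundled
    HiGHS bindings are importable the model is kept hot inside one HiGHS
    instance so successive solves warm-start from the previous basis
    (~2x faster than cold solves); otherwise each solve goes through
    ``linprog``.  Both paths solve the identical LP.
    """

    def __init__(self, n: int, ei: np.ndarray, ej: np.ndarray, w: np.ndarray):
        m = len(ei)
        self.n = n
        inc = sp.coo_matrix(
            (
                np.concatenate([np.ones(m), -np.ones(m)]),
                (np.concatenate([ei, ej]), np.concatenate([np.arange(m), np.arange(m)])),
            ),
            shape=(n, m),
        )
        self.A_eq = sp.hstack([inc, -inc], format="csr")
        self.cost = np.concatenate([w, w])
        self._core = _try_highs_core()
        self._highs = None
        if self._core is not None:
            self._highs = self._build_model()

    def _build_model(self):
        core = self._core
        m2 = 2 * (len(self.cost) // 2)
        h = core._Highs()
        h.setOptionValue("output_flag", False)
        lp = core.HighsLp()
        lp.num_col_ = m2
        lp.num_row_ = self.n
        lp.col_cost_ = self.cost
        lp.col_lower_ = np.zeros(m2)
        lp.col_upper_ = np.full(m2, core.kHighsInf)
        lp.row_lower_ = np.zeros(self.n)
        lp.row_upper_ = np.zeros(self.n)
        lp.a_matrix_.format_ = core.MatrixFormat.kRowwise
        lp.a_matrix_.start_ = self.A_eq.indptr.astype(np.int32)
        lp.a_matrix_.index_ = self.A_eq.indices.astype(np.int32)
        lp.a_matrix_.value_ = self.A_eq.data
        if h.passModel(lp) != core.HighsStatus.kOk:
            return None
        return h

    def solve(self, r: np.ndarray) -> float:
        if self._highs is not None:
            h = self._highs
            for i in range(self.n):
                h.changeRowBounds(i, r[i], r[i])
            h.run()
            if h.getModelStatus() != self._core.HighsModelStatus.kOptimal:
                raise RuntimeError("flow LP failed to reach optimality")
            return float(h.getObjectiveValue())
        res = linprog(self.cost, A_eq=self.A_eq[:-1], b_eq=r[:-1],
                      method="highs", options={"presolve": False})
        if not res.success:
            raise RuntimeError(f"flow LP failed: {res.message}")
        return float(res.fun)


def _w1_dispatch(r: np.ndarray, d: np.ndarray, flow: _GraphFlowSolver) -> float:
    """Exact W1 of a difference vector r = p - q; small supports go to the coupling LP."""
    pos = np.nonzero(r > _SUPPORT_TOL)[0]
    neg = np.nonzero(r < -_SUPPORT_TOL)[0]
    if len(pos) == 0 or len(neg) == 0:
        return 0.0
    if len(pos) * len(neg) <= _COUPLING_SIZE_CAP and flow._highs is None:
        return _coupling_lp(r[pos], -r[neg], d[np.ix_(pos, neg)])
    return flow.solve(r)


def edge_curvature(p_i: np.ndarray, p_j: np.ndarray, d: np.ndarray,
                   edge: tuple[int, int]) -> float:
    """Ollivier-Ricci curvature 1 - W1(p_i, p_j) / d_ij for one edge."""
    i, j = edge
    dij = float(d[i, j])
    if dij <= 0:
        raise ValueError("edge endpoints at zero distance")
    w1 = max(wasserstein_w1(p_i, p_j, d), 0.0)
    return 1.0 - w1 / dij


@dataclass
class CurvatureTrace:
    """Per-edge curvature over the sampled tau grid, plus critical-scale summaries."""

    edges: list[tuple[str, str]]
    tau_grid: np.ndarray
    kappa: np.ndarray  # (n_edges, n_tau)
    tau_crit: float | None = None
    kappa_crit: dict[tuple[str, str], float] = field(default_factory=dict)
    kappa_bar_crit: dict[tuple[str, str], float] = field(default_factory=dict)
    kappa_bar_raw: dict[tuple[str, str], float] = field(default_factory=dict)


def _kappa_column(D: np.ndarray, network: CorrelationNetwork,
                  ei: np.ndarray, ej: np.ndarray, denom: np.ndarray,
                  flow: _GraphFlowSolver, mass_floor: float,
                  threads: int = 1) -> np.ndarray:
    if mass_floor > 0:
        D = np.apply_along_axis(truncate_distribution, 1, D, mass_floor)
    if threads > 1:
        # one solver per worker: the warm HiGHS model is not thread-safe
        from joblib import Parallel, delayed

        _, ei_all, ej_all, _, w_all = network.edge_arrays()
        chunks = np.array_split(np.arange(len(ei)), threads)
        solvers = [_GraphFlowSolver(D.shape[0], ei_all, ej_all, w_all)
                   for _ in chunks]

        def _chunk(idx, solver):
            return [_w1_dispatch(D[ei[k]] - D[ej[k]], network.d, solver)
                    for k in idx]

        parts = Parallel(n_jobs=threads, backend="threading")(
            delayed(_chunk)(idx, solver) for idx, solver in zip(chunks, solvers)
        )
        w1s = [v for part in parts for v in part]
    else:
        w1s = [_w1_dispatch(D[i] - D[j], network.d, flow) for i, j in zip(ei, ej)]
    return 1.0 - np.maximum(w1s, 0.0) / denom


def curvature_trace(
    network: CorrelationNetwork,
    tau_grid: np.ndarray | None = None,
    mass_floor: float = 0.0,
    denominator_mode: str = "shortest_path",
    threads: int = 1,
) -> CurvatureTrace:
    """Curvature of every edge at every grid tau (no early stopping).

    ``denominator_mode`` selects d_ij: ``"shortest_path"`` (default; kappa
    is then <= 1 with kappa -> 0 as tau -> 0) or ``"edge_weight"`` (raw
    transport distance of the edge itself).
    """
    tau_grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, float)
    if (np.diff(tau_grid) <= 0).any():
        raise ValueError("tau grid must be strictly ascending")
    op = build_laplacian(network)
    edges, ei, ej, _, w = network.edge_arrays()
    denom = network.d[ei, ej] if denominator_mode == "shortest_path" else w
    flow = _GraphFlowSolver(len(network.nodes), ei, ej, w)
    kappa = np.empty((len(edges), len(tau_grid)))
    for t, tau in enumerate(tau_grid):
        D = diffuse(op, tau)
        kappa[:, t] = _kappa_column(D, network, ei, ej, denom, flow, mass_floor, threads)
    return CurvatureTrace(edges=edges, tau_grid=tau_grid, kappa=kappa)


def _percentile_reached(column: np.ndarray, percentile: float, threshold: float,
                        mode: str) -> bool:
    if mode == "percentile":
        return float(np.percentile(column, percentile)) >= threshold
    if mode == "fraction":
        return float(np.mean(column >= threshold)) >= percentile / 100.0
    raise ValueError(f"unknown tau_crit mode {mode!r}")


def find_tau_crit(trace: CurvatureTrace, percentile: float = 99.0,
                  threshold: float = 0.75, mode: str = "percentile") -> float:
    """First grid tau at which the upper percentile of edge curvature reaches threshold.

    Default reading: the 99th percentile (linear interpolation) of the kappa
    distribution is >= 0.75.  ``mode="fraction"`` instead requires 99% of
    edges to be >= 0.75.
    """
    for t, tau in enumerate(trace.tau_grid):
        if _percentile_reached(trace.kappa[:, t], percentile, threshold, mode):
            return float(tau)
    raise ValueError(
        "critical-scale condition never met on the tau grid; widen the grid"
    )


def integrate_kappa(trace: CurvatureTrace, tau_crit: float):
    """Time-averaged trapezoidal integral of kappa(tau) up to tau_crit.

    Integration runs on the linear tau axis from the smallest sampled tau to
    tau_crit and is divided by the span, so the result lies between the min
    and max of kappa over that range (|kappa_bar| <= 1).  Returns
    (kappa_bar per edge, raw integral per edge) as arrays in edge order.
    """
    grid = trace.tau_grid
    if tau_crit < grid[0]:
        raise ValueError("tau_crit below the smallest grid point")
    hits = np.nonzero(np.isclose(grid, tau_crit))[0]
    if len(hits) == 0:
        raise ValueError("tau_crit is not a member of the tau grid")
    t = int(hits[0])
    if t == 0:
        return trace.kappa[:, 0].copy(), np.zeros(len(trace.edges))
    raw = np.trapezoid(trace.kappa[:, : t + 1], grid[: t + 1], axis=1)
    return raw / (grid[t] - grid[0]), raw


def critical_curvature(
    network: CorrelationNetwork,
    tau_grid: np.ndarray | None = None,
    percentile: float = 99.0,
    threshold: float = 0.75,
    mode: str = "percentile",
    mass_floor: float = 0.0,
    denominator_mode: str = "shortest_path",
    early_stop: bool = True,
    threads: int = 1,
) -> CurvatureTrace:
    """Sweep tau ascending, locate tau_crit, and summarize per-edge curvature.

    With ``early_stop`` (default) the sweep halts at tau_crit — nothing
    downstream uses kappa beyond it — and the returned trace's grid is
    truncated there.  ``early_stop=False`` evaluates the full grid.
    """
    tau_grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, float)
    if (np.diff(tau_grid) <= 0).any():
        raise ValueError("tau grid must be strictly ascending")
    op = build_laplacian(network)
    edges, ei, ej, _, w = network.edge_arrays()
    denom = network.d[ei, ej] if denominator_mode == "shortest_path" else w
    flow = _GraphFlowSolver(len(network.nodes), ei, ej, w)

    columns = []
    t_crit = None
    for t, tau in enumerate(tau_grid):
        D = diffuse(op, tau)
        col = _kappa_column(D, network, ei, ej, denom, flow, mass_floor, threads)
        columns.append(col)
        if t_crit is None and _percentile_reached(col, percentile, threshold, mode):
            t_crit = t
            if early_stop:
                break
    if t_crit is None:
        raise ValueError(
            "critical-scale condition never met on the tau grid; widen the grid"
        )
    kappa = np.column_stack(columns)
    trace = CurvatureTrace(edges=edges, tau_grid=tau_grid[: kappa.shape[1]], kappa=kappa)
    trace.tau_crit = float(tau_grid[t_crit])
    kappa_bar, raw = integrate_kappa(trace, trace.tau_crit)
    trace.kappa_crit = dict(zip(edges, kappa[:, t_crit]))
    trace.kappa_bar_crit = dict(zip(edges, kappa_bar))
    trace.kappa_bar_raw = dict(zip(edges, raw))
    return trace
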