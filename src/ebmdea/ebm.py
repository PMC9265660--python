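"""Input-oriented (super-efficiency) epsilon-based-measure DEA.

The epsilon-based measure (EBM) blends the radial contraction factor theta
with weighted input slacks:

    min  theta - eps * sum_i w_i * s_i / x_ik
    s.t. sum_{j in R} lambda_j x_ij + s_i = theta * x_ik   (each input i)
         sum_{j in R} lambda_j y_rj >= y_rk                (each good output r)
         sum_{j in R} lambda_j = 1                         (VRS only)
         lambda, s >= 0

eps = 0 recovers the classical radial CCR/BCC model; eps = 1 approaches the
slacks-based measure. Undesirable outputs are by default folded in as extra
input-side rows (they should shrink, like inputs); a weak-disposability mode
instead imposes equality constraints on them.

Super-efficiency removes the evaluated observation from the reference set R,
letting frontier units score above 1. The frontier can be contemporaneous
(same-period observations) or global (every unit-period observation), the
latter making scores comparable across periods.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "TechnologySpec",
    "EfficiencyResult",
    "affinity_epsilon_weights",
    "solve_ebm",
    "score_panel",
    "decompose_efficiency",
]

#: optimality / feasibility tolerance handed to the LP solver
LP_TOL = 1e-9
#: tolerance for score comparisons downstream
SCORE_TOL = 1e-7


@dataclass
class TechnologySpec:
    """Configuration of the DEA technology and the EBM objective."""

    orientation: str = "input"
    rts: str = "crs"                    # "crs" | "vrs"
    frontier: str = "global"            # "global" | "contemporaneous" | indices
    epsilon_x: float = 0.0
    input_weights: np.ndarray | None = None   # over inputs (+ bads if as-input)
    super_efficiency: bool = False
    bad_output_mode: str = "as-input"   # "as-input" | "weak-disposability"

    def __post_init__(self):
        if self.orientation != "input":
            raise ValueError("only input orientation is supported")
        if self.rts not in ("crs", "vrs"):
            raise ValueError(f"unknown rts: {self.rts!r}")
        if not 0.0 <= self.epsilon_x <= 1.0:
            raise ValueError("epsilon_x must lie in [0, 1]")
        if self.bad_output_mode not in ("as-input", "weak-disposability"):
            raise ValueError(f"unknown bad_output_mode: {self.bad_output_mode!r}")
        if self.input_weights is not None:
            w = np.asarray(self.input_weights, dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("input weights must be nonnegative and sum to 1")
            self.input_weights = w


@dataclass
class EfficiencyResult:
    score: float
    theta: float
    slacks: np.ndarray            # per input-side row (inputs [+ bads])
    lambdas: np.ndarray           # intensity weights over the reference set
    ref_index: list               # observation indices forming the reference set
    status: str                   # "optimal" | "infeasible" | "fallback-used"


# ---------------------------------------------------------------------------
# epsilon and weights via the diversity/affinity index
# ---------------------------------------------------------------------------

def _affinity(a, b):
    """Affinity in [0, 1] between two positive profiles (1 = proportional)."""
    c = np.log(np.asarray(a, dtype=float) / np.asarray(b, dtype=float))
    rng = c.max() - c.min()
    if rng < 1e-12:
        return 1.0
    diversity = np.mean(np.abs(c - c.mean())) / rng     # in [0, 1/2]
    return 1.0 - 2.0 * diversity


def affinity_epsilon_weights(input_matrix):
    """Data-driven (epsilon, weights) from the affinity-index eigen procedure.

    Builds the m x m affinity matrix between input columns, takes its largest
    eigenvalue rho and Perron vector:  eps = (m - rho)/(m - 1), weights are the
    normalized principal eigenvector. Perfectly proportional columns give
    rho = m, hence eps = 0 (the radial limit). A single input gives (0, [1]).
    """
    X = np.asarray(input_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 observations, >= 1 input")
    if np.any(X <= 0):
        raise ValueError("affinity index requires strictly positive inputs")
    m = X.shape[1]
    if m == 1:
        return 0.0, np.array([1.0])
    S = np.eye(m)
    for i in range(m):
        for k in range(i + 1, m):
            S[i, k] = S[k, i] = _affinity(X[:, i], X[:, k])
    eigval, eigvec = np.linalg.eigh(S)
    rho = eigval[-1]
    w = np.abs(eigvec[:, -1])
    w = w / w.sum()
    eps = float(np.clip((m - rho) / (m - 1), 0.0, 1.0))
    return eps, w


# ---------------------------------------------------------------------------
# the LP
# ---------------------------------------------------------------------------

def _augment(Xo, Bo, spec):
    """Input-side matrix: inputs plus undesirable outputs when as-input."""
    if spec.bad_output_mode == "as-input" and Bo.shape[1] > 0:
        return np.hstack([Xo, Bo])
    return Xo


def solve_ebm(k, Xo, Yo, Bo, spec: TechnologySpec, ref_index=None):
    """Solve the EBM program for observation ``k`` against a reference set.

    Parameters
    ----------
    k : int
        Row index of the evaluated observation.
    Xo, Yo, Bo : ndarray
        Observation-by-variable matrices (inputs, desirable outputs,
        undesirable outputs). ``Bo`` may have zero columns.
    spec : TechnologySpec
    ref_index : sequence of int, optional
        Observation indices forming the reference set. Defaults to all rows.
        The evaluated observation is removed iff ``spec.super_efficiency``.
    """
    Xo = np.atleast_2d(np.asarray(Xo, dtype=float))
    Yo = np.atleast_2d(np.asarray(Yo, dtype=float))
    Bo = np.asarray(Bo, dtype=float)
    if Bo.ndim != 2:
        Bo = Bo.reshape(Xo.shape[0], -1)

    ref = list(range(Xo.shape[0])) if ref_index is None else list(ref_index)
    if spec.super_efficiency:
        ref = [j for j in ref if j != k]
    if not ref:
        raise ValueError("empty reference set")

    Xin = _augment(Xo, Bo, spec)
    n_in = Xin.shape[1]
    xk = Xin[k]
    yk = Yo[k]

    w = spec.input_weights
    if w is None:
        w = np.full(n_in, 1.0 / n_in)
    if len(w) != n_in:
        raise ValueError(
            f"input_weights has length {len(w)}, expected {n_in} "
            "(inputs plus undesirable outputs in as-input mode)"
        )

    nR = len(ref)
    # variables: [theta, lambda_1..lambda_nR, s_1..s_n_in]
    nvar = 1 + nR + n_in
    c = np.zeros(nvar)
    c[0] = 1.0
    for i in range(n_in):
        if xk[i] > 0:
            c[1 + nR + i] = -spec.epsilon_x * w[i] / xk[i]

    A_eq, b_eq = [], []
    # inputs: sum lambda x + s - theta x_k = 0
    for i in range(n_in):
        row = np.zeros(nvar)
        row[0] = -xk[i]
        row[1:1 + nR] = Xin[ref, i]
        row[1 + nR + i] = 1.0
        A_eq.append(row)
        b_eq.append(0.0)
    # weak-disposability equality on bads
    if spec.bad_output_mode == "weak-disposability" and Bo.shape[1] > 0:
        for f in range(Bo.shape[1]):
            row = np.zeros(nvar)
            row[1:1 + nR] = Bo[ref, f]
            A_eq.append(row)
            b_eq.append(Bo[k, f])
    if spec.rts == "vrs":
        row = np.zeros(nvar)
        row[1:1 + nR] = 1.0
        A_eq.append(row)
        b_eq.append(1.0)

    A_ub, b_ub = [], []
    for r in range(Yo.shape[1]):
        row = np.zeros(nvar)
        row[1:1 + nR] = -Yo[ref, r]
        A_ub.append(row)
        b_ub.append(-yk[r])

    bounds = [(None, None)] + [(0, None)] * (nR + n_in)
    res = linprog(
        c, A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq), b_eq=np.array(b_eq),
        bounds=bounds, method="highs",
        options={"presolve": True, "primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    if res.status == 2:  # infeasible (possible for VRS super-efficiency)
        return EfficiencyResult(
            score=np.nan, theta=np.nan, slacks=np.full(n_in, np.nan),
            lambdas=np.full(nR, np.nan), ref_index=ref, status="infeasible",
        )
    if not res.success:
        raise RuntimeError(f"LP solver failure for observation {k}: {res.message}")
    x = res.x
    return EfficiencyResult(
        score=float(res.fun), theta=float(x[0]),
        slacks=np.maximum(x[1 + nR:], 0.0),
        lambdas=np.maximum(x[1:1 + nR], 0.0),
        ref_index=ref, status="optimal",
    )


def score_panel(data, spec: TechnologySpec, return_details=False):
    """Score every (unit, period) cell of a panel under ``spec``.

    The reference set is all J*T observations (global frontier), the
    same-period observations (contemporaneous), or an explicit index list.
    VRS super-efficiency cells whose program is infeasible fall back to the
    non-super-efficiency score with status "fallback-used".

    Returns a (J x T) DataFrame of scores, plus a parallel dict of
    :class:`EfficiencyResult` keyed by (unit, period) if ``return_details``.
    """
    labels, Xo, Yo, Bo, Zo, Wo, tidx = data.flatten()
    N = len(labels)
    if isinstance(spec.frontier, str):
        if spec.frontier == "global":
            refsets = [None] * N
        elif spec.frontier == "contemporaneous":
            refsets = [np.flatnonzero(tidx == tidx[kk]).tolist() for kk in range(N)]
        else:
            raise ValueError(f"unknown frontier: {spec.frontier!r}")
    else:
        refsets = [list(spec.frontier)] * N

    scores = np.empty((data.n_units, data.n_periods))
    details = {}
    for kk, (j, t) in enumerate(labels):
        try:
            res = solve_ebm(kk, Xo, Yo, Bo, spec, ref_index=refsets[kk])
            if res.status == "infeasible" and spec.super_efficiency:
                res = solve_ebm(kk, Xo, Yo, Bo,
                                replace(spec, super_efficiency=False),
                                ref_index=refsets[kk])
                res.status = "fallback-used"
        except Exception as exc:
            raise RuntimeError(
                f"EBM failed at unit={data.dmu_ids[j]}, year={data.periods[t]}"
            ) from exc
        scores[j, t] = res.score
        details[(data.dmu_ids[j], data.periods[t])] = res

    table = pd.DataFrame(scores, index=data.dmu_ids, columns=data.periods)
    return (table, details) if return_details else table


def decompose_efficiency(cte, pte):
    """Scale efficiency = CRS score / VRS score (CTE = PTE x SE)."""
    cte_a, pte_a = np.asarray(cte, dtype=float), np.asarray(pte, dtype=float)
    if np.any(pte_a <= 0):
        raise ValueError("pure technical efficiency must be positive")
    out = cte_a / pte_a
    if isinstance(cte, pd.DataFrame):
        return pd.DataFrame(out, index=cte.index, columns=cte.columns)
    return out if out.ndim else float(out)
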