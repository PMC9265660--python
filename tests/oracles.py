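"""Independent reference implementations used only to cross-check tests.

The radial DEA oracle uses the *multiplier* (dual) linear program, a
formulation disjoint from the package's envelopment-form implementation;
agreement between the two is guaranteed by LP duality, so any coding error
on either side shows up as a score mismatch.
"""

import numpy as np
from scipy.optimize import linprog


def multiplier_radial_score(k, X, Y, vrs=False, super_eff=False):
    """Input-oriented CCR/BCC efficiency of unit k via the multiplier form.

    max u'y_k (+ w)  s.t.  v'x_k = 1,  u'y_j (+ w) - v'x_j <= 0 for j in R,
    u, v >= 0 (w free under VRS). Returns the optimal value, or None when the
    program is unbounded (the envelopment super-efficiency LP is infeasible).
    """
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    n, m = X.shape
    s = Y.shape[1]
    ref = [j for j in range(n) if not (super_eff and j == k)]
    nw = 1 if vrs else 0
    nvar = s + m + nw

    c = np.zeros(nvar)
    c[:s] = -Y[k]
    if vrs:
        c[-1] = -1.0
    A_eq = np.zeros((1, nvar))
    A_eq[0, s:s + m] = X[k]
    b_eq = [1.0]
    A_ub = np.zeros((len(ref), nvar))
    for row, j in enumerate(ref):
        A_ub[row, :s] = Y[j]
        A_ub[row, s:s + m] = -X[j]
        if vrs:
            A_ub[row, -1] = 1.0
    b_ub = np.zeros(len(ref))
    bounds = [(0, None)] * (s + m) + ([(None, None)] if vrs else [])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 3:     # unbounded dual <-> infeasible envelopment LP
        return None
    assert res.success, res.message
    return -res.fun
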