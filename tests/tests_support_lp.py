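"""Independent LP oracle shared by the test modules: the same child
optimization assembled from scratch with a different variable layout and
solved through scipy's generic interface."""

import numpy as np
from scipy.optimize import linprog


def oracle_objective(problem) -> float:
    X = problem.parent_samples
    n, P = X.shape
    active = problem.child_samples >= problem.delta
    inact = np.flatnonzero(~active)
    L = len(inact)
    xbar = X.mean(axis=0)
    nv = 2 * P + 1 + L
    c = np.zeros(nv)
    for j in range(P):
        c[2 * j] = xbar[j]
        c[2 * j + 1] = xbar[j]
    c[2 * P] = 1.0 / problem.upsilon
    c[2 * P + 1 :] = 1.0 / problem.lam
    A, b = [], []
    for m in np.flatnonzero(active):
        row = np.zeros(nv)
        for j in range(P):
            row[2 * j] = -X[m, j]
            row[2 * j + 1] = X[m, j]
        row[2 * P] = -1.0
        A.append(row)
        b.append(-problem.delta)
    for k, m in enumerate(inact):
        row = np.zeros(nv)
        for j in range(P):
            row[2 * j] = X[m, j]
            row[2 * j + 1] = -X[m, j]
        row[2 * P] = 1.0
        row[2 * P + 1 + k] = -1.0
        A.append(row)
        b.append(0.0)
    res = linprog(
        c,
        A_ub=np.array(A) if A else None,
        b_ub=np.array(b) if b else None,
        bounds=[(0, None)] * nv,
        method="highs",
    )
    assert res.success
    return float(res.fun)
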