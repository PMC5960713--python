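"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately literal implementation — explicit loops,
explicit deletions, closed forms, or a generic QP solver — kept separate
from the code paths it checks.
"""

import numpy as np
from scipy import optimize


def pearson(a, b):
    """Definitional Pearson correlation of two 1-D vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a0 = a - a.mean()
    b0 = b - b.mean()
    return float((a0 @ b0) / np.sqrt((a0 @ a0) * (b0 @ b0)))


def brute_low_order(x):
    """Pairwise-loop correlation matrix of time-series columns."""
    r = x.shape[1]
    out = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            out[i, j] = out[j, i] = pearson(x[:, i], x[:, j])
    return out


def brute_high_order(c):
    """One correlation-of-correlations step, literally deleting the
    entries at positions i and j from both rows before correlating."""
    r = c.shape[0]
    out = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            a = np.delete(c[i], [i, j])
            b = np.delete(c[j], [i, j])
            out[i, j] = out[j, i] = pearson(a, b)
    return out


def soft_threshold(z, lam):
    return np.sign(z) * max(abs(z) - lam, 0.0)


def lasso_kkt_violation(X, k, w, lam):
    """Worst violation of the KKT conditions of
    1/2 ||k - Xw||^2 + lam ||w||_1 at w."""
    grad = X.T @ (k - X @ w)
    worst = 0.0
    for j in range(X.shape[1]):
        if abs(w[j]) > 1e-10:
            worst = max(worst, abs(grad[j] - lam * np.sign(w[j])))
        else:
            worst = max(worst, max(abs(grad[j]) - lam, 0.0))
    return worst


def svm_dual_qp(X, y, C):
    """Soft-margin linear-SVM dual solved with a generic QP routine.

    maximise  sum(a) - 1/2 a^T Q a,  Q = (y y^T) * (X X^T)
    s.t.      0 <= a <= C,  a . y = 0

    Returns (alpha, w, b).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    Q = (X @ X.T) * np.outer(y, y)

    def obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(n)

    res = optimize.minimize(
        obj, x0=np.full(n, min(C, 1.0) / 2), jac=grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y,
                      "jac": lambda a: y}],
        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    alpha = res.x
    w = X.T @ (alpha * y)
    on_margin = (alpha > 1e-6) & (alpha < C - 1e-6)
    sv = on_margin if on_margin.any() else alpha > 1e-6
    b = float(np.mean(y[sv] - X[sv] @ w))
    return alpha, w, b


def paired_t(a, b):
    """Textbook two-tailed paired t-test."""
    from scipy import stats

    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    n = d.size
    mean = d.mean()
    s = np.sqrt(np.sum((d - mean) ** 2) / (n - 1))
    t = mean / (s / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return t, p
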