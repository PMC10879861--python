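"""Independent reference implementations used only by the test suite.

These are deliberately written differently from the package code paths they
check: the LASSO oracles use exhaustive support enumeration / projected
gradient / scipy NNLS instead of coordinate descent, the SSIM oracle
evaluates the windowwise formula directly, and the 1-D TV oracle is a
proximal-gradient run on the ROF objective to tight tolerance.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import nnls


def lasso_objective(y, A, c, lam):
    """‖y − Aᵀc‖² + λ‖c‖₁ with A rows as reference spectra."""
    return float(np.sum((y - c @ A) ** 2) + lam * np.sum(np.abs(c)))


def lasso_active_set_oracle(y, A, lam, nonneg=True):
    """Exhaustive enumeration of supports (and signs, if unconstrained).

    For each support solve the KKT equality system and keep the feasible
    candidate with the lowest objective; c = 0 is always a candidate.  Exact
    up to linear-algebra precision for small K.
    """
    k = A.shape[0]
    G = A @ A.T
    b = A @ y
    best_c = np.zeros(k)
    best_obj = lasso_objective(y, A, best_c, lam)
    sign_choices = [(1,)] if nonneg else [(1,), (-1,)]
    for size in range(1, k + 1):
        for supp in itertools.combinations(range(k), size):
            supp = list(supp)
            for signs in itertools.product(*([s for ch in sign_choices for s in ch]
                                             for _ in supp)):
                s = np.array(signs, dtype=float)
                rhs = b[supp] - 0.5 * lam * s
                try:
                    sol = np.linalg.solve(G[np.ix_(supp, supp)], rhs)
                except np.linalg.LinAlgError:
                    continue
                if nonneg:
                    if np.any(sol < 0):
                        continue
                else:
                    if np.any(np.sign(sol) * s < 0):
                        continue
                c = np.zeros(k)
                c[supp] = sol
                obj = lasso_objective(y, A, c, lam)
                if obj < best_obj:
                    best_obj, best_c = obj, c
    return best_c, best_obj


def lasso_projected_gradient_oracle(y, A, lam, nonneg=True, iters=200000, tol=1e-12):
    """Proximal/projected gradient run to tight tolerance."""
    k = A.shape[0]
    G = A @ A.T
    b = A @ y
    L = 2.0 * np.linalg.eigvalsh(G).max()
    step = 1.0 / L
    c = np.zeros(k)
    for _ in range(iters):
        grad = 2.0 * (G @ c - b)
        z = c - step * grad
        if nonneg:
            new = np.maximum(z - step * lam, 0.0)
        else:
            new = np.sign(z) * np.maximum(np.abs(z) - step * lam, 0.0)
        if np.max(np.abs(new - c)) < tol:
            c = new
            break
        c = new
    return c


def nnls_oracle(y, A):
    """λ=0 non-negative least squares via scipy."""
    sol, _ = nnls(A.T, y)
    return sol


def ssim_formula_oracle(a, b, data_range, win=7):
    """Direct windowwise evaluation of the SSIM formula (uniform window).

    Mean over all fully-contained win×win windows of
    ((2 μaμb + C1)(2 cov + C2)) / ((μa²+μb²+C1)(σa²+σb²+C2)),
    with unbiased (N−1) variance/covariance estimates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, w = a.shape
    vals = []
    for i in range(h - win + 1):
        for j in range(w - win + 1):
            pa = a[i:i + win, j:j + win].ravel()
            pb = b[i:i + win, j:j + win].ravel()
            mu_a, mu_b = pa.mean(), pb.mean()
            va = pa.var(ddof=1)
            vb = pb.var(ddof=1)
            cov = np.sum((pa - mu_a) * (pb - mu_b)) / (pa.size - 1)
            num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
            den = (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
            vals.append(num / den)
    return float(np.mean(vals))


def tv1d_objective(u, y, lam):
    return 0.5 * float(np.sum((u - y) ** 2)) + lam * float(np.sum(np.abs(np.diff(u))))


def tv1d_proximal_oracle(y, lam, iters=200000, tol=1e-12):
    """1-D ROF solve by subgradient-free smoothing-free proximal gradient on the dual.

    Dual of min_u ½‖u−y‖² + λ‖Du‖₁ is a box-constrained quadratic in p
    (‖p‖∞ ≤ λ): minimize ½‖Dᵀp‖² − pᵀDy.  Projected gradient to tight
    tolerance, then u = y − Dᵀp.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        return y.copy()
    p = np.zeros(n - 1)

    def Dt(p):
        out = np.zeros(n)
        out[:-1] -= p
        out[1:] += p
        return out

    step = 1.0 / 4.0  # ‖D‖² ≤ 4
    for _ in range(iters):
        grad = np.diff(Dt(p)) - np.diff(y)
        new = np.clip(p - step * grad, -lam, lam)
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    return y - Dt(p)
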