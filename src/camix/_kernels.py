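"""Compiled inner loops for the exhaustive simplex-vertex search.

Everything here works on the Gram matrix ``G = C @ C.T`` of the M cluster
centers, so the cost of a candidate evaluation is independent of the number
of samples J.  For a candidate vertex subset S and an exterior center m the
squared margin-of-error is

    min_{alpha >= 0, sum(alpha) = 1} || c_m - C_S^T alpha ||^2
      = G_mm - 2 alpha^T G_{S,m} + alpha^T G_{S,S} alpha

i.e. a tiny equality-constrained non-negative quadratic program.  The
equality-constrained (affine) solution is obtained from the KKT system via
a Cholesky factorization of ``G_SS``; non-negativity is then enforced by an
active-set iteration with an exhaustive support-enumeration fallback, which
makes every margin exact up to floating-point error.
"""

import numpy as np
from numba import njit

# Tolerances: _FEAS_TOL on simplex weights, _PIV_TOL flags a numerically
# rank-deficient candidate (Gram pivot ~ squared singular value).
_FEAS_TOL = 1e-10
_PIV_TOL = 1e-16
_TIE_TOL = 1e-12
# Gram-form squared distances below this level may be dominated by
# cancellation error; they are recomputed as an explicit residual norm in
# center space, which is cancellation-free at zero.
_DUST2 = 1e-12


@njit(cache=True)
def _direct_d2(C, idx, n, alpha, m):
    """Stable ||c_m - sum_a alpha_a c_idx[a]||^2 in center space."""
    J = C.shape[1]
    d2 = 0.0
    for j in range(J):
        r = C[m, j]
        for a in range(n):
            r -= alpha[a] * C[idx[a], j]
        d2 += r * r
    return d2


@njit(cache=True)
def _chol(Gs, L):
    """In-place Cholesky of Gs into lower-triangular L; returns min pivot."""
    n = Gs.shape[0]
    minpiv = 1e300
    for i in range(n):
        s = Gs[i, i]
        for k in range(i):
            s -= L[i, k] * L[i, k]
        if s < minpiv:
            minpiv = s
        if s <= 0.0:
            return minpiv
        L[i, i] = np.sqrt(s)
        for j in range(i + 1, n):
            t = Gs[j, i]
            for k in range(i):
                t -= L[j, k] * L[i, k]
            L[j, i] = t / L[i, i]
    return minpiv


@njit(cache=True)
def _solve_chol(L, b, x, n):
    """Solve (L L^T) x = b for the leading n x n block."""
    for i in range(n):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(n - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, n):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]


@njit(cache=True)
def _affine_solve(G, idx, n, m, L, buf, alpha):
    """KKT solve: project center m onto the affine hull of centers idx[:n].

    Returns (d2, mu, ok).  ``alpha[:n]`` receives the affine weights
    (sum = 1, possibly negative); d2 is the squared affine distance.
    ok=False flags a numerically singular support.
    """
    for a in range(n):
        for b in range(n):
            L[a, b] = 0.0
    Gs = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            Gs[a, b] = G[idx[a], idx[b]]
    piv = _chol(Gs, L)
    if piv < _PIV_TOL:
        return 0.0, 0.0, False
    for a in range(n):
        buf[a] = 1.0
    u = np.empty(n)
    _solve_chol(L, buf, u, n)          # u = Gs^-1 1
    s1 = 0.0
    for a in range(n):
        s1 += u[a]
    if s1 <= 0.0:
        return 0.0, 0.0, False
    for a in range(n):
        buf[a] = G[idx[a], m]
    v = np.empty(n)
    _solve_chol(L, buf, v, n)          # v = Gs^-1 b
    tv = 0.0
    for a in range(n):
        tv += v[a]
    mu = (tv - 1.0) / s1
    d2 = G[m, m] - mu
    for a in range(n):
        alpha[a] = v[a] - mu * u[a]
        d2 -= alpha[a] * buf[a]
    if d2 < 0.0:
        d2 = 0.0
    return d2, mu, True


@njit(cache=True)
def _margin2_enum(G, C, c, K, m):
    """Exact squared margin by exhaustive support enumeration (fallback)."""
    best = 1e300
    idx = np.empty(K, dtype=np.int64)
    L = np.zeros((K, K))
    buf = np.empty(K)
    alpha = np.empty(K)
    for mask in range(1, 1 << K):
        n = 0
        for k in range(K):
            if mask & (1 << k):
                idx[n] = c[k]
                n += 1
        if n == 1:
            d2 = G[m, m] - 2.0 * G[idx[0], m] + G[idx[0], idx[0]]
            if d2 < _DUST2:
                alpha[0] = 1.0
                d2 = _direct_d2(C, idx, 1, alpha, m)
            if d2 < best:
                best = d2
            continue
        d2, mu, ok = _affine_solve(G, idx, n, m, L, buf, alpha)
        if not ok:
            continue
        feas = True
        for a in range(n):
            if alpha[a] < -_FEAS_TOL:
                feas = False
                break
        if feas:
            if d2 < _DUST2:
                d2 = _direct_d2(C, idx, n, alpha, m)
            if d2 < best:
                best = d2
    if best >= 1e300:
        best = 0.0
    return best


@njit(cache=True)
def _margin2(G, C, c, K, m, L, buf, alpha, idx, act):
    """Exact squared margin of center m w.r.t. hull of centers c[:K].

    Active-set iteration (drop negative weights, re-solve, verify dual
    feasibility); falls back to support enumeration when the quick path
    cannot certify optimality.
    """
    for k in range(K):
        act[k] = c[k]
    n = K
    for _ in range(2 * K):
        d2, mu, ok = _affine_solve(G, act, n, m, L, buf, alpha)
        if not ok:
            return _margin2_enum(G, C, c, K, m)
        neg = False
        nn = 0
        for a in range(n):
            if alpha[a] < -_FEAS_TOL:
                neg = True
            else:
                idx[nn] = act[a]
                nn += 1
        if not neg:
            # dual feasibility for dropped vertices:
            # lambda_k = sum_t alpha_t G[k,t] - G[k,m] - mu >= 0
            opt = True
            for k in range(K):
                j = c[k]
                inT = False
                for a in range(n):
                    if act[a] == j:
                        inT = True
                        break
                if inT:
                    continue
                lam = -G[j, m] + mu
                for a in range(n):
                    lam += alpha[a] * G[j, act[a]]
                if lam < -1e-9:
                    opt = False
                    break
            if opt:
                if d2 < _DUST2:
                    d2 = _direct_d2(C, act, n, alpha, m)
                return d2
            return _margin2_enum(G, C, c, K, m)
        if nn == 0:
            return _margin2_enum(G, C, c, K, m)
        if nn == 1:
            t = idx[0]
            d2 = G[m, m] - 2.0 * G[t, m] + G[t, t]
            if d2 < _DUST2:
                alpha[0] = 1.0
                d2 = _direct_d2(C, idx, 1, alpha, m)
            # single-point support: certify via dual check against others
            opt = True
            for k in range(K):
                j = c[k]
                if j == t:
                    continue
                lam = G[j, t] - G[j, m] - (G[t, t] - G[t, m])
                if lam < -1e-9:
                    opt = False
                    break
            if opt:
                return d2
            return _margin2_enum(G, C, c, K, m)
        for a in range(nn):
            act[a] = idx[a]
        n = nn
    return _margin2_enum(G, C, c, K, m)


@njit(cache=True)
def eval_subset(G, C, c, K, order, cutoff):
    """Sum of exterior margins for one candidate subset.

    Walks exterior centers in the supplied order, accumulating exact
    margins; aborts with +inf as soon as the running sum reaches
    ``cutoff``.  Returns -1.0 for a rank-deficient candidate.
    """
    M = G.shape[0]
    L = np.zeros((K, K))
    buf = np.empty(K)
    alpha = np.empty(K)
    idx = np.empty(K, dtype=np.int64)
    act = np.empty(K, dtype=np.int64)
    # rank / conditioning check on the candidate Gram block
    Gs = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            Gs[a, b] = G[c[a], c[b]]
    piv = _chol(Gs, L)
    if piv < _PIV_TOL:
        return -1.0
    total = 0.0
    for mi in range(M):
        m = order[mi]
        skip = False
        for a in range(K):
            if c[a] == m:
                skip = True
                break
        if skip:
            continue
        d2, mu, ok = _affine_solve(G, c, K, m, L, buf, alpha)
        if not ok:
            return -1.0
        feas = True
        for a in range(K):
            if alpha[a] < -_FEAS_TOL:
                feas = False
                break
        if feas:
            if d2 < _DUST2:
                d2 = _direct_d2(C, c, K, alpha, m)
            total += np.sqrt(d2)
        else:
            total += np.sqrt(_margin2(G, C, c, K, m, L, buf, alpha, idx, act))
        if total >= cutoff:
            return 1e300
    return total


@njit(cache=True)
def exhaustive_search(G, C, K, order, init_subset, budget):
    """Enumerate all C(M, K) vertex subsets, returning the minimizer.

    Candidates are visited in lexicographic index order; a candidate
    replaces the incumbent only when its exterior margin sum is smaller
    by more than the tie tolerance, so the reported subset is the
    lexicographically smallest minimizer.  ``init_subset`` (e.g. from a
    farthest-point heuristic) only primes the pruning cutoff — it is
    re-visited during enumeration.

    Returns (best_subset, best_sum, n_evaluated); n_evaluated is negative
    when the subset budget was exhausted before completing enumeration.
    """
    M = G.shape[0]
    best_c = init_subset.copy()
    best_sum = eval_subset(G, C, init_subset, K, order, 1e300)
    if best_sum < 0.0:
        best_sum = 1e300
    c = np.empty(K, dtype=np.int64)
    for k in range(K):
        c[k] = k
    n_eval = 0
    while True:
        n_eval += 1
        if n_eval > budget:
            return best_c, best_sum, -n_eval
        s = eval_subset(G, C, c, K, order, best_sum + 2.0 * _TIE_TOL)
        if s >= 0.0 and s < best_sum - _TIE_TOL:
            best_sum = s
            for k in range(K):
                best_c[k] = c[k]
        elif s >= 0.0 and s <= best_sum + _TIE_TOL:
            # tie: keep lexicographically smaller subset
            smaller = False
            for k in range(K):
                if c[k] != best_c[k]:
                    smaller = c[k] < best_c[k]
                    break
            if smaller and s < best_sum + _TIE_TOL:
                for k in range(K):
                    best_c[k] = c[k]
                if s < best_sum:
                    best_sum = s
        i = K - 1
        while i >= 0 and c[i] == M - K + i:
            i -= 1
        if i < 0:
            break
        c[i] += 1
        for j in range(i + 1, K):
            c[j] = c[j - 1] + 1
    return best_c, best_sum, n_eval


@njit(cache=True)
def margins_to_subset(G, C, c, K):
    """Exact margin of every center w.r.t. hull of centers c[:K]."""
    M = G.shape[0]
    out = np.zeros(M)
    L = np.zeros((K, K))
    buf = np.empty(K)
    alpha = np.empty(K)
    idx = np.empty(K, dtype=np.int64)
    act = np.empty(K, dtype=np.int64)
    for m in range(M):
        inS = False
        for a in range(K):
            if c[a] == m:
                inS = True
                break
        if inS:
            continue
        out[m] = np.sqrt(_margin2(G, C, c, K, m, L, buf, alpha, idx, act))
    return out
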