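"""Linear maximum-margin classifier (C-SVC dual, hinge loss, fixed C=1).

The decoding analyses need hundreds of thousands of SVM fits on very small
problems (tens of trials, tens of voxels): every searchlight sphere is
scored by leave-one-out cross-validation inside every outer fold. General
purpose SVM wrappers carry per-call overhead in the millisecond range,
which makes the faithful nested procedure impractical, so the dual problem

    min 0.5 a' Q a - e' a   s.t.  0 <= a_i <= C,  y' a = 0,
    Q_ij = y_i y_j <x_i, x_j>

is solved here by a compact SMO with second-order working-set selection
and the standard stopping rule (KKT violation <= 1e-3), i.e. the same
optimisation problem and tolerance as libsvm. Leave-one-out and
leave-two-out sweeps warm-start each subproblem from the full-data
solution (removing a trial barely moves the optimum), which is what makes
exhaustive nested cross-validation affordable. Unit tests pin decision
values and predictions against sklearn's libsvm binding.

Labels are +/-1; the decision function is f(x) = sum_t a_t y_t <x, x_t> - rho
and a decision value of exactly 0 predicts the negative class, so with the
conventional sorted-class encoding (first class -> -1) ties deterministically
go to the first class in label sort order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "C_DEFAULT",
    "solve_svc",
    "decision_values",
    "loo_correct",
    "pairwise_loo_correct",
]

C_DEFAULT = 1.0
_EPS = 1e-3
_TAU = 1e-12
_MAX_ITER = 200_000


@njit(cache=True)
def _reconstruct_G(Q, alpha, G, active, m):  # pragma: no cover
    """Recompute the gradient for shrunk-out entries [active, m)."""
    for b in range(active, m):
        g = -1.0
        Qb = Q[b]
        for a in range(m):
            if alpha[a] > 0.0:
                g += Qb[a] * alpha[a]
        G[b] = g


@njit(cache=True)
def _swap_state(Q, y, alpha, G, perm, a, b, m):  # pragma: no cover
    if a == b:
        return
    y[a], y[b] = y[b], y[a]
    alpha[a], alpha[b] = alpha[b], alpha[a]
    G[a], G[b] = G[b], G[a]
    perm[a], perm[b] = perm[b], perm[a]
    for k in range(m):
        Q[a, k], Q[b, k] = Q[b, k], Q[a, k]
    for k in range(m):
        Q[k, a], Q[k, b] = Q[k, b], Q[k, a]


@njit(cache=True)
def _smo_q(Q, y, alpha, G, C, eps, max_iter):  # pragma: no cover
    """SMO with second-order working-set selection on Q_ij = y_i y_j K_ij.

    ``alpha`` and ``G`` (G = Q a - e) are updated in place; returns rho.
    Bound variables that strongly satisfy their KKT conditions are shrunk
    out of the selection loops (libsvm's shrinking heuristic, realised by
    swapping them to the tail); the gradient is reconstructed and the full
    problem re-checked before convergence is declared. NOTE: Q and y are
    permuted in place while shrinking is active; alpha and G are returned
    in the original order.
    """
    m = Q.shape[0]
    perm = np.arange(m)
    active = m
    counter = min(m, 1000)
    unshrunk = False
    it = 0
    while it < max_iter:
        it += 1
        counter -= 1
        if counter == 0:
            counter = min(m, 1000)
            # shrinking pass: thresholds over the active set
            s_max1 = -1e300
            s_max2 = -1e300
            for a in range(active):
                if y[a] > 0:
                    if alpha[a] < C and -G[a] > s_max1:
                        s_max1 = -G[a]
                    if alpha[a] > 0 and G[a] > s_max2:
                        s_max2 = G[a]
                else:
                    if alpha[a] < C and -G[a] > s_max2:
                        s_max2 = -G[a]
                    if alpha[a] > 0 and G[a] > s_max1:
                        s_max1 = G[a]
            if (not unshrunk) and s_max1 + s_max2 <= eps * 10:
                unshrunk = True
                _reconstruct_G(Q, alpha, G, active, m)
                active = m
            a = 0
            while a < active:
                shrink = False
                if alpha[a] >= C:
                    if y[a] > 0:
                        shrink = -G[a] > s_max1
                    else:
                        shrink = -G[a] > s_max2
                elif alpha[a] <= 0.0:
                    if y[a] > 0:
                        shrink = G[a] > s_max2
                    else:
                        shrink = G[a] > s_max1
                if shrink:
                    active -= 1
                    _swap_state(Q, y, alpha, G, perm, a, active, m)
                else:
                    a += 1
        i = -1
        g_max = -1e300
        for a in range(active):
            if (y[a] > 0 and alpha[a] < C) or (y[a] < 0 and alpha[a] > 0):
                v = -y[a] * G[a]
                if v >= g_max:
                    g_max = v
                    i = a
        j = -1
        g_max2 = -1e300
        obj_min = 1e300
        if i >= 0:
            Qii = Q[i, i]
            yi = y[i]
            Qi = Q[i]
            for a in range(active):
                if (y[a] < 0 and alpha[a] < C) or (y[a] > 0 and alpha[a] > 0):
                    v = y[a] * G[a]
                    if v >= g_max2:
                        g_max2 = v
                    b = g_max + v
                    if b > 0:
                        # curvature along the feasible pair direction
                        q = Qii + Q[a, a] - 2.0 * yi * y[a] * Qi[a]
                        if q <= 0:
                            q = _TAU
                        obj = -(b * b) / q
                        if obj <= obj_min:
                            obj_min = obj
                            j = a
        if i < 0 or j < 0 or g_max + g_max2 < eps:
            if active == m:
                break
            # converged on the shrunk set: restore the full problem and
            # re-run selection on it before any further shrinking, so a
            # fully optimal problem exits rather than re-shrinking forever
            _reconstruct_G(Q, alpha, G, active, m)
            active = m
            counter = min(m, 1000)
            continue
        old_ai = alpha[i]
        old_aj = alpha[j]
        q = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        if q <= 0:
            q = _TAU
        if y[i] != y[j]:
            delta = (-G[i] - G[j]) / q
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = diff
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
            if diff > 0:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            delta = (G[i] - G[j]) / q
            s = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if s > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = s - C
            else:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = s
            if s > C:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = s - C
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = s
        dai = alpha[i] - old_ai
        daj = alpha[j] - old_aj
        Qi = Q[i]
        Qj = Q[j]
        for a in range(active):
            G[a] += Qi[a] * dai + Qj[a] * daj
    if active < m:  # max_iter exhausted while shrunk
        _reconstruct_G(Q, alpha, G, active, m)
    # undo the shrinking permutation so all in-place arrays are restored
    # to the caller's order (cheap no-op when nothing was ever shrunk)
    permuted = False
    for a in range(m):
        if perm[a] != a:
            permuted = True
            break
    if permuted:
        inv = np.empty(m, dtype=np.int64)
        for a in range(m):
            inv[perm[a]] = a
        alpha_out = np.empty(m)
        G_out = np.empty(m)
        y_out = np.empty(m, dtype=np.int8)
        for a in range(m):
            alpha_out[a] = alpha[inv[a]]
            G_out[a] = G[inv[a]]
            y_out[a] = y[inv[a]]
        alpha[:] = alpha_out
        G[:] = G_out
        y[:] = y_out
        Q_out = np.empty((m, m))
        for a in range(m):
            for b in range(m):
                Q_out[a, b] = Q[inv[a], inv[b]]
        Q[:, :] = Q_out
    # rho from the KKT conditions
    n_free = 0
    sum_free = 0.0
    ub = 1e300
    lb = -1e300
    for a in range(m):
        yg = y[a] * G[a]
        if alpha[a] <= 0.0:
            if y[a] > 0:
                ub = min(ub, yg)
            else:
                lb = max(lb, yg)
        elif alpha[a] >= C:
            if y[a] > 0:
                lb = max(lb, yg)
            else:
                ub = min(ub, yg)
        else:
            n_free += 1
            sum_free += yg
    if n_free > 0:
        rho = sum_free / n_free
    else:
        rho = 0.5 * (ub + lb)
    return rho


@njit(cache=True)
def _delete_rowcol(Q, d, out):  # pragma: no cover
    """Copy Q without row/column d into ``out`` (contiguous blocks)."""
    n = Q.shape[0]
    out[:d, :d] = Q[:d, :d]
    out[:d, d:] = Q[:d, d + 1:]
    out[d:, :d] = Q[d + 1:, :d]
    out[d:, d:] = Q[d + 1:, d + 1:]


@njit(cache=True)
def _delete_elem(v, d, out):  # pragma: no cover
    out[:d] = v[:d]
    out[d:] = v[d + 1:]


@njit(cache=True)
def _repair(Qa, ya, alpha, G, r, C):  # pragma: no cover
    """Restore y'alpha = 0 after dropping trials carrying signed mass r.

    Moves mass onto variables with slack, free variables first; returns the
    residual (0.0 when fully repaired).
    """
    m = alpha.shape[0]
    while r != 0.0:
        # pick the in-room variable whose KKT gradient most favours the move:
        # for r > 0 any beneficial move has benefit -G_a, for r < 0 it is +G_a
        best = -1
        best_benefit = -1e300
        best_room = 0.0
        for a in range(m):
            if r > 0:
                room = (C - alpha[a]) if ya[a] > 0 else alpha[a]
                benefit = -G[a]
            else:
                room = alpha[a] if ya[a] > 0 else (C - alpha[a])
                benefit = G[a]
            if room > 0.0 and benefit > best_benefit:
                best = a
                best_benefit = benefit
                best_room = room
        if best < 0:
            return r
        step = min(best_room, abs(r))
        signed = step if r > 0 else -step
        dalpha = signed if ya[best] > 0 else -signed
        alpha[best] += dalpha
        r -= signed
        Qa_row = Qa[best]
        for b in range(m):
            G[b] += Qa_row[b] * dalpha
    return 0.0


@njit(cache=True)
def _loo_correct(K, y, C, eps, max_iter):  # pragma: no cover
    n = K.shape[0]
    Q = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            Q[i, j] = y[i] * y[j] * K[i, j]
    out = np.zeros(n, dtype=np.uint8)
    alpha0 = np.zeros(n)
    G0 = np.full(n, -1.0)
    _smo_q(Q, y, alpha0, G0, C, eps, max_iter)
    Qa = np.empty((n - 1, n - 1))
    ya = np.empty(n - 1, dtype=np.int8)
    alpha = np.empty(n - 1)
    G = np.empty(n - 1)
    qt = np.empty(n - 1)
    for t in range(n):
        _delete_rowcol(Q, t, Qa)
        _delete_elem(y, t, ya)
        _delete_elem(alpha0, t, alpha)
        _delete_elem(G0, t, G)
        _delete_elem(Q[t], t, qt)  # Q[t, active]
        # remove trial t's contribution from the gradient
        for a in range(n - 1):
            G[a] -= qt[a] * alpha0[t]
        resid = _repair(Qa, ya, alpha, G, y[t] * alpha0[t], C)
        if resid != 0.0:
            alpha[:] = 0.0
            G[:] = -1.0
        rho = _smo_q(Qa, ya, alpha, G, C, eps, max_iter)
        # y_t * f(x_t) = sum_a alpha_a Q[t, act_a] - y_t * rho
        yf = -y[t] * rho
        for a in range(n - 1):
            yf += alpha[a] * qt[a]
        if yf > 0:
            out[t] = 1
        elif yf == 0.0 and y[t] < 0:
            out[t] = 1  # decision value 0 predicts the first (negative) class
    return out


@njit(cache=True)
def _pairwise_loo_correct(K, y, C, eps, max_iter, want):  # pragma: no cover
    """want[j] selects which trials are ever predicted (inner-fold subsampling);
    pair (i, j) is fitted only if at least one endpoint is wanted."""
    n = K.shape[0]
    Q = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            Q[i, j] = y[i] * y[j] * K[i, j]
    out = np.zeros((n, n), dtype=np.uint8)
    alpha0 = np.zeros(n)
    G0 = np.full(n, -1.0)
    _smo_q(Q, y, alpha0, G0, C, eps, max_iter)
    Qi = np.empty((n - 1, n - 1))
    yi_arr = np.empty(n - 1, dtype=np.int8)
    alpha_i = np.empty(n - 1)
    G_i = np.empty(n - 1)
    Qa = np.empty((n - 2, n - 2))
    ya = np.empty(n - 2, dtype=np.int8)
    alpha = np.empty(n - 2)
    G = np.empty(n - 2)
    qrow_i = np.empty(n - 1)  # Q[i, active-of-i]
    qi = np.empty(n - 2)      # Q[i, active-of-ij]
    qj = np.empty(n - 2)      # Q[j, active-of-ij]
    for i in range(n):
        # state with trial i removed, shared across all j > i
        _delete_rowcol(Q, i, Qi)
        _delete_elem(y, i, yi_arr)
        _delete_elem(alpha0, i, alpha_i)
        _delete_elem(G0, i, G_i)
        _delete_elem(Q[i], i, qrow_i)
        for a in range(n - 1):
            G_i[a] -= qrow_i[a] * alpha0[i]
        for j in range(i + 1, n):
            if not (want[i] or want[j]):
                continue
            j2 = j - 1  # position of trial j within active-of-i
            _delete_rowcol(Qi, j2, Qa)
            _delete_elem(yi_arr, j2, ya)
            _delete_elem(alpha_i, j2, alpha)
            _delete_elem(G_i, j2, G)
            _delete_elem(qrow_i, j2, qi)
            _delete_elem(Qi[j2], j2, qj)
            aj = alpha_i[j2]
            for a in range(n - 2):
                G[a] -= qj[a] * aj
            r = y[i] * alpha0[i] + y[j] * aj
            resid = _repair(Qa, ya, alpha, G, r, C)
            if resid != 0.0:
                alpha[:] = 0.0
                G[:] = -1.0
            rho = _smo_q(Qa, ya, alpha, G, C, eps, max_iter)
            yfi = -y[i] * rho
            yfj = -y[j] * rho
            for a in range(n - 2):
                yfi += alpha[a] * qi[a]
                yfj += alpha[a] * qj[a]
            # out[i, j]: prediction of trial j by the model that saw
            # neither i nor j (and symmetrically for out[j, i])
            out[i, j] = 1 if (yfj > 0 or (yfj == 0.0 and y[j] < 0)) else 0
            out[j, i] = 1 if (yfi > 0 or (yfi == 0.0 and y[i] < 0)) else 0
    return out


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be +/-1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y.astype(np.int8)


def solve_svc(K: np.ndarray, y: np.ndarray, C: float = C_DEFAULT,
              eps: float = _EPS, max_iter: int = _MAX_ITER):
    """Fit the C-SVC dual on a precomputed linear kernel.

    Returns ``(alpha, rho)``; see module docstring for the decision rule.
    """
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = _check_labels(y)
    Q = (y[:, None] * y[None, :]).astype(float) * K
    alpha = np.zeros(K.shape[0])
    G = np.full(K.shape[0], -1.0)
    rho = _smo_q(np.ascontiguousarray(Q), y, alpha, G, C, eps, max_iter)
    return alpha, rho


def decision_values(K_test_train: np.ndarray, y_train: np.ndarray,
                    alpha: np.ndarray, rho: float) -> np.ndarray:
    """Decision values for test points given their kernel against training."""
    coef = alpha * np.asarray(y_train, dtype=float)
    return np.asarray(K_test_train, dtype=float) @ coef - rho


def loo_correct(K: np.ndarray, y: np.ndarray, C: float = C_DEFAULT) -> np.ndarray:
    """Leave-one-out correctness vector: entry t is 1 iff the classifier
    trained on all other trials predicts trial t's label."""
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = _check_labels(y)
    return _loo_correct(K, y, C, _EPS, _MAX_ITER)


def pairwise_loo_correct(K: np.ndarray, y: np.ndarray,
                         C: float = C_DEFAULT,
                         predict_subset: np.ndarray | None = None) -> np.ndarray:
    """Leave-two-out correctness table.

    ``out[i, j]`` (i != j) is 1 iff the classifier trained on all trials
    except {i, j} correctly predicts trial j. Row i therefore contains the
    inner leave-one-out results of the outer fold that holds out trial i.
    The diagonal is unused (0).

    ``predict_subset`` (trial ids) restricts which columns are computed —
    the inner-fold subsampling speed knob; entries outside the subset stay
    0 and must not be read.
    """
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = _check_labels(y)
    want = np.ones(len(y), dtype=np.bool_)
    if predict_subset is not None:
        want = np.zeros(len(y), dtype=np.bool_)
        want[np.asarray(predict_subset, dtype=int)] = True
    return _pairwise_loo_correct(K, y, C, _EPS, _MAX_ITER, want)
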