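"""Independent reference implementations used only to check the package.

Everything here is deliberately written in a different style from the
library code (explicit per-step/ per-unit recursions, classical NIPALS
normalization) so the comparisons are meaningful.
"""

import numpy as np


def nipals_pls1_reference(X, y, n_components):
    """Classical NIPALS for a univariate response, normalized weight vectors.

    Returns a ``predict(X_new)`` closure.  Normalizing w (the textbook
    convention) rescales w, t, q per component but leaves the fitted
    subspace — and therefore all predictions — unchanged, which makes this
    a genuinely independent check of the unnormalized stepwise recursion.
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float).ravel()
    Ws, Ps, Qs = [], [], []
    Xd, yd = X.copy(), y.copy()
    first_p = first_q = None
    for _ in range(n_components):
        w = Xd.T @ yd
        w = w / np.linalg.norm(w)
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        q = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        Ws.append(w)
        Ps.append(p)
        Qs.append(q)
        if first_p is None:
            first_p, first_q = p, q
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    Q = np.array(Qs)
    beta = W @ np.linalg.solve(P.T @ W, Q)
    beta0 = first_q - first_p @ beta

    def predict(X_new):
        return np.atleast_2d(np.asarray(X_new, float)) @ beta + beta0

    return predict


def lstm_direct_recursion(X, W_c, W_u, W_f, W_o, variant="paper", bias=False):
    """Step-by-step scalar evaluation of the stack-cell equations.

    X is (T, d); weight matrices are (u, u + d [+1]).  Implemented with
    explicit python loops over time and units.
    """
    T, d = X.shape
    u = W_c.shape[0]
    y = np.zeros(u)
    C = np.zeros(u)
    outputs = np.zeros((T, u))
    for t in range(T):
        z = np.concatenate([y, X[t], [1.0] if bias else []])
        C_new = np.zeros(u)
        y_new = np.zeros(u)
        for i in range(u):
            a_c = sum(W_c[i, j] * z[j] for j in range(len(z)))
            a_u = sum(W_u[i, j] * z[j] for j in range(len(z)))
            a_f = sum(W_f[i, j] * z[j] for j in range(len(z)))
            a_o = sum(W_o[i, j] * z[j] for j in range(len(z)))
            c_til = np.tanh(a_c)
            g_u = 1.0 / (1.0 + np.exp(-a_u))
            g_f = 1.0 / (1.0 + np.exp(-a_f))
            g_o = 1.0 / (1.0 + np.exp(-a_o))
            C_new[i] = g_u * c_til + g_f * C[i]
            if variant == "standard":
                y_new[i] = g_o * np.tanh(C_new[i])
            else:
                y_new[i] = g_o * C_new[i]
        C, y = C_new, y_new
        outputs[t] = y
    return outputs


def press_bruteforce(X, y, n_components, fold_indices, fit_fn):
    """PRESS by literally refitting on each training split and summing
    squared out-of-fold errors; ``fit_fn(X, y, l)`` must return an object
    with a ``predict`` method."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    press = 0.0
    for test_idx in fold_indices:
        mask = np.ones(n, bool)
        mask[test_idx] = False
        res = fit_fn(X[mask], y[mask], n_components)
        pred = res.predict(X[test_idx])
        press += float(np.sum((y[test_idx] - pred) ** 2))
    return press
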