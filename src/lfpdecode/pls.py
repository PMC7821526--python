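"""PLS-1 regression with PRESS/Wold model-order selection.

Partial least squares for a univariate response, written exactly as the
classical stepwise recursion: at each step the loading weight
``w = X'y`` (the covariance-maximizing direction), score ``t = Xw``,
loadings ``p = X't / t't`` and ``q = y't / t't``, then deflation
``X <- X - t p'``, ``y <- y - t q``.  After ``l`` steps the regression
vector is ``beta = W (P'W)^{-1} Q`` with intercept ``beta0 = q1 - p1' beta``.

Neither X nor y is centered inside the recursion (features are expected to
arrive z-scored from the preprocessing stage; a pre-centering flag is
available).  With all ``min(n, m)`` components on a full-column-rank X the
fit coincides with ordinary least squares of y on X.

The number of latent components is chosen with Wold's criterion: PRESS(l)
is the out-of-fold squared prediction error from a seeded 10-fold
cross-validation over the training data, and component addition stops at
the first l whose ratio ``PRESS(l+1)/PRESS(l)`` reaches 0.9 — i.e. when an
extra component no longer buys a meaningful error reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

__all__ = [
    "PLS1Model",
    "PLS1Results",
    "WoldSelection",
    "pls1_fit",
    "pls1_predict",
    "compute_press",
    "select_components_wold",
]


@dataclass
class WoldSelection:
    """PRESS curve and the component count picked from it."""

    press: np.ndarray  # PRESS(l) for l = 1..max_l (index 0 -> l=1)
    ratios: np.ndarray  # press[l+1]/press[l]
    selected_l: int
    threshold: float
    flagged: bool = False  # True when the ratio never reached the threshold

    def __post_init__(self) -> None:
        if self.selected_l < 1:
            raise ValueError("selected_l must be >= 1")


def _wold_from_press(press: np.ndarray, threshold: float = 0.9) -> WoldSelection:
    """Apply the stopping rule to a precomputed PRESS sequence."""
    press = np.asarray(press, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = press[1:] / press[:-1]
    for i, p in enumerate(press[:-1]):
        if p == 0.0:  # perfect prediction cannot improve
            return WoldSelection(press, ratios, i + 1, threshold)
        if ratios[i] >= threshold:
            return WoldSelection(press, ratios, i + 1, threshold)
    if press[-1] == 0.0:
        return WoldSelection(press, ratios, len(press), threshold)
    return WoldSelection(press, ratios, len(press), threshold, flagged=True)


class PLS1Model:
    """PLS-1 of a univariate response on a feature matrix.

    Parameters
    ----------
    X : (n, m) array
        Predictors, typically z-scored lagged band-power features.
    y : (n,) array
        Response (force, newtons).
    center : bool
        Optionally subtract column means of X and the mean of y before the
        recursion (off by default: the printed recursion has no centering
        step and the intercept is carried by ``beta0`` alone).
    """

    def __init__(self, X, y, *, center: bool = False):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")
        self.X = X
        self.y = y
        self.center = center
        self.nobs, self.nfeat = X.shape

    @classmethod
    def from_dataframe(cls, df, target: str, *, center: bool = False) -> "PLS1Model":
        """Build from a DataFrame; every non-target column is a predictor."""
        y = df[target].to_numpy(dtype=float)
        X = df.drop(columns=[target]).to_numpy(dtype=float)
        return cls(X, y, center=center)

    def fit(self, n_components: int) -> "PLS1Results":
        """Run the stepwise recursion for ``n_components`` latent components.

        Stops early (flagged on the results) if a score degenerates,
        ``t't <= 1e-12 * ||X||_F^2``.
        """
        l = int(n_components)
        if not 1 <= l <= min(self.nobs, self.nfeat):
            raise ValueError(f"n_components must be in [1, {min(self.nobs, self.nfeat)}]")

        x_mean = self.X.mean(axis=0) if self.center else np.zeros(self.nfeat)
        y_mean = self.y.mean() if self.center else 0.0
        Xd = self.X - x_mean
        yd = self.y - y_mean
        tol = 1e-12 * np.sum(Xd * Xd)

        W, T, P, Q = [], [], [], []
        degenerate = False
        for _ in range(l):
            w = Xd.T @ yd
            t = Xd @ w
            tt = t @ t
            if tt <= tol:
                degenerate = True
                break
            p = Xd.T @ t / tt
            q = yd @ t / tt
            Xd = Xd - np.outer(t, p)
            yd = yd - t * q
            W.append(w)
            T.append(t)
            P.append(p)
            Q.append(q)
        if not W:
            raise ValueError("no usable component: X'y is numerically zero")
        W = np.column_stack(W)
        T = np.column_stack(T)
        P = np.column_stack(P)
        Q = np.asarray(Q)

        PtW = P.T @ W
        try:
            beta = W @ np.linalg.solve(PtW, Q)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular P'W in the regression-weight step") from exc
        beta0 = Q[0] - P[:, 0] @ beta
        return PLS1Results(
            model=self,
            W=W,
            T=T,
            P=P,
            Q=Q,
            beta=beta,
            beta0=float(beta0),
            n_components=W.shape[1],
            degenerate=degenerate,
            x_mean=x_mean,
            y_mean=float(y_mean),
            x_residual=Xd,
        )

    def fit_wold(
        self,
        max_l: int = 15,
        threshold: float = 0.9,
        folds: int = 10,
        seed: int = 0,
        groups: np.ndarray | None = None,
    ) -> "PLS1Results":
        """Select the component count by Wold's criterion, then fit."""
        sel = select_components_wold(
            self.X,
            self.y,
            max_l,
            threshold=threshold,
            folds=folds,
            seed=seed,
            groups=groups,
            center=self.center,
        )
        res = self.fit(sel.selected_l)
        res.selection = sel
        return res


@dataclass
class PLS1Results:
    """Fitted PLS-1 decoder: loadings, scores and the regression vector."""

    model: PLS1Model
    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    beta: np.ndarray
    beta0: float
    n_components: int
    degenerate: bool = False
    x_mean: np.ndarray | None = None
    y_mean: float = 0.0
    x_residual: np.ndarray | None = None  # deflated X after the last step
    selection: WoldSelection | None = None

    def predict(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.beta.shape[0]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects {self.beta.shape[0]}"
            )
        Xc = X_new - (self.x_mean if self.x_mean is not None else 0.0)
        return Xc @ self.beta + self.beta0 + self.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    @property
    def rsquared(self) -> float:
        y = self.model.y
        sst = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum(self.resid**2) / sst

    def summary(self) -> str:
        lines = [
            "PLS-1 regression results",
            "=" * 40,
            f"observations        {self.model.nobs}",
            f"features            {self.model.nfeat}",
            f"latent components   {self.n_components}"
            + ("  (early stop)" if self.degenerate else ""),
            f"train R^2           {self.rsquared: .4f}",
            f"intercept beta0     {self.beta0: .6g}",
        ]
        if self.selection is not None:
            s = self.selection
            lines.append(
                f"Wold selection      l={s.selected_l} at ratio>= {s.threshold}"
                + ("  (never reached; max_l used)" if s.flagged else "")
            )
            lines.append(
                "PRESS               "
                + ", ".join(f"{p:.4g}" for p in s.press[: s.selected_l + 1])
            )
        return "\n".join(lines)


def pls1_fit(X, y, n_components: int, *, center: bool = False) -> PLS1Results:
    """Functional wrapper around :meth:`PLS1Model.fit`."""
    return PLS1Model(X, y, center=center).fit(n_components)


def pls1_predict(results: PLS1Results, X_new) -> np.ndarray:
    return results.predict(X_new)


def _fold_indices(
    n: int, folds: int, seed: int, groups: np.ndarray | None
) -> list[np.ndarray]:
    """Seeded row partition; whole groups (trials) stay in one fold."""
    rng = np.random.default_rng(seed)
    if groups is None:
        perm = rng.permutation(n)
        return [np.sort(part) for part in np.array_split(perm, folds)]
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < folds:
        raise ValueError(f"{folds}-fold CV needs >= {folds} groups, got {len(uniq)}")
    perm = rng.permutation(len(uniq))
    out = []
    for part in np.array_split(perm, folds):
        mask = np.isin(groups, uniq[part])
        out.append(np.flatnonzero(mask))
    return out


def _press_curve(
    X,
    y,
    max_l: int,
    folds: int,
    seed: int,
    groups: np.ndarray | None,
    center: bool,
) -> np.ndarray:
    """PRESS(l) for l = 1..max_l from one seeded fold partition.

    Each fold is fit once with max_l components; predictions for every
    truncation l reuse the stored loadings (beta_l from the first l columns),
    which is identical to refitting with l components — the recursion is
    greedy and earlier components never change.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < folds:
        raise ValueError("more folds than rows")
    press = np.zeros(max_l)
    for test_idx in _fold_indices(n, folds, seed, groups):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        res = PLS1Model(X[train_mask], y[train_mask], center=center).fit(
            min(max_l, train_mask.sum(), X.shape[1])
        )
        Xt = X[test_idx] - (res.x_mean if res.x_mean is not None else 0.0)
        for l in range(1, max_l + 1):
            leff = min(l, res.n_components)
            beta_l = res.W[:, :leff] @ np.linalg.solve(
                res.P[:, :leff].T @ res.W[:, :leff], res.Q[:leff]
            )
            beta0_l = res.Q[0] - res.P[:, 0] @ beta_l
            pred = Xt @ beta_l + beta0_l + res.y_mean
            press[l - 1] += np.sum((y[test_idx] - pred) ** 2)
    return press


def compute_press(
    X,
    y,
    n_components: int,
    folds: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    *,
    center: bool = False,
) -> float:
    """Out-of-fold squared prediction error of an l-component PLS-1 fit."""
    curve = _press_curve(X, y, n_components, folds, seed, groups, center)
    return float(curve[n_components - 1])


def select_components_wold(
    X,
    y,
    max_l: int,
    threshold: float = 0.9,
    folds: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    *,
    center: bool = False,
) -> WoldSelection:
    """Smallest l whose PRESS ratio PRESS(l+1)/PRESS(l) reaches ``threshold``.

    Falls back to ``max_l`` (flagged) if the ratio never reaches it.
    """
    if max_l < 2:
        raise ValueError("max_l must be >= 2")
    press = _press_curve(X, y, max_l, folds, seed, groups, center)
    return _wold_from_press(press, threshold)
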