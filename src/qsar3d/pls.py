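"""NIPALS partial least squares with leave-one-out model selection.

PLS1 relates the many, highly collinear field columns to activity through
a small number of latent components.  Model quality is summarized the way
the 3D-QSAR literature reports it:

* q²  — leave-one-out cross-validated determination coefficient,
  ``1 − PRESS/SS_tot`` (> 0.5 conventionally read as significant);
* ONC — number of components maximizing q² (ties go to the smaller
  model; a "5% improvement" rule is available as an option);
* r², SEE = sqrt(RSS/(n−c−1)), F = [r²/(1−r²)]·[(n−c−1)/c] at the ONC;
* per-field contribution percentages Σ|b_j s_j| within the field over the
  total, the quantity the model-summary tables report.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .fields import FieldMatrix

__all__ = [
    "nipals_pls1",
    "pls_fit",
    "loo_cross_validate",
    "model_statistics",
    "field_contributions",
    "PLSQsar",
]


def nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int) -> dict:
    """NIPALS PLS1 on already-centered data.

    Returns weights ``W``, X-loadings ``P``, y-loadings ``q`` (per
    component) and the equivalent regression vector
    ``b = W (PᵀW)⁻¹ q``.  For PLS1 each component is a single
    deflation step — no inner iteration is needed.
    """
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).copy()
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for c in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            # residual orthogonal to y: remaining components are null
            W, P, q = W[:, :c], P[:, :c], q[:c]
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            W, P, q = W[:, :c], P[:, :c], q[:c]
            break
        pvec = X.T @ t / tt
        qc = float(y @ t / tt)
        X -= np.outer(t, pvec)
        y -= qc * t
        W[:, c], P[:, c], q[c] = w, pvec, qc
    k = W.shape[1]
    if k == 0:
        b = np.zeros(p)
    else:
        b = W @ np.linalg.solve(P.T @ W, q[:k])
    return {"W": W, "P": P, "q": q[:k] if k else q, "coef": b, "n_components": k}


def pls_fit(X, y, n_components: int) -> "PLSQsar":
    """Fit a PLS model with a fixed number of components."""
    model = PLSQsar(n_components=n_components)
    model.fit(X, y)
    return model


def loo_cross_validate(X, y, max_components: int = 10) -> tuple[np.ndarray, int]:
    """Leave-one-out q² for 1..max_components and the optimal count.

    Each left-out sample is predicted by a model refit on the remaining
    n−1; ``q²(c) = 1 − Σ(y_i − ŷ_(−i))² / Σ(y_i − ȳ)²`` with ȳ the full
    training mean.  ONC is the argmax (ties → fewer components).
    """
    X = _descriptors(X)
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out cross-validation needs at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("activities are constant; q² is undefined")
    cmax = int(min(max_components, n - 2, X.shape[1]))
    press = np.zeros(cmax)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    for i in range(n):
        keep = np.arange(n) != i
        Xt, yt = X[keep], y[keep]
        xm, ym = Xt.mean(axis=0), yt.mean()
        fit = nipals_pls1(Xt - xm, yt - ym, cmax)
        # predictions at every component count from one NIPALS pass
        W, P, q = fit["W"], fit["P"], fit["q"]
        k = W.shape[1]
        if k:
            R = W @ np.linalg.inv(P.T @ W)  # columns: per-component weights
            x0 = X[i] - xm
            tscores = x0 @ R
            partial = ym + np.cumsum(tscores * q)
            preds = np.concatenate([partial, np.full(cmax - k, partial[-1] if k else ym)])
        else:
            preds = np.full(cmax, ym)
        press += (y[i] - preds) ** 2
    q2 = 1.0 - press / ss_tot
    onc = int(np.argmax(q2)) + 1
    return q2, onc


def model_statistics(y: np.ndarray, y_fit: np.ndarray, n_components: int) -> tuple[float, float, float]:
    """(r², SEE, F) for fitted training predictions at ``n_components``.

    ``SEE = sqrt(RSS/(n−c−1))``, ``F = [r²/(1−r²)]·[(n−c−1)/c]``; a
    perfect fit returns F = inf.
    """
    y = np.asarray(y, float)
    y_fit = np.asarray(y_fit, float)
    n, c = len(y), int(n_components)
    if n <= c + 1:
        raise ValueError("SEE undefined: need n > n_components + 1")
    rss = float(((y - y_fit) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("activities are constant; r² is undefined")
    r2 = 1.0 - rss / ss_tot
    see = float(np.sqrt(rss / (n - c - 1)))
    f = float("inf") if r2 >= 1.0 else (r2 / (1.0 - r2)) * ((n - c - 1) / c)
    return r2, see, f


def field_contributions(coef: np.ndarray, stdevs: np.ndarray, fields: np.ndarray) -> dict[str, float]:
    """Percent contribution of each field block: Σ|b_j·s_j| over the block
    relative to the total, summing to 100."""
    coef = np.asarray(coef, float)
    stdevs = np.asarray(stdevs, float)
    fields = np.asarray(fields)
    w = np.abs(coef * stdevs)
    total = w.sum()
    labels = list(dict.fromkeys(fields.tolist()))
    if total == 0:
        return {f: 100.0 / len(labels) for f in labels}
    return {f: float(100.0 * w[fields == f].sum() / total) for f in labels}


def _descriptors(X) -> np.ndarray:
    return X.descriptors if isinstance(X, FieldMatrix) else np.asarray(X, float)


def _field_labels(X) -> np.ndarray | None:
    return X.active_fields if isinstance(X, FieldMatrix) else None


class PLSQsar(BaseEstimator, RegressorMixin):
    """PLS1 regressor with built-in leave-one-out component selection.

    Parameters
    ----------
    n_components : int or None
        Fixed component count; ``None`` selects the optimum by LOO q².
    max_components : int
        Upper bound scanned during selection (capped at n−2 and the
        column count).
    onc_rule : {'argmax', 'improve_5pct'}
        ``'argmax'`` takes the q² maximum (ties → fewer components);
        ``'improve_5pct'`` stops adding components once the relative q²
        gain drops below 5%.

    Attributes
    ----------
    coef_, intercept_ : regression vector on the descriptor scale.
    n_components_ : selected/used component count (the ONC).
    q2_, q2_by_components_ : LOO statistics (when selection ran or
        ``cross_validate=True`` at fit).
    r2_, see_, f_ : non-cross-validated fit statistics.
    contributions_ : field → percent, when X carries field labels.
    """

    def __init__(self, n_components: int | None = None, max_components: int = 10,
                 onc_rule: str = "argmax"):
        self.n_components = n_components
        self.max_components = max_components
        self.onc_rule = onc_rule

    def fit(self, X, y, cross_validate: bool = True) -> "PLSQsar":
        Xd = _descriptors(X)
        y = np.asarray(y, float)
        if Xd.shape[0] != len(y):
            raise ValueError("X rows and y length differ")
        if np.ptp(y) == 0:
            raise ValueError("activities are constant; PLS is undefined")
        n, p = Xd.shape
        self.q2_by_components_ = None
        self.q2_ = None
        if self.n_components is None or cross_validate:
            q2s, onc = loo_cross_validate(Xd, y, self.max_components)
            if self.onc_rule == "improve_5pct":
                onc = _onc_improve_rule(q2s)
            elif self.onc_rule != "argmax":
                raise ValueError("onc_rule must be 'argmax' or 'improve_5pct'")
            self.q2_by_components_ = q2s
            if self.n_components is None:
                c = onc
            else:
                c = int(self.n_components)
            self.q2_ = float(q2s[min(c, len(q2s)) - 1])
        else:
            c = int(self.n_components)
        if not 1 <= c <= min(p, n - 1):
            raise ValueError(f"n_components={c} outside [1, min(n_columns, n-1)]")
        self._x_mean = Xd.mean(axis=0)
        self._y_mean = float(y.mean())
        fit = nipals_pls1(Xd - self._x_mean, y - self._y_mean, c)
        self.n_components_ = c
        self.coef_ = fit["coef"]
        self.intercept_ = self._y_mean - float(self._x_mean @ self.coef_)
        self._column_meta = X.column_meta if isinstance(X, FieldMatrix) else None
        self._active_mask = X.active_mask if isinstance(X, FieldMatrix) else None
        y_fit = self.predict(Xd)
        if n > c + 1:
            self.r2_, self.see_, self.f_ = model_statistics(y, y_fit, c)
        else:
            rss = float(((y - y_fit) ** 2).sum())
            self.r2_ = 1.0 - rss / float(((y - y.mean()) ** 2).sum())
            self.see_ = self.f_ = float("nan")
        labels = _field_labels(X)
        self.contributions_ = (
            field_contributions(self.coef_, Xd.std(axis=0, ddof=1), labels)
            if labels is not None else None
        )
        self._x_std = Xd.std(axis=0, ddof=1)
        return self

    def predict(self, X) -> np.ndarray:
        Xd = _descriptors(X)
        if Xd.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"descriptor column mismatch: model has {self.coef_.shape[0]}, "
                f"input has {Xd.shape[1]}"
            )
        return self.intercept_ + Xd @ self.coef_

    _SCHEMA_VERSION = 1

    def save(self, path) -> None:
        """Serialize the fitted model to a single JSON archive
        (coefficients, centering, statistics, contributions)."""
        import json
        from pathlib import Path

        def _num(v):
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        payload = {
            "schema_version": self._SCHEMA_VERSION,
            "params": self.get_params(),
            "n_components": int(self.n_components_),
            "coef": self.coef_.tolist(),
            "intercept": float(self.intercept_),
            "x_mean": self._x_mean.tolist(),
            "x_std": self._x_std.tolist(),
            "y_mean": float(self._y_mean),
            "stats": {"q2": _num(self.q2_), "r2": _num(self.r2_),
                      "see": _num(self.see_),
                      "f": None if not np.isfinite(self.f_) else float(self.f_)},
            "contributions": self.contributions_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "PLSQsar":
        """Restore a model saved with :meth:`save`."""
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        version = payload.get("schema_version")
        if version != cls._SCHEMA_VERSION:
            raise ValueError(f"unsupported model archive schema: {version!r}")
        model = cls(**payload["params"])
        model.n_components_ = payload["n_components"]
        model.coef_ = np.asarray(payload["coef"])
        model.intercept_ = payload["intercept"]
        model._x_mean = np.asarray(payload["x_mean"])
        model._x_std = np.asarray(payload["x_std"])
        model._y_mean = payload["y_mean"]
        stats = payload["stats"]
        model.q2_ = stats["q2"]
        model.r2_ = stats["r2"]
        model.see_ = stats["see"]
        model.f_ = float("inf") if stats["f"] is None and stats["r2"] == 1.0 else stats["f"]
        model.contributions_ = payload["contributions"]
        model.q2_by_components_ = None
        model._column_meta = model._active_mask = None
        return model


def _onc_improve_rule(q2s: np.ndarray, threshold: float = 0.05) -> int:
    """Add components only while q² improves by at least ``threshold``
    relatively (a conservative alternative to the plain argmax)."""
    onc = 1
    for c in range(1, len(q2s)):
        prev = q2s[onc - 1]
        if q2s[c] > prev and (q2s[c] - prev) >= threshold * abs(prev if prev != 0 else 1.0):
            onc = c + 1
    return onc
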