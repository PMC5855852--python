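"""External test-set validation and printed-table auditing.

The external predictive factor is

    r²_pred = (SD − PRESS) / SD

with ``SD`` the squared deviation of the *test* activities about the
*training-set mean* and ``PRESS`` the squared deviation between actual
and predicted test activities.  ``audit_table`` applies the same
definitions — plus training r², SEE and F at a given component count —
directly to a printed actual/predicted activity table, which makes the
published model statistics checkable from the table alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import PLSQsar, model_statistics

__all__ = ["ValidationReport", "external_validate", "r2_pred", "audit_table"]


@dataclass
class ValidationReport:
    """Per-molecule test predictions with SD, PRESS and r²_pred."""

    table: pd.DataFrame  # columns: id, y_obs, y_pre
    y_mean_train: float
    sd: float
    press: float
    r2_pred: float

    def __str__(self) -> str:  # human-readable summary
        lines = [f"{r.id:>8s}  obs {r.y_obs:6.3f}  pred {r.y_pre:6.3f}" for r in self.table.itertuples()]
        lines += [
            f"training mean = {self.y_mean_train:.4f}",
            f"SD = {self.sd:.4f}   PRESS = {self.press:.4f}   r2_pred = {self.r2_pred:.4f}",
        ]
        return "\n".join(lines)


def r2_pred(y_obs: np.ndarray, y_pre: np.ndarray, y_mean_train: float) -> tuple[float, float, float]:
    """(SD, PRESS, r²_pred) for a test set, SD about the training mean."""
    y_obs = np.asarray(y_obs, float)
    y_pre = np.asarray(y_pre, float)
    sd = float(((y_obs - y_mean_train) ** 2).sum())
    if sd == 0:
        raise ValueError("SD = 0: every test activity equals the training mean; r2_pred undefined")
    press = float(((y_obs - y_pre) ** 2).sum())
    return sd, press, (sd - press) / sd


def external_validate(model: PLSQsar, X_test, y_test: np.ndarray,
                      ids: list[str] | None = None,
                      y_mean_train: float | None = None) -> ValidationReport:
    """Predict the test molecules and score the model externally.

    ``y_mean_train`` defaults to the mean activity the model was centered
    on at fit time.
    """
    y_test = np.asarray(y_test, float)
    if y_test.size == 0:
        raise ValueError("empty test set")
    y_pre = model.predict(X_test)
    if y_mean_train is None:
        y_mean_train = model._y_mean
    sd, press, r2p = r2_pred(y_test, y_pre, y_mean_train)
    if ids is None:
        ids = [f"test{i}" for i in range(len(y_test))]
    table = pd.DataFrame({"id": ids, "y_obs": y_test, "y_pre": y_pre})
    return ValidationReport(table, float(y_mean_train), sd, press, r2p)


def audit_table(actual: np.ndarray, predicted: np.ndarray, split: np.ndarray,
                onc: int, ids: np.ndarray | None = None,
                expected: dict[str, float] | None = None,
                r_tol: float = 0.01, f_rtol: float = 0.01) -> dict:
    """Recompute model statistics from a printed actual/predicted table.

    Training rows give r², SEE and F at the stated component count; test
    rows give SD, PRESS and r²_pred about the training mean.  When
    ``expected`` supplies published values, the result carries a
    per-statistic comparison at ±``r_tol`` absolute for r-type statistics
    and ±``f_rtol`` relative for F (printed predictions are rounded to 3
    decimals, so exact agreement is not expected).
    """
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    split = np.asarray(split)
    if not (len(actual) == len(predicted) == len(split)):
        raise ValueError("actual, predicted and split must align row by row")
    if ids is not None and len(np.unique(ids)) != len(actual):
        raise ValueError("compound ids are not unique")
    tr = split == "train"
    te = split == "test"
    if not tr.any() or not te.any():
        raise ValueError("both training and test rows are required")
    r2, see, f = model_statistics(actual[tr], predicted[tr], onc)
    y_mean = float(actual[tr].mean())
    sd, press, r2p = r2_pred(actual[te], predicted[te], y_mean)
    out = {
        "n_train": int(tr.sum()), "n_test": int(te.sum()), "onc": int(onc),
        "y_mean_train": y_mean, "r2": r2, "see": see, "f": f,
        "sd": sd, "press": press, "r2_pred": r2p,
    }
    if expected:
        comparison = {}
        for key, exp in expected.items():
            got = out[key]
            tol = f_rtol * abs(exp) if key == "f" else r_tol
            comparison[key] = {"expected": float(exp), "recomputed": float(got),
                               "within_tolerance": bool(abs(got - exp) <= tol)}
        out["comparison"] = comparison
    return out
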