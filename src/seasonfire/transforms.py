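"""Normality transformations and the small-sample correlation/normality checks.

The modeled descriptors are skewed on their natural scales, so each variable
gets a fixed variance-stabilizing transform before covariance modeling:
square root for the fire counts and area burned, natural log for wet-season
duration and rainfall, log10 for dry-season onset day, squaring for the
negatively skewed wet onset and dry duration, and the reflect-log transform
y = |ln(1 - x)| for trend consistency (an R^2 bounded in [0, 1) with extreme
negative skew; the transform is strictly increasing so orderings survive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformSpec",
    "DEFAULT_TRANSFORMS",
    "reflect_ln",
    "reflect_ln_inverse",
    "transform_values",
    "inverse_transform_values",
    "apply_transforms",
    "TransformDomainError",
    "normality_check",
    "pearson_with_p",
    "pearson_pvalue",
]


@dataclass(frozen=True)
class TransformSpec:
    variable: str
    transform: str  # sqrt | ln | log10 | square | reflect_ln | identity


# Default per-variable assignment for the pipeline's wide descriptor table.
DEFAULT_TRANSFORMS: dict[str, str] = {
    "n_fires": "sqrt",
    "area_burned": "sqrt",
    "duration_wet": "ln",
    "rainfall_wet": "ln",
    "onset_dry": "log10",
    "onset_wet": "square",
    "duration_dry": "square",
    "tc_dry": "reflect_ln",
    "tc_wet": "reflect_ln",
}


class TransformDomainError(ValueError):
    """Raised when values fall outside a transform's domain; lists offenders."""

    def __init__(self, violations):
        self.violations = violations  # list of (variable, row_label, value)
        detail = "; ".join(f"{v}[{r}]={x!r}" for v, r, x in violations[:10])
        super().__init__(f"{len(violations)} transform domain violation(s): {detail}")


def reflect_ln(x):
    """Reflect-log transform y = |ln(1 - x)| for R^2 scores in [0, 1).

    Reflecting a negatively skewed bounded score, logging, and re-reflecting
    collapses to this single sign-free formula.  Monotone increasing on [0, 1).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("reflect_ln requires 0 <= x < 1")
    out = np.abs(np.log1p(-arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def reflect_ln_inverse(y):
    arr = np.asarray(y, dtype=float)
    out = -np.expm1(-arr)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


_FORWARD = {
    "identity": lambda a: a,
    "sqrt": np.sqrt,
    "ln": np.log,
    "log10": np.log10,
    "square": np.square,
    "reflect_ln": lambda a: np.abs(np.log1p(-a)),
}

_INVERSE = {
    "identity": lambda a: a,
    "sqrt": np.square,
    "ln": np.exp,
    "log10": lambda a: np.power(10.0, a),
    "square": np.sqrt,  # nonnegative branch; all squared variables are positive
    "reflect_ln": lambda a: -np.expm1(-a),
}


def _domain_ok(name: str, arr: np.ndarray) -> np.ndarray:
    if name in ("ln", "log10"):
        return arr > 0
    if name == "sqrt":
        return arr >= 0
    if name == "reflect_ln":
        return (arr >= 0) & (arr < 1)
    return np.ones_like(arr, dtype=bool)


def transform_values(name: str, values):
    arr = np.asarray(values, dtype=float)
    if name not in _FORWARD:
        raise KeyError(f"unknown transform {name!r}")
    ok = _domain_ok(name, arr)
    if not np.all(ok):
        bad = np.atleast_1d(arr)[~np.atleast_1d(ok)][0]
        raise ValueError(f"value {bad!r} outside domain of {name}")
    return _FORWARD[name](arr)


def inverse_transform_values(name: str, values):
    if name not in _INVERSE:
        raise KeyError(f"unknown transform {name!r}")
    return _INVERSE[name](np.asarray(values, dtype=float))


def apply_transforms(table: pd.DataFrame, specs=None, suffix: str = "_t") -> pd.DataFrame:
    """Column-wise transforms; originals kept, transformed columns suffixed.

    ``specs`` maps column name -> transform name (or a list of TransformSpec).
    Domain violations are collected across all cells and raised together with
    row identities rather than failing on the first offender.
    """
    if specs is None:
        specs = {k: v for k, v in DEFAULT_TRANSFORMS.items() if k in table.columns}
    if not isinstance(specs, dict):
        specs = {s.variable: s.transform for s in specs}
    out = table.copy()
    violations = []
    for col, name in specs.items():
        if col not in table.columns:
            raise KeyError(f"transform spec references missing column {col!r}")
        if name not in _FORWARD:
            raise KeyError(f"unknown transform {name!r} for column {col!r}")
        arr = table[col].to_numpy(dtype=float)
        ok = _domain_ok(name, arr) | np.isnan(arr)
        if not ok.all():
            violations.extend((col, table.index[i], arr[i]) for i in np.flatnonzero(~ok))
            continue
        with np.errstate(divide="ignore"):
            out[col + suffix] = _FORWARD[name](arr)
    if violations:
        raise TransformDomainError(violations)
    return out


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (delegated to scipy)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or arr.size > 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("constant sample: normality test undefined")
    res = stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a product-moment correlation via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d samples")
    if x.size < 3:
        raise ValueError("need n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("degenerate (zero-variance) sample")
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    return r, pearson_pvalue(r, x.size)
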