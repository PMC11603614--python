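"""Experiment-vs-prediction scoreboard: Kendall tau-b, linear-fit R^2 and
slope, MAE/ME/RMSE, with percentile-bootstrap confidence intervals
(systems resampled with replacement, optional Gaussian noise from each
system's reported uncertainty).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

METRIC_NAMES = ("tau", "r_squared", "slope_m", "intercept", "mae", "me", "rmse")


@dataclass
class AffinityTable:
    """Predicted vs experimental affinities (kcal/mol) per system."""

    system_ids: list[str]
    predicted: np.ndarray
    experimental: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.experimental = np.asarray(self.experimental, dtype=float)
        n = len(self.system_ids)
        if len(self.predicted) != n or len(self.experimental) != n:
            raise ValueError("misaligned table columns")
        if len(set(self.system_ids)) != n:
            raise ValueError("duplicate system ids")
        if self.uncertainty is None:
            self.uncertainty = np.zeros(n)
        else:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if len(self.uncertainty) != n:
                raise ValueError("misaligned uncertainty column")

    def __len__(self) -> int:
        return len(self.system_ids)

    @classmethod
    def from_csv(cls, path) -> "AffinityTable":
        df = pd.read_csv(path)
        required = {"id", "predicted", "experimental"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"affinity CSV missing columns: {sorted(missing)}")
        unc = df["uncertainty"].to_numpy() if "uncertainty" in df.columns else None
        return cls(
            [str(s) for s in df["id"]],
            df["predicted"].to_numpy(),
            df["experimental"].to_numpy(),
            unc,
        )


@dataclass
class MetricsReport:
    tau: float
    r_squared: float
    slope_m: float
    intercept: float
    mae: float
    me: float
    rmse: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0
    n_excluded: int = 0
    confidence: float = 0.95

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        d.update(
            n_boot=self.n_boot, seed=self.seed,
            n_excluded=self.n_excluded, confidence=self.confidence,
        )
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def summary(self) -> str:
        lines = [f"n_boot={self.n_boot} confidence={self.confidence}"]
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if name in self.ci:
                lo, hi = self.ci[name]
                lines.append(f"{name:>10s} = {v: .4f}  [{lo: .4f}, {hi: .4f}]")
            else:
                lines.append(f"{name:>10s} = {v: .4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# point metrics
# ---------------------------------------------------------------------------

def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall tau-b; NaN when either axis is all-tied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    tau, _ = stats.kendalltau(x, y)
    return float(tau)


def linear_fit_metrics(pred, exp) -> tuple[float, float, float]:
    """OLS of predicted on experimental: (slope m, intercept, R^2).

    R^2 is the squared Pearson correlation.  NaN triple on zero variance.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if len(pred) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(pred) == 0 or np.ptp(exp) == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(exp, pred)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def error_metrics(pred, exp) -> tuple[float, float, float]:
    """(MAE, ME, RMSE) of predicted - experimental."""
    d = np.asarray(pred, dtype=float) - np.asarray(exp, dtype=float)
    if d.size == 0:
        raise ValueError("need n >= 1")
    return (
        float(np.mean(np.abs(d))),
        float(np.mean(d)),
        float(np.sqrt(np.mean(d * d))),
    )


def compute_metrics(pred, exp) -> dict[str, float]:
    m, b, r2 = linear_fit_metrics(pred, exp)
    mae, me, rmse = error_metrics(pred, exp)
    return {
        "tau": kendall_tau(exp, pred),
        "r_squared": r2,
        "slope_m": m,
        "intercept": b,
        "mae": mae,
        "me": me,
        "rmse": rmse,
    }


# ---------------------------------------------------------------------------
# vectorized batch metrics (bootstrap hot path)
# ---------------------------------------------------------------------------

def _tau_b_batch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Kendall tau-b for each row pair of (B, n) arrays, by explicit pair
    enumeration (exact for small n; independent of scipy's O(n log n) path,
    which the unit tests cross-check)."""
    iu, ju = np.triu_indices(x.shape[1], k=1)
    dx = np.sign(x[:, iu] - x[:, ju])
    dy = np.sign(y[:, iu] - y[:, ju])
    s = np.sum(dx * dy, axis=1)
    n0 = len(iu)
    tx = np.sum(dx == 0, axis=1)
    ty = np.sum(dy == 0, axis=1)
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, s / denom, np.nan)


def _metrics_batch(pred: np.ndarray, exp: np.ndarray) -> dict[str, np.ndarray]:
    """All scoreboard metrics row-wise over (B, n) resample arrays."""
    n = pred.shape[1]
    mx = exp.mean(axis=1)
    my = pred.mean(axis=1)
    cx = exp - mx[:, None]
    cy = pred - my[:, None]
    sxx = np.sum(cx * cx, axis=1)
    syy = np.sum(cy * cy, axis=1)
    sxy = np.sum(cx * cy, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, np.nan)
        r2 = np.where((sxx > 0) & (syy > 0), sxy**2 / (sxx * syy), np.nan)
    intercept = my - slope * mx
    d = pred - exp
    return {
        "tau": _tau_b_batch(exp, pred),
        "r_squared": r2,
        "slope_m": slope,
        "intercept": intercept,
        "mae": np.mean(np.abs(d), axis=1),
        "me": np.mean(d, axis=1),
        "rmse": np.sqrt(np.mean(d * d, axis=1)),
    }


def bootstrap_ci(
    table: AffinityTable,
    n_iter: int = 100_000,
    confidence: float = 0.95,
    seed: int = 0,
    noise_from_uncertainty: bool = True,
) -> MetricsReport:
    """Percentile bootstrap over systems (with replacement), each iteration
    optionally perturbing predictions with per-system Gaussian noise.

    Iterations whose resample degenerates (zero variance on either axis)
    yield NaN metrics; they are excluded from the percentiles and counted
    in ``n_excluded``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 systems")
    rng = np.random.default_rng(seed)
    point = compute_metrics(table.predicted, table.experimental)

    idx = rng.integers(0, n, size=(n_iter, n))
    pred = table.predicted[idx]
    exp = table.experimental[idx]
    if noise_from_uncertainty and np.any(table.uncertainty > 0):
        pred = pred + rng.standard_normal(pred.shape) * table.uncertainty[idx]
    batch = _metrics_batch(pred, exp)

    alpha = (1.0 - confidence) / 2.0
    ci = {}
    n_excluded = 0
    for name, vals in batch.items():
        ok = np.isfinite(vals)
        n_excluded = max(n_excluded, int(np.sum(~ok)))
        if np.any(ok):
            lo, hi = np.quantile(vals[ok], [alpha, 1.0 - alpha])
            ci[name] = (float(lo), float(hi))
        else:
            ci[name] = (float("nan"), float("nan"))
    return MetricsReport(
        **point, ci=ci, n_boot=n_iter, seed=seed,
        n_excluded=n_excluded, confidence=confidence,
    )
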