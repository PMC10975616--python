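"""Cross-run statistics.

* exponential law for the maximum shoulder-rotation amplitude against the
  width-to-shoulder ratio R = w/s, ``f(R) = a e^(-bR + c) + d`` (fitted in the
  identifiable three-parameter form ``a' e^(-bR) + d`` with ``a' = a e^c``),
* the critical ratio R_crit located on a 180-point grid over [0.8, 2.6] by
  Tukey comparisons between 0.05-wide intervals of the fitted curve,
* the linear crossing-offset law C(w) = slope * w + intercept (side-folded),
* all-pairs Tukey(-Kramer) tests via the studentized range distribution,
* significance-masked correlation matrices split at R = 1.3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------- exponential

@dataclass
class FitResult:
    """Parameters of f(x) = a e^(-bx + c) + d.

    ``a`` and ``c`` are jointly unidentifiable, so the fit is performed on
    ``a' e^(-bx) + d``; the reported ``a`` is ``a'`` with ``c = 0``.
    """

    a: float
    b: float
    c: float
    d: float
    stderr: dict[str, float]
    residuals: np.ndarray
    r_domain: tuple[float, float] = (0.8, 2.6)
    degenerate: bool = False

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(x, dtype=float) + self.c) + self.d

    @property
    def residual_sd(self) -> float:
        dof = max(len(self.residuals) - 3, 1)
        return float(np.sqrt(np.sum(self.residuals ** 2) / dof))


def _exp_model(x, a, b, d):
    return a * np.exp(-b * x) + d


def fit_max_rotation_curve(R: np.ndarray, amplitude: np.ndarray,
                           r_domain: tuple[float, float] = (0.8, 2.6)
                           ) -> FitResult:
    """Nonlinear least squares of |gamma_max| against R = w/s.

    Multi-start initialisation over decay rates; a flat input is flagged
    degenerate (b unidentifiable) and returns the mean as the plateau.
    """
    R = np.asarray(R, dtype=float)
    y = np.asarray(amplitude, dtype=float)
    ok = np.isfinite(R) & np.isfinite(y)
    R, y = R[ok], y[ok]
    if len(R) < 8:
        raise ValueError(f"need >= 8 points, got {len(R)}")
    span = float(np.ptp(y))
    if span < 1e-9 * max(1.0, float(np.abs(y).max())):
        return FitResult(a=0.0, b=0.0, c=0.0, d=float(np.mean(y)),
                         stderr={}, residuals=y - np.mean(y),
                         r_domain=r_domain, degenerate=True)
    best = None
    x0 = float(np.min(R))
    for b0 in (0.5, 1.0, 2.0, 3.0, 5.0, 8.0):
        a0 = span * np.exp(b0 * x0)
        d0 = float(np.min(y))
        try:
            popt, pcov = optimize.curve_fit(
                _exp_model, R, y, p0=(a0, b0, d0),
                bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000)
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _exp_model(R, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError(
            "exponential fit did not converge from any start "
            f"(n={len(R)}, y range {y.min():.3g}..{y.max():.3g})")
    _, popt, pcov = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 3
    resid = y - _exp_model(R, *popt)
    # a flat fit (negligible decaying component over the domain) is degenerate
    decay_span = popt[0] * (np.exp(-popt[1] * r_domain[0])
                            - np.exp(-popt[1] * r_domain[1]))
    degenerate = bool(decay_span < 1e-6 * max(1.0, span))
    return FitResult(a=float(popt[0]), b=float(popt[1]), c=0.0,
                     d=float(popt[2]),
                     stderr={"a": float(perr[0]), "b": float(perr[1]),
                             "d": float(perr[2])},
                     residuals=resid, r_domain=r_domain, degenerate=degenerate)


# ---------------------------------------------------------------- Tukey tools

def _tukey_table(means: np.ndarray, ns: np.ndarray, sd: float, df: int,
                 level: float) -> tuple[np.ndarray, float]:
    """All-pairs |q| statistics and the studentized-range critical value."""
    k = len(means)
    q_crit = float(stats.studentized_range.ppf(level, k, max(df, 2)))
    q = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = sd * np.sqrt(0.5 * (1.0 / ns[i] + 1.0 / ns[j]))
        diff = np.abs(means[i] - means[j])
        q[i, j] = q[j, i] = diff / se if se > 0 else (np.inf if diff > 0 else 0.0)
    return q, q_crit


def tukey_hsd(groups: dict[str, np.ndarray], level: float = 0.95) -> pd.DataFrame:
    """All-pairs Tukey (Tukey–Kramer for unbalanced designs) comparisons.

    Returns one row per pair with the mean difference, q statistic, p value
    (studentized range) and a significance flag at ``level``.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    for lab, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {lab!r} has < 2 samples")
    ns = np.array([len(s) for s in samples])
    means = np.array([np.mean(s) for s in samples])
    k = len(labels)
    df = int(ns.sum() - k)
    mse = float(sum(np.sum((s - m) ** 2) for s, m in zip(samples, means)) / df)
    sd = np.sqrt(mse)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = sd * np.sqrt(0.5 * (1.0 / ns[i] + 1.0 / ns[j]))
        diff = np.abs(means[i] - means[j])
        q = diff / se if se > 0 else (np.inf if diff > 0 else 0.0)
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append({"group1": labels[i], "group2": labels[j],
                     "diff": means[i] - means[j], "q": q, "p": p,
                     "significant": p < 1.0 - level})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- critical point

@dataclass
class CriticalPoint:
    rcrit: float
    grid: np.ndarray
    interval: float = 0.05
    level: float = 0.95
    interval_edges: np.ndarray = field(default_factory=lambda: np.array([]))


def critical_point(fit: FitResult, residual_sd: float,
                   group_sizes: np.ndarray | None = None,
                   grid: tuple[float, float, int] = (0.8, 2.6, 180),
                   interval: float = 0.05,
                   level: float = 0.95) -> CriticalPoint:
    """Locate R_crit: the ratio beyond which the fitted amplitude stops
    changing.

    The fitted curve is evaluated on an evenly spaced grid, partitioned into
    consecutive intervals of width ``interval``; interval means are compared
    all-pairs with a Tukey–Kramer test whose error model uses ``residual_sd``
    and the per-interval observation counts.  R_crit is the lower edge of the
    earliest interval from which on no pairwise comparison among the remaining
    intervals is significant.
    """
    lo, hi, n = grid
    x = np.linspace(lo, hi, n)
    f = fit(x)
    n_int = int(round((hi - lo) / interval))
    which = np.clip(((x - lo) / interval).astype(int), 0, n_int - 1)
    edges = lo + interval * np.arange(n_int + 1)
    means = np.array([f[which == i].mean() if np.any(which == i) else np.nan
                      for i in range(n_int)])
    if group_sizes is None:
        counts = np.full(n_int, 5.0)
    else:
        counts = np.asarray(group_sizes, dtype=float)
        if len(counts) != n_int:
            raise ValueError(f"group_sizes must have {n_int} entries")
    populated = np.nonzero(np.isfinite(means) & (counts >= 1))[0]
    if len(populated) < 2:
        raise ValueError("fewer than 2 populated intervals")
    sd = max(float(residual_sd), 1e-12)
    k = len(populated)
    df = int(max(counts[populated].sum() - k, 2))
    q, q_crit = _tukey_table(means[populated], counts[populated], sd, df, level)
    sig = q > q_crit
    # earliest suffix of intervals with no significant pair
    start = k - 1
    for s in range(k):
        if not np.any(sig[s:, s:]):
            start = s
            break
    rcrit = float(edges[populated[start]])
    return CriticalPoint(rcrit=rcrit, grid=x, interval=interval, level=level,
                         interval_edges=edges)


# ------------------------------------------------------------- crossing model

@dataclass
class CrossingLaw:
    slope: float            # m lateral offset per m of width
    intercept: float        # m
    stderr_slope: float
    stderr_intercept: float
    n: int

    @property
    def shift_per_10cm_cm(self) -> float:
        """Lateral shift in cm per 10 cm of additional bottleneck width."""
        return self.slope * 10.0

    def __call__(self, width: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(width, dtype=float) + self.intercept


def fit_crossing_model(widths: np.ndarray, x_cross: np.ndarray,
                       sides: np.ndarray) -> CrossingLaw:
    """Least-squares fit of the side-folded crossing offset against width.

    ``sides`` is +1/-1 (the side of origin, from the angle sign); rows with
    side 0 are excluded.  The folded offset ``side * x_cross`` is regressed on
    the width, so a positive slope means crossing shifts towards the side of
    origin as the bottleneck widens.
    """
    widths = np.asarray(widths, dtype=float)
    x_cross = np.asarray(x_cross, dtype=float)
    sides = np.asarray(sides, dtype=float)
    ok = np.isfinite(widths) & np.isfinite(x_cross) & (sides != 0)
    w, y = widths[ok], sides[ok] * x_cross[ok]
    if len(np.unique(w)) < 2:
        raise ValueError("need >= 2 distinct widths to fit the crossing law")
    res = stats.linregress(w, y)
    return CrossingLaw(slope=float(res.slope), intercept=float(res.intercept),
                       stderr_slope=float(res.stderr),
                       stderr_intercept=float(res.intercept_stderr),
                       n=int(len(w)))


# ------------------------------------------------------------- correlations

_BINARY_CODES = {
    "motivation": {"normal": -1.0, "hurried": 1.0},
    "direction": {"right": -1.0, "left": 1.0},
    "foot_at_onset": {"left": -1.0, "right": 1.0},
    "foot_at_max": {"left": -1.0, "right": 1.0},
    "footedness": {"left": -1.0, "right": 1.0},
}


def _encode(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        s = df[col]
        if col in _BINARY_CODES:
            out[col] = s.map(lambda v: _BINARY_CODES[col].get(v, np.nan))
        else:
            out[col] = pd.to_numeric(s, errors="coerce")
    return pd.DataFrame(out)


def correlation_matrix(run_table: pd.DataFrame,
                       variables: list[str] | None = None,
                       level: float = 0.95,
                       r_split: float = 1.3,
                       method: str = "pearson"
                       ) -> dict[str, pd.DataFrame]:
    """Significance-masked correlation matrices for the two R regimes.

    Binary variables are coded as +/-1 ('none' feet become NaN and drop out
    pairwise).  Entries with p >= 1 - level are masked to NaN; the diagonal is
    always shown.  Returns ``{'R<=split': ..., 'R>split': ...}``.
    """
    if variables is None:
        variables = [c for c in run_table.columns if c != "ratio_R"]
    if "ratio_R" not in run_table.columns:
        raise ValueError("run_table needs a 'ratio_R' column for the split")
    out = {}
    for name, mask in ((f"R<={r_split}", run_table["ratio_R"] <= r_split),
                       (f"R>{r_split}", run_table["ratio_R"] > r_split)):
        sub = _encode(run_table.loc[mask, variables])
        if len(sub) < 10:
            raise ValueError(f"split {name!r} has {len(sub)} runs (< 10)")
        k = len(variables)
        corr = pd.DataFrame(np.eye(k), index=variables, columns=variables)
        for i, j in itertools.combinations(range(k), 2):
            a = sub[variables[i]]
            b = sub[variables[j]]
            both = a.notna() & b.notna()
            val = np.nan
            if both.sum() >= 3 and a[both].nunique() > 1 and b[both].nunique() > 1:
                if method == "pearson":
                    r, p = stats.pearsonr(a[both], b[both])
                elif method == "spearman":
                    r, p = stats.spearmanr(a[both], b[both])
                else:
                    raise ValueError(f"unknown method {method!r}")
                if p < 1.0 - level:
                    val = r
            corr.iloc[i, j] = corr.iloc[j, i] = val
        out[name] = corr
    return out
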