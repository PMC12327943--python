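"""Resampling and rank statistics used by the isoform analyses.

* Welch's t-test for unequal variances, with its p-value estimated by a
  bootstrap under the null: both samples are shifted to the pooled mean and
  resampled with replacement within group; the two-sided p is the
  add-one-smoothed fraction of bootstrap statistics at least as extreme as
  the observed one, ``(1 + #{|t*| >= |t_obs|}) / (1 + n_boot)``.
* Kruskal-Wallis H (mid-ranks, tie-corrected) with pairwise post-hoc Dunn
  z-tests and Benjamini-Hochberg adjustment across pairs.
* 2x2 chi-square with the Yates continuity correction,
  ``sum (max(|O - E| - 1/2, 0))^2 / E`` on one degree of freedom.

The mean-shift null for the bootstrap preserves each group's own variance,
matching the unequal-variance assumption of the Welch statistic (pooled
resampling would impose equal variances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DegenerateDataError",
    "welch_t_bootstrap",
    "kruskal_dunn",
    "chi_square_yates",
    "benjamini_hochberg",
]


class DegenerateDataError(ValueError):
    """Input data cannot support the requested test."""


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    pairwise: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": ",".join(map(str, self.n)),
        }


def _welch_t(mx, my, vx, vy, nx, ny):
    denom = np.sqrt(vx / nx + vy / ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / denom
    return t


def welch_t_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int | None = None,
    batch_elems: int = 2_000_000,
) -> TestResult:
    """Welch's t with a bootstrap null p-value.

    Requires n >= 2 per sample and positive variance in at least one
    group.  ``n_boot`` defaults to 10,000; raise to 1,000,000 to match
    full-replication analyses.  Reproducible for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise DegenerateDataError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateDataError("both samples have zero variance")
    mx, my = x.mean(), y.mean()
    t_obs = float(_welch_t(mx, my, vx, vy, nx, ny))

    grand = np.concatenate([x, y]).mean()
    x0 = x - mx + grand
    y0 = y - my + grand
    rng = np.random.default_rng(seed)
    extreme = 0
    done = 0
    per_batch = max(1, batch_elems // (nx + ny))
    while done < n_boot:
        b = min(per_batch, n_boot - done)
        xs = x0[rng.integers(0, nx, size=(b, nx))]
        ys = y0[rng.integers(0, ny, size=(b, ny))]
        t = _welch_t(
            xs.mean(axis=1), ys.mean(axis=1),
            xs.var(axis=1, ddof=1), ys.var(axis=1, ddof=1),
            nx, ny,
        )
        # degenerate resamples (both variances zero) count as extreme
        t = np.where(np.isnan(t), np.inf, t)
        extreme += int(np.count_nonzero(np.abs(t) >= abs(t_obs)))
        done += b
    p = (1 + extreme) / (1 + n_boot)
    return TestResult(
        method="welch_t_bootstrap",
        statistic=t_obs,
        p_value=float(p),
        n=(nx, ny),
        extras={"n_boot": n_boot},
    )


def _tie_term(values: np.ndarray) -> float:
    """Sum over tie groups of t^3 - t."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """Kruskal-Wallis test with pairwise Dunn post-hoc and BH correction.

    H uses mid-ranks with the standard tie correction.  The Dunn z for
    pair (i, j) is (Ri - Rj) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/ni + 1/nj))
    with T the tie term; two-sided p-values come from the standard normal
    and are BH-adjusted across all pairs.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise DegenerateDataError("every group must be non-empty")
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    ns = np.array([len(a) for a in arrays])
    n_total = int(ns.sum())
    if n_total < k + 2:
        raise DegenerateDataError("too few observations for a k-group rank test")
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    splits = np.cumsum(ns)[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = np.array([r.mean() for r in group_ranks])

    h = (12.0 / (n_total * (n_total + 1))) * np.sum(
        ns * mean_ranks**2
    ) - 3.0 * (n_total + 1)
    tie_sum = _tie_term(pooled)
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    if correction == 0:
        h_corr = 0.0  # all observations identical
    else:
        h_corr = h / correction
    p_kw = float(sps.chi2.sf(h_corr, df=k - 1))

    sigma_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(sigma_base * (1.0 / ns[i] + 1.0 / ns[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {"group_a": labels[i], "group_b": labels[j], "z": float(z), "p": float(p)}
        )
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = benjamini_hochberg(pairwise["p"].to_numpy())
    pairwise["significant"] = pairwise["p_adj"] < alpha
    return TestResult(
        method="kruskal_dunn",
        statistic=float(h_corr),
        p_value=p_kw,
        n=tuple(int(n) for n in ns),
        pairwise=pairwise,
    )


def chi_square_yates(table) -> TestResult:
    """2x2 chi-square with the Yates continuity correction.

    The adjusted deviation |O - E| - 0.5 is floored at zero so tiny tables
    cannot produce negative corrections.  Both margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    total = t.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateDataError("both margins must be positive")
    expected = np.outer(row, col) / total
    dev = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(
        method="chi_square_yates",
        statistic=chi2,
        p_value=p,
        n=tuple(int(v) for v in row),
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment, order-preserving, with monotone enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
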