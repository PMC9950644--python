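"""Exhaustive best-subset linear screening under BIC.

Every non-empty subset of a candidate predictor pool is fitted to the
response by ordinary least squares (always with an intercept) and scored
with the Bayesian information criterion.  Under a Gaussian likelihood the
profile log-likelihood collapses to the residual sum of squares, giving

    BIC = n * ln(RSS / n) + k * ln(n)

up to the additive constant n*(ln 2*pi + 1), which is dropped: it cancels in
every comparison across subsets of the same data.  k counts the intercept
plus the slopes.  Because the constant is dropped, absolute BIC magnitudes
are convention-dependent; ``relative_to_null=True`` reports BIC minus the
intercept-only model's BIC, the convention of R's best-subset tooling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

MAX_POOL = 25  # 2^25 subsets is the hard guard


@dataclass
class SubsetResult:
    subset: tuple[str, ...]
    k: int                      # intercept + slopes
    rss: float
    bic: float
    coefficients: dict[str, float]  # includes "intercept"


@dataclass
class ScreeningReport:
    best_per_size: dict[int, SubsetResult]
    overall_best: SubsetResult
    n_evaluated: int
    n_samples: int
    response: str
    relative_to_null: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "size": s,
                "subset": "+".join(r.subset),
                "rss": r.rss,
                "bic": r.bic,
                "best_overall": r.subset == self.overall_best.subset,
            }
            for s, r in sorted(self.best_per_size.items())
        ]
        return pd.DataFrame(rows)


def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit of a full design matrix (intercept included by caller).

    Returns (coefficients, residual sum of squares).  Rank-deficient designs
    raise, naming the offending columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree in length")
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        # identify near-dependent columns from the R factor of a QR
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [int(i) for i in np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]]
        raise ValueError(f"design matrix is rank deficient (collinear columns {bad})")
    resid = y - X @ beta
    return beta, float(resid @ resid)


def bic_of(rss: float, n: int, k: int) -> float:
    """Gaussian profile-likelihood BIC: n*ln(rss/n) + k*ln(n).

    An exact fit (rss = 0) has unbounded likelihood; -inf is returned so the
    subset still wins every comparison.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rss < 0:
        raise ValueError("rss cannot be negative")
    if rss == 0:
        return -np.inf
    return float(n * np.log(rss / n) + k * np.log(n))


def full_subset_screen(
    table: pd.DataFrame,
    candidates: Sequence[str],
    response: str = "sc",
    max_size: int | None = None,
    relative_to_null: bool = False,
) -> ScreeningReport:
    """Fit every predictor subset up to ``max_size`` and rank by BIC.

    Deterministic: ties in BIC break toward the smaller subset, then
    lexicographically.  Pools beyond 25 candidates are refused.
    """
    candidates = list(candidates)
    if len(candidates) > MAX_POOL:
        raise ValueError(
            f"{len(candidates)} candidates means 2^{len(candidates)} fits; "
            f"reduce the pool or set max_size"
        )
    missing = [c for c in candidates if c not in table.columns]
    if missing:
        raise ValueError(f"candidates not in table: {missing}")
    if max_size is None:
        max_size = len(candidates)
    if not 1 <= max_size <= len(candidates):
        raise ValueError("max_size must be in [1, len(candidates)]")

    y = table[response].to_numpy(dtype=float)
    X = table[candidates].to_numpy(dtype=float)
    n = len(y)
    if n <= max_size + 1:
        raise ValueError("too few samples for the largest subset")

    # centred sufficient statistics: with an intercept, subset RSS depends
    # only on the centred Gram matrix and cross-moments
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc
    xty = Xc.T @ yc
    yty = float(yc @ yc)

    best_per_size: dict[int, SubsetResult] = {}
    overall: SubsetResult | None = None
    n_eval = 0
    idx_of = {c: i for i, c in enumerate(candidates)}
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(candidates, size):
            n_eval += 1
            ids = [idx_of[c] for c in combo]
            Gs = G[np.ix_(ids, ids)]
            bs = xty[ids]
            try:
                beta = np.linalg.solve(Gs, bs)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(Gs, bs, rcond=None)[0]
            rss = max(0.0, yty - float(bs @ beta))
            k = size + 1
            bic = bic_of(rss, n, k)
            key = (bic, k, combo)
            cur = best_per_size.get(size)
            if cur is None or key < (cur.bic, cur.k, cur.subset):
                intercept = float(
                    y.mean() - X[:, ids].mean(axis=0) @ beta
                )
                coeffs = {"intercept": intercept}
                coeffs.update({c: float(b) for c, b in zip(combo, beta)})
                best_per_size[size] = SubsetResult(
                    subset=combo, k=k, rss=rss, bic=bic, coefficients=coeffs
                )
            cand = best_per_size[size]
            if overall is None or (cand.bic, cand.k, cand.subset) < (
                overall.bic, overall.k, overall.subset
            ):
                overall = cand
    assert overall is not None
    if relative_to_null:
        null_bic = bic_of(yty, n, 1)
        for r in best_per_size.values():
            r.bic -= null_bic
        # overall is one of best_per_size entries, already shifted
    return ScreeningReport(
        best_per_size=best_per_size,
        overall_best=overall,
        n_evaluated=n_eval,
        n_samples=n,
        response=response,
        relative_to_null=relative_to_null,
    )


def screen_standard_pools(
    table: pd.DataFrame,
    response: str = "sc",
    relative_to_null: bool = True,
) -> dict[str, ScreeningReport]:
    """Screen the three canonical pools: vegetation indices (11 candidates:
    four band reflectances + seven indices), 808 nm texture features (8),
    and their union (19)."""
    from canopysc.features import COMBINED_POOL, TEXTURE_POOL, VI_POOL

    pools = {"vis": VI_POOL, "texture": TEXTURE_POOL, "combined": COMBINED_POOL}
    return {
        name: full_subset_screen(
            table, pool, response=response, relative_to_null=relative_to_null
        )
        for name, pool in pools.items()
    }


def screening_summary(reports: dict[str, ScreeningReport]) -> pd.DataFrame:
    """One row per pool: candidates, selected subset and its BIC."""
    from canopysc.features import COMBINED_POOL, TEXTURE_POOL, VI_POOL

    pools = {"vis": VI_POOL, "texture": TEXTURE_POOL, "combined": COMBINED_POOL}
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "type": name,
                "n_candidates": len(pools[name]),
                "selected": "+".join(rep.overall_best.subset),
                "n_selected": len(rep.overall_best.subset),
                "bic": rep.overall_best.bic,
            }
        )
    return pd.DataFrame(rows)
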