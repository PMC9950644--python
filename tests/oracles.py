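"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible — explicit Python loops
over pixels, histogram cut points or predictor subsets — and never calls the
code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def glcm_bruteforce(
    img_q: np.ndarray,
    levels: int,
    offsets: list[tuple[int, int]],
    symmetric: bool,
) -> np.ndarray:
    """Double-loop co-occurrence counter; level -1 marks masked-out pixels."""
    h, w = img_q.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < h and 0 <= c2 < w):
                    continue
                a, b = int(img_q[r, c]), int(img_q[r2, c2])
                if a < 0 or b < 0:
                    continue
                counts[a, b] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total


def texture_bruteforce(p: np.ndarray) -> dict[str, float]:
    """Scalar-loop evaluation of the eight texture statistics."""
    ng = p.shape[0]
    mea = sum(i * p[i, j] for i in range(ng) for j in range(ng))
    var = sum((i - mea) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    hom = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    con = 0.0
    dis = 0.0
    for n in range(ng):
        pn = sum(
            p[i, j] for i in range(ng) for j in range(ng) if abs(i - j) == n
        )
        con += n**2 * pn
        dis += n * pn
    ent = -sum(
        p[i, j] * math.log(p[i, j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0
    )
    sec = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sd_x = math.sqrt(max(0.0, sum(i * i * px[i] for i in range(ng)) - mu_x**2))
    sd_y = math.sqrt(max(0.0, sum(j * j * py[j] for j in range(ng)) - mu_y**2))
    if sd_x < 1e-12 or sd_y < 1e-12:
        cor = 0.0
    else:
        cor = (
            sum(i * j * p[i, j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / (sd_x * sd_y)
    return {
        "mea": mea, "var": var, "hom": hom, "con": con,
        "dis": dis, "ent": ent, "sec": sec, "cor": cor,
    }


def otsu_bruteforce(img: np.ndarray, n_bins: int) -> float:
    """Exhaustive scan of all histogram cut points for max between-class variance."""
    img = np.asarray(img, dtype=float).ravel()
    counts, edges = np.histogram(img, bins=n_bins, range=(img.min(), img.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    sigmas = np.full(n_bins, -1.0)
    for t in range(1, n_bins):
        n0 = counts[:t].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[:t] * centers[:t]).sum() / n0
        mu1 = (counts[t:] * centers[t:]).sum() / n1
        sigmas[t] = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
    m = sigmas.max()
    tol = 1e-9 * max(1.0, abs(m))
    # lowest cut within tolerance of the max (cuts across empty bins tie)
    best_t = int(np.argmax(sigmas >= m - tol))
    return float(edges[best_t])


def mcc_formula(tp: int, tn: int, fp: int, fn: int) -> float:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def subset_screen_bruteforce(X: np.ndarray, y: np.ndarray, names: list[str]):
    """Enumerate every subset in shuffled order with plain lstsq + BIC.

    Returns (best subset as tuple of names, best bic).
    """
    n = len(y)
    combos = []
    for size in range(1, len(names) + 1):
        combos.extend(itertools.combinations(range(len(names)), size))
    # randomised evaluation order (fixed seed) to decouple from the
    # implementation's lexicographic sweep
    order = np.random.default_rng(99).permutation(len(combos))
    best = None
    for k in order:
        ids = combos[k]
        Xs = np.column_stack([np.ones(n), X[:, ids]])
        beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        rss = float(((y - Xs @ beta) ** 2).sum())
        kparams = len(ids) + 1
        bic = (
            -np.inf if rss == 0 else n * math.log(rss / n) + kparams * math.log(n)
        )
        key = (bic, kparams, tuple(names[i] for i in ids))
        if best is None or key < best:
            best = key
    return best[2], best[0]
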