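"""Canopy features: vegetation indices, GLCM texture statistics, correlations.

Vegetation indices are computed from per-sample mean canopy reflectance in
the four bands (560, 650, 725, 808 nm).  Texture features come from a
gray-level co-occurrence matrix (GLCM) restricted to canopy pixels: the
image is quantised to Ng gray levels, co-occurring level pairs are counted
at a set of pixel offsets (pairs that touch background are discarded), and
eight Haralick-style statistics are read off the normalised matrix.

Gray levels are indexed from 0 throughout.  This shifts the absolute values
of the mean (MEA) and variance (VAR) relative to a 1-based convention but
leaves every contrast-type statistic and all downstream modelling untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from canopysc.synthetic import BANDS, SpectralScene

VI_NAMES: tuple[str, ...] = ("ndvi", "cvi", "ci_re", "gndvi", "ndgi", "ndre", "rvi")
TEXTURE_NAMES: tuple[str, ...] = ("mea", "var", "hom", "con", "dis", "ent", "sec", "cor")

_EPS = 1e-12


def compute_vis(b: Mapping[int, float] | Mapping[str, float]) -> dict[str, float]:
    """Multispectral vegetation indices from mean band reflectance.

    NDVI = (B808-B650)/(B808+B650);  CVI = (B808/B560)*(B650/B560);
    CI_RE = B808/B725 - 1;           GNDVI = (B808-B560)/(B808+B560);
    NDGI = (B560-B650)/(B560+B650);  NDRE = (B808-B725)/(B808+B725);
    RVI = B808/B650.

    Any index whose denominator falls below 1e-12 is set to 0.  Negative
    reflectance raises.
    """
    if all(isinstance(k, str) for k in b):
        vals = {int(str(k).lstrip("b")): float(v) for k, v in b.items()}
    else:
        vals = {int(k): float(v) for k, v in b.items()}
    missing = [w for w in BANDS if w not in vals]
    if missing:
        raise ValueError(f"missing bands {missing}")
    if any(v < 0 for v in vals.values()):
        raise ValueError("negative reflectance")
    b560, b650, b725, b808 = (vals[w] for w in BANDS)

    def _ratio(num: float, den: float) -> float:
        return num / den if abs(den) > _EPS else 0.0

    return {
        "ndvi": _ratio(b808 - b650, b808 + b650),
        "cvi": _ratio(b808, b560) * _ratio(b650, b560),
        "ci_re": _ratio(b808, b725) - 1.0 if b725 > _EPS else 0.0,
        "gndvi": _ratio(b808 - b560, b808 + b560),
        "ndgi": _ratio(b560 - b650, b560 + b650),
        "ndre": _ratio(b808 - b725, b808 + b725),
        "rvi": _ratio(b808, b650),
    }


@dataclass(frozen=True)
class GlcmConfig:
    """GLCM settings: Ng gray levels, pixel distance, offsets, symmetry.

    Default offsets are the four standard directions (0, 45, 90, 135 deg) at
    the configured distance; their counts are pooled before normalisation.
    """

    levels: int = 32
    distance: int = 1
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")

    def offsets(self) -> list[tuple[int, int]]:
        """(row, col) pixel offsets; 0 deg is horizontal, 90 deg vertical-up."""
        d = self.distance
        table = {0.0: (0, d), 45.0: (-d, d), 90.0: (-d, 0), 135.0: (-d, -d)}
        try:
            return [table[a] for a in self.angles]
        except KeyError as e:
            raise ValueError(f"unsupported angle {e.args[0]}; use 0/45/90/135") from None


def quantize(
    img: np.ndarray, cfg: GlcmConfig, mask: np.ndarray | None = None
) -> np.ndarray:
    """Equal-width quantisation of masked pixels into levels 0..Ng-1.

    Bins span [min, max] of the masked values; pixels outside the mask are
    marked -1 and never participate in co-occurrence pairs.
    """
    img = np.asarray(img, dtype=float)
    m = np.ones(img.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    vals = img[m]
    if vals.size == 0:
        raise ValueError("empty canopy: mask selects no pixels")
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values inside mask")
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise ValueError("constant region: cannot quantize")
    q = np.floor((img - lo) / (hi - lo) * cfg.levels).astype(np.int64)
    q = np.clip(q, 0, cfg.levels - 1)
    q[~m] = -1
    return q


def glcm(img_q: np.ndarray, cfg: GlcmConfig) -> np.ndarray:
    """Normalised gray-level co-occurrence matrix.

    Pairs (i, j) of quantised levels are counted at every configured offset;
    pairs with either pixel masked out (level -1) are skipped; with
    ``symmetric`` both orderings count.  Counts are pooled over offsets and
    normalised to sum to 1.
    """
    q = np.asarray(img_q)
    if q.max() >= cfg.levels:
        raise ValueError("quantized levels exceed cfg.levels")
    ng = cfg.levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    for dr, dc in cfg.offsets():
        a, b = _shifted_pairs(q, dr, dc)
        valid = (a >= 0) & (b >= 0)
        a, b = a[valid], b[valid]
        np.add.at(counts, (a, b), 1)
    if cfg.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid co-occurrence pairs")
    return counts / total


def _shifted_pairs(q: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=q.dtype), np.empty(0, dtype=q.dtype)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a.ravel(), b.ravel()


def texture_features(p: np.ndarray, atol: float = 1e-8) -> dict[str, float]:
    """Eight texture statistics of a normalised co-occurrence matrix.

    MEA = sum_ij i p(i,j);  VAR = sum_ij (i-MEA)^2 p(i,j);
    HOM = sum_ij p(i,j)/(1+(i-j)^2);  CON = sum_n n^2 P(|i-j|=n);
    DIS = sum_n n P(|i-j|=n);  ENT = -sum p ln p (0 ln 0 := 0);
    SEC = sum p^2;  COR = (sum_ij i j p - mu_x mu_y)/(sigma_x sigma_y).

    COR is set to 0 (degenerate marginal) when either marginal SD vanishes.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("p must be a square matrix")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError("p is not normalized")
    ng = p.shape[0]
    i = np.arange(ng)[:, None]
    j = np.arange(ng)[None, :]
    mea = float((i * p).sum())
    var = float(((i - mea) ** 2 * p).sum())
    absdiff = np.abs(i - j)
    hom = float((p / (1.0 + (i - j) ** 2)).sum())
    con = float((absdiff**2 * p).sum())
    dis = float((absdiff * p).sum())
    nz = p[p > 0]
    ent = float(-(nz * np.log(nz)).sum())
    sec = float((p**2).sum())
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    idx = np.arange(ng, dtype=float)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sd_x = float(np.sqrt(max(0.0, idx**2 @ px - mu_x**2)))
    sd_y = float(np.sqrt(max(0.0, idx**2 @ py - mu_y**2)))
    if sd_x < _EPS or sd_y < _EPS:
        cor = 0.0
    else:
        cor = float(((i * j * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    return {
        "mea": mea,
        "var": var,
        "hom": hom,
        "con": con,
        "dis": dis,
        "ent": ent,
        "sec": sec,
        "cor": cor,
    }


#: texture of a perfectly flat region: the GLCM collapses to a single cell
DEGENERATE_TEXTURE: dict[str, float] = {
    "mea": 0.0, "var": 0.0, "hom": 1.0, "con": 0.0,
    "dis": 0.0, "ent": 0.0, "sec": 1.0, "cor": 0.0,
}


def glcm_texture(
    img: np.ndarray, cfg: GlcmConfig | None = None, mask: np.ndarray | None = None
) -> dict[str, float]:
    """Quantise, build the GLCM and compute the eight texture statistics.

    A constant region (e.g. a noise-free synthetic canopy) has a one-cell
    co-occurrence matrix; the degenerate limits are returned rather than
    failing, so zero-noise scenes stay processable end to end.
    """
    cfg = cfg or GlcmConfig()
    try:
        q = quantize(img, cfg, mask)
    except ValueError as e:
        if "constant region" in str(e):
            return dict(DEGENERATE_TEXTURE)
        raise
    return texture_features(glcm(q, cfg))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient with degenerate-input guards."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has undefined correlation")
    return float(_sstats.pearsonr(x, y).statistic)


def build_feature_table(
    scenes: Sequence[SpectralScene],
    masks: Sequence[np.ndarray],
    sc_table: pd.DataFrame,
    glcm_cfg: GlcmConfig | None = None,
) -> pd.DataFrame:
    """Assemble the per-tree feature table.

    For every tree in every scene: mean canopy reflectance per band (canopy
    pixels = predicted mask intersected with the tree's label region),
    vegetation indices from those means, and per-band texture features from
    the GLCM over the tree's canopy pixels within its bounding box.  Joined
    with measured stomatal conductance; rows ordered by tree id.

    ``sc_table`` needs columns tree_id, stress, sc.
    """
    glcm_cfg = glcm_cfg or GlcmConfig()
    sc = sc_table.set_index("tree_id")
    rows = []
    missing: list[int] = []
    for scene, mask in zip(scenes, masks):
        m = np.asarray(mask).astype(bool)
        if m.shape != scene.shape:
            raise ValueError("mask shape differs from scene")
        if scene.labels is None:
            raise ValueError("scene carries no tree labels")
        for tid in sorted(int(t) for t in np.unique(scene.labels) if t > 0):
            tree_px = (scene.labels == tid) & m
            if not tree_px.any():
                raise ValueError(f"empty canopy for tree {tid}: mask removed all pixels")
            if tid not in sc.index:
                missing.append(tid)
                continue
            band_means = {b: float(a[tree_px].mean()) for b, a in scene.bands.items()}
            row: dict[str, object] = {
                "tree_id": tid,
                "stress": sc.loc[tid, "stress"],
                "b560": band_means[560],
                "b650": band_means[650],
                "b725": band_means[725],
                "b808": band_means[808],
            }
            row.update(compute_vis(band_means))
            rr, cc = np.nonzero(tree_px)
            sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
            for b, a in scene.bands.items():
                tex = glcm_texture(a[sl], glcm_cfg, tree_px[sl])
                for name, val in tex.items():
                    row[f"b{b}_{name}"] = val
            row["sc"] = float(sc.loc[tid, "sc"])
            rows.append(row)
    if missing:
        raise ValueError(f"missing Sc records for tree_ids {sorted(set(missing))}")
    df = pd.DataFrame(rows).sort_values("tree_id").reset_index(drop=True)
    return df


def correlation_table(table: pd.DataFrame, response: str = "sc") -> pd.DataFrame:
    """Pearson r of every numeric feature against the response."""
    out = []
    for col in table.columns:
        if col in ("tree_id", "stress", response):
            continue
        if not np.issubdtype(table[col].dtype, np.number):
            continue
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            r = np.nan
        else:
            r = pearson(x, table[response].to_numpy(dtype=float))
        out.append({"feature": col, "r": r})
    return pd.DataFrame(out)


#: candidate predictor pools for best-subset screening
VI_POOL: tuple[str, ...] = (
    "b560", "b650", "b725", "b808",
    "ndvi", "cvi", "ci_re", "gndvi", "ndgi", "ndre", "rvi",
)
TEXTURE_POOL: tuple[str, ...] = tuple(f"b808_{n}" for n in TEXTURE_NAMES)
COMBINED_POOL: tuple[str, ...] = VI_POOL + TEXTURE_POOL
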