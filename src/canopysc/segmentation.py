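"""Canopy/background segmentation and pixel-level scoring.

Two threshold families are implemented: (a) HSV gating — a pixel is canopy
iff its hue, saturation and value each fall inside a configured range — and
(b) Otsu's maximum between-class-variance threshold applied to a
visible-light vegetation-index transform of the RGB composite, with the
greener class labelled canopy.  Masks are scored against a reference mask
with intersection-over-reference accuracy (ACC), Matthews correlation
coefficient (MCC) and intersection over union (IOU).

ACC here is recall-like — the overlap with the reference canopy divided by
the reference canopy area — not overall pixel accuracy; plain pixel
accuracy is reported alongside for transparency.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from skimage import color, morphology

from canopysc.synthetic import SpectralScene

VISIBLE_VI_NAMES: tuple[str, ...] = (
    "EXG", "EXR", "EXGR", "NGBDI", "BGRI", "BRRI", "IPCA",
)


@dataclass(frozen=True)
class HsvThresholds:
    """Hue/saturation/value gates.  Hue in degrees, wrap-around allowed
    (h_range=(330, 30) accepts reds across the 0-degree seam)."""

    h_range: tuple[float, float] = (35.0, 120.0)
    s_range: tuple[float, float] = (0.15, 1.0)
    v_range: tuple[float, float] = (0.10, 1.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.s_range, self.v_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("s_range/v_range must satisfy 0 <= lo <= hi <= 1")
        for h in self.h_range:
            if not 0.0 <= h < 360.0:
                raise ValueError("hue bounds must lie in [0, 360)")


@dataclass
class CanopyMask:
    """Binary canopy mask with provenance (method and its parameters)."""

    mask: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class SegScore:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float       # percent, intersection over reference canopy
    pixel_acc: float  # percent, (tp+tn)/total
    mcc: float
    iou: float
    mcc_degenerate: bool = False


def _normalize_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must be an HxWx3 array")
    if rgb.max() > 1.5:  # 8-bit input
        rgb = rgb / 255.0
    return np.clip(rgb, 0.0, 1.0)


def _cleanup(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    selem = morphology.disk(radius)
    return morphology.closing(morphology.opening(mask, selem), selem).astype(bool)


def hsv_segment(
    rgb: np.ndarray,
    thr: HsvThresholds | None = None,
    cleanup_radius: int = 1,
) -> CanopyMask:
    """Gate each pixel on hue, saturation and value ranges."""
    thr = thr or HsvThresholds()
    rgb = _normalize_rgb(rgb)
    hsv = color.rgb2hsv(rgb)
    h = hsv[..., 0] * 360.0
    s = hsv[..., 1]
    v = hsv[..., 2]
    lo, hi = thr.h_range
    if lo <= hi:
        h_ok = (h >= lo) & (h <= hi)
    else:  # wrap across 0 degrees
        h_ok = (h >= lo) | (h <= hi)
    mask = (
        h_ok
        & (s >= thr.s_range[0]) & (s <= thr.s_range[1])
        & (v >= thr.v_range[0]) & (v <= thr.v_range[1])
    )
    mask = _cleanup(mask, cleanup_radius)
    return CanopyMask(mask=mask, method="hsv", params={"thresholds": thr, "cleanup_radius": cleanup_radius})


def visible_vi(rgb: np.ndarray, name: str) -> np.ndarray:
    """Visible-light vegetation-index transform of an RGB image.

    With chromatic coordinates r, g, b = R/(R+G+B) etc.:
      EXG = 2g - r - b;  EXR = 1.4r - g;  EXGR = EXG - EXR;
      NGBDI = (G-B)/(G+B);  BGRI = B/G;  BRRI = B/R;
      IPCA = 0.994|R-B| + 0.961|G-B| + 0.914|G-R|.
    Zero-denominator pixels map to 0.
    """
    key = name.upper()
    if key not in VISIBLE_VI_NAMES:
        raise ValueError(f"unknown visible VI {name!r}; choose from {VISIBLE_VI_NAMES}")
    rgb = _normalize_rgb(rgb)
    R, G, B = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = R + G + B
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(total > 0, R / total, 0.0)
        g = np.where(total > 0, G / total, 0.0)
        b = np.where(total > 0, B / total, 0.0)
        if key == "EXG":
            out = 2 * g - r - b
        elif key == "EXR":
            out = 1.4 * r - g
        elif key == "EXGR":
            out = (2 * g - r - b) - (1.4 * r - g)
        elif key == "NGBDI":
            out = np.where(G + B > 0, (G - B) / (G + B), 0.0)
        elif key == "BGRI":
            out = np.where(G > 0, B / G, 0.0)
        elif key == "BRRI":
            out = np.where(R > 0, B / R, 0.0)
        else:  # IPCA
            out = 0.994 * np.abs(R - B) + 0.961 * np.abs(G - B) + 0.914 * np.abs(G - R)
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the bin edge maximising between-class variance.

    The histogram spans [min, max] of the data with ``n_bins`` equal-width
    bins; the returned threshold is the bin edge t maximising
    sigma_b^2(t) = w0 w1 (mu0 - mu1)^2, ties broken toward the lowest edge.
    Constant images have no between-class structure and raise.
    """
    img = np.asarray(img, dtype=float).ravel()
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise ValueError("degenerate histogram: constant image")
    counts, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    w = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    cum_w = np.cumsum(w)
    cum_mu = np.cumsum(w * centers)
    mu_total = cum_mu[-1]
    # candidate cuts after bin t-1, i.e. threshold at edges[1..n_bins-1]
    w0 = cum_w[:-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mu[:-1] / w0
        mu1 = (mu_total - cum_mu[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)
    # lowest threshold within numerical tolerance of the maximum: cuts that
    # sweep across empty histogram bins tie exactly in exact arithmetic
    m = sigma_b.max()
    tol = 1e-9 * max(1.0, abs(m))
    best = int(np.argmax(sigma_b >= m - tol))
    return float(edges[best + 1])


def otsu_vi_segment(
    rgb: np.ndarray,
    vi_name: str = "EXG",
    n_bins: int = 256,
    cleanup_radius: int = 1,
) -> CanopyMask:
    """Otsu threshold on a visible-VI image; the greener class is canopy.

    Polarity is decided by comparing the mean excess-green (EXG) of the two
    threshold classes, so the rule is stable under index sign flips.
    """
    rgb = _normalize_rgb(rgb)
    vi = visible_vi(rgb, vi_name)
    t = otsu_threshold(vi, n_bins=n_bins)
    high = vi > t
    exg = visible_vi(rgb, "EXG")
    if not high.any() or high.all():
        mask = high
    else:
        mask = high if exg[high].mean() >= exg[~high].mean() else ~high
    mask = _cleanup(mask, cleanup_radius)
    return CanopyMask(
        mask=mask,
        method="otsu_vi",
        params={"vi": vi_name.upper(), "threshold": t, "n_bins": n_bins,
                "cleanup_radius": cleanup_radius},
    )


def score_mask(pred: CanopyMask | np.ndarray, truth: np.ndarray) -> SegScore:
    """Pixel confusion counts and ACC / pixel accuracy / MCC / IOU.

    ACC = 100 * |pred AND truth| / |truth| (intersection over the reference
    canopy); MCC from the confusion matrix with a 0-denominator flagged as
    degenerate (MCC := 0); IOU over the canopy class.
    """
    p = (pred.mask if isinstance(pred, CanopyMask) else np.asarray(pred)).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    total = tp + tn + fp + fn
    acc = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 0.0
    pixel_acc = 100.0 * (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    if degenerate:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    union = tp + fp + fn
    iou = tp / union if union > 0 else (1.0 if tp + fn == 0 else 0.0)
    return SegScore(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, pixel_acc=pixel_acc,
                    mcc=float(mcc), iou=float(iou), mcc_degenerate=degenerate)


def apply_mask(scene: SpectralScene, mask: CanopyMask | np.ndarray) -> SpectralScene:
    """Blank background pixels to NaN so they drop out of all statistics."""
    m = (mask.mask if isinstance(mask, CanopyMask) else np.asarray(mask)).astype(bool)
    if m.shape != scene.shape:
        raise ValueError("mask shape differs from scene")
    bands = {}
    for b, a in scene.bands.items():
        out = np.asarray(a, dtype=float).copy()
        out[~m] = np.nan
        bands[b] = out
    masked = dataclasses.replace(scene, bands=bands)
    return masked
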