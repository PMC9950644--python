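"""Gray-panel radiometric calibration: digital numbers to reflectance.

The sensor's raw digital number (DN) is proportional to radiance, so target
reflectance follows from a reference panel of known reflectance imaged in
the same frame: R1 = (DN1 / DN2) * R2, where DN2 and R2 are the panel's DN
and reflectance.  The panel DN is averaged over an interior sub-region to
avoid edge pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from canopysc.synthetic import BANDS, SpectralScene


@dataclass(frozen=True)
class PanelCalibration:
    """Per-band panel digital number (dn2) and known reflectance (r2)."""

    dn2: Mapping[int, float]
    r2: Mapping[int, float]

    def __post_init__(self) -> None:
        for b, v in self.dn2.items():
            if v <= 0:
                raise ValueError(f"panel DN for band {b} must be > 0 (got {v})")
        for b, v in self.r2.items():
            if not 0.0 < v <= 1.0:
                raise ValueError(f"panel reflectance for band {b} must be in (0, 1]")
        if set(self.dn2) != set(self.r2):
            raise ValueError("dn2 and r2 must cover the same bands")


@dataclass
class CalibrationResult:
    """Calibrated reflectance plus a count of clipped pixels per band."""

    bands: dict[int, np.ndarray]
    clipped: dict[int, int]

    @property
    def total_clipped(self) -> int:
        return sum(self.clipped.values())


def calibrate(
    dn1: Mapping[int, np.ndarray] | np.ndarray | float,
    cal: PanelCalibration,
    band: int | None = None,
    clip_max: float | None = 1.0,
) -> CalibrationResult | np.ndarray | float:
    """Convert DN to reflectance, R1 = (DN1/DN2) * R2, per band.

    ``dn1`` may be a mapping band -> raster (returns a CalibrationResult
    with clip counts) or a single raster/scalar with ``band`` given
    (returns the calibrated values directly).  Output is clipped to
    [0, clip_max]; pass ``clip_max=None`` to disable clipping (the raw
    linear transform, e.g. for linearity checks).
    """
    if isinstance(dn1, Mapping):
        out: dict[int, np.ndarray] = {}
        clipped: dict[int, int] = {}
        for b, arr in dn1.items():
            if b not in cal.dn2:
                raise ValueError(f"no panel calibration for band {b}")
            r, n = _calibrate_one(arr, cal.dn2[b], cal.r2[b], clip_max)
            out[b] = r
            clipped[b] = n
        return CalibrationResult(bands=out, clipped=clipped)
    if band is None:
        raise ValueError("band must be given when dn1 is not a mapping")
    if band not in cal.dn2:
        raise ValueError(f"no panel calibration for band {band}")
    r, _ = _calibrate_one(dn1, cal.dn2[band], cal.r2[band], clip_max)
    if np.isscalar(dn1):
        return float(r)
    return r


def _calibrate_one(
    dn: np.ndarray | float, dn2: float, r2: float, clip_max: float | None
) -> tuple[np.ndarray, int]:
    arr = np.asarray(dn, dtype=float)
    if (arr < 0).any():
        raise ValueError("DN values must be non-negative")
    refl = arr / dn2 * r2
    if clip_max is None:
        return refl, 0
    n_clipped = int((refl > clip_max).sum() + (refl < 0).sum())
    return np.clip(refl, 0.0, clip_max), n_clipped


def calibrate_scene(
    scene: SpectralScene, cal: PanelCalibration, clip_max: float = 1.0
) -> SpectralScene:
    """Calibrate a DN scene in place of its bands, returning a reflectance scene."""
    if scene.units != "dn":
        raise ValueError("scene is already in reflectance units")
    res = calibrate(scene.bands, cal, clip_max=clip_max)
    return dataclasses.replace(scene, bands=res.bands, units="reflectance")


def estimate_panel_dn(
    scene: SpectralScene,
    panel_reflectance: float | Mapping[int, float] | None = None,
    margin: float = 1.0 / 3.0,
) -> PanelCalibration:
    """Measure the panel DN as the mean over an inset panel sub-region.

    The panel rectangle is inset on every side by ``margin`` times its
    half-extent (default one third), excluding edge pixels the way a field
    operator samples the plate interior away from its rim.
    """
    if scene.panel_region is None:
        raise ValueError("scene has no panel region")
    if not 0.0 <= margin < 1.0:
        raise ValueError("margin must be in [0, 1)")
    r0, c0, r1, c1 = scene.panel_region
    dr = int(np.ceil(margin * (r1 - r0) / 2))
    dc = int(np.ceil(margin * (c1 - c0) / 2))
    rr0, rr1 = r0 + dr, r1 - dr
    cc0, cc1 = c0 + dc, c1 - dc
    if rr1 - rr0 < 1 or cc1 - cc0 < 1:
        raise ValueError("inset margin leaves an empty panel region")
    if panel_reflectance is None:
        if scene.panel_reflectance is None:
            raise ValueError("panel reflectance not provided and not on the scene")
        r2 = dict(scene.panel_reflectance)
    elif isinstance(panel_reflectance, Mapping):
        r2 = {int(b): float(v) for b, v in panel_reflectance.items()}
    else:
        r2 = {b: float(panel_reflectance) for b in BANDS}
    dn2 = {
        b: float(a[rr0:rr1, cc0:cc1].mean()) for b, a in scene.bands.items()
    }
    return PanelCalibration(dn2=dn2, r2={b: r2[b] for b in dn2})
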