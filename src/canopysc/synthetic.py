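"""Synthetic multispectral canopy scenes with known ground truth.

The generator emulates the study design the analysis chain assumes: potted
citrus trees under four irrigation treatments (T1 = full field capacity,
T2/T3/T4 = 80/65/50 % of field capacity), imaged in four narrow bands
(560, 650, 725, 808 nm) over a soil/pot background with a gray reference
panel in the frame.  Water stress raises red-edge (725 nm) and NIR (808 nm)
canopy reflectance while leaving the green and red bands essentially
unchanged, increases spatial texture (canopy roughening under wilting), and
lowers stomatal conductance.  Every scene carries an exact canopy mask and
per-tree stomatal-conductance values, so segmentation, feature extraction
and modelling can all be scored against truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

BANDS: tuple[int, ...] = (560, 650, 725, 808)

STRESS_LABELS: tuple[str, ...] = ("T1", "T2", "T3", "T4")

#: irrigation treatment -> fraction of field capacity
FC_FRACTION: dict[str, float] = {"T1": 1.00, "T2": 0.80, "T3": 0.65, "T4": 0.50}

#: mean canopy reflectance per treatment and band.  Green (560) and red
#: (650) are stress-invariant; red-edge (725) and NIR (808) rise with
#: stress.  Values are plausible for dense green citrus canopy; no field
#: measurement is claimed.
CANOPY_BAND_MEANS: dict[str, dict[int, float]] = {
    "T1": {560: 0.08, 650: 0.05, 725: 0.28, 808: 0.42},
    "T2": {560: 0.08, 650: 0.05, 725: 0.31, 808: 0.45},
    "T3": {560: 0.08, 650: 0.05, 725: 0.35, 808: 0.48},
    "T4": {560: 0.08, 650: 0.05, 725: 0.39, 808: 0.53},
}

#: dry sandy-loam soil / pot background: high red, low NIR relative to canopy
SOIL_BAND_MEANS: dict[int, float] = {560: 0.12, 650: 0.18, 725: 0.22, 808: 0.25}

#: multiplicative gain on the correlated-noise field inside the canopy, per
#: treatment — stressed canopies are rougher, so texture carries signal
NOISE_GAIN: dict[str, float] = {"T1": 1.0, "T2": 1.2, "T3": 1.4, "T4": 1.6}

#: stress also shortens the noise correlation length (leaf wilting breaks up
#: smooth canopy patches).  Texture statistics are computed on per-tree
#: min-max quantised images, which are invariant to pure amplitude scaling,
#: so the roughness signal must live in the field's spatial structure.
GRAIN_FACTOR: dict[str, float] = {"T1": 1.0, "T2": 0.85, "T3": 0.70, "T4": 0.55}

#: per-treatment stomatal conductance means (mol m-2 s-1) and the common
#: within-treatment SD.  Chosen so the pooled 120-sample statistics land
#: near mean 0.0154 / SD 0.0037 with every draw inside [0.0080, 0.0245].
SC_LEVEL_MEAN: dict[str, float] = {
    "T1": 0.0195,
    "T2": 0.0170,
    "T3": 0.0140,
    "T4": 0.0112,
}
SC_LEVEL_SD: float = 0.0022
SC_MIN: float = 0.0080
SC_MAX: float = 0.0245


@dataclass(frozen=True)
class StressLevel:
    """Irrigation treatment: label T1..T4 and its fraction of field capacity."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in FC_FRACTION:
            raise ValueError(f"unknown stress label {self.label!r}; expected one of {STRESS_LABELS}")

    @property
    def fc_fraction(self) -> float:
        return FC_FRACTION[self.label]

    @property
    def rank(self) -> int:
        """0 for T1 (no stress) .. 3 for T4 (severe stress)."""
        return STRESS_LABELS.index(self.label)


@dataclass
class SceneConfig:
    """Configuration of one synthetic scene.

    ``canopy_fraction`` is the exact fraction of image pixels covered by
    canopy (to one-pixel rasterisation); ``texture_grain`` is the
    correlation length (pixels) of the within-canopy noise field;
    ``noise_sd`` is the base reflectance noise SD before the per-treatment
    texture gain; ``rgb_noise_sd`` perturbs only the RGB composite used for
    colour segmentation.
    """

    image_size: tuple[int, int] = (128, 128)
    n_trees: int = 4
    stress_assignment: tuple[str, ...] = ("T1", "T2", "T3", "T4")
    canopy_fraction: float = 0.35
    panel_reflectance: float | Mapping[int, float] = 0.5
    noise_sd: float = 0.02
    rgb_noise_sd: float = 0.035
    texture_grain: float = 3.0
    shadow_radius: int = 2
    seed: int = 0
    band_means: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: CANOPY_BAND_MEANS
    )
    soil_means: Mapping[int, float] = field(default_factory=lambda: SOIL_BAND_MEANS)

    def panel_reflectance_by_band(self) -> dict[int, float]:
        if isinstance(self.panel_reflectance, Mapping):
            missing = [b for b in BANDS if b not in self.panel_reflectance]
            if missing:
                raise ValueError(f"panel_reflectance missing bands {missing}")
            return {b: float(self.panel_reflectance[b]) for b in BANDS}
        return {b: float(self.panel_reflectance) for b in BANDS}

    def validate(self) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        if not 0.0 < self.canopy_fraction < 1.0:
            raise ValueError("canopy_fraction must lie in (0, 1)")
        if self.noise_sd < 0 or self.rgb_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if len(self.stress_assignment) != self.n_trees:
            raise ValueError("stress_assignment must name one treatment per tree")
        for lab in self.stress_assignment:
            StressLevel(lab)
        for b, r in self.panel_reflectance_by_band().items():
            if not 0.0 < r <= 1.0:
                raise ValueError(f"panel reflectance for {b} nm must be in (0, 1]")
        panel = _panel_rect(self.image_size)
        panel_area = (panel[2] - panel[0]) * (panel[3] - panel[1])
        target = self.canopy_fraction * h * w
        free = h * w - panel_area
        if target > 0.85 * free:
            raise ValueError(
                "canopy_fraction incompatible with image_size: canopy would "
                "overlap the reference panel"
            )
        if target / self.n_trees < 16:
            raise ValueError(
                "canopy_fraction incompatible with n_trees and image_size: "
                "fewer than 16 pixels per tree"
            )


@dataclass
class SpectralScene:
    """Co-registered 4-band raster plus RGB composite and ground truth.

    ``bands`` maps wavelength (nm) to a 2-D array, reflectance in [0, 1]
    (float) or digital numbers (integer) depending on ``units``.
    ``labels`` assigns each pixel its tree id (1..n) or 0 for background.
    """

    bands: dict[int, np.ndarray]
    rgb: np.ndarray
    panel_region: tuple[int, int, int, int]
    units: str = "reflectance"
    truth_mask: np.ndarray | None = None
    labels: np.ndarray | None = None
    truth_sc: dict[int, float] | None = None
    stress_of_tree: dict[int, str] | None = None
    panel_reflectance: dict[int, float] | None = None

    def __post_init__(self) -> None:
        shapes = {b: a.shape for b, a in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"band rasters disagree in shape: {shapes}")
        shape = next(iter(shapes.values()))
        if self.rgb.shape[:2] != shape:
            raise ValueError("rgb composite shape differs from bands")
        if self.truth_mask is not None:
            if self.truth_mask.shape != shape:
                raise ValueError("truth_mask shape differs from bands")
            vals = np.unique(self.truth_mask)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError("truth_mask must be binary")
        if self.units == "reflectance":
            for b, a in self.bands.items():
                if a.min() < 0 or a.max() > 1:
                    raise ValueError(f"reflectance band {b} outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def sc_table(self) -> pd.DataFrame:
        if self.truth_sc is None:
            raise ValueError("scene carries no stomatal-conductance truth")
        rows = [
            {"tree_id": t, "stress": self.stress_of_tree[t], "sc": v}
            for t, v in sorted(self.truth_sc.items())
        ]
        return pd.DataFrame(rows)


def _panel_rect(image_size: tuple[int, int]) -> tuple[int, int, int, int]:
    """Gray reference panel: a square in the top-left corner."""
    h, w = image_size
    side = max(10, min(h, w) // 8)
    return (2, 2, 2 + side, 2 + side)


def _tree_blobs(
    cfg: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    """Rasterise trees as irregular blobs (union of random disks).

    Returns an integer label raster (0 background, 1..n_trees canopy) whose
    total canopy area equals round(canopy_fraction * H * W) exactly: each
    tree claims exactly its target pixel count, taken greedily from a
    disk-union score field so boundaries are irregular but compact.
    """
    h, w = cfg.image_size
    panel = _panel_rect(cfg.image_size)
    total_target = int(round(cfg.canopy_fraction * h * w))
    per_tree = np.full(cfg.n_trees, total_target // cfg.n_trees)
    per_tree[: total_target - per_tree.sum()] += 1

    rows, cols = np.mgrid[0:h, 0:w]
    forbidden = np.zeros((h, w), dtype=bool)
    forbidden[panel[0] - 2 : panel[2] + 2, panel[1] - 2 : panel[3] + 2] = True

    # tree centres on a jittered grid over the lower-right free area
    grid = int(np.ceil(np.sqrt(cfg.n_trees)))
    labels = np.zeros((h, w), dtype=np.int32)
    margin_r = panel[2] + 2
    cells = [(i, j) for i in range(grid) for j in range(grid)][: cfg.n_trees]
    for tid, (ci, cj) in enumerate(cells, start=1):
        r0 = np.sqrt(per_tree[tid - 1] / np.pi)
        cy = margin_r + (ci + 0.5) * (h - margin_r) / grid
        cx = (cj + 0.5) * w / grid
        cy += rng.uniform(-0.15, 0.15) * (h - margin_r) / grid
        cx += rng.uniform(-0.15, 0.15) * w / grid
        score = np.zeros((h, w))
        n_disks = 6
        for _ in range(n_disks):
            dy, dx = rng.normal(scale=0.55 * r0, size=2)
            rad = rng.uniform(0.7, 1.1) * r0
            d = np.hypot(rows - (cy + dy), cols - (cx + dx))
            score += np.maximum(0.0, 1.0 - d / rad)
        # tiny centre-distance tiebreak keeps the fallback region compact
        d_centre = np.hypot(rows - cy, cols - cx)
        score += 1e-6 / (1.0 + d_centre)
        score[forbidden | (labels > 0)] = -np.inf
        order = np.argsort(-score.ravel(), kind="stable")
        chosen = order[: per_tree[tid - 1]]
        lab_flat = labels.ravel()
        lab_flat[chosen] = tid
        labels = lab_flat.reshape(h, w)
    return labels


def _correlated_noise(
    shape: tuple[int, int], grain: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian field with correlation length ~grain pixels."""
    white = rng.standard_normal(shape)
    if grain <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=grain, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


# RGB composite transforms.  Canopy maps to a saturated green (hue ~100 deg),
# soil to a desaturated brown (hue ~20 deg), litter patches on the soil to a
# yellow-ochre, and pixels shadowed by the canopy to a very dark green.  The
# study's colour imagery is not reconstructable, so this is a stand-in with
# the colour structure HSV gating and greenness indices rely on.
def _compose_rgb(
    cfg: SceneConfig,
    bands: dict[int, np.ndarray],
    labels: np.ndarray,
    panel: tuple[int, int, int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = labels.shape
    canopy = labels > 0
    b560, b650 = bands[560], bands[650]

    rgb = np.empty((h, w, 3))
    # soil / pots
    rgb[..., 0] = 1.7 * b650 + 0.14
    rgb[..., 1] = 1.1 * b560 + 0.10
    rgb[..., 2] = 0.45 * b560 + 0.06

    # dry-litter patches: yellow-ochre clusters on the soil (hue just below
    # the green gate, low greenness) covering ~6 % of soil pixels
    litter_field = _correlated_noise((h, w), 2.5, rng)
    soil = ~canopy
    if soil.any():
        thr = np.quantile(litter_field[soil], 0.94)
        litter = soil & (litter_field > thr)
        rgb[litter, 0] = 0.55 + 0.4 * b650[litter]
        rgb[litter, 1] = 0.30 + 0.5 * b560[litter]
        rgb[litter, 2] = 0.06 + 0.2 * b560[litter]

    # canopy: green-dominant transform of the visible bands
    rgb[canopy, 0] = 0.9 * b650[canopy] + 0.13
    rgb[canopy, 1] = 2.4 * b560[canopy] + 0.22
    rgb[canopy, 2] = 0.5 * b560[canopy] + 0.02

    # cast shadow: a dark rim of soil pixels around each blob.  Greenish in
    # chromaticity (light filtered through leaves) but far too dark to be
    # canopy — a classic trap for greenness-only thresholds.
    if cfg.shadow_radius > 0:
        dil = ndimage.binary_dilation(canopy, iterations=cfg.shadow_radius)
        shadow = dil & soil
        rgb[shadow, 0] = 0.021
        rgb[shadow, 1] = 0.052
        rgb[shadow, 2] = 0.012

    if cfg.rgb_noise_sd > 0:
        rgb = rgb + rng.normal(scale=cfg.rgb_noise_sd, size=rgb.shape)

    # reference panel: neutral gray, no noise
    pr = float(np.mean(list(cfg.panel_reflectance_by_band().values())))
    rgb[panel[0] : panel[2], panel[1] : panel[3], :] = pr
    return np.clip(rgb, 0.0, 1.0)


def generate_scene(cfg: SceneConfig) -> SpectralScene:
    """Render one synthetic reflectance scene with full ground truth.

    Canopy pixels of a tree under treatment T carry that treatment's band
    means plus a correlated noise field whose amplitude grows with stress;
    soil is spectrally distinct (high red, low NIR); the gray panel region
    holds its nominal reflectance exactly.  Fixing ``cfg.seed`` reproduces
    the scene bit for bit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    panel = _panel_rect(cfg.image_size)

    labels = _tree_blobs(cfg, rng)
    canopy = labels > 0
    stress_of_tree = {
        tid: cfg.stress_assignment[tid - 1] for tid in range(1, cfg.n_trees + 1)
    }

    treatments = sorted(set(stress_of_tree.values()), key=STRESS_LABELS.index)

    bands: dict[int, np.ndarray] = {}
    panel_refl = cfg.panel_reflectance_by_band()
    for b in BANDS:
        base = np.full((h, w), cfg.soil_means[b], dtype=float)
        for tid, lab in stress_of_tree.items():
            base[labels == tid] = cfg.band_means[lab][b]
        if cfg.noise_sd > 0:
            # one field per treatment: amplitude grows and correlation
            # length shrinks with stress, so canopy texture carries signal
            noise = cfg.noise_sd * _correlated_noise((h, w), cfg.texture_grain, rng)
            for lab in treatments:
                f = _correlated_noise(
                    (h, w), cfg.texture_grain * GRAIN_FACTOR[lab], rng
                )
                in_treatment = np.isin(
                    labels, [t for t, s in stress_of_tree.items() if s == lab]
                )
                noise[in_treatment] = (
                    cfg.noise_sd * NOISE_GAIN[lab] * f[in_treatment]
                )
            base = base + noise
        base[panel[0] : panel[2], panel[1] : panel[3]] = panel_refl[b]
        bands[b] = np.clip(base, 0.0, 1.0)

    rgb = _compose_rgb(cfg, bands, labels, panel, rng)

    sc_seed = int(rng.integers(0, 2**31 - 1))
    truth_sc: dict[int, float] = {}
    for tid, lab in stress_of_tree.items():
        truth_sc[tid] = float(
            generate_sc(StressLevel(lab), 1, seed=sc_seed + tid)[0]
        )

    return SpectralScene(
        bands=bands,
        rgb=rgb,
        panel_region=panel,
        units="reflectance",
        truth_mask=canopy.astype(np.uint8),
        labels=labels,
        truth_sc=truth_sc,
        stress_of_tree=stress_of_tree,
        panel_reflectance=panel_refl,
    )


def generate_sc(
    stress: StressLevel | str,
    n: int,
    seed: int,
    mean: float | None = None,
    sd: float | None = None,
) -> np.ndarray:
    """Draw stomatal-conductance values (mol m-2 s-1) for one treatment.

    Truncated normal on [SC_MIN, SC_MAX] with treatment-specific mean;
    means decrease strictly from T1 to T4.  ``sd=0`` returns the exact
    treatment mean for every draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(stress, str):
        stress = StressLevel(stress)
    mu = SC_LEVEL_MEAN[stress.label] if mean is None else float(mean)
    sigma = SC_LEVEL_SD if sd is None else float(sd)
    if sigma < 0:
        raise ValueError("sd must be non-negative")
    if sigma == 0:
        return np.full(n, mu)
    a = (SC_MIN - mu) / sigma
    b = (SC_MAX - mu) / sigma
    rng = np.random.default_rng(seed)
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def generate_dn_scene(
    cfg: SceneConfig, panel_dn: int, max_dn: int = 65535
) -> SpectralScene:
    """Render a scene in raw digital numbers instead of reflectance.

    DN = round(R * panel_dn / R_panel) per band, so gray-panel calibration
    (R1 = DN1/DN2 * R2) recovers the underlying reflectance to within the
    quantisation error 0.5 * R_panel / panel_dn.
    """
    if panel_dn <= 0:
        raise ValueError("panel_dn must be a positive integer")
    scene = generate_scene(cfg)
    panel_refl = cfg.panel_reflectance_by_band()
    dn_bands: dict[int, np.ndarray] = {}
    for b, refl in scene.bands.items():
        scale = panel_dn / panel_refl[b]
        if scale > max_dn:  # reflectance 1.0 would overflow the DN range
            raise ValueError(
                f"panel_dn={panel_dn} with panel reflectance {panel_refl[b]} "
                f"overflows the {max_dn} DN range"
            )
        dn = np.rint(refl * scale).astype(np.uint16)
        dn_bands[b] = dn
    return dataclasses.replace(scene, bands=dn_bands, units="dn")


def generate_scene_batch(
    n_scenes: int,
    seed: int,
    cfg: SceneConfig | None = None,
) -> list[SpectralScene]:
    """Render ``n_scenes`` scenes with globally unique tree ids.

    Each scene uses the template config (default: one tree per treatment)
    with a derived seed; tree ids are renumbered so a batch of 30 four-tree
    scenes yields trees 1..120.
    """
    template = cfg if cfg is not None else SceneConfig()
    scenes: list[SpectralScene] = []
    next_id = 1
    for i in range(n_scenes):
        c = dataclasses.replace(template, seed=seed + i)
        s = generate_scene(c)
        remap = {old: next_id + k for k, old in enumerate(sorted(s.truth_sc))}
        labels = np.zeros_like(s.labels)
        for old, new in remap.items():
            labels[s.labels == old] = new
        s.labels = labels
        s.truth_sc = {remap[o]: v for o, v in s.truth_sc.items()}
        s.stress_of_tree = {remap[o]: v for o, v in s.stress_of_tree.items()}
        next_id += len(remap)
        scenes.append(s)
    return scenes


# ---------------------------------------------------------------------------
# feature-level generator: same statistical structure as the rendered scenes
# but sampled directly in feature space, for fast modelling experiments
# ---------------------------------------------------------------------------

#: per-band texture-feature model: (base, per-stress-rank slope, noise SD).
#: Only the 808 nm band carries a usable stress signal (its noise gain rises
#: with stress), matching what the rendered scenes produce.
_TEXTURE_MODEL: dict[str, tuple[float, float, float]] = {
    "mea": (15.5, 0.0, 0.6),
    "var": (6.0, 1.2, 0.8),
    "hom": (0.55, -0.03, 0.03),
    "con": (4.0, 0.9, 0.6),
    "dis": (1.4, 0.18, 0.15),
    "ent": (3.6, 0.12, 0.12),
    "sec": (0.060, -0.006, 0.004),
    "cor": (0.80, -0.05, 0.03),
}
_TEXTURE_BOUNDS: dict[str, tuple[float, float]] = {
    "hom": (1e-3, 1.0),
    "sec": (1e-4, 1.0),
    "cor": (-1.0, 1.0),
}


def generate_feature_table(
    n: int = 120,
    seed: int = 0,
    band_noise_sd: float = 0.012,
    sc_sd: float | None = None,
) -> pd.DataFrame:
    """Sample a per-tree feature table directly in feature space.

    Rows cycle through the four treatments.  Band means follow the scene
    generator's treatment means plus noise, vegetation indices are computed
    from those means, 808 nm texture features carry a stress trend (other
    bands are noise), and stomatal conductance comes from the same
    truncated-normal treatment model as the rendered scenes.
    """
    from canopysc.features import TEXTURE_NAMES, compute_vis

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        lab = STRESS_LABELS[i % 4]
        rank = STRESS_LABELS.index(lab)
        b = {
            band: max(
                1e-4,
                CANOPY_BAND_MEANS[lab][band] + rng.normal(scale=band_noise_sd),
            )
            for band in BANDS
        }
        row: dict[str, float | str | int] = {
            "tree_id": i + 1,
            "stress": lab,
            "b560": b[560],
            "b650": b[650],
            "b725": b[725],
            "b808": b[808],
        }
        row.update(compute_vis(b))
        for band in BANDS:
            signal = band == 808
            for name, (base, slope, sd) in _TEXTURE_MODEL.items():
                val = base + (slope * rank if signal else 0.0) + rng.normal(scale=sd)
                if name in _TEXTURE_BOUNDS:
                    lo, hi = _TEXTURE_BOUNDS[name]
                    val = float(np.clip(val, lo, hi))
                row[f"b{band}_{name}"] = val
        row["sc"] = float(
            generate_sc(lab, 1, seed=int(rng.integers(0, 2**31 - 1)), sd=sc_sd)[0]
        )
        rows.append(row)
    cols = ["tree_id", "stress", "b560", "b650", "b725", "b808"]
    df = pd.DataFrame(rows)
    ordered = cols + [c for c in df.columns if c not in cols]
    return df[ordered]


def plant_linear_response(
    table: pd.DataFrame,
    predictors: Sequence[str],
    beta: Sequence[float] | None = None,
    snr: float = 3.0,
    seed: int = 0,
    response: str = "sc",
) -> pd.DataFrame:
    """Replace the response with a known linear signal plus noise.

    The signal is ``X_std @ beta`` on z-scored predictors, rescaled to the
    stomatal-conductance range, with Gaussian noise of SD = SD(signal)/snr.
    Used for support-recovery and parameter-recovery experiments.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    X = table[list(predictors)].to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    b = np.ones(len(predictors)) if beta is None else np.asarray(beta, dtype=float)
    signal = Xs @ b
    signal_sd = signal.std()
    if signal_sd == 0:
        raise ValueError("planted signal is constant; check predictors/beta")
    sc_scale = 0.0035  # match the observed Sc spread
    y = 0.0154 + sc_scale * signal / signal_sd
    y = y + rng.normal(scale=sc_scale / snr, size=len(y))
    out = table.copy()
    out[response] = y
    return out
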