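"""Seeded echocardiogram-like phantom generator.

Renders apical 4-chamber-style test images: a sector-shaped fan field, four
dark elliptical blood pools, bright speckled myocardial walls, and optional
burned-in text-block overlays to exercise annotation removal.

The class contrast emulates hypertensive remodeling: HTN phantoms have
thicker walls (hypertrophy) and a longer speckle correlation length than
normal phantoms, so the class signal lives in both geometry and texture.
Speckle is the magnitude of a smoothed complex Gaussian field — the standard
fully-developed-speckle model with exactly Rayleigh marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .preprocess import RawFrame

# chamber layout in (row_frac, col_frac, semi_axis_row_frac, semi_axis_col_frac):
# ventricles near the apex (top), atria below, per an apical 4-chamber view.
_CHAMBERS = (
    (0.40, 0.40, 0.17, 0.11),  # left ventricle
    (0.38, 0.62, 0.13, 0.08),  # right ventricle
    (0.70, 0.42, 0.10, 0.09),  # left atrium
    (0.70, 0.62, 0.10, 0.08),  # right atrium
)


@dataclass
class OverlaySpec:
    """A burned-in rectangular text block: (row, col) origin, height, width."""

    row: int = 8
    col: int = 8
    height: int = 8
    width: int = 40
    intensity: float = 1.0


@dataclass
class PhantomConfig:
    """Geometry, texture and class-effect parameters of the phantom.

    Wall thickness is drawn per image from a class-dependent normal
    distribution (pixels); speckle correlation length (pixels) is also
    class-dependent so texture-only features carry class information.
    """

    size: int = 512
    sector_half_angle_deg: float = 45.0
    apex_row: int = 8
    radius_frac: float = 0.98
    chamber_level: float = 0.06
    tissue_level: float = 0.35
    wall_level: float = 0.80
    wall_thickness_mean: dict = field(
        default_factory=lambda: {"normal": 8.0, "htn": 14.0}
    )
    wall_thickness_sd: dict = field(default_factory=lambda: {"normal": 1.0, "htn": 1.5})
    speckle_corr_len: dict = field(default_factory=lambda: {"normal": 2.0, "htn": 3.0})
    center_jitter: float = 0.015
    axis_jitter: float = 0.05
    overlays: tuple[OverlaySpec, ...] = (OverlaySpec(),)
    seed: int = 0

    def __post_init__(self) -> None:
        for cls in ("normal", "htn"):
            if self.wall_thickness_mean[cls] <= 0:
                raise ValueError("wall thickness means must be positive")
        if self.wall_thickness_mean["normal"] >= self.wall_thickness_mean["htn"]:
            raise ValueError("normal wall thickness mean must be below htn mean")
        if self.size < 64:
            raise ValueError("impossible geometry: size too small")
        if not 0 < self.sector_half_angle_deg < 90:
            raise ValueError("impossible geometry: bad sector angle")


@dataclass
class PhantomRecord:
    """A rendered phantom with its ground truth."""

    image: RawFrame
    label: str
    wall_thickness: float
    wall_mask: np.ndarray
    overlay_mask: np.ndarray
    clean_image: np.ndarray  # overlay-free twin, equals image where mask is 0
    seed: int


def _sector_mask(cfg: PhantomConfig) -> np.ndarray:
    n = cfg.size
    rows, cols = np.mgrid[0:n, 0:n]
    dr = rows - cfg.apex_row
    dc = cols - n / 2.0
    radius = cfg.radius_frac * n
    dist = np.hypot(dr, dc)
    # angle from the straight-down direction
    angle = np.degrees(np.abs(np.arctan2(dc, np.maximum(dr, 1e-9))))
    inside = (dist <= radius) & (angle <= cfg.sector_half_angle_deg) & (dr >= 0)
    return inside


def _speckle(cfg: PhantomConfig, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean Rayleigh speckle field with Gaussian spatial correlation."""
    n = cfg.size
    re = ndimage.gaussian_filter(rng.standard_normal((n, n)), corr_len, mode="wrap")
    im = ndimage.gaussian_filter(rng.standard_normal((n, n)), corr_len, mode="wrap")
    mag = np.hypot(re, im)
    return mag / mag.mean()


def generate_phantom(cfg: PhantomConfig, label: str, seed: int) -> PhantomRecord:
    """Render one phantom; deterministic for a given (cfg, label, seed)."""
    if label not in ("normal", "htn"):
        raise ValueError("label must be 'normal' or 'htn'")
    rng = np.random.default_rng(seed)
    n = cfg.size
    sector = _sector_mask(cfg)

    thickness = float(
        np.clip(
            rng.normal(cfg.wall_thickness_mean[label], cfg.wall_thickness_sd[label]),
            1.0,
            None,
        )
    )

    base = np.full((n, n), cfg.tissue_level)
    wall_mask = np.zeros((n, n), dtype=bool)
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    for cr, cc, ar, ac in _CHAMBERS:
        cr = (cr + rng.uniform(-cfg.center_jitter, cfg.center_jitter)) * n
        cc = (cc + rng.uniform(-cfg.center_jitter, cfg.center_jitter)) * n
        ar = ar * n * (1 + rng.uniform(-cfg.axis_jitter, cfg.axis_jitter))
        ac = ac * n * (1 + rng.uniform(-cfg.axis_jitter, cfg.axis_jitter))
        q = np.sqrt(((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2)
        # approximate Euclidean distance outside the ellipse boundary
        dist_out = (q - 1.0) * min(ar, ac)
        wall = (dist_out > 0) & (dist_out <= thickness)
        chamber = q <= 1.0
        base[chamber] = cfg.chamber_level
        wall_mask |= wall
    wall_mask &= base > cfg.chamber_level  # walls do not intrude into pools
    base[wall_mask] = cfg.wall_level

    speckle = _speckle(cfg, cfg.speckle_corr_len[label], rng)
    img = base * speckle * sector
    img = img / img.max()

    clean = img.copy()
    overlay_mask = np.zeros((n, n), dtype=bool)
    for ov in cfg.overlays or ():
        r0, c0 = ov.row, ov.col
        overlay_mask[r0 : r0 + ov.height, c0 : c0 + ov.width] = True
        img[r0 : r0 + ov.height, c0 : c0 + ov.width] = ov.intensity
    wall_mask &= sector

    frame = RawFrame(pixels=img, source_id=f"phantom-{label}-{seed}", label=label)
    return PhantomRecord(
        image=frame,
        label=label,
        wall_thickness=thickness,
        wall_mask=wall_mask,
        overlay_mask=overlay_mask,
        clean_image=clean,
        seed=seed,
    )


def generate_dataset(
    cfg: PhantomConfig | None = None,
    n_normal: int = 51,
    n_htn: int = 61,
    seed: int = 0,
) -> list[PhantomRecord]:
    """Generate a labelled phantom dataset (default 51 normal + 61 HTN).

    Per-record seeds are derived deterministically from the master seed, so
    the same master seed always reproduces the identical dataset.
    """
    if n_normal < 1 or n_htn < 1:
        raise ValueError("counts must be >= 1")
    cfg = cfg if cfg is not None else PhantomConfig()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_normal + n_htn)]
    records = []
    for i in range(n_normal):
        records.append(generate_phantom(cfg, "normal", child_seeds[i]))
    for i in range(n_htn):
        records.append(generate_phantom(cfg, "htn", child_seeds[n_normal + i]))
    return records


def null_effect_config(cfg: PhantomConfig | None = None) -> PhantomConfig:
    """A copy of ``cfg`` with the class effect removed (identical classes).

    HTN parameters are set marginally above normal (the config requires a
    strict ordering) — within a small fraction of a pixel, i.e. no usable
    class signal.  Used for chance-level controls.
    """
    cfg = cfg if cfg is not None else PhantomConfig()
    return replace(
        cfg,
        wall_thickness_mean={"normal": 10.0, "htn": 10.0 + 1e-9},
        wall_thickness_sd={"normal": 1.2, "htn": 1.2},
        speckle_corr_len={"normal": 2.5, "htn": 2.5},
    )
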