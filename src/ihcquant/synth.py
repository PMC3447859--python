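"""Synthetic, ground-truthed inputs for the quantification pipeline.

No raw images or tables accompany the study this package models, so every
input is simulated with known ground truth.  Absolute levels (stain RGB
triplets, blob geometry, LDH totals, colony means, growth rates) are design
values; only the *ratios* between control and treated conditions are treated
as quantities to reproduce, and those ratios are encoded in named presets:

``ki67-fig3c``
    Proliferation-marker study: DAB-positive area fraction 0.25 (control)
    vs 0.16 (treated) — a 36% decrease.
``cd34-fig3d``
    Vessel-marker study: fraction 0.10 vs 0.076 — a 24% decrease.
``ldh-fig4a``
    LDH release step profiles: released/total 0.02 (control) at all times;
    0.15 from 3 h onward at 1 µM; 0.80 from 3 h onward at 7.5 µM.
``colony-fig1b``
    Soft-agar colony Poisson means: 30 per well untreated, 25% of control at
    0.1 µM, complete suppression at >= 2.5 µM.
``tumor-fig3a``
    Xenograft growth: treated endpoint mean volume = 0.45x control, with
    lognormal between-mouse dispersion (CV 0.6).

Every generator is a pure function of its parameters and an integer seed:
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

from ihcquant.segment import RGBField
from ihcquant.stats import FourPLFit

__all__ = [
    "SynthIHCConfig",
    "GroundTruth",
    "SynthPreset",
    "PRESETS",
    "TABLE1_GI50_UM",
    "generate_ihc_field",
    "generate_flatfield",
    "generate_ihc_study",
    "generate_dose_response",
    "generate_ldh_plate",
    "generate_tumor_series",
    "generate_colony_counts",
]

#: Published GI50 values (µM) used as generating truths for synthetic
#: proliferation curves; the fitting machinery must recover them.
TABLE1_GI50_UM = {"PC3": 1.24, "LNCAP": 0.31, "MDA-MB231": 8.06}


@dataclass(frozen=True)
class SynthIHCConfig:
    """Parameters of one synthetic DAB/hematoxylin brightfield field.

    Stain colors default to literature-typical hues rendered as RGB in
    [0,1]: DAB brown (0.42, 0.28, 0.14), hematoxylin blue (0.35, 0.35,
    0.65) over a near-white background.  ``illum_gradient`` is the
    peak-to-trough ratio of the smooth multiplicative illumination field
    (1 = perfectly even).  ``noise_sd`` is the SD of zero-mean Gaussian
    intensity noise added per channel.
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 0.5  # µm/px
    target_fraction: float = 0.25
    n_blobs: int = 150
    blob_radius_mean: float = 12.0
    blob_radius_sd: float = 3.0
    n_nuclei: int = 150
    nucleus_radius: float = 4.0
    dab_rgb: tuple[float, float, float] = (0.42, 0.28, 0.14)
    hematoxylin_rgb: tuple[float, float, float] = (0.35, 0.35, 0.65)
    background_rgb: tuple[float, float, float] = (0.92, 0.90, 0.90)
    illum_gradient: float = 1.2
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fraction <= 0.9):
            raise ValueError("target_fraction must be in [0, 0.9]")
        for name in ("dab_rgb", "hematoxylin_rgb", "background_rgb"):
            if not all(0.0 <= c <= 1.0 for c in getattr(self, name)):
                raise ValueError(f"{name} components must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.illum_gradient < 1:
            raise ValueError("illum_gradient must be >= 1")
        if self.width < 32 or self.height < 32:
            raise ValueError("fields must be at least 32x32 pixels")


@dataclass(frozen=True)
class GroundTruth:
    """True positive mask of a synthetic field plus derived scalars."""

    mask: np.ndarray  # boolean H x W
    realized_fraction: float
    object_count: int


@dataclass(frozen=True)
class SynthPreset:
    """Named parameter bundle pinning one study condition's effect size."""

    name: str
    kind: str  # "ihc" | "ldh" | "colony" | "tumor"
    parameters: dict
    note: str = ""


PRESETS: dict[str, SynthPreset] = {
    "ki67-fig3c": SynthPreset(
        name="ki67-fig3c",
        kind="ihc",
        parameters={"control_fraction": 0.25, "treated_fraction": 0.16},
        note="proliferation-marker area study; design decrease 36%",
    ),
    "cd34-fig3d": SynthPreset(
        name="cd34-fig3d",
        kind="ihc",
        parameters={"control_fraction": 0.10, "treated_fraction": 0.076},
        note="vessel-marker area study; design decrease 24%",
    ),
    "ldh-fig4a": SynthPreset(
        name="ldh-fig4a",
        kind="ldh",
        parameters={
            # condition -> (fraction before 3 h, fraction from 3 h onward)
            "profiles": {
                "control": (0.02, 0.02),
                "1uM": (0.06, 0.15),
                "7.5uM": (0.30, 0.80),
            },
            "step_time_h": 3.0,
            "total_signal": 2.0,  # absorbance a.u., invented absolute level
        },
        note="LDH release step profiles; 15% and 80% of total from 3 h",
    ),
    "colony-fig1b": SynthPreset(
        name="colony-fig1b",
        kind="colony",
        parameters={
            "doses_uM": (0.0, 0.1, 1.0, 2.5, 5.0),
            "means": {0.0: 30.0, 0.1: 7.5, 1.0: 1.5},
            "zero_above_uM": 2.5,
        },
        note="Poisson colonies/well; 75% inhibition at 0.1 µM, none >= 2.5 µM",
    ),
    "tumor-fig3a": SynthPreset(
        name="tumor-fig3a",
        kind="tumor",
        parameters={
            "volume_ratio": 0.45,
            "dispersion_cv": 0.6,
            "start_volume_mm3": 25.0,
            "control_endpoint_mm3": 500.0,
            "duration_days": 47.0,
            "aspect_ratio": 1.3,  # R2 / R1 of the spheroid
        },
        note="xenograft growth; design endpoint inhibition 55%",
    ),
}


def _get_preset(name: str, kind: str) -> SynthPreset:
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    if preset.kind != kind:
        raise ValueError(f"preset {name!r} is of kind {preset.kind!r}, not {kind!r}")
    return preset


# --------------------------------------------------------------------------
# illumination

def _smooth_unit_surface(width: int, height: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random surface normalized to [0, 1] (low-order cosine mixture)."""
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    xn = xx / width
    yn = yy / height
    u = np.zeros((height, width))
    for _ in range(3):
        fx, fy = rng.uniform(-1.0, 1.0, size=2)  # <= one cycle across field
        phase = rng.uniform(0, 2 * np.pi)
        u += rng.uniform(0.5, 1.0) * np.cos(2 * np.pi * (fx * xn + fy * yn) + phase)
    u -= u.min()
    peak = u.max()
    if peak > 0:
        u /= peak
    return u


def _illumination(width, height, gradient, rng) -> np.ndarray:
    """Multiplicative field with max 1, min 1/gradient (ratio == gradient)."""
    if gradient == 1.0:
        return np.ones((height, width))
    u = _smooth_unit_surface(width, height, rng)
    return 1.0 - (1.0 - 1.0 / gradient) * (1.0 - u)


def generate_flatfield(width: int, height: int, illum_gradient: float, seed: int) -> RGBField:
    """Light-field image of the empty optical path (for flat-field division).

    The returned image is a smooth multiplicative illumination surface with
    max/min pixel ratio equal to ``illum_gradient``, replicated over the
    three channels.
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    if illum_gradient < 1:
        raise ValueError("illum_gradient must be >= 1")
    rng = np.random.default_rng(seed)
    illum = _illumination(width, height, illum_gradient, rng)
    pixels = np.repeat(illum[:, :, None], 3, axis=2)
    return RGBField(pixels=pixels, pixel_size=1.0, field_id=f"flatfield-{seed}")


# --------------------------------------------------------------------------
# IHC fields

def _ellipse_mask(shape, cx, cy, a, b, theta) -> np.ndarray:
    h, w = shape
    x0 = max(int(cx - max(a, b)) - 2, 0)
    x1 = min(int(cx + max(a, b)) + 3, w)
    y0 = max(int(cy - max(a, b)) - 2, 0)
    y1 = min(int(cy + max(a, b)) + 3, h)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    sub = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = sub
    return mask


def generate_ihc_field(config: SynthIHCConfig) -> tuple[RGBField, GroundTruth]:
    """One synthetic DAB/hematoxylin brightfield field with ground truth.

    Composition: near-white background, circular hematoxylin nuclei, then
    elliptical DAB blobs painted on top (so nuclei never contribute to the
    positive mask), a smooth multiplicative illumination field, and clipped
    Gaussian intensity noise.  Blobs are added one at a time until the
    positive area reaches the requested fraction; the final blob is shrunk
    by bisection so the realized fraction lands within 10% relative of the
    target (in practice well within 1%).

    The illumination surface is reproducible independently via
    ``generate_flatfield(width, height, illum_gradient, seed)`` with the
    same seed, mimicking a light-field acquisition of the optical path.

    Raises
    ------
    ValueError
        When ``target_fraction`` cannot be reached with the configured blob
        count and geometry.
    """
    cfg = config
    h, w = cfg.height, cfg.width
    # illumination drawn from its own generator so the companion flatfield
    # (same seed) matches exactly
    illum = _illumination(w, h, cfg.illum_gradient, np.random.default_rng(cfg.seed))
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))

    mask = np.zeros((h, w), dtype=bool)
    target_px = cfg.target_fraction * h * w
    if cfg.target_fraction > 0 and cfg.n_blobs > 0:
        max_attempts = max(12, 12 * cfg.n_blobs)
        attempts = 0
        # 0.5% landing tolerance: rasterization can leave a shrunk blob just
        # short of the target, which must not trigger an extra speck blob
        while mask.sum() < 0.995 * target_px and attempts < max_attempts:
            attempts += 1
            a = max(2.0, rng.normal(cfg.blob_radius_mean, cfg.blob_radius_sd))
            b = max(2.0, rng.normal(cfg.blob_radius_mean, cfg.blob_radius_sd))
            theta = rng.uniform(0, np.pi)
            margin = max(a, b) + 1
            if 2 * margin >= min(h, w):
                raise ValueError(
                    "blob radius too large for the field; reduce "
                    "blob_radius_mean or enlarge the field"
                )
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            blob = _ellipse_mask((h, w), cx, cy, a, b, theta)
            overshoot = (mask | blob).sum() - target_px
            if overshoot > 0:
                # shrink the final blob toward the target (monotone in scale)
                lo, hi = 0.0, 1.0
                for _ in range(30):
                    mid = 0.5 * (lo + hi)
                    trial = _ellipse_mask((h, w), cx, cy, a * mid, b * mid, theta)
                    if (mask | trial).sum() > target_px:
                        hi = mid
                    else:
                        lo = mid
                blob = _ellipse_mask((h, w), cx, cy, a * hi, b * hi, theta)
            mask |= blob
        realized = mask.sum() / (h * w)
        if abs(realized - cfg.target_fraction) > 0.1 * cfg.target_fraction:
            raise ValueError(
                f"target_fraction {cfg.target_fraction:g} unreachable with "
                f"n_blobs={cfg.n_blobs}, blob_radius_mean={cfg.blob_radius_mean:g} "
                f"(realized {realized:g} after {attempts} blobs)"
            )

    img = np.empty((h, w, 3))
    img[:] = cfg.background_rgb
    for _ in range(cfg.n_nuclei):
        r = cfg.nucleus_radius
        cx = rng.uniform(r, w - r)
        cy = rng.uniform(r, h - r)
        nuc = _ellipse_mask((h, w), cx, cy, r, r, 0.0)
        img[nuc] = cfg.hematoxylin_rgb
    img[mask] = cfg.dab_rgb

    img *= illum[:, :, None]
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    gt = GroundTruth(
        mask=mask,
        realized_fraction=float(mask.sum()) / (h * w),
        object_count=int(measure.label(mask, connectivity=2).max()),
    )
    field = RGBField(pixels=img, pixel_size=cfg.pixel_size,
                     field_id=f"synth-{cfg.seed}")
    return field, gt


def generate_ihc_study(
    preset: str | SynthPreset,
    n_fields_per_group: int = 6,
    seed: int = 0,
    base_config: SynthIHCConfig | None = None,
) -> tuple[list[tuple[RGBField, GroundTruth]], list[tuple[RGBField, GroundTruth]]]:
    """Control and treated field sets for a two-group staining study.

    Six fields per group by default (the conventional number of randomly
    selected microscopic fields per section).  Per-field seeds are derived
    deterministically from the master seed, so the whole study is a pure
    function of (preset, n, seed).
    """
    if n_fields_per_group < 1:
        raise ValueError("n_fields_per_group must be >= 1")
    if isinstance(preset, str):
        preset = _get_preset(preset, "ihc")
    base = base_config or SynthIHCConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_fields_per_group)
    groups: list[list[tuple[RGBField, GroundTruth]]] = []
    for gi, key in enumerate(("control_fraction", "treated_fraction")):
        fields = []
        for i in range(n_fields_per_group):
            s = int(child_seeds[gi * n_fields_per_group + i] >> 1)
            cfg = replace(base, target_fraction=preset.parameters[key], seed=s)
            field, gt = generate_ihc_field(cfg)
            group = "control" if gi == 0 else "treated"
            field = replace(field, field_id=f"{preset.name}-{group}-{i}")
            fields.append((field, gt))
        groups.append(fields)
    return groups[0], groups[1]


# --------------------------------------------------------------------------
# tabular generators

def generate_dose_response(
    fit: FourPLFit,
    doses: Sequence[float],
    cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    cell_line: str = "PC3",
) -> pd.DataFrame:
    """Replicate cell counts from a 4PL curve with multiplicative CV noise.

    Counts are ``fit.predict(dose) * (1 + Normal(0, cv))`` floored at zero;
    the dose-0 rows define the untreated control.  Columns:
    ``cell_line, dose_uM, replicate, count``.
    """
    doses = list(doses)
    if not doses:
        raise ValueError("dose list must not be empty")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        y = fit.predict(d)
        for rep in range(n_reps):
            noisy = y * (1.0 + rng.normal(0.0, cv)) if cv > 0 else y
            rows.append((cell_line, float(d), rep + 1, max(0.0, float(noisy))))
    return pd.DataFrame(rows, columns=["cell_line", "dose_uM", "replicate", "count"])


def generate_ldh_plate(
    preset: str | SynthPreset,
    timepoints: Sequence[float] = (0.5, 3.0, 24.0, 48.0),
    seed: int = 0,
    noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Released/total LDH signals per condition and timepoint.

    The released fraction follows the preset's step profile (a lower early
    fraction switching to the plateau fraction at ``step_time_h``); optional
    multiplicative noise is applied to the released signal.  Columns:
    ``condition, time_h, released, total``.
    """
    if isinstance(preset, str):
        preset = _get_preset(preset, "ldh")
    p = preset.parameters
    total = float(p["total_signal"])
    if total <= 0:
        raise ValueError("preset total_signal must be positive")
    if any(t <= 0 for t in timepoints):
        raise ValueError("timepoints must be positive hours")
    for cond, (early, late) in p["profiles"].items():
        if not (0.0 <= early <= 1.0 and 0.0 <= late <= 1.0):
            raise ValueError(f"released fraction outside [0,1] for {cond!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, (early, late) in p["profiles"].items():
        for t in timepoints:
            frac = late if t >= p["step_time_h"] else early
            released = frac * total
            if noise_cv > 0:
                released *= 1.0 + rng.normal(0.0, noise_cv)
                released = min(max(released, 0.0), total)
            rows.append((cond, float(t), released, total))
    return pd.DataFrame(rows, columns=["condition", "time_h", "released", "total"])


def generate_tumor_series(
    preset: str | SynthPreset,
    n_mice_per_group: int = 8,
    n_timepoints: int = 14,
    seed: int = 0,
) -> pd.DataFrame:
    """Caliper measurements for a two-group xenograft growth experiment.

    Each mouse grows exponentially from the enrollment volume to an
    endpoint volume ``group_mean * L`` where ``L`` is lognormal with mean 1
    and the preset's coefficient of variation — reproducing the large
    between-mouse dispersion typical of xenografts.  Treated endpoint mean
    over control endpoint mean equals the preset ratio in expectation.
    Radii assume a prolate spheroid of fixed aspect ratio, so R1 <= R2 in
    every emitted row.  Columns: ``group, mouse, day, R1_mm, R2_mm``.
    """
    if isinstance(preset, str):
        preset = _get_preset(preset, "tumor")
    p = preset.parameters
    if n_mice_per_group < 2:
        raise ValueError("need >= 2 mice per group (SEM undefined otherwise)")
    if n_timepoints < 1:
        raise ValueError("need >= 1 timepoint")
    ratio = float(p["volume_ratio"])
    if ratio <= 0:
        raise ValueError("preset volume_ratio must be positive")
    cv = float(p["dispersion_cv"])
    v0 = float(p["start_volume_mm3"])
    duration = float(p["duration_days"])
    rho = float(p["aspect_ratio"])
    endpoint_means = {
        "control": float(p["control_endpoint_mm3"]),
        "treated": float(p["control_endpoint_mm3"]) * ratio,
    }
    days = np.linspace(0.0, duration, n_timepoints)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        mu = -0.5 * sigma**2  # lognormal with mean exactly 1
    rng = np.random.default_rng(seed)
    rows = []
    for group, v_end_mean in endpoint_means.items():
        for mouse in range(n_mice_per_group):
            mult = float(np.exp(rng.normal(mu, sigma))) if cv > 0 else 1.0
            v_end = v_end_mean * mult
            rate = np.log(v_end / v0) / duration
            for day in days:
                v = v0 * np.exp(rate * day)
                r1 = (3.0 * v / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
                r2 = rho * r1
                rows.append((group, f"{group}-{mouse + 1}", float(day),
                             float(r1), float(r2)))
    return pd.DataFrame(rows, columns=["group", "mouse", "day", "R1_mm", "R2_mm"])


def generate_colony_counts(
    preset: str | SynthPreset,
    doses: Sequence[float] | None = None,
    n_wells: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson colony counts per well at each dose.

    Per-dose means come from the preset; doses at or above the preset's
    suppression dose have mean zero (complete inhibition of colony
    formation).  Columns: ``dose_uM, well, count``.
    """
    if isinstance(preset, str):
        preset = _get_preset(preset, "colony")
    p = preset.parameters
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if doses is None:
        doses = p["doses_uM"]
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        if d >= p["zero_above_uM"]:
            mean = 0.0
        else:
            try:
                mean = float(p["means"][float(d)])
            except KeyError:
                raise KeyError(f"preset {preset.name!r} defines no mean for dose {d} µM")
        if mean < 0:
            raise ValueError("colony mean must be >= 0")
        counts = rng.poisson(mean, size=n_wells) if mean > 0 else np.zeros(n_wells, int)
        for wi, c in enumerate(counts):
            rows.append((float(d), wi + 1, int(c)))
    return pd.DataFrame(rows, columns=["dose_uM", "well", "count"])
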