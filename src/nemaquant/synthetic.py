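"""Seeded generators for stained-section images, enzymatic-OD panels and
staining-kinetics traces with exact ground truth.

No stained-section micrographs are publicly deposited for this kind of
experiment, so every pipeline stage is validated on synthetic data whose
ground truth is known by construction:

* ``generate_section`` paints a wormlike section (counterstain blue) with
  red lipid droplets on a bright background, with per-tissue red-pixel
  fractions enforced by exact pixel bookkeeping;
* ``generate_od_panel`` paints tissue compartments whose intensity is
  background x transmittance, so the true OD is -log10(transmittance);
* ``generate_kinetics`` samples a logistic stain-accumulation curve with
  Gaussian OD noise.

The canonical section presets encode the strain contrasts used for
validation: ``daf2`` doubles every ``n2`` lipid fraction and ``lpd3``
halves it, so two-fold and 50% contrasts are ground truth, not
measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import KineticsTrace, _logistic
from .roi import Roi, RoiSet, roi_mask


class GenerationError(ValueError):
    pass


@dataclass
class TissueCompartment:
    """An elliptical tissue compartment: center (cx, cy) and semi-axes
    (ax, ay) in pixels, as fractions of image width/height."""

    tissue: str
    cx: float
    cy: float
    ax: float
    ay: float


@dataclass
class SectionPreset:
    name: str
    tissue_layout: list[TissueCompartment]
    lipid_fraction: dict[str, float]
    counterstain_rgb: tuple[int, int, int] = (70, 80, 170)
    lipid_rgb: tuple[int, int, int] = (180, 40, 50)
    background_rgb: tuple[int, int, int] = (245, 245, 245)
    noise_sigma: float = 8.0

    def __post_init__(self) -> None:
        for tissue, f in self.lipid_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"lipid_fraction[{tissue!r}]={f} outside [0,1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class KineticsPreset:
    name: str
    stain: str
    A: float
    t_mid: float
    k: float
    baseline: float
    sampling_interval: float   # minutes
    duration: float            # minutes
    noise_sigma_od: float
    truncate_before: float = 0.0   # drop frames earlier than this, minutes


@dataclass
class GroundTruth:
    """Exact per-output truth recorded by the generators."""

    lipid_fraction: dict[str, float] = field(default_factory=dict)
    section_area_px: int = 0
    transmittance: dict[str, float] = field(default_factory=dict)
    od: dict[str, float] = field(default_factory=dict)
    onset_min: float = math.nan
    end_min: float = math.nan

    def to_dict(self) -> dict:
        out: dict = {}
        if self.lipid_fraction:
            out["lipid_fraction"] = self.lipid_fraction
            out["section_area_px"] = self.section_area_px
        if self.transmittance:
            out["transmittance"] = self.transmittance
            out["od"] = self.od
        if not math.isnan(self.onset_min):
            out["onset_min"] = self.onset_min
            out["end_min"] = self.end_min
        return out


# Layout shared by the section presets: a longitudinal wormlike section with
# intestine, distal and proximal germline compartments (the three tissues
# annotated for lipid quantification), all expressed as image fractions.
_WORM_LAYOUT = [
    TissueCompartment("intestine", 0.32, 0.42, 0.17, 0.16),
    TissueCompartment("germline_distal", 0.68, 0.34, 0.14, 0.11),
    TissueCompartment("germline_proximal", 0.66, 0.64, 0.15, 0.12),
]

_N2_FRACTIONS = {
    "intestine": 0.30,
    "germline_proximal": 0.20,
    "germline_distal": 0.08,
}

SECTION_PRESETS: dict[str, SectionPreset] = {
    "n2": SectionPreset("n2", list(_WORM_LAYOUT), dict(_N2_FRACTIONS)),
    "daf2": SectionPreset(
        "daf2", list(_WORM_LAYOUT),
        {t: 2.0 * f for t, f in _N2_FRACTIONS.items()}),
    "lpd3": SectionPreset(
        "lpd3", list(_WORM_LAYOUT),
        {t: 0.5 * f for t, f in _N2_FRACTIONS.items()}),
}

KINETICS_PRESETS: dict[str, KineticsPreset] = {
    # onset = t_mid - 2/k: 5 min (NADH), 10 min (SDH), 120 min (COX)
    "nadh_20C": KineticsPreset("nadh_20C", "NADH", A=0.60, t_mid=7.0, k=1.0,
                               baseline=0.02, sampling_interval=0.25,
                               duration=20.0, noise_sigma_od=0.005),
    "sdh_20C": KineticsPreset("sdh_20C", "SDH", A=0.55, t_mid=13.0, k=2.0 / 3.0,
                              baseline=0.02, sampling_interval=0.25,
                              duration=30.0, noise_sigma_od=0.005),
    # COX: slow reaction, lighter DAB product, first minutes unrecorded
    # because the slide must be wax-sealed before mounting.
    "cox_20C": KineticsPreset("cox_20C", "COX", A=0.25, t_mid=135.0, k=2.0 / 15.0,
                              baseline=0.02, sampling_interval=1.0,
                              duration=300.0, noise_sigma_od=0.005,
                              truncate_before=10.0),
}


def _ellipse_roi(comp: TissueCompartment, width: int, height: int,
                 name: str) -> Roi:
    cx, cy = comp.cx * width, comp.cy * height
    ax, ay = comp.ax * width, comp.ay * height
    # oval ROI stored as bounding-box corners, matching roi_mask's half-open
    # center convention so the ROI reproduces the painted compartment exactly
    x1 = round(cx - ax)
    y1 = round(cy - ay)
    x2 = round(cx + ax)
    y2 = round(cy + ay)
    return Roi(name=name, tissue=comp.tissue, shape_kind="oval",
               vertices=[(x1, y1), (x2, y2)], source="synthetic")


def generate_section(preset: SectionPreset | str, width: int = 256,
                     height: int = 192, seed: int = 0,
                     ) -> tuple[np.ndarray, RoiSet, GroundTruth]:
    """Render one stained section with exact per-tissue red fractions.

    Disk droplets (radius 1-4 px) are placed by a seeded uniform point
    process inside each compartment until the tissue's red-pixel count
    reaches ``lipid_fraction`` of the compartment area, trimming the last
    droplet pixel-by-pixel so the achieved fraction is exact.  Gaussian
    channel noise is added last and clipped to [0, 255].
    """
    if isinstance(preset, str):
        preset = SECTION_PRESETS[preset]
    rng = np.random.default_rng(seed)

    section_outline = Roi(
        name="section", tissue="other", shape_kind="oval",
        vertices=[(round(0.04 * width), round(0.10 * height)),
                  (round(0.96 * width), round(0.90 * height))],
        source="synthetic")
    section_mask = roi_mask(section_outline, width, height)

    image = np.empty((height, width, 3), dtype=float)
    image[:] = preset.background_rgb
    image[section_mask] = preset.counterstain_rgb

    red_mask = np.zeros((height, width), dtype=bool)
    rois: list[Roi] = []
    achieved: dict[str, float] = {}

    for comp in preset.tissue_layout:
        roi = _ellipse_roi(comp, width, height, name=comp.tissue)
        rois.append(roi)
        comp_mask = roi_mask(roi, width, height) & section_mask
        area = int(comp_mask.sum())
        frac = preset.lipid_fraction.get(comp.tissue, 0.0)
        if frac > 0 and area == 0:
            raise GenerationError(
                f"tissue {comp.tissue!r} has no pixels inside the section; "
                f"cannot place lipid at fraction {frac}"
            )
        target = int(round(frac * area))
        if target > area:
            raise GenerationError(
                f"tissue {comp.tissue!r}: target {target} red px exceeds "
                f"compartment area {area}"
            )
        count = 0
        comp_red = np.zeros_like(comp_mask)
        guard = 0
        while count < target:
            guard += 1
            if guard > 100_000:
                raise GenerationError(
                    f"tissue {comp.tissue!r}: cannot reach fraction {frac}"
                )
            r = int(rng.integers(1, 5))
            cx = rng.uniform(comp.cx * width - comp.ax * width,
                             comp.cx * width + comp.ax * width)
            cy = rng.uniform(comp.cy * height - comp.ay * height,
                             comp.cy * height + comp.ay * height)
            x0 = max(int(cx) - r - 1, 0)
            x1b = min(int(cx) + r + 2, width)
            y0 = max(int(cy) - r - 1, 0)
            y1b = min(int(cy) + r + 2, height)
            if x0 >= x1b or y0 >= y1b:
                continue
            yy, xx = np.mgrid[y0:y1b, x0:x1b]
            disk = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r * r)
            new = disk & comp_mask[y0:y1b, x0:x1b] & ~comp_red[y0:y1b, x0:x1b]
            n_new = int(new.sum())
            if n_new == 0:
                continue
            if count + n_new > target:
                # trim the droplet: keep only as many new pixels as needed
                ys, xs = np.nonzero(new)
                keep = target - count
                new = np.zeros_like(new)
                new[ys[:keep], xs[:keep]] = True
                n_new = keep
            comp_red[y0:y1b, x0:x1b] |= new
            count += n_new
        red_mask |= comp_red
        achieved[comp.tissue] = count / area if area else 0.0

    image[red_mask] = preset.lipid_rgb

    if preset.noise_sigma > 0:
        image = image + rng.normal(0.0, preset.noise_sigma, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    bg1 = Roi("background_1", "background", "oval",
              [(round(0.02 * width), round(0.02 * height)),
               (round(0.14 * width), round(0.14 * height) + 2)],
              source="synthetic")
    bg2 = Roi("background_2", "background", "oval",
              [(round(0.86 * width), round(0.88 * height) - 2),
               (round(0.98 * width), round(0.98 * height))],
              source="synthetic")
    roi_set = RoiSet(rois=rois + [bg1, bg2],
                     image_ref=f"{preset.name}_seed{seed}")
    truth = GroundTruth(lipid_fraction=achieved,
                        section_area_px=int(section_mask.sum()))
    return image, roi_set, truth


def generate_od_panel(tissue_transmittances: dict[str, float],
                      width: int = 256, height: int = 192,
                      noise_sigma: float = 2.0, seed: int = 0,
                      background_intensity: float = 240.0,
                      ) -> tuple[np.ndarray, RoiSet, GroundTruth]:
    """Grayscale panel for densitometry testing: each tissue compartment's
    intensity is background x transmittance; true OD = -log10(T)."""
    for tissue, t in tissue_transmittances.items():
        if not 0.0 < t <= 1.0:
            raise ValueError(f"transmittance[{tissue!r}]={t} outside (0,1]")
    rng = np.random.default_rng(seed)
    image = np.full((height, width), background_intensity, dtype=float)

    layout = {c.tissue: c for c in _WORM_LAYOUT}
    rois: list[Roi] = []
    truth = GroundTruth()
    # place requested tissues; fall back to a row of compartments for
    # tissues outside the canonical worm layout
    extra_x = 0.2
    for tissue, transm in tissue_transmittances.items():
        comp = layout.get(tissue)
        if comp is None:
            comp = TissueCompartment(tissue, extra_x, 0.5, 0.12, 0.2)
            extra_x += 0.3
        roi = _ellipse_roi(comp, width, height, name=tissue)
        mask = roi_mask(roi, width, height)
        image[mask] = background_intensity * transm
        rois.append(roi)
        truth.transmittance[tissue] = transm
        truth.od[tissue] = -math.log10(transm)

    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    bg1 = Roi("background_1", "background", "rectangle",
              [(2, 2), (round(0.15 * width), round(0.15 * height))],
              source="synthetic")
    bg2 = Roi("background_2", "background", "rectangle",
              [(round(0.85 * width), round(0.85 * height)),
               (width - 2, height - 2)], source="synthetic")
    roi_set = RoiSet(rois=rois + [bg1, bg2], image_ref=f"odpanel_seed{seed}")
    return image, roi_set, truth


def generate_kinetics(preset: KineticsPreset | str, seed: int = 0,
                      ) -> tuple[KineticsTrace, GroundTruth]:
    """Sample a logistic stain-accumulation curve with Gaussian OD noise.

    The ground-truth exponential phase is t_mid +/- 2/k exactly.  Presets
    with ``truncate_before`` > 0 drop the earliest frames, mimicking
    reactions whose start could not be recorded."""
    if isinstance(preset, str):
        preset = KINETICS_PRESETS[preset]
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, preset.duration + 1e-9, preset.sampling_interval)
    keep = t >= preset.truncate_before
    t = t[keep]
    od = _logistic(t, preset.baseline, preset.A, preset.t_mid, preset.k)
    if preset.noise_sigma_od > 0:
        od = od + rng.normal(0.0, preset.noise_sigma_od, od.shape)
    trace = KineticsTrace(times=t, od_values=od, stain=preset.stain,
                          temperature_C=20.0,
                          truncated=preset.truncate_before > 0)
    truth = GroundTruth(onset_min=preset.t_mid - 2.0 / preset.k,
                        end_min=preset.t_mid + 2.0 / preset.k)
    return trace, truth
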