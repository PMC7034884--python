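"""Synthetic longitudinal phantom-tibia generator.

Generates two groups of "mice" ("wild" controls vs "PTH"-treated, anabolic)
imaged weekly as stacks of 2-D monochrome cross-sections. Each slice shows a
soft-edged annulus (the cortical ring of a tibia cross-section) on a dark
background; brighter pixels stand for denser tissue. The generator emulates
the statistical structure the downstream method assumes:

* a class signal that exists **only** as a monotonic week-to-week trend —
  PTH ring intensity rises by ``trend_per_week`` per week, wild stays flat;
* week-0 class distributions that are identical by construction;
* per-subject anatomy (ring radius, thickness, baseline density) that is
  constant across weeks, drawn per mouse *position* so that a wild mouse and
  its same-position PTH counterpart share identical anatomy — the label
  enters only through the trend term;
* variable image dimensions per mouse-week (operator-crop variation),
  variable slice counts per mouse-week, one missing week for every mouse,
  and a small random integer translation per mouse-week (residual
  registration error).

All randomness is derived from counter-based seeds of the form
``(seed, mouse position, week, slice, stream)``, so any slice can be
regenerated bit-identically in isolation and in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging_io import DatasetIndex, SliceRecord, write_manifest, write_slice

WILD, PTH = "wild", "PTH"

# stream tags separating the per-mouse / per-mouse-week / per-slice RNGs
_S_MOUSE, _S_WEEK, _S_SLICE, _S_PROFILE = 11, 22, 33, 44

FULL_SCALE = 65535  # 16-bit intensity full scale


class MissingWeekError(ValueError):
    """Requested a week for which no data exist (scanner downtime)."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic longitudinal dataset.

    Defaults are scaled down (48-64 px instead of 400-800) so the whole
    pipeline runs on a single CPU in minutes; full-size generation is a
    matter of widening the dimension ranges.
    """

    n_mice_per_group: int = 8
    weeks: tuple = tuple(range(9))
    missing_weeks: frozenset = frozenset({2})
    slices_range: tuple = (6, 10)
    height_range: tuple = (48, 64)
    width_range: tuple = (48, 64)
    #: additive intensity increment per week for the anabolic (PTH) class,
    #: in raw 16-bit intensity units
    trend_per_week: float = 2500.0
    #: per-pixel Gaussian noise standard deviation, raw intensity units
    noise_sd: float = 1000.0
    #: maximum absolute per-mouse-week integer translation, pixels
    jitter_max: int = 3
    seed: int = 0
    #: per-mouse constant anatomy ranges (outer ring radius / ring thickness
    #: in pixels, baseline ring intensity in raw units); degenerate ranges
    #: give every mouse the same geometry, which keeps single images free of
    #: subject-identity cues
    radius_range: tuple = (15.0, 15.0)
    thickness_range: tuple = (4.5, 4.5)
    base_intensity_range: tuple = (10000.0, 55000.0)
    #: quantise per-mouse baseline intensities to multiples of
    #: trend_per_week above the range minimum, so that a treated ring after
    #: w weeks is exactly as bright as some other animal's baseline: single
    #: images are then ambiguous by construction, not by sampling luck
    quantise_base_to_trend: bool = True
    #: multiplicative axial sensitivity profile: each slice position gets a
    #: fixed factor drawn from this range, constant across weeks (a scanner
    #: property of the axial position). It multiplies the whole trajectory,
    #: so it cancels in week-to-week ratios of the difference signal while
    #: smearing single-image intensity levels.
    slice_profile_range: tuple = (0.8, 1.2)

    def __post_init__(self):
        for lo, hi, name in [
            (*self.slices_range, "slices_range"),
            (*self.height_range, "height_range"),
            (*self.width_range, "width_range"),
            (*self.radius_range, "radius_range"),
            (*self.thickness_range, "thickness_range"),
            (*self.base_intensity_range, "base_intensity_range"),
        ]:
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if self.height_range[0] <= 0 or self.width_range[0] <= 0:
            raise ValueError("image dimensions must be positive")
        if not set(self.missing_weeks) <= set(self.weeks):
            raise ValueError("missing_weeks must be a subset of weeks")
        if self.trend_per_week < 0:
            raise ValueError("trend_per_week must be non-negative")
        if not 0 < self.slice_profile_range[0] <= self.slice_profile_range[1]:
            raise ValueError("slice_profile_range must be positive and ordered")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be non-negative")

    @property
    def available_weeks(self):
        return tuple(w for w in self.weeks if w not in self.missing_weeks)

    def mouse_ids(self):
        n = self.n_mice_per_group
        return [f"{WILD}_{i:02d}" for i in range(n)] + [f"{PTH}_{i:02d}" for i in range(n)]


def mouse_position(mouse_id: str) -> int:
    """Position of a mouse within its group (label-blind seeding key)."""
    return int(str(mouse_id).rsplit("_", 1)[1])


def mouse_label(mouse_id: str) -> str:
    return PTH if str(mouse_id).startswith(PTH) else WILD


def _mouse_rng(config, position):
    return np.random.default_rng([config.seed, position, _S_MOUSE])


def _week_rng(config, position, week):
    return np.random.default_rng([config.seed, position, week, _S_WEEK])


def _slice_rng(config, position, week, slice_index):
    return np.random.default_rng([config.seed, position, week, slice_index, _S_SLICE])


def _mouse_anatomy(config, position):
    rng = _mouse_rng(config, position)
    radius = rng.uniform(*config.radius_range)
    thickness = rng.uniform(*config.thickness_range)
    lo, hi = config.base_intensity_range
    if config.quantise_base_to_trend and config.trend_per_week > 0:
        n_levels = int((hi - lo) // config.trend_per_week) + 1
        base = lo + config.trend_per_week * float(rng.integers(0, n_levels))
    else:
        base = rng.uniform(lo, hi)
    return radius, thickness, base


def _week_geometry(config, position, week):
    rng = _week_rng(config, position, week)
    h = int(rng.integers(config.height_range[0], config.height_range[1] + 1))
    w = int(rng.integers(config.width_range[0], config.width_range[1] + 1))
    j = config.jitter_max
    dy = int(rng.integers(-j, j + 1)) if j else 0
    dx = int(rng.integers(-j, j + 1)) if j else 0
    n_slices = int(rng.integers(config.slices_range[0], config.slices_range[1] + 1))
    return h, w, dy, dx, n_slices


def generate_phantom_slice(
    config: SynthConfig, mouse: str, week: int, slice_index: int, label: str | None = None
) -> SliceRecord:
    """Render one phantom cross-section.

    Ring intensity at week ``w`` is ``base + 1[label==PTH] * trend_per_week * w``
    plus pixel noise; anatomy is constant per mouse position, so the trend is
    the only class-dependent term and the week-0 distribution is identical
    for both classes.
    """
    if week in config.missing_weeks:
        raise MissingWeekError(f"week {week} is a missing week")
    if week not in config.weeks:
        raise ValueError(f"week {week} outside study weeks {config.weeks}")
    label = mouse_label(mouse) if label is None else label
    pos = mouse_position(mouse)

    radius, thickness, base = _mouse_anatomy(config, pos)
    h, w, dy, dx, _ = _week_geometry(config, pos, week)

    # mild axial taper: ring radius varies along the bone, identically at
    # every week so that differencing cancels it
    r_out = radius + 0.8 * np.sin(0.35 * slice_index)
    r_in = r_out - thickness

    intensity = base + (config.trend_per_week * week if label == PTH else 0.0)
    # axial sensitivity: fixed per (mouse position, slice), identical at every
    # week, so it scales the whole trajectory uniformly
    profile_rng = np.random.default_rng([config.seed, pos, slice_index, _S_PROFILE])
    intensity *= profile_rng.uniform(*config.slice_profile_range)

    yy = np.arange(h)[:, None] - (h - 1) / 2.0 - dy
    xx = np.arange(w)[None, :] - (w - 1) / 2.0 - dx
    d = np.sqrt(yy**2 + xx**2)
    # soft-edged annulus mask in [0, 1]
    mask = np.clip(np.minimum(d - r_in, r_out - d) + 0.5, 0.0, 1.0)
    img = mask * intensity
    if config.noise_sd > 0:
        img = img + _slice_rng(config, pos, week, slice_index).normal(
            0.0, config.noise_sd, size=img.shape
        )
    pixels = np.clip(np.rint(img), 0, FULL_SCALE).astype(np.uint16)
    return SliceRecord(mouse_id=mouse, week=week, slice_index=slice_index, label=label, pixels=pixels)


def generate_dataset(
    config: SynthConfig, out_dir=None, image_format: str = "png"
) -> tuple[DatasetIndex, dict]:
    """Generate all slices for all mice and non-missing weeks.

    If ``out_dir`` is given, slices are written there (as PNG by default, or
    single-frame DICOM with ``image_format="dcm"``) together with a
    ``manifest.csv``; otherwise the dataset is kept in memory. Returns the
    :class:`DatasetIndex` and the ground-truth mouse -> label mapping.
    """
    if image_format not in ("png", "dcm"):
        raise ValueError("image_format must be 'png' or 'dcm'")
    index = DatasetIndex()
    truth = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for mouse in config.mouse_ids():
        truth[mouse] = mouse_label(mouse)
        pos = mouse_position(mouse)
        for week in config.available_weeks:
            n_slices = _week_geometry(config, pos, week)[4]
            for k in range(n_slices):
                rec = generate_phantom_slice(config, mouse, week, k)
                if out_dir is not None:
                    rel = f"{mouse}/week{week:02d}_slice{k:03d}.{image_format}"
                    path = out_dir / rel
                    write_slice(rec, path)
                    rec = SliceRecord(
                        mouse_id=rec.mouse_id,
                        week=rec.week,
                        slice_index=rec.slice_index,
                        label=rec.label,
                        pixels=rec.pixels,
                        path=rel,
                    )
                index.add(rec)
    if out_dir is not None:
        write_manifest(index, out_dir / "manifest.csv")
    return index, truth
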