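"""Expansion, translation alignment and temporal difference maps.

The preprocessing pipeline takes the raw slice stacks to model-ready pairs:

1. every image is expanded onto a common canvas (the dataset maxima),
   centred, with padding set to the per-image minimum intensity;
2. for each comparison week the reference week is chosen — the subject's
   first recorded week (*absolute* differencing, long-range dependencies) or
   the most recent earlier week (*relative* differencing, short-range);
3. reference and comparison slices are paired k-th with k-th (scans start at
   the proximal growth plate), stopping when either week runs out;
4. the reference is shifted by the integer translation that best aligns it
   with the comparison, then subtracted pixel-wise to give a signed
   difference map ``D[i, j] = I_comparison[i, j] - I_reference[i, j]``;
5. the earliest week, having no reference, receives a uniform map filled
   with the minimum intensity of its comparison image.

All geometry follows the package convention: row-major ``(row=y, col=x)``,
translations ``(dy, dx)``. Preprocessing is one-shot: results can be
persisted to disk and reloaded for training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .imaging_io import DatasetIndex, SliceRecord

ABSOLUTE, RELATIVE, INITIAL = "absolute", "relative", "initial"


@dataclass(frozen=True)
class CanvasSpec:
    """Common target dimensions: the maxima observed over the dataset."""

    target_height: int
    target_width: int


@dataclass(frozen=True)
class Translation:
    """Integer pixel offset applied to the reference image."""

    dy: int
    dx: int


@dataclass
class DifferenceMap:
    """Signed pixel-wise difference with its provenance."""

    values: np.ndarray
    mode: str
    reference_week: int
    comparison_week: int
    mouse_id: str
    slice_index: int


@dataclass
class Sample:
    """One model input: an expanded comparison image and its difference map."""

    image: np.ndarray
    diff: DifferenceMap
    mouse_id: str
    week: int
    slice_index: int
    label: str | None


def max_dims(index: DatasetIndex) -> CanvasSpec:
    """Maximum height and width over all records in the index."""
    heights, widths = [], []
    for r in index:
        if r.pixels is not None:
            heights.append(r.height)
            widths.append(r.width)
        else:
            raise ValueError("record has no pixels loaded; call SliceRecord.loaded()")
    if not heights:
        raise ValueError("cannot take dimensions of an empty index")
    return CanvasSpec(int(max(heights)), int(max(widths)))


def expand(record: SliceRecord, canvas: CanvasSpec) -> SliceRecord:
    """Place the image centrally on the canvas, padding with its own minimum.

    When the leftover padding is odd, the extra row/column goes to the
    bottom/right (a fixed tie-break so expansion is bit-reproducible).
    """
    px = record.pixels
    h, w = px.shape
    th, tw = canvas.target_height, canvas.target_width
    if h > th or w > tw:
        raise ValueError(f"image {h}x{w} larger than canvas {th}x{tw}")
    if (h, w) == (th, tw):
        return record
    fill = px.min()
    out = np.full((th, tw), fill, dtype=px.dtype)
    top = (th - h) // 2
    left = (tw - w) // 2
    out[top : top + h, left : left + w] = px
    return SliceRecord(
        mouse_id=record.mouse_id,
        week=record.week,
        slice_index=record.slice_index,
        label=record.label,
        pixels=out,
        path=record.path,
    )


def _tie_break_key(dy, dx):
    return (abs(dy) + abs(dx), dy, dx)


def estimate_translation(reference: SliceRecord, comparison: SliceRecord) -> Translation:
    """Integer ``(dy, dx)`` maximising the cross-correlation of the shifted
    reference with the comparison.

    Images are reduced by their own minimum first so that the padding level
    does not bias the score; vacated regions then contribute zero, matching
    :func:`apply_translation`'s minimum fill. Ties (e.g. constant images)
    are broken toward the smallest ``|dy| + |dx|``, then lexicographically.
    """
    a = reference.pixels
    b = comparison.pixels
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    af = (a - a.min()).astype(np.float64)
    bf = (b - b.min()).astype(np.float64)
    # score(t) = sum_u ref[u] * comp[u + t]  == full cross-correlation
    corr = fftconvolve(bf, af[::-1, ::-1], mode="full")
    h, w = a.shape
    best = None
    peak = corr.max()
    tol = 1e-7 * max(peak, 1.0)
    ties = np.argwhere(corr >= peak - tol)
    for iy, ix in ties:
        dy, dx = int(iy - (h - 1)), int(ix - (w - 1))
        if best is None or _tie_break_key(dy, dx) < _tie_break_key(*best):
            best = (dy, dx)
    return Translation(dy=best[0], dx=best[1])


def apply_translation(record: SliceRecord, t: Translation) -> SliceRecord:
    """Shift content by ``(dy, dx)``; vacated pixels take the image minimum."""
    px = record.pixels
    h, w = px.shape
    dy, dx = int(t.dy), int(t.dx)
    if abs(dy) >= h or abs(dx) >= w:
        raise ValueError(f"shift ({dy}, {dx}) out of range for {h}x{w} image")
    out = np.full_like(px, px.min())
    ys = slice(max(0, dy), h + min(0, dy))
    xs = slice(max(0, dx), w + min(0, dx))
    ys_src = slice(max(0, -dy), h + min(0, -dy))
    xs_src = slice(max(0, -dx), w + min(0, -dx))
    out[ys, xs] = px[ys_src, xs_src]
    return SliceRecord(
        mouse_id=record.mouse_id,
        week=record.week,
        slice_index=record.slice_index,
        label=record.label,
        pixels=out,
        path=record.path,
    )


def difference_map(reference_aligned: SliceRecord, comparison: SliceRecord, mode: str) -> DifferenceMap:
    """Signed pixel-wise subtraction ``comparison - reference`` (no clipping)."""
    if mode not in (ABSOLUTE, RELATIVE):
        raise ValueError(f"mode must be '{ABSOLUTE}' or '{RELATIVE}'")
    a = reference_aligned.pixels
    b = comparison.pixels
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if reference_aligned.week >= comparison.week:
        raise ValueError(
            f"reference week {reference_aligned.week} must precede "
            f"comparison week {comparison.week}"
        )
    values = b.astype(np.int32) - a.astype(np.int32)
    return DifferenceMap(
        values=values,
        mode=mode,
        reference_week=reference_aligned.week,
        comparison_week=comparison.week,
        mouse_id=comparison.mouse_id,
        slice_index=comparison.slice_index,
    )


def initial_fill(comparison: SliceRecord, available_weeks=None) -> DifferenceMap:
    """Uniform difference map for a subject's earliest week.

    Every entry equals the minimum intensity of the comparison image itself
    (per-image, not global), standing for the absence of preceding data
    while staying consistent with the expansion padding.
    """
    if available_weeks is not None and comparison.week != min(available_weeks):
        raise ValueError(
            f"initial fill requested for week {comparison.week}, but earliest "
            f"available week is {min(available_weeks)}"
        )
    imin = int(comparison.pixels.min())
    values = np.full(comparison.pixels.shape, imin, dtype=np.int32)
    return DifferenceMap(
        values=values,
        mode=INITIAL,
        reference_week=comparison.week,
        comparison_week=comparison.week,
        mouse_id=comparison.mouse_id,
        slice_index=comparison.slice_index,
    )


def select_reference_week(available_weeks, current_week: int, mode: str):
    """Reference week for differencing, or ``None`` for the earliest week.

    Absolute differencing uses the subject's first recorded week; relative
    differencing the most recent earlier one (skipping missing weeks).
    """
    weeks = sorted(set(available_weeks))
    if current_week not in weeks:
        raise ValueError(f"week {current_week} not among available weeks {weeks}")
    earlier = [w for w in weeks if w < current_week]
    if not earlier:
        return None
    if mode == ABSOLUTE:
        return weeks[0]
    if mode == RELATIVE:
        return max(earlier)
    raise ValueError(f"mode must be '{ABSOLUTE}' or '{RELATIVE}'")


def pair_slices(reference_slices, comparison_slices):
    """Pair the k-th reference slice with the k-th comparison slice.

    Pairing stops when either week is exhausted; surplus slices are returned
    as unused so the caller can report them.
    """
    n = min(len(reference_slices), len(comparison_slices))
    pairs = list(zip(reference_slices[:n], comparison_slices[:n]))
    unused = list(reference_slices[n:]) + list(comparison_slices[n:])
    return pairs, unused


# ---------------------------------------------------------------------------
# batch pipeline


def build_samples(index: DatasetIndex, mode: str, canvas: CanvasSpec | None = None):
    """Run the full preprocessing pipeline over an index.

    Returns ``(samples, canvas, unused)`` where ``samples`` is a list of
    :class:`Sample` (expanded comparison image + difference map) and
    ``unused`` lists slices dropped by the k-th/k-th pairing rule.
    """
    if mode not in (ABSOLUTE, RELATIVE):
        raise ValueError(f"mode must be '{ABSOLUTE}' or '{RELATIVE}'")
    loaded = DatasetIndex(r.loaded() for r in index)
    if canvas is None:
        canvas = max_dims(loaded)
    samples, unused = [], []
    expanded_cache: dict[tuple, list[SliceRecord]] = {}

    def expanded(mouse, week):
        key = (mouse, week)
        if key not in expanded_cache:
            expanded_cache[key] = [expand(r, canvas) for r in loaded.slices_of(mouse, week)]
        return expanded_cache[key]

    for mouse in loaded.mice():
        weeks = loaded.weeks_of(mouse)
        for week in weeks:
            comp_slices = expanded(mouse, week)
            ref_week = select_reference_week(weeks, week, mode)
            if ref_week is None:
                for comp in comp_slices:
                    samples.append(
                        Sample(
                            image=comp.pixels,
                            diff=initial_fill(comp, available_weeks=weeks),
                            mouse_id=mouse,
                            week=week,
                            slice_index=comp.slice_index,
                            label=comp.label,
                        )
                    )
                continue
            ref_slices = expanded(mouse, ref_week)
            pairs, extra = pair_slices(ref_slices, comp_slices)
            unused.extend(extra)
            for ref, comp in pairs:
                t = estimate_translation(ref, comp)
                ref_aligned = apply_translation(ref, t)
                samples.append(
                    Sample(
                        image=comp.pixels,
                        diff=difference_map(ref_aligned, comp, mode),
                        mouse_id=mouse,
                        week=week,
                        slice_index=comp.slice_index,
                        label=comp.label,
                    )
                )
    return samples, canvas, unused


def save_samples(samples, canvas: CanvasSpec, out_dir) -> None:
    """Persist preprocessed samples: one ``samples.npz`` plus ``pairs.csv``.

    ``samples.npz`` holds ``images`` (uint16), ``diffs`` (int32, signed —
    differences of 16-bit images need 17 bits) and ``weeks``; ``pairs.csv``
    records provenance per sample.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = np.stack([s.image for s in samples]).astype(np.uint16)
    diffs = np.stack([s.diff.values for s in samples]).astype(np.int32)
    weeks = np.array([s.week for s in samples], dtype=np.int64)
    np.savez_compressed(out_dir / "samples.npz", images=images, diffs=diffs, weeks=weeks)
    rows = [
        {
            "mouse_id": s.mouse_id,
            "group": s.label,
            "mode": s.diff.mode,
            "ref_week": s.diff.reference_week,
            "comp_week": s.week,
            "slice_k": s.slice_index,
            "canvas_height": canvas.target_height,
            "canvas_width": canvas.target_width,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(out_dir / "pairs.csv", index=False)


def load_samples(in_dir):
    """Inverse of :func:`save_samples`."""
    in_dir = Path(in_dir)
    with np.load(in_dir / "samples.npz") as z:
        images, diffs, weeks = z["images"], z["diffs"], z["weeks"]
    meta = pd.read_csv(in_dir / "pairs.csv")
    canvas = CanvasSpec(int(meta["canvas_height"].iloc[0]), int(meta["canvas_width"].iloc[0]))
    samples = []
    for i, row in enumerate(meta.itertuples(index=False)):
        diff = DifferenceMap(
            values=diffs[i],
            mode=row.mode,
            reference_week=int(row.ref_week),
            comparison_week=int(row.comp_week),
            mouse_id=str(row.mouse_id),
            slice_index=int(row.slice_k),
        )
        samples.append(
            Sample(
                image=images[i],
                diff=diff,
                mouse_id=str(row.mouse_id),
                week=int(row.comp_week),
                slice_index=int(row.slice_k),
                label=None if pd.isna(row.group) else str(row.group),
            )
        )
    return samples, canvas
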