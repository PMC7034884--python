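"""Train/validation/test partitioning with mouse-week test units.

Adjacent slices from the same subject and week are nearly duplicates, so an
image-level test split would leak. The test set is therefore drawn at
*mouse-week* granularity: every slice of a held-out (mouse, week) goes to
test and only test. The remaining images are randomly permuted and split
90/10 into train/validation at image granularity (train/val leakage between
neighbouring slices is accepted, as only the test set supports claims).

Difference-map samples inherit the split of their comparison image, since
the comparison week carries the label-relevant time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging_io import DatasetIndex

TRAIN, VAL, TEST = "train", "val", "test"


@dataclass
class PartitionPlan:
    """Assignment of every image key (mouse, week, slice) to a split."""

    assignment: dict
    test_mouse_weeks: frozenset
    test_fraction: float
    val_fraction: float
    seed: int

    def split_of(self, mouse_id, week, slice_index) -> str:
        return self.assignment[(mouse_id, week, slice_index)]

    def split_of_sample(self, sample) -> str:
        """Split of a preprocessed sample, via its comparison image."""
        return self.assignment[(sample.mouse_id, sample.week, sample.slice_index)]

    def keys_in(self, split):
        return sorted(k for k, s in self.assignment.items() if s == split)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split(
    index: DatasetIndex,
    test_fraction: float = 0.2,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> PartitionPlan:
    """Partition an index into train/val/test.

    ``round_half_up(test_fraction * #mouse-weeks)`` whole mouse-weeks are
    held out for testing; remaining images are permuted and split
    ``(1 - val_fraction) : val_fraction`` by image. Deterministic per seed.
    """
    for name, frac in (("test_fraction", test_fraction), ("val_fraction", val_fraction)):
        if not 0 < frac < 1:
            raise ValueError(f"{name} must lie in (0, 1), got {frac}")
    mouse_weeks = index.mouse_weeks()
    if len(mouse_weeks) < 2:
        raise ValueError("need at least 2 mouse-weeks to partition")

    rng = np.random.default_rng(seed)
    n_test = _round_half_up(test_fraction * len(mouse_weeks))
    test_idx = rng.choice(len(mouse_weeks), size=n_test, replace=False)
    test_mw = frozenset(mouse_weeks[i] for i in test_idx)

    assignment = {}
    remaining = []
    for rec in index:
        key = rec.key
        if (rec.mouse_id, rec.week) in test_mw:
            assignment[key] = TEST
        else:
            remaining.append(key)
    perm = rng.permutation(len(remaining))
    n_val = _round_half_up(val_fraction * len(remaining))
    # val membership follows the permutation order, not index order
    ordered = [remaining[i] for i in perm]
    for i, key in enumerate(ordered):
        assignment[key] = VAL if i < n_val else TRAIN

    return PartitionPlan(
        assignment=assignment,
        test_mouse_weeks=test_mw,
        test_fraction=test_fraction,
        val_fraction=val_fraction,
        seed=seed,
    )


def balance_report(plan: PartitionPlan, truth: dict) -> dict:
    """Per-split class proportions and sample counts.

    ``truth`` maps mouse id -> class label. Proportions within each split
    sum to 1; an unlabeled mouse raises.
    """
    labels = sorted(set(truth.values()))
    report = {}
    for split_name in (TRAIN, VAL, TEST):
        keys = plan.keys_in(split_name)
        counts = {lab: 0 for lab in labels}
        for mouse_id, _week, _k in keys:
            if mouse_id not in truth:
                raise ValueError(f"mouse {mouse_id!r} has no ground-truth label")
            counts[truth[mouse_id]] += 1
        n = len(keys)
        report[split_name] = {
            "n": n,
            "proportions": {lab: (counts[lab] / n if n else 0.0) for lab in labels},
        }
    return report
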