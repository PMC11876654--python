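"""w-space edit directions identified from labelled groups of images.

A semantic direction is the difference of the per-group means of the w
vectors of two labelled image groups: the *treatment* vector maps the severe
regime onto the moderate regime (adding it reduces apparent severity), and
the *size* vector separates low-coverage from high-coverage plaques.
Directions can be applied fractionally (0.2, 0.4, ... of the vector),
composed linearly, and combined so that the size vector cancels the plaque
area drift that a severity-size-correlated training set imprints on the
treatment vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import simulate

__all__ = [
    "DirectionVector",
    "LabelRecord",
    "compute_direction",
    "apply_fraction",
    "compose",
    "select_label_groups",
    "find_compensation_scale",
    "save_direction",
    "load_direction",
]


@dataclass(frozen=True)
class LabelRecord:
    image_id: str
    erythema: int
    scale: int
    rater_id: str

    def __post_init__(self):
        for name in ("erythema", "scale"):
            v = getattr(self, name)
            if not (0 <= v <= 4):
                raise ValueError(f"{name}={v} outside 0-4")


@dataclass(frozen=True)
class DirectionVector:
    """A w-space edit direction with provenance metadata.

    Sign convention: adding the vector moves a w toward the positive
    (target) group's regime.
    """

    values: np.ndarray
    name: str = "direction"
    n_positive_group: int = 0
    n_negative_group: int = 0
    sign_convention: str = "adding moves toward the positive group"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    @property
    def w_dim(self) -> int:
        return self.values.size

    def scaled(self, factor: float) -> "DirectionVector":
        return DirectionVector(
            values=self.values * factor,
            name=self.name,
            n_positive_group=self.n_positive_group,
            n_negative_group=self.n_negative_group,
        )


def compute_direction(
    target_group: Sequence[np.ndarray],
    source_group: Sequence[np.ndarray],
    name: str = "direction",
) -> DirectionVector:
    """mean(target) - mean(source): adding the result to a source-regime w
    moves it toward the target regime."""
    tg = np.atleast_2d(np.asarray(list(target_group), dtype=np.float64))
    sg = np.atleast_2d(np.asarray(list(source_group), dtype=np.float64))
    if tg.size == 0 or sg.size == 0:
        raise ValueError("both groups must be nonempty")
    if tg.shape[1] != sg.shape[1]:
        raise ValueError(f"w_dim mismatch: {tg.shape[1]} vs {sg.shape[1]}")
    return DirectionVector(
        values=tg.mean(axis=0) - sg.mean(axis=0),
        name=name,
        n_positive_group=tg.shape[0],
        n_negative_group=sg.shape[0],
    )


def apply_fraction(w: np.ndarray, direction: DirectionVector, fraction: float) -> np.ndarray:
    """w + fraction * direction; fraction may be negative (increases the
    edited attribute) and is not clamped."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape[-1] != direction.w_dim:
        raise ValueError(f"w_dim mismatch: {w.shape[-1]} vs {direction.w_dim}")
    return w + float(fraction) * direction.values


def compose(
    directions_and_fractions: Sequence[tuple[DirectionVector, float]],
    name: str = "composite",
) -> DirectionVector:
    """Weighted sum of directions; applying the composite equals applying
    each in sequence."""
    if not directions_and_fractions:
        raise ValueError("empty composition")
    dims = {d.w_dim for d, _ in directions_and_fractions}
    if len(dims) != 1:
        raise ValueError(f"inconsistent w_dim in composition: {sorted(dims)}")
    total = np.zeros(dims.pop(), dtype=np.float64)
    for d, frac in directions_and_fractions:
        total += float(frac) * d.values
    return DirectionVector(values=total, name=name)


def _consensus(labels: pd.DataFrame) -> pd.Series:
    """Per-image consensus severity: mean over raters of the combined
    (erythema+scale)/2 score, rounded half-up to the integer scale."""
    combined = (labels["erythema"] + labels["scale"]) / 2.0
    per_image = combined.groupby(labels["image_id"]).mean()
    return np.floor(per_image + 0.5).astype(int)


def select_label_groups(
    labels: pd.DataFrame | Sequence[LabelRecord],
    rule: str,
    coverage_threshold: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Split labelled images into (positive_ids, negative_ids).

    rule="severity": positive = "severe" (consensus 3-4), negative =
    "moderate" (consensus exactly 2); consensus is the rater-mean combined
    score rounded half-up.  rule="coverage": positive = area_fraction below
    the threshold (small plaques), negative = above; requires an
    area_fraction column.  Order within groups follows sorted image_id.
    """
    if not isinstance(labels, pd.DataFrame):
        labels = pd.DataFrame([vars(r) for r in labels])
    if labels.empty:
        raise ValueError("empty label table")
    if rule == "severity":
        cons = _consensus(labels).sort_index()
        pos = list(cons.index[(cons >= 3) & (cons <= 4)])
        neg = list(cons.index[cons == 2])
        return pos, neg
    if rule == "coverage":
        if "area_fraction" not in labels.columns:
            raise ValueError("coverage rule needs an area_fraction column")
        area = labels.groupby("image_id")["area_fraction"].first().sort_index()
        pos = list(area.index[area < coverage_threshold])
        neg = list(area.index[area >= coverage_threshold])
        return pos, neg
    raise ValueError(f"unknown rule {rule!r}; expected 'severity' or 'coverage'")


def _measured_area(gen, w: np.ndarray) -> float:
    img = gen.synthesize(w)
    return float(simulate.segment_plaque(img).mean())


def find_compensation_scale(
    gen,
    w_examples: Sequence[np.ndarray],
    treatment: DirectionVector,
    size_direction: DirectionVector,
    scales: np.ndarray | None = None,
) -> float:
    """Scale s for the size vector that cancels the treatment vector's area
    drift.

    Minimises the mean absolute change in measured (segmented) plaque area
    between each original image and its fully treated (fraction 1.0) +
    s-scaled-size edit, over a 1-D grid refined once around the best point.
    """
    if scales is None:
        scales = np.linspace(-2.0, 2.0, 17)
    w_examples = [np.asarray(w, dtype=np.float64) for w in w_examples]
    base_areas = [_measured_area(gen, w) for w in w_examples]

    def cost(s: float) -> float:
        comp = compose([(treatment, 1.0), (size_direction, s)])
        drift = [
            abs(_measured_area(gen, apply_fraction(w, comp, 1.0)) - a0)
            for w, a0 in zip(w_examples, base_areas)
        ]
        return float(np.mean(drift))

    costs = [cost(s) for s in scales]
    best = scales[int(np.argmin(costs))]
    width = (scales[1] - scales[0]) if len(scales) > 1 else 0.5
    fine = np.linspace(best - width, best + width, 9)
    fine_costs = [cost(s) for s in fine]
    return float(fine[int(np.argmin(fine_costs))])


def save_direction(direction: DirectionVector, path) -> None:
    """CSV with `#`-prefixed metadata header lines, then one value per row."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# name: {direction.name}\n")
        fh.write(f"# n_positive_group: {direction.n_positive_group}\n")
        fh.write(f"# n_negative_group: {direction.n_negative_group}\n")
        fh.write(f"# sign_convention: {direction.sign_convention}\n")
        fh.write("value\n")
        for v in direction.values:
            fh.write(f"{float(v)!r}\n")


def load_direction(path) -> DirectionVector:
    meta = {}
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
            elif line and line != "value":
                values.append(float(line))
    return DirectionVector(
        values=np.array(values, dtype=np.float64),
        name=meta.get("name", "direction"),
        n_positive_group=int(meta.get("n_positive_group", 0)),
        n_negative_group=int(meta.get("n_negative_group", 0)),
        sign_convention=meta.get("sign_convention", "adding moves toward the positive group"),
    )
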