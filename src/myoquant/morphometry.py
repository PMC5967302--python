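"""Syncytium morphometry: per-object shape metrics and field-level indices.

During myogenic differentiation, myoblasts fuse into multinucleated
MyHC-positive syncytia (myotubes) that elongate into a bipolar shape.
Three per-field percentages quantify this:

* fusion index — nuclei residing in multinucleate MyHC+ cells with at
  least ``fusion_nuclei_threshold`` nuclei, as a percentage of all nuclei
  in MyHC+ cells in the field;
* polarized elongation index — area of MyHC+ cells whose best-fit-ellipse
  aspect ratio is >= ``elongation_ar_threshold`` (default 3), as a
  percentage of the total MyHC+ area;
* differentiation index — nuclei in MyHC+ cells as a percentage of all
  nuclei in the field.

Inputs are a labelled segmentation mask (one integer label per cell) and a
table of nuclei centroids; the "best-fit ellipse" is the second-central-
moment-matched ellipse of the filled region (axes = 4·sqrt of the
normalized covariance eigenvalues, the usual image-moments convention).
Coordinates are 0-based (row, col) pixel centres; ``x_px`` is the column
and ``y_px`` the row.  Areas are reported in μm² via ``pixel_size**2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .errors import InvalidParameterError, UndefinedIndexError


@dataclass
class MorphometryConfig:
    """Thresholds and geometry for the field-level indices.

    The nucleus-count threshold is dataset-dependent: 16 for the standard
    C2C12 per-nucleus counting, 50 or 26 for the per-syncytium variants.
    """

    fusion_nuclei_threshold: int = 16
    elongation_ar_threshold: float = 3.0
    pixel_size: float = 1.0
    #: restrict the elongation index to multinucleate objects (off by
    #: default: every MyHC+ object contributes).
    elongation_multinucleate_only: bool = False

    def __post_init__(self) -> None:
        if self.fusion_nuclei_threshold < 1:
            raise InvalidParameterError("fusion_nuclei_threshold must be >= 1")
        if self.elongation_ar_threshold < 1:
            raise InvalidParameterError("elongation_ar_threshold must be >= 1")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")


@dataclass
class SyncytiumRecord:
    """One segmented MyHC+/- object in a field."""

    label: int
    nucleus_count: int
    area: float  # μm²
    aspect_ratio: float  # >= 1
    centroid: tuple[float, float]  # (row, col) in μm
    is_differentiated: bool = True


@dataclass
class FieldSummary:
    """Per-microscopic-field index values (all percentages in [0, 100])."""

    fusion_index: float
    elongation_index: float
    differentiation_index: float
    n_syncytia: int
    n_nuclei_total: int

    def as_dict(self) -> dict:
        return {
            "fusion_index_pct": self.fusion_index,
            "elongation_index_pct": self.elongation_index,
            "differentiation_index_pct": self.differentiation_index,
            "n_syncytia": self.n_syncytia,
            "n_nuclei_total": self.n_nuclei_total,
        }


# ---------------------------------------------------------------------------
# Per-object measurements
# ---------------------------------------------------------------------------

def ellipse_metrics(
    region_mask: np.ndarray, pixel_size: float
) -> tuple[float, float, tuple[float, float]]:
    """Area, best-fit-ellipse aspect ratio and centroid of a binary region.

    Area is pixel count × pixel_size²; the aspect ratio is major/minor axis
    of the moment-matched ellipse, so it is invariant to translation and
    (up to rasterization) rotation.  A region so thin its minor axis
    degenerates gets an infinite aspect ratio.
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise InvalidParameterError("empty region")
    props = regionprops(region_mask.astype(np.uint8))[0]
    area = float(props.area) * pixel_size**2
    minor = props.axis_minor_length
    aspect_ratio = float(props.axis_major_length / minor) if minor > 0 else np.inf
    aspect_ratio = max(aspect_ratio, 1.0)
    centroid = (props.centroid[0] * pixel_size, props.centroid[1] * pixel_size)
    return area, aspect_ratio, centroid


def assign_nuclei(
    label_mask: np.ndarray, nuclei: pd.DataFrame
) -> tuple[dict[int, int], int]:
    """Count nuclei centroids per label by pixel containment.

    Each centroid (columns ``x_px``, ``y_px``) is assigned to the label of
    the pixel containing it (nearest pixel centre); centroids landing on
    background (label 0) are tallied as unassigned.

    Returns
    -------
    counts
        Mapping label -> nucleus count for every nonzero label in the mask
        (zero for labels with no nuclei).
    n_unassigned
        Number of centroids on background.
    """
    label_mask = np.asarray(label_mask)
    rows = np.rint(nuclei["y_px"].to_numpy(dtype=float)).astype(int)
    cols = np.rint(nuclei["x_px"].to_numpy(dtype=float)).astype(int)
    bad = (
        (rows < 0)
        | (rows >= label_mask.shape[0])
        | (cols < 0)
        | (cols >= label_mask.shape[1])
    )
    if bad.any():
        raise InvalidParameterError(
            "centroids outside image bounds at rows "
            f"{np.flatnonzero(bad).tolist()}"
        )
    labels_at = label_mask[rows, cols]
    counts = {int(lbl): 0 for lbl in np.unique(label_mask) if lbl != 0}
    for lbl in labels_at:
        if lbl != 0:
            counts[int(lbl)] += 1
    n_unassigned = int(np.count_nonzero(labels_at == 0))
    return counts, n_unassigned


def extract_records(
    label_mask: np.ndarray,
    nuclei: pd.DataFrame,
    config: MorphometryConfig,
    myhc_image: np.ndarray | None = None,
    myhc_threshold: float | None = None,
) -> list[SyncytiumRecord]:
    """Build one :class:`SyncytiumRecord` per labelled object.

    If a MyHC channel is supplied, an object is called differentiated when
    its mean intensity exceeds ``myhc_threshold`` (Otsu's threshold of the
    whole channel when not given); otherwise every object is taken as MyHC+.
    """
    label_mask = np.asarray(label_mask)
    counts, _ = assign_nuclei(label_mask, nuclei)
    if myhc_image is not None and myhc_threshold is None:
        myhc_threshold = float(threshold_otsu(np.asarray(myhc_image, dtype=float)))
    records = []
    for props in regionprops(label_mask):
        lbl = int(props.label)
        minor = props.axis_minor_length
        ar = float(props.axis_major_length / minor) if minor > 0 else np.inf
        if myhc_image is None:
            differentiated = True
        else:
            mean_intensity = float(
                np.asarray(myhc_image, dtype=float)[label_mask == lbl].mean()
            )
            differentiated = mean_intensity > myhc_threshold
        records.append(
            SyncytiumRecord(
                label=lbl,
                nucleus_count=counts.get(lbl, 0),
                area=float(props.area) * config.pixel_size**2,
                aspect_ratio=max(ar, 1.0),
                centroid=(
                    props.centroid[0] * config.pixel_size,
                    props.centroid[1] * config.pixel_size,
                ),
                is_differentiated=differentiated,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Field-level indices
# ---------------------------------------------------------------------------

def fusion_index(
    records: Sequence[SyncytiumRecord], config: MorphometryConfig
) -> float:
    """Percentage of MyHC+ nuclei inside syncytia with >= threshold nuclei.

    MyHC- records are excluded from numerator and denominator alike.
    """
    myhc = [r for r in records if r.is_differentiated]
    denom = sum(r.nucleus_count for r in myhc)
    if denom == 0:
        raise UndefinedIndexError("fusion index undefined: zero MyHC+ nuclei")
    num = sum(
        r.nucleus_count
        for r in myhc
        if r.nucleus_count >= config.fusion_nuclei_threshold
    )
    return 100.0 * num / denom


def elongation_index(
    records: Sequence[SyncytiumRecord], config: MorphometryConfig
) -> float:
    """Percentage of MyHC+ area in cells with aspect ratio >= threshold."""
    myhc = [r for r in records if r.is_differentiated]
    if config.elongation_multinucleate_only:
        myhc = [r for r in myhc if r.nucleus_count >= 2]
    denom = sum(r.area for r in myhc)
    if denom <= 0:
        raise UndefinedIndexError("elongation index undefined: zero MyHC+ area")
    num = sum(
        r.area for r in myhc if r.aspect_ratio >= config.elongation_ar_threshold
    )
    return 100.0 * num / denom


def differentiation_index(
    records: Sequence[SyncytiumRecord], total_nuclei_in_field: int
) -> float:
    """Percentage of all field nuclei that reside in MyHC+ cells."""
    if total_nuclei_in_field <= 0:
        raise UndefinedIndexError(
            "differentiation index undefined: zero nuclei in field"
        )
    num = sum(r.nucleus_count for r in records if r.is_differentiated)
    return 100.0 * num / total_nuclei_in_field


def analyze_field(
    label_mask: np.ndarray,
    nuclei: pd.DataFrame,
    config: MorphometryConfig,
    myhc_image: np.ndarray | None = None,
    myhc_threshold: float | None = None,
) -> tuple[list[SyncytiumRecord], FieldSummary]:
    """Full per-field morphometry: records plus the three indices.

    The differentiation-index denominator is every nucleus in the table,
    including centroids on background (unfused mononuclear cells outside
    segmented objects still carry a nucleus).
    """
    records = extract_records(label_mask, nuclei, config, myhc_image, myhc_threshold)
    summary = FieldSummary(
        fusion_index=fusion_index(records, config),
        elongation_index=elongation_index(records, config),
        differentiation_index=differentiation_index(records, len(nuclei)),
        n_syncytia=len(records),
        n_nuclei_total=len(nuclei),
    )
    return records, summary


def aggregate_fields(summaries: Sequence[FieldSummary]) -> FieldSummary:
    """Unweighted mean of per-field indices (the reporting convention is
    per-field values; this pooling helper is opt-in)."""
    if len(summaries) == 0:
        raise InvalidParameterError("no field summaries to aggregate")
    return FieldSummary(
        fusion_index=float(np.mean([s.fusion_index for s in summaries])),
        elongation_index=float(np.mean([s.elongation_index for s in summaries])),
        differentiation_index=float(
            np.mean([s.differentiation_index for s in summaries])
        ),
        n_syncytia=int(np.sum([s.n_syncytia for s in summaries])),
        n_nuclei_total=int(np.sum([s.n_nuclei_total for s in summaries])),
    )


def records_to_frame(records: Sequence[SyncytiumRecord]) -> pd.DataFrame:
    """Tidy per-record table for CSV export."""
    return pd.DataFrame(
        {
            "label": [r.label for r in records],
            "nucleus_count": [r.nucleus_count for r in records],
            "area_um2": [r.area for r in records],
            "aspect_ratio": [r.aspect_ratio for r in records],
            "centroid_row_um": [r.centroid[0] for r in records],
            "centroid_col_um": [r.centroid[1] for r in records],
            "is_differentiated": [r.is_differentiated for r in records],
        }
    )
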