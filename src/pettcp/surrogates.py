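"""Tumor delineation and per-patient survival-fraction surrogates.

The tumor is delineated on the *pre*-treatment PET as the set of voxels with
SUV strictly above a threshold (2.5 by default, the conventional FDG cutoff
separating malignant from benign uptake), and that mask is reused unchanged on
the registered post-treatment volume. Three scalar surrogates for mean
effective cell survival are computed over the mask:

* ``mean_ratio``   — <SUV_after / SUV_before>, the voxel-wise ratio averaged
  over the mask (the surrogate of record, <SUV_R>);
* ``ratio_of_means`` — <SUV_after> / <SUV_before>;
* ``mean_diff``    — <SUV_before> - <SUV_after>.

No registration or resampling is performed here; volumes on different grids
are an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyMaskError, GridMismatchError, LabelError

__all__ = [
    "SUVVolume",
    "TumorMask",
    "SurrogateSet",
    "delineate_tumor",
    "compute_surrogates",
    "build_cohort_table",
    "load_suv_volume",
    "cohort_table_from_files",
    "RESPONDER_LABELS",
    "NONRESPONDER_LABELS",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 2.5

# pathologic complete response and microscopic residual disease carry similar
# survival and are grouped as responders; gross residual disease is a nonresponder
RESPONDER_LABELS = frozenset({"pCR", "mRD", "responder"})
NONRESPONDER_LABELS = frozenset({"gRD", "nonresponder"})


@dataclass(frozen=True)
class SUVVolume:
    """A 3-D grid of standardized uptake values with isotropic-ish voxel spacing.

    SUVs are body-weight normalized and dimensionless; ``spacing`` is mm per
    axis. Values must be finite and nonnegative.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3:
            raise ValueError(f"SUV volume must be 3-D, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("SUV volume contains non-finite values")
        if np.any(vals < 0):
            raise ValueError("SUV volume contains negative values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class TumorMask:
    """Boolean tumor mask aligned to the pre-treatment volume."""

    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SurrogateSet:
    """Per-patient scalar surrogates over a single tumor mask.

    ``mean_diff == mean_pre - mean_post`` holds by construction.
    """

    mean_ratio: float
    ratio_of_means: float
    mean_diff: float
    mean_pre: float
    mean_post: float
    n_voxels: int

    def as_dict(self) -> dict:
        return {
            "mean_ratio": self.mean_ratio,
            "ratio_of_means": self.ratio_of_means,
            "mean_diff": self.mean_diff,
            "mean_pre": self.mean_pre,
            "mean_post": self.mean_post,
            "n_voxels": self.n_voxels,
        }


def delineate_tumor(
    pre_volume: SUVVolume,
    threshold: float = DEFAULT_THRESHOLD,
    patient_id: str | None = None,
) -> TumorMask:
    """Delineate the tumor as the voxels with pre-treatment SUV > threshold.

    The inequality is strict: a voxel at exactly the threshold is excluded.
    Raises :class:`EmptyMaskError` if nothing exceeds the threshold.
    """
    mask = pre_volume.values > threshold
    if not mask.any():
        who = f" for patient {patient_id}" if patient_id else ""
        raise EmptyMaskError(f"no tumor above SUV {threshold}{who}")
    return TumorMask(mask=mask, threshold=float(threshold))


def compute_surrogates(
    pre_volume: SUVVolume, post_volume: SUVVolume, mask: TumorMask
) -> SurrogateSet:
    """Compute the survival surrogates over one mask on a registered pair.

    All means run over the same masked voxel set. Masked pre-treatment voxels
    must be strictly positive (guaranteed whenever the mask came from a
    positive delineation threshold, but guarded regardless).
    """
    if pre_volume.shape != post_volume.shape:
        raise GridMismatchError(
            f"pre {pre_volume.shape} and post {post_volume.shape} volumes are on "
            "different grids; inputs must be registered upstream"
        )
    if mask.mask.shape != pre_volume.shape:
        raise GridMismatchError(
            f"mask shape {mask.mask.shape} does not match volume shape {pre_volume.shape}"
        )
    if not mask.mask.any():
        raise EmptyMaskError("mask is empty")
    pre = pre_volume.values[mask.mask]
    post = post_volume.values[mask.mask]
    if np.any(pre <= 0):
        raise ValueError("masked pre-treatment voxels must be > 0 to form voxel ratios")
    mean_pre = float(pre.mean())
    mean_post = float(post.mean())
    return SurrogateSet(
        mean_ratio=float((post / pre).mean()),
        ratio_of_means=mean_post / mean_pre,
        mean_diff=mean_pre - mean_post,
        mean_pre=mean_pre,
        mean_post=mean_post,
        n_voxels=int(pre.size),
    )


def outcome_indicator(label: str) -> int:
    """Map a pathologic-response label to the recurrence indicator R.

    R = 1 for nonresponders (gRD), R = 0 for responders (pCR or mRD).
    """
    if label in RESPONDER_LABELS:
        return 0
    if label in NONRESPONDER_LABELS:
        return 1
    raise LabelError(
        f"unknown response label {label!r}; expected one of "
        f"{sorted(RESPONDER_LABELS | NONRESPONDER_LABELS)}"
    )


def build_cohort_table(
    patients: Iterable, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Assemble the per-patient cohort table used for model fitting.

    ``patients`` yields objects with ``patient_id``, ``pre_volume``,
    ``post_volume`` and a ``label`` (or ``true_label``) attribute. Returns one
    row per patient: the surrogate set plus the binary outcome ``R``
    (1 = nonresponder). An empty iterable yields an empty table.
    """
    rows = []
    for p in patients:
        label = getattr(p, "label", None) or getattr(p, "true_label")
        mask = delineate_tumor(p.pre_volume, threshold, patient_id=p.patient_id)
        surr = compute_surrogates(p.pre_volume, p.post_volume, mask)
        rows.append({"patient_id": p.patient_id, **surr.as_dict(), "R": outcome_indicator(label)})
    columns = [
        "patient_id",
        "mean_ratio",
        "ratio_of_means",
        "mean_diff",
        "mean_pre",
        "mean_post",
        "n_voxels",
        "R",
    ]
    return pd.DataFrame(rows, columns=columns)


def load_suv_volume(path: str | Path) -> SUVVolume:
    """Read a NIfTI SUV volume; voxel spacing is taken from the header."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SUVVolume(values=data, spacing=spacing)


def cohort_table_from_files(
    outcomes_csv: str | Path, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Build the cohort table from an outcomes CSV referencing NIfTI pairs.

    The CSV must contain columns ``patient_id``, ``label``, ``pre_path`` and
    ``post_path`` (paths relative to the CSV's directory or absolute).
    """
    outcomes_csv = Path(outcomes_csv)
    table = pd.read_csv(outcomes_csv)
    required = {"patient_id", "label", "pre_path", "post_path"}
    missing = required - set(table.columns)
    if missing:
        raise LabelError(f"outcomes CSV is missing columns: {sorted(missing)}")
    base = outcomes_csv.parent

    class _P:
        def __init__(self, row):
            self.patient_id = str(row.patient_id)
            self.label = str(row.label)
            self.pre_volume = load_suv_volume(_resolve(base, row.pre_path))
            self.post_volume = load_suv_volume(_resolve(base, row.post_path))

    return build_cohort_table((_P(r) for r in table.itertuples()), threshold)


def _resolve(base: Path, p: str | Path) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p
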