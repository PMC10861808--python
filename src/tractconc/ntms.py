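"""Construction of motor-response masks from stimulation exports.

Responses are classified into three classes by amplitude and primary-motor
(M1) membership:

* ``+M1+`` — positive response (amplitude >= threshold) inside M1;
* ``-M1+`` — positive response outside M1;
* ``-M1-`` — negative response outside M1.

Negative responses inside M1 are excluded, as are responses whose latency
falls outside the physiological window (inclusive bounds).  Classified
records are rasterized onto a 1 mm3 grid and filtered against the
intracranial and white-matter masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import BinaryMask, Grid, Volume, require_same_grid

logger = logging.getLogger(__name__)

POS_IN_M1 = "+M1+"
POS_OUT_M1 = "-M1+"
NEG_OUT_M1 = "-M1-"
EXCLUDED = "excluded"
CLASSES = (POS_IN_M1, POS_OUT_M1, NEG_OUT_M1)

DEFAULT_AMP_THRESHOLD_UV = 50.0
DEFAULT_LATENCY_WINDOW_MS = (18.0, 26.0)

RESPONSE_CSV_COLUMNS = [
    "subject_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "amplitude_uv",
    "latency_ms",
    "muscle",
    "hemisphere",
    "manually_excluded",
]


@dataclass(frozen=True)
class ResponseRecord:
    """One stimulation response: world position plus electrophysiology."""

    position: tuple[float, float, float]
    amplitude: float
    latency: float
    muscle: str = "APB"
    hemisphere: str = "left"
    manually_excluded: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ValueError(f"amplitude must be finite and >= 0, got {self.amplitude}")
        if not (np.isfinite(self.latency) and self.latency >= 0):
            raise ValueError(f"latency must be finite and >= 0, got {self.latency}")


@dataclass
class ClassifiedResponseMask:
    """A rasterized, class-labelled response mask."""

    mask: BinaryMask
    klass: str
    n_responses: int

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"klass must be one of {CLASSES}, got {self.klass!r}")


def classify_response(
    rec: ResponseRecord,
    m1: BinaryMask,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD_UV,
    latency_window: tuple[float, float] = DEFAULT_LATENCY_WINDOW_MS,
) -> str:
    """Classify a record into ``+M1+``, ``-M1+``, ``-M1-`` or ``excluded``.

    Amplitude at or above the threshold counts as positive.  Latency
    bounds are inclusive.  A negative response inside M1 is excluded, as
    is a position falling outside the M1 grid extent (logged — it signals
    a registration problem).
    """
    if rec.manually_excluded:
        return EXCLUDED
    lo, hi = latency_window
    if not (lo <= rec.latency <= hi):
        return EXCLUDED
    ijk = np.rint(m1.world_to_voxel(rec.position)[0]).astype(int)
    if (ijk < 0).any() or (ijk >= np.array(m1.shape)).any():
        logger.warning(
            "response at %s maps to voxel %s outside grid %s — excluded "
            "(possible registration problem)",
            rec.position,
            tuple(ijk),
            m1.shape,
        )
        return EXCLUDED
    inside_m1 = bool(m1.data[tuple(ijk)] > 0)
    positive = rec.amplitude >= amp_threshold
    if positive:
        return POS_IN_M1 if inside_m1 else POS_OUT_M1
    return EXCLUDED if inside_m1 else NEG_OUT_M1


def threshold_export(raw_export: Volume) -> BinaryMask:
    """Binarize a raw response export: strictly positive voxels become 1."""
    return BinaryMask((raw_export.data > 0).astype(np.uint8), raw_export.affine)


def remove_landmarks(responses: BinaryMask, intracranial: BinaryMask) -> BinaryMask:
    """Strip registration-landmark annotations: AND with the intracranial mask."""
    require_same_grid(responses, intracranial, "landmark removal")
    out = (responses.data.astype(bool) & intracranial.data.astype(bool)).astype(np.uint8)
    return BinaryMask(out, responses.affine)


def wm_filter(responses: BinaryMask, wm: BinaryMask, keep_in_wm: bool = True) -> BinaryMask:
    """Filter response voxels against the white-matter mask.

    Default keeps voxels inside WM; ``keep_in_wm=False`` keeps the
    complement (the wording of the source protocol is ambiguous, so both
    readings are available).
    """
    require_same_grid(responses, wm, "WM filtering")
    wm_fg = wm.data.astype(bool)
    if not keep_in_wm:
        wm_fg = ~wm_fg
    out = (responses.data.astype(bool) & wm_fg).astype(np.uint8)
    return BinaryMask(out, responses.affine)


def rasterize_responses(
    records: list[ResponseRecord],
    grid: Grid | Volume,
    klass: str,
    radius: float = 0.0,
) -> ClassifiedResponseMask:
    """Rasterize records of one class onto a grid.

    ``radius == 0`` marks only the voxel containing each point;
    ``radius > 0`` marks every voxel whose center lies within ``radius``
    mm of the point.  Rasterization is idempotent: coincident records set
    the same voxel once while still counting in ``n_responses``.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    g = grid.grid if isinstance(grid, Volume) else grid
    data = np.zeros(g.shape, dtype=np.uint8)
    carrier = Volume(np.zeros(g.shape, dtype=np.uint8), g.affine)
    shape = np.array(g.shape)
    for rec in records:
        pt = np.asarray(rec.position, dtype=float)
        cont = carrier.world_to_voxel(pt)[0]
        if radius == 0:
            ijk = np.rint(cont).astype(int)
            if (ijk < 0).any() or (ijk >= shape).any():
                logger.warning("response at %s falls outside the raster grid — skipped", rec.position)
                continue
            data[tuple(ijk)] = 1
        else:
            reach = np.ceil(radius / carrier.spacing).astype(int) + 1
            lo = np.maximum(np.floor(cont).astype(int) - reach, 0)
            hi = np.minimum(np.ceil(cont).astype(int) + reach + 1, shape)
            if (lo >= hi).any():
                continue
            ii, jj, kk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            idx = np.c_[ii.ravel(), jj.ravel(), kk.ravel()]
            centers = carrier.voxel_to_world(idx)
            within = np.linalg.norm(centers - pt, axis=1) <= radius
            sel = idx[within]
            data[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    return ClassifiedResponseMask(BinaryMask(data, g.affine), klass, len(records))


def read_responses_csv(path) -> pd.DataFrame:
    """Load a responses table, validating the expected columns."""
    df = pd.read_csv(path)
    missing = [c for c in RESPONSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"responses CSV {path} is missing columns: {missing}")
    return df


def records_from_frame(df: pd.DataFrame) -> list[ResponseRecord]:
    return [
        ResponseRecord(
            position=(row.x_mm, row.y_mm, row.z_mm),
            amplitude=row.amplitude_uv,
            latency=row.latency_ms,
            muscle=str(row.muscle),
            hemisphere=str(row.hemisphere),
            manually_excluded=bool(row.manually_excluded),
        )
        for row in df.itertuples()
    ]


def build_response_masks(
    records: list[ResponseRecord],
    m1: BinaryMask,
    intracranial: BinaryMask,
    wm: BinaryMask,
    grid: Grid | Volume | None = None,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD_UV,
    latency_window: tuple[float, float] = DEFAULT_LATENCY_WINDOW_MS,
    radius: float = 0.0,
    keep_in_wm: bool = True,
) -> dict[str, ClassifiedResponseMask]:
    """Full response-mask construction for one subject.

    Classifies every record, rasterizes each class onto the target grid
    (defaults to the M1 grid), removes landmark annotations via the
    intracranial mask, and applies the WM filter.  Returns one mask per
    class; classes with no surviving records yield empty masks.
    """
    g = (grid or m1).grid if isinstance(grid or m1, Volume) else (grid or m1)
    by_class: dict[str, list[ResponseRecord]] = {k: [] for k in CLASSES}
    for rec in records:
        k = classify_response(rec, m1, amp_threshold, latency_window)
        if k != EXCLUDED:
            by_class[k].append(rec)
    out: dict[str, ClassifiedResponseMask] = {}
    claimed = np.zeros(g.shape, dtype=bool)
    for klass in CLASSES:  # fixed precedence keeps the class masks disjoint
        recs = by_class[klass]
        crm = rasterize_responses(recs, g, klass, radius=radius)
        filtered = wm_filter(remove_landmarks(crm.mask, intracranial), wm, keep_in_wm)
        data = filtered.data.astype(bool)
        overlap = int(np.count_nonzero(data & claimed))
        if overlap:
            logger.warning(
                "%d voxel(s) of class %s also hit by a higher-precedence class — dropped",
                overlap,
                klass,
            )
            data &= ~claimed
        claimed |= data
        out[klass] = ClassifiedResponseMask(
            BinaryMask(data.astype(np.uint8), filtered.affine), klass, crm.n_responses
        )
    return out
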