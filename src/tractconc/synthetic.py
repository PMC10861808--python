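"""Synthetic phantom cohorts with the statistical structure the analysis assumes.

Each phantom subject consists of:

* a tubular tract mask along a smooth random curve, widening into a fan
  near the top face (a stand-in for a motor tract reaching cortex);
* an ensemble of T probability maps built from the tract's signed
  distance field under independent smooth deformations plus voxel noise,
  so that across-member variability concentrates near the mask boundary;
* three response classes whose distance-to-tract distributions are
  ordered (inside/near < intermediate < far), with positive-in-M1
  responses constrained to a cortical M1 region;
* intracranial / WM / M1 masks and a responses CSV so the full pipeline
  can run end-to-end.

All numeric defaults are emulation parameters chosen so the three classes
are separable at 1 mm resolution.  Every generator is a pure function of
(spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .ntms import (
    CLASSES,
    NEG_OUT_M1,
    POS_IN_M1,
    POS_OUT_M1,
    RESPONSE_CSV_COLUMNS,
    ClassifiedResponseMask,
)
from .volumes import BinaryMask, Volume, write_volume

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "SubjectBundle",
    "generate_tract",
    "generate_ensemble",
    "generate_responses",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom subject / cohort."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 1.0  # mm, isotropic
    tube_radius: float = 4.0  # mm
    fan_radius: float = 8.0  # mm, reached at the top of the track
    fan_fraction: float = 0.2  # top fraction of the track that widens
    boundary_softness: float = 1.5  # mm, sigmoid scale of the probability falloff
    ensemble_t: int = 20
    deform_sigma: float = 1.0  # mm, amplitude of the smooth deformation field
    noise_sigma: float = 0.03  # probability units, voxel noise sd
    # class -> (mean, sd) of the target distance-to-tract distribution (mm);
    # +M1+ uses |Normal|, the others Normal truncated at >= 0
    class_distances: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            POS_IN_M1: (0.0, 2.0),
            POS_OUT_M1: (6.0, 3.0),
            NEG_OUT_M1: (14.0, 4.0),
        }
    )
    responses_per_class: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_size", "tube_radius", "fan_radius", "boundary_softness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.deform_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("deform_sigma and noise_sigma must be >= 0")
        if self.ensemble_t < 1:
            raise ValueError("ensemble_t must be >= 1")
        means = [self.class_distances[k][0] for k in CLASSES]
        if not (means[0] < means[1] < means[2]):
            raise ValueError(f"class distance means must be ordered {CLASSES}, got {means}")

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    def replace(self, **kwargs) -> "PhantomSpec":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


@dataclass
class SubjectBundle:
    """Everything the analysis consumes for one phantom subject."""

    subject_id: str
    spec: PhantomSpec
    tract: BinaryMask
    ensemble_members: list[Volume]
    responses: dict[str, ClassifiedResponseMask]
    m1: BinaryMask
    wm: BinaryMask
    intracranial: BinaryMask
    alt_mask: BinaryMask  # a second segmentation method's output
    records: pd.DataFrame  # responses CSV rows
    metadata: dict


def _centerline(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth (Z, 2) in-plane centerline, bounded so the tube fits the grid."""
    nx, ny, nz = spec.grid_shape
    margin = spec.fan_radius / spec.voxel_size + 2
    max_amp = min(nx, ny) / 2 - margin
    if max_amp <= 0:
        raise ValueError(
            f"radii too large for the grid: fan_radius {spec.fan_radius} mm does not "
            f"fit in a {spec.grid_shape} grid at {spec.voxel_size} mm"
        )
    wiggle = rng.standard_normal((nz, 2))
    wiggle = ndimage.gaussian_filter1d(wiggle, sigma=max(nz / 8, 1), axis=0)
    peak = np.abs(wiggle).max()
    if peak > 0:
        wiggle *= min(max_amp / 3, 8.0) / peak
    center = np.array([nx / 2, ny / 2])
    return center + wiggle


def generate_tract(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    centerline: np.ndarray | None = None,
) -> BinaryMask:
    """Tubular mask along a smooth curve from the bottom to the top face.

    The radius is ``tube_radius`` along most of the track and ramps
    linearly to ``fan_radius`` over the top ``fan_fraction`` of slices.
    ``centerline`` (a (Z, 2) array of in-plane voxel coordinates) may be
    supplied to force e.g. a straight cylinder.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    nx, ny, nz = spec.grid_shape
    if centerline is None:
        centerline = _centerline(spec, rng)
    else:
        centerline = np.asarray(centerline, dtype=float)
        if centerline.shape != (nz, 2):
            raise ValueError(f"centerline must have shape ({nz}, 2)")
        if spec.fan_radius / spec.voxel_size + 1 > min(nx, ny) / 2:
            raise ValueError("radii too large for the grid")
    fan_start = int(round(nz * (1 - spec.fan_fraction)))
    xs = (np.arange(nx) + 0.0)[:, None]
    ys = (np.arange(ny) + 0.0)[None, :]
    data = np.zeros(spec.grid_shape, dtype=np.uint8)
    for z in range(nz):
        if z < fan_start:
            r_mm = spec.tube_radius
        else:
            frac = (z - fan_start) / max(nz - 1 - fan_start, 1)
            r_mm = spec.tube_radius + frac * (spec.fan_radius - spec.tube_radius)
        r_vox = r_mm / spec.voxel_size
        cx, cy = centerline[z]
        data[:, :, z] = ((xs - cx) ** 2 + (ys - cy) ** 2) <= r_vox**2
    mask = BinaryMask(data, spec.affine())
    labeled, n = ndimage.label(data, structure=np.ones((3, 3, 3)))
    if n != 1:
        raise RuntimeError(f"generated tract has {n} connected components, expected 1")
    return mask


def _signed_distance(mask: BinaryMask) -> np.ndarray:
    """Signed distance to the mask surface, mm: positive outside, negative inside."""
    fg = mask.data > 0
    sampling = mask.spacing
    outside = ndimage.distance_transform_edt(~fg, sampling=sampling)
    inside = ndimage.distance_transform_edt(fg, sampling=sampling)
    return outside - inside


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _member(
    sdist: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    field = sdist
    if spec.deform_sigma > 0:
        delta = ndimage.gaussian_filter(rng.standard_normal(sdist.shape), sigma=4.0)
        sd = delta.std()
        if sd > 0:
            delta *= spec.deform_sigma / sd
        field = sdist + delta
    prob = _sigmoid(-field / spec.boundary_softness)
    if spec.noise_sigma > 0:
        prob = prob + rng.normal(0.0, spec.noise_sigma, size=prob.shape)
    return np.clip(prob, 0.0, 1.0).astype(np.float32)


def generate_ensemble(
    tract: BinaryMask, spec: PhantomSpec, rng: np.random.Generator | None = None
) -> list[Volume]:
    """T probability maps: sigmoid of the deformed signed distance plus noise.

    With ``deform_sigma == noise_sigma == 0`` all members are identical
    and thresholding the mean at 0.5 recovers the tract exactly.
    """
    if spec.ensemble_t < 2:
        raise ValueError("an ensemble needs at least 2 members")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    sdist = _signed_distance(tract)
    return [Volume(_member(sdist, spec, rng), tract.affine) for _ in range(spec.ensemble_t)]


def _draw_target(klass: str, mean: float, sd: float, rng: np.random.Generator) -> float:
    if klass == POS_IN_M1:
        return abs(rng.normal(mean, sd))
    for _ in range(1000):
        t = rng.normal(mean, sd)
        if t >= 0:
            return t
    return max(mean, 0.0)


def generate_responses(
    tract: BinaryMask,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    m1: BinaryMask | None = None,
) -> dict[str, ClassifiedResponseMask]:
    """Sample response voxels whose tract distance follows each class's target.

    Candidates must match the drawn distance within +-0.5 mm (the
    tolerance widens if no voxel qualifies, falling back to the nearest
    achievable distance).  ``+M1+`` candidates are constrained inside the
    M1 mask when given, and in-tract candidates are kept within 2 mm of
    the boundary (responses live at the cortical interface, not deep in
    the tract core).  The three class masks are pairwise disjoint.
    """
    if tract.foreground_count == 0:
        raise ValueError("tract mask is empty")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    fg = tract.data > 0
    dist = ndimage.distance_transform_edt(~fg, sampling=tract.spacing)
    depth = ndimage.distance_transform_edt(fg, sampling=tract.spacing)
    far_mean = spec.class_distances[NEG_OUT_M1][0]
    if dist.max() < far_mean:
        raise ValueError(
            f"grid too small: max achievable distance {dist.max():.1f} mm is below "
            f"the far-class mean {far_mean:.1f} mm"
        )
    shallow = depth <= 2.0  # in-tract candidates stay near the boundary
    used = np.zeros(tract.shape, dtype=bool)
    out: dict[str, ClassifiedResponseMask] = {}
    for klass in CLASSES:
        mean, sd = spec.class_distances[klass]
        data = np.zeros(tract.shape, dtype=np.uint8)
        n_placed = 0
        for _ in range(spec.responses_per_class):
            t = _draw_target(klass, mean, sd, rng)
            chosen = None
            for tol in (0.5, 1.0, 2.0, 4.0):
                ok = (np.abs(dist - t) <= tol) & ~used & shallow
                if m1 is not None:
                    ok &= (m1.data > 0) if klass == POS_IN_M1 else (m1.data == 0)
                cand = np.flatnonzero(ok.ravel())
                if len(cand):
                    chosen = cand[rng.integers(len(cand))]
                    break
            if chosen is None:
                # nearest achievable distance under the constraints
                ok = ~used & shallow
                if m1 is not None:
                    ok &= (m1.data > 0) if klass == POS_IN_M1 else (m1.data == 0)
                cand = np.flatnonzero(ok.ravel())
                if not len(cand):
                    raise RuntimeError(f"no candidate voxels left for class {klass}")
                chosen = cand[np.argmin(np.abs(dist.ravel()[cand] - t))]
            ijk = np.unravel_index(chosen, tract.shape)
            data[ijk] = 1
            used[ijk] = True
            n_placed += 1
        if n_placed == 0:
            raise RuntimeError(f"class {klass} ended up empty")
        out[klass] = ClassifiedResponseMask(BinaryMask(data, tract.affine), klass, n_placed)
    return out


def _m1_mask(tract: BinaryMask, spec: PhantomSpec) -> BinaryMask:
    """Cortical M1 stand-in: a 3 mm shell around the top fifth of the tract."""
    nz = tract.shape[2]
    top = np.zeros(tract.shape, dtype=bool)
    top[:, :, int(round(nz * 0.8)):] = tract.data[:, :, int(round(nz * 0.8)):] > 0
    if not top.any():
        raise RuntimeError("tract has no voxels in the top fifth of the grid")
    d = ndimage.distance_transform_edt(~top, sampling=tract.spacing)
    return BinaryMask((d <= 3.0).astype(np.uint8), tract.affine)


def _brain_masks(spec: PhantomSpec) -> tuple[BinaryMask, BinaryMask]:
    """Intracranial mask (grid interior, 3-voxel margin) and WM (eroded by 1)."""
    data = np.zeros(spec.grid_shape, dtype=np.uint8)
    data[3:-3, 3:-3, 3:-3] = 1
    intracranial = BinaryMask(data, spec.affine())
    wm = np.zeros(spec.grid_shape, dtype=np.uint8)
    wm[4:-4, 4:-4, 4:-4] = 1
    return intracranial, BinaryMask(wm, spec.affine())


_LOCATIONS = ["Frontal", "Supplementary Motor Area", "Subcentral", "Temporo-Insular", "Fronto-Insular"]
_DIAGNOSES = [
    "Astrocytoma WHO Grade 2",
    "Oligodendroglioma WHO Grade 2",
    "Anaplastic Astrocytoma WHO Grade 3",
    "Anaplastic Oligodendroglioma WHO Grade 3",
    "Glioblastoma WHO Grade 4",
]


def _records_frame(
    subject_id: str,
    responses: dict[str, ClassifiedResponseMask],
    intracranial: BinaryMask,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Responses CSV rows reproducing the rasterized class masks.

    Amplitudes/latencies are drawn consistently with each class, and three
    landmark-style rows outside the intracranial mask are appended to
    exercise landmark removal downstream.
    """
    from .volumes import world_coords_of_foreground

    rows = []
    hemi = "left" if rng.random() < 0.75 else "right"
    muscles = np.array(["APB", "FDI", "ADM"])
    for klass, crm in responses.items():
        pts = world_coords_of_foreground(crm.mask)
        positive = klass in (POS_IN_M1, POS_OUT_M1)
        for p in pts:
            amp = rng.uniform(60, 400) if positive else rng.uniform(5, 45)
            rows.append(
                dict(
                    subject_id=subject_id,
                    x_mm=p[0],
                    y_mm=p[1],
                    z_mm=p[2],
                    amplitude_uv=round(float(amp), 1),
                    latency_ms=round(float(rng.uniform(18.5, 25.5)), 2),
                    muscle=str(rng.choice(muscles)),
                    hemisphere=hemi,
                    manually_excluded=0,
                )
            )
    # landmark annotations sit outside the intracranial mask near a corner
    corner = np.array(intracranial.shape) - 2
    for off in ((0, 0, 0), (0, 1, 0), (1, 0, 0)):
        p = intracranial.voxel_to_world(corner - np.array(off))[0]
        rows.append(
            dict(
                subject_id=subject_id,
                x_mm=p[0],
                y_mm=p[1],
                z_mm=p[2],
                amplitude_uv=100.0,
                latency_ms=20.0,
                muscle="APB",
                hemisphere=hemi,
                manually_excluded=0,
            )
        )
    return pd.DataFrame(rows, columns=RESPONSE_CSV_COLUMNS)


def generate_subject(spec: PhantomSpec, subject_id: str = "sub-01") -> SubjectBundle:
    """One fully specified phantom subject, a pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    tract = generate_tract(spec, rng)
    members = generate_ensemble(tract, spec, rng)
    m1 = _m1_mask(tract, spec)
    intracranial, wm = _brain_masks(spec)
    responses = generate_responses(tract, spec, rng, m1=m1)
    # a second "method": one extra deformed draw, thresholded
    sdist = _signed_distance(tract)
    alt_prob = _member(sdist, spec.replace(noise_sigma=0.0), rng)
    alt_mask = BinaryMask((alt_prob > 0.5).astype(np.uint8), tract.affine)
    records = _records_frame(subject_id, responses, intracranial, spec, rng)
    metadata = dict(
        subject_id=subject_id,
        age=int(rng.integers(25, 70)),
        sex=str(rng.choice(["M", "F"])),
        tumor_location=str(rng.choice(_LOCATIONS)),
        hemisphere=str(rng.choice(["Left", "Right"], p=[0.75, 0.25])),
        tumor_volume_cm3=round(float(rng.uniform(4, 210)), 1),
        diagnosis=str(rng.choice(_DIAGNOSES)),
        peeling_depth_mm=25.0,
        seed=spec.seed,
    )
    return SubjectBundle(
        subject_id=subject_id,
        spec=spec,
        tract=tract,
        ensemble_members=members,
        responses=responses,
        m1=m1,
        wm=wm,
        intracranial=intracranial,
        alt_mask=alt_mask,
        records=records,
        metadata=metadata,
    )


def generate_cohort(
    n_subjects: int = 16, base_spec: PhantomSpec | None = None, seed: int = 0
) -> list[SubjectBundle]:
    """Independent phantom subjects with per-subject seeds spawned from ``seed``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base_spec = base_spec or PhantomSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects)
    bundles = []
    for i in range(n_subjects):
        spec_i = base_spec.replace(seed=int(child_seeds[i]))
        bundles.append(generate_subject(spec_i, subject_id=f"sub-{i + 1:02d}"))
    return bundles


def write_cohort(bundles: list[SubjectBundle], out_dir: str | Path) -> Path:
    """Write the file tree the pipeline CLI consumes.

    Layout::

        out_dir/cohort.csv
        out_dir/<subject>/responses.csv
        out_dir/<subject>/{m1,wm,intracranial,alt_mask}.nii.gz
        out_dir/<subject>/ensemble/member_##.nii.gz
        out_dir/<subject>/phantom_spec.json
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for b in bundles:
        sdir = out_dir / b.subject_id
        (sdir / "ensemble").mkdir(parents=True, exist_ok=True)
        for name, mask in (
            ("m1", b.m1),
            ("wm", b.wm),
            ("intracranial", b.intracranial),
            ("alt_mask", b.alt_mask),
            ("tract_truth", b.tract),
        ):
            write_volume(mask, sdir / f"{name}.nii.gz")
        for t, member in enumerate(b.ensemble_members):
            write_volume(member, sdir / "ensemble" / f"member_{t:02d}.nii.gz")
        b.records.to_csv(sdir / "responses.csv", index=False)
        (sdir / "phantom_spec.json").write_text(json.dumps(b.spec.to_dict(), indent=2, sort_keys=True))
        meta_rows.append(b.metadata)
    pd.DataFrame(meta_rows).to_csv(out_dir / "cohort.csv", index=False)
    return out_dir
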