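"""End-to-end orchestration over a cohort directory tree.

Expected input layout (as written by :func:`tractconc.synthetic.write_cohort`,
or assembled by hand from clinical exports)::

    data_dir/cohort.csv                      # optional cohort metadata
    data_dir/<subject>/responses.csv
    data_dir/<subject>/{m1,wm,intracranial}.nii.gz
    data_dir/<subject>/ensemble/*.nii*       # T probability maps
    data_dir/<subject>/alt_mask.nii.gz       # optional second method

Stages: response-mask construction -> ensemble aggregation -> concordance
(OC/Dice + Wilcoxon) -> uncertainty-vs-distance (joint histogram,
Spearman, linear trend) -> report.  Per-subject failures are isolated and
logged; a subject missing a class yields NA, never a fabricated 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, cohort_summary
from .concordance import (
    ConcordanceTable,
    cohort_mean_oc,
    dice,
    oc_ordering_check,
    overlap_coefficient,
    wilcoxon_signed_rank,
)
from .ensemble import ProbabilityEnsemble, binarize, ensemble_mean, uncertainty_map
from .ntms import (
    CLASSES,
    ClassifiedResponseMask,
    build_response_masks,
    read_responses_csv,
    records_from_frame,
)
from .uncdist import (
    binned_spearman,
    distance_map,
    joint_histogram,
    linear_trend,
    pair_uncertainty_distance,
    spearman,
)
from .volumes import BinaryMask, read_volume, write_volume

logger = logging.getLogger(__name__)

METHOD_PRIMARY = "primary"
METHOD_BASELINE = "baseline"

# filesystem-safe names for the class labels
CLASS_FILE_TAGS = {"+M1+": "pM1p", "-M1+": "mM1p", "-M1-": "mM1m"}

OC_DEFINITION_NOTE = (
    "overlap coefficient = |A n B| / min(|A|, |B|) (Szymkiewicz-Simpson): "
    "1 when the smaller mask is enclosed by the larger, 0 when disjoint"
)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters; defaults are the protocol's stated values."""

    amp_threshold: float = 50.0  # uV
    latency_window: tuple[float, float] = (18.0, 26.0)  # ms, inclusive
    binarize_tau: float = 0.5
    n_bins: int = 30
    uncertainty_estimator: str = "std"  # or "entropy"
    rasterize_radius: float = 0.0  # mm
    keep_in_wm: bool = True
    oc_precision: int = 3  # per-subject values
    summary_precision: int = 2  # cohort means / stds

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["latency_window"] = list(self.latency_window)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SubjectResult:
    subject_id: str
    oc: dict[str, dict[str, float | None]] = field(default_factory=dict)  # method -> klass -> oc
    dice_between_methods: float | None = None
    pairs: np.ndarray | None = None  # pooled (u, d) pairs for this subject
    pairs_by_class: dict[str, np.ndarray] = field(default_factory=dict)
    n_responses: dict[str, int] = field(default_factory=dict)
    error: str | None = None


def find_subjects(data_dir: str | Path) -> list[Path]:
    """Subject directories are those containing a responses.csv."""
    data_dir = Path(data_dir)
    return sorted(p.parent for p in data_dir.glob("*/responses.csv"))


def process_subject_ntms(sdir: Path, cfg: RunConfig) -> dict[str, ClassifiedResponseMask]:
    """Build and persist the three class masks for one subject."""
    m1 = BinaryMask.from_volume(read_volume(sdir / "m1.nii.gz"), threshold=0.5)
    intracranial = BinaryMask.from_volume(read_volume(sdir / "intracranial.nii.gz"), threshold=0.5)
    wm = BinaryMask.from_volume(read_volume(sdir / "wm.nii.gz"), threshold=0.5)
    records = records_from_frame(read_responses_csv(sdir / "responses.csv"))
    masks = build_response_masks(
        records,
        m1,
        intracranial,
        wm,
        amp_threshold=cfg.amp_threshold,
        latency_window=cfg.latency_window,
        radius=cfg.rasterize_radius,
        keep_in_wm=cfg.keep_in_wm,
    )
    derived = sdir / "derived"
    derived.mkdir(exist_ok=True)
    for klass, crm in masks.items():
        write_volume(crm.mask, derived / f"responses_{CLASS_FILE_TAGS[klass]}.nii.gz")
    return masks


def aggregate_subject_ensemble(sdir: Path, cfg: RunConfig):
    """Mean / binary mask / uncertainty map for one subject's ensemble."""
    ens_dir = sdir / "ensemble"
    if ens_dir.is_dir():
        ens = ProbabilityEnsemble.from_dir(ens_dir)
    else:
        ens = ProbabilityEnsemble.from_4d(sdir / "ensemble.nii.gz")
    mean = ensemble_mean(ens)
    mask = binarize(mean, cfg.binarize_tau)
    unc = uncertainty_map(ens, cfg.uncertainty_estimator)
    derived = sdir / "derived"
    derived.mkdir(exist_ok=True)
    write_volume(mean, derived / "mean.nii.gz")
    write_volume(mask, derived / "mask.nii.gz")
    write_volume(unc.volume, derived / "uncertainty.nii.gz")
    return mean, mask, unc


def analyze_subject(sdir: Path, cfg: RunConfig) -> SubjectResult:
    res = SubjectResult(subject_id=sdir.name)
    masks = process_subject_ntms(sdir, cfg)
    _, tract_mask, unc = aggregate_subject_ensemble(sdir, cfg)
    methods = {METHOD_PRIMARY: tract_mask}
    alt_path = sdir / "alt_mask.nii.gz"
    if alt_path.exists():
        methods[METHOD_BASELINE] = BinaryMask.from_volume(read_volume(alt_path), threshold=0.5)
    for method, mmask in methods.items():
        res.oc[method] = {}
        for klass in CLASSES:
            res.oc[method][klass] = overlap_coefficient(mmask, masks[klass].mask)
    if METHOD_BASELINE in methods:
        res.dice_between_methods = dice(methods[METHOD_PRIMARY], methods[METHOD_BASELINE])
    if tract_mask.foreground_count > 0:
        dmap = distance_map(tract_mask)
        all_pairs = []
        for klass in CLASSES:
            pairs = pair_uncertainty_distance(unc, dmap, masks[klass])
            res.pairs_by_class[klass] = pairs
            if len(pairs):
                all_pairs.append(pairs)
        res.pairs = np.vstack(all_pairs) if all_pairs else np.empty((0, 2))
    res.n_responses = {k: masks[k].n_responses for k in CLASSES}
    return res


def _concordance_frame(results: list[SubjectResult]) -> ConcordanceTable:
    rows = []
    dice_rows = []
    for r in results:
        for method, ocs in r.oc.items():
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "method": method,
                    **{ConcordanceTable.OC_COLUMNS[k]: ocs.get(k) for k in CLASSES},
                }
            )
        if r.dice_between_methods is not None:
            dice_rows.append(
                {
                    "subject_id": r.subject_id,
                    "method_a": METHOD_PRIMARY,
                    "method_b": METHOD_BASELINE,
                    "dice": r.dice_between_methods,
                }
            )
    if not rows:
        raise RuntimeError("no subject produced concordance rows")
    return ConcordanceTable(pd.DataFrame(rows), pd.DataFrame(dice_rows) if dice_rows else None)


def _concordance_summary(table: ConcordanceTable, results: list[SubjectResult]) -> dict:
    methods = sorted(table.frame["method"].unique())
    summary: dict = {"per_method": {}, "wilcoxon": {}}
    for method in methods:
        per = {}
        for klass in CLASSES:
            vals = table.column(method, klass).dropna()
            if len(vals) == 0:
                per[klass] = None
                continue
            mean, std = cohort_mean_oc(table, method, klass)
            per[klass] = {
                "mean": mean,
                "std": std,
                "median": float(vals.median()),
                "n": int(len(vals)),
            }
        ordering = []
        for r in results:
            ocs = r.oc.get(method, {})
            if all(ocs.get(k) is not None for k in CLASSES):
                ordering.append(oc_ordering_check(*[ocs[k] for k in CLASSES]))
        per["ordering_holds_fraction"] = (
            float(np.mean(ordering)) if ordering else None
        )
        summary["per_method"][method] = per
    if len(methods) == 2:
        a, b = methods
        for klass in CLASSES:
            xa = table.column(a, klass)
            xb = table.column(b, klass)
            joined = pd.concat([xa, xb], axis=1, keys=["a", "b"]).dropna()
            try:
                stat, p = wilcoxon_signed_rank(joined["a"].values, joined["b"].values)
                summary["wilcoxon"][klass] = {"methods": [a, b], "statistic": stat, "p_value": p}
            except ValueError as exc:
                summary["wilcoxon"][klass] = {"methods": [a, b], "error": str(exc)}
    return summary


def _uncdist_summary(results: list[SubjectResult], cfg: RunConfig, out_dir: Path) -> dict:
    pooled = [r.pairs for r in results if r.pairs is not None and len(r.pairs)]
    if not pooled:
        return {"error": "no uncertainty/distance pairs available"}
    pairs = np.vstack(pooled)
    hist = joint_histogram(pairs, n_bins=cfg.n_bins)
    hist.to_frame().to_csv(out_dir / "histogram.csv", index=False)
    out: dict = {"n_pairs": int(len(pairs)), "n_bins": hist.n_bins}
    try:
        rho, p = spearman(pairs)
        out["rho_pooled"], out["p_pooled"] = rho, p
    except ValueError as exc:
        out["rho_pooled_error"] = str(exc)
    b = binned_spearman(hist)
    if b is not None:
        out["rho_binned"], out["p_binned"] = b
    try:
        slope, intercept = linear_trend(pairs)
        out["slope"], out["intercept"] = slope, intercept
    except ValueError as exc:
        out["trend_error"] = str(exc)
    out["per_class"] = {}
    for klass in CLASSES:
        kp = [r.pairs_by_class.get(klass) for r in results]
        kp = [p_ for p_ in kp if p_ is not None and len(p_)]
        if not kp:
            out["per_class"][klass] = None
            continue
        cp = np.vstack(kp)
        entry: dict = {
            "n_pairs": int(len(cp)),
            "mean_distance_mm": float(cp[:, 1].mean()),
            "mean_uncertainty": float(cp[:, 0].mean()),
        }
        try:
            entry["rho"], entry["p_value"] = spearman(cp)
        except ValueError as exc:
            entry["rho_error"] = str(exc)
        out["per_class"][klass] = entry
    return out


def plot_joint_histogram(pairs: np.ndarray, hist, path: Path) -> None:
    """Summary figure: scatter, per-bin mean +- std, and the linear trend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(pairs[:, 1], pairs[:, 0], ".", ms=2, alpha=0.3, color="gray")
    centers = hist.bin_centers()
    keep = ~np.isnan(hist.means)
    ax.errorbar(centers[keep], hist.means[keep], yerr=hist.stds[keep], fmt="o", color="red")
    slope, intercept = linear_trend(pairs)
    xs = np.linspace(0, pairs[:, 1].max(), 50)
    ax.plot(xs, slope * xs + intercept, color="blue")
    ax.set_xlabel("distance to tract mask (mm)")
    ax.set_ylabel("uncertainty")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
    make_figure: bool = False,
) -> dict:
    """Run every stage over a cohort tree; returns the summary record.

    Writes concordance.csv, histogram.csv and summary.json under
    ``out_dir``.  Per-subject failures are isolated: the subject is
    reported with an error and NA metrics, and the run continues.
    """
    cfg = cfg or RunConfig()
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subject_dirs = find_subjects(data_dir)
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories (with responses.csv) under {data_dir}")
    results: list[SubjectResult] = []
    failures: dict[str, str] = {}
    for sdir in subject_dirs:
        try:
            results.append(analyze_subject(sdir, cfg))
        except Exception as exc:  # noqa: BLE001 — per-subject isolation is the contract
            logger.exception("subject %s failed", sdir.name)
            failures[sdir.name] = str(exc)
            results.append(SubjectResult(subject_id=sdir.name, error=str(exc)))
    ok = [r for r in results if r.error is None]
    summary: dict = {
        "tool": "tractconc",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "oc_definition": OC_DEFINITION_NOTE,
        "uncertainty_estimator": cfg.uncertainty_estimator,
        "n_subjects": len(subject_dirs),
        "n_failed": len(failures),
        "failures": failures,
    }
    if ok:
        table = _concordance_frame(ok)
        frame = table.frame.copy()
        for col in ConcordanceTable.OC_COLUMNS.values():
            frame[col] = frame[col].round(cfg.oc_precision)
        frame.to_csv(out_dir / "concordance.csv", index=False)
        if table.dice_frame is not None:
            table.dice_frame.round(cfg.oc_precision).to_csv(out_dir / "dice.csv", index=False)
        summary["concordance"] = _concordance_summary(table, ok)
        summary["uncertainty_distance"] = _uncdist_summary(ok, cfg, out_dir)
        if make_figure:
            pooled = [r.pairs for r in ok if r.pairs is not None and len(r.pairs)]
            if pooled:
                pairs = np.vstack(pooled)
                plot_joint_histogram(pairs, joint_histogram(pairs, cfg.n_bins), out_dir / "uncdist.png")
    cohort_csv = data_dir / "cohort.csv"
    if cohort_csv.exists():
        summary["cohort"] = cohort_summary(CohortTable.from_csv(cohort_csv))
    (out_dir / "summary.json").write_text(json.dumps(_round_floats(summary), indent=2, sort_keys=True))
    return summary


def _round_floats(obj, ndigits: int = 6):
    """Stable serialization: bound float precision so reruns are byte-identical."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
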