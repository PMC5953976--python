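"""End-to-end orchestration: simulate → segment → compare → survival.

Each stage is a plain function over files/DataFrames so it can be driven
either from Python or from the thin CLI in :mod:`petmtv.cli`.  Per-patient
failures during batch segmentation are isolated: the run continues, errors
are collected into a machine-readable ledger, and the caller decides the
exit status.  Every report embeds the run configuration and package version
for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .image_model import BoxVOI, SeedPoint, SUVImage, load_nifti, save_nifti
from .reference_region import PercistConfig, choose_reference, percist_threshold
from .segmentation import (
    MTVRecord,
    SegmentationConfig,
    edit_labels,
    percist_tumor_finder,
    segment_fixed,
    segment_pct_max,
    total_mtv,
)
from .agreement_stats import PairedMeasurements, agreement_report
from .survival_analysis import survival_report, validate_cohort
from .synthetic_data import (
    CohortSpec,
    LesionSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    perturb_annotations,
)

logger = logging.getLogger("petmtv")

ALL_METHODS = ("fixed25", "pct41", "percist")


@dataclass
class RunConfig:
    """Options shared by the pipeline stages; serialized into every report."""

    input_dir: str = "."
    output_dir: str = "out"
    methods: Tuple[str, ...] = ALL_METHODS
    observer_id: str = "obs1"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    percist: PercistConfig = field(default_factory=PercistConfig)
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        per = PercistConfig(**raw.pop("percist", {}))
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(segmentation=seg, percist=per, **raw)

    def provenance(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate_phantoms(
    out_dir,
    n_patients: int = 3,
    rng_seed: int = 0,
    observer_jitter_mm: float = 0.0,
) -> List[str]:
    """Write a small phantom dataset: NIfTI volumes + annotation JSON.

    Each phantom varies lesion size and heterogeneity deterministically from
    the seed.  With ``observer_jitter_mm`` > 0 a second observer's jittered
    annotations are written alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)
    ids = []
    for i in range(n_patients):
        pid = f"PH{i:03d}"
        hetero = i % 2 == 1
        semi = tuple(rng.uniform(14.0, 30.0, 3))
        lesion = LesionSpec(
            center=(130.0, 130.0, 120.0),
            semi_axes=semi,
            core_suv=10.0 if hetero else float(rng.uniform(4.0, 8.0)),
            rim_suv=4.5 if hetero else None,
        )
        spec = PhantomSpec(
            shape=(48, 48, 48),
            lesions=(lesion,),
            physiologic_spots=(((40.0, 150.0, 150.0), 16.0, 12.0),),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth, ann = generate_phantom(spec)
        ann["patient_id"] = pid
        save_nifti(image, out / f"{pid}_suv.nii.gz")
        with open(out / f"{pid}_annotations.json", "w") as fh:
            json.dump(ann, fh, indent=1)
        if observer_jitter_mm > 0:
            ann2 = perturb_annotations(
                ann,
                observer_jitter_mm,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                truth=truth,
                spacing=spec.spacing,
            )
            with open(out / f"{pid}_annotations_obs2.json", "w") as fh:
                json.dump(ann2, fh, indent=1)
        ids.append(pid)
    logger.info("wrote %d phantoms to %s", n_patients, out)
    return ids


def simulate_cohort_csv(out_path, spec: Optional[CohortSpec] = None) -> pd.DataFrame:
    df = generate_cohort(spec or CohortSpec())
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False)
    logger.info("wrote cohort (%d patients) to %s", len(df), out_path)
    return df


# ---------------------------------------------------------------------------
# segment
# ---------------------------------------------------------------------------

def segment_patient(
    image: SUVImage,
    annotations: dict,
    methods: Sequence[str] = ALL_METHODS,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    percist_cfg: PercistConfig = PercistConfig(),
    patient_id: str = "unknown",
    observer_id: str = "obs1",
) -> List[MTVRecord]:
    """All requested methods on one annotated image → one MTVRecord each.

    fixed25 grows one region per annotated seed (duplicate components are
    merged); pct41 recontours within each annotated constraining box;
    percist thresholds the whole image from the liver (or aorta) reference
    and removes labels located at the annotated physiological centres.
    """
    records = []
    for method in methods:
        if method == "fixed25":
            masks = []
            seen = set()
            for seed in annotations["seeds"]:
                m = segment_fixed(image, SeedPoint(tuple(seed)), seg_cfg)
                key = tuple(np.flatnonzero(m.mask.ravel())[:1]) + (m.voxel_count,)
                if key not in seen:
                    seen.add(key)
                    masks.append(m)
        elif method == "pct41":
            masks = [
                segment_pct_max(
                    image,
                    BoxVOI(tuple(b["center_mm"]), tuple(b["size_mm"])),
                    seg_cfg,
                )
                for b in annotations["boxes"]
            ]
        elif method == "percist":
            ref = choose_reference(
                annotations.get("liver_involved", False),
                image,
                annotations["liver_center_mm"],
                annotations["aorta_center_mm"],
                percist_cfg,
            )
            thr = percist_threshold(ref, percist_cfg)
            labels = percist_tumor_finder(image, thr, seg_cfg)
            excluded = set()
            spacing = np.asarray(image.spacing)
            origin = np.asarray(image.origin)
            for c in annotations.get("physiologic_centers_mm", []):
                vox = np.round((np.asarray(c) - origin) / spacing).astype(int)
                vox = np.clip(vox, 0, np.asarray(image.shape) - 1)
                lab = int(labels.labels[tuple(vox)])
                if lab > 0:
                    excluded.add(lab)
            labels = edit_labels(labels, excluded)
            masks = [labels.region(k) for k in range(1, labels.n_regions + 1)]
        else:
            raise ValueError(f"unknown method {method!r}")
        records.append(
            total_mtv(masks, image, patient_id=patient_id, method=method,
                      observer_id=observer_id)
        )
    return records


def run_segment(config: RunConfig) -> Tuple[pd.DataFrame, List[dict]]:
    """Batch segmentation over ``<input_dir>/<pid>_suv.nii.gz`` volumes.

    Returns the MTV table (one row per patient × method × observer) and the
    per-patient error ledger; failing patients are logged and skipped.
    """
    in_dir = Path(config.input_dir)
    rows, errors = [], []
    volumes = sorted(in_dir.glob("*_suv.nii.gz")) + sorted(in_dir.glob("*_suv.nii"))
    for vol in volumes:
        pid = vol.name.split("_suv.nii")[0]
        try:
            image = load_nifti(vol)
            ann_paths = {"obs1": in_dir / f"{pid}_annotations.json"}
            obs2 = in_dir / f"{pid}_annotations_obs2.json"
            if obs2.exists():
                ann_paths["obs2"] = obs2
            if not ann_paths["obs1"].exists():
                raise FileNotFoundError(f"missing annotations for {pid}")
            for obs, ap in ann_paths.items():
                with open(ap) as fh:
                    ann = json.load(fh)
                for rec in segment_patient(
                    image, ann, config.methods, config.segmentation,
                    config.percist, patient_id=pid, observer_id=obs,
                ):
                    rows.append(
                        {
                            "patient_id": rec.patient_id,
                            "method": rec.method,
                            "observer_id": rec.observer_id,
                            "n_lesions": len(rec.lesion_volumes),
                            "total_mtv_cm3": rec.total_mtv,
                            "tlg": rec.tlg,
                        }
                    )
        except Exception as exc:  # noqa: BLE001 — per-patient isolation
            logger.error("patient %s failed: %s", pid, exc)
            errors.append({"patient_id": pid, "error": str(exc)})
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "method", "observer_id", "n_lesions",
                 "total_mtv_cm3", "tlg"],
    )
    return df, errors


# ---------------------------------------------------------------------------
# compare
# ---------------------------------------------------------------------------

def run_compare(mtv_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise agreement between every method × observer column.

    The MTV table is pivoted to one column per (method, observer); each
    unordered column pair yields an ICC / tau / Bland–Altman row.
    """
    required = {"patient_id", "method", "observer_id", "total_mtv_cm3"}
    missing = required - set(mtv_table.columns)
    if missing:
        raise ValueError(f"MTV table missing columns: {sorted(missing)}")
    wide = mtv_table.pivot_table(
        index="patient_id",
        columns=["method", "observer_id"],
        values="total_mtv_cm3",
    )
    if wide.isna().any().any():
        offenders = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"patients missing in some columns: {offenders}")
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 method/observer columns to compare")
    cols = list(wide.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            name = f"{cols[i][0]}/{cols[i][1]} vs. {cols[j][0]}/{cols[j][1]}"
            pairs = PairedMeasurements(
                tuple(wide.index),
                wide[cols[i]].to_numpy(),
                wide[cols[j]].to_numpy(),
            )
            rows.append(agreement_report(pairs, pair_name=name).as_dict())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def run_survival(
    cohort: pd.DataFrame,
    mtv_columns: Optional[Sequence[str]] = None,
    config: Optional[RunConfig] = None,
) -> dict:
    """Per-method prognostic report (ROC / cut-off / KM / log-rank / Cox).

    PFS cut-offs are ROC-derived; the OS block reuses each method's
    PFS-derived cut-off, matching the clinical workflow of deriving one
    cut-off and applying it to both endpoints.
    """
    if mtv_columns is None:
        mtv_columns = [c for c in cohort.columns if c.startswith("mtv_")]
    if not mtv_columns:
        raise ValueError("no MTV columns found (expected 'mtv_*')")
    validate_cohort(cohort, mtv_columns)
    report: Dict[str, dict] = {"methods": {}}
    for col in mtv_columns:
        pfs = survival_report(cohort, col, endpoint="pfs")
        os_ = survival_report(
            cohort, col, endpoint="os", cutoff=pfs["cutoff_used_cm3"]
        )
        report["methods"][col] = {"pfs": pfs, "os": os_}
    report["config"] = (config or RunConfig()).provenance()
    return report
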