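"""File formats, atlas projection and pipeline orchestration.

The canonical interchange format is one TSV per subject (rows =
regions, columns = timepoints, first column the region name) plus a
manifest TSV (subject_id, file, label) and a YAML config echo.  Entropy
matrices travel as TSV with a JSON sidecar carrying (m, r, tau) and the
undefined-entry count.  An optional NIfTI front-end averages a 4D
functional volume over an integer-labelled atlas; it assumes the two
volumes are already on the same grid (registration, filtering and
motion correction are upstream concerns, not replicated here).

``run_all`` executes the full pipeline from a single YAML config:
entropy grid -> (m, r, tau) optimization -> biomarker selection ->
LOOCV classification, writing every artifact plus a provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mselat.biomarkers import BiomarkerSet, biomarker_report, select_biomarkers
from mselat.classify import LoocvResult, NestedSelection, SvmGridConfig, holdout_eval, loocv
from mselat.mse import EntropyMatrix, MseParams, entropy_matrix
from mselat.optimize import ParamGrid, optimize_all
from mselat.synthetic import RoiTimeSeriesDataset, SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "AtlasSpec",
    "read_roi_matrix",
    "write_roi_matrix",
    "write_dataset",
    "read_dataset",
    "write_entropy_matrix",
    "read_entropy_matrix",
    "extract_roi_timeseries",
    "load_config",
    "run_all",
]


class ParseError(ValueError):
    """Raised for malformed input files, with row/column context."""


@dataclass(frozen=True)
class AtlasSpec:
    """Integer-labelled atlas volume and the region ids to extract."""

    atlas_volume: np.ndarray
    region_ids: tuple[int, ...]
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.region_names):
            raise ValueError("region_ids and region_names must align")
        if any(i == 0 for i in self.region_ids):
            raise ValueError("region_ids must be nonzero (0 is background)")


def write_roi_matrix(path, matrix: np.ndarray, region_names: list[str]) -> None:
    """Write one subject's region x time matrix as TSV."""
    df = pd.DataFrame(matrix, index=region_names)
    df.columns = [str(t) for t in range(matrix.shape[1])]
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_roi_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a subject TSV back into (matrix, region_names)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows/columns")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate region name {dup!r}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(f"{path}: non-numeric cell at region {row!r}, column {col!r}")
        if df[col].isna().any():
            row = df.index[df[col].isna().argmax()]
            raise ParseError(f"{path}: missing value at region {row!r}, column {col!r}")
    matrix = df.to_numpy(dtype=float)
    return matrix, [str(r) for r in df.index]


def write_dataset(ds: RoiTimeSeriesDataset, out_dir, cfg: SyntheticConfig | None = None) -> Path:
    """Write a dataset as per-subject TSVs plus manifest and config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in range(ds.n_subjects):
        fname = f"sub-{s + 1:03d}.tsv"
        write_roi_matrix(out_dir / fname, ds.data[s], ds.region_names)
        rows.append({"subject_id": f"sub-{s + 1:03d}", "file": fname, "label": int(ds.labels[s])})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    if cfg is not None:
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump({"simulate": asdict(cfg), "provenance": ds.provenance}, fh)
    return out_dir


def read_dataset(manifest_path) -> RoiTimeSeriesDataset:
    """Load a dataset from a manifest TSV (subject_id, file, label)."""
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "file", "label"}
    if not required <= set(man.columns):
        raise ParseError(f"{manifest_path}: manifest needs columns {sorted(required)}")
    if man["subject_id"].duplicated().any():
        raise ParseError(f"{manifest_path}: duplicate subject_id")
    mats, names = [], None
    for _, row in man.iterrows():
        m, region_names = read_roi_matrix(manifest_path.parent / row["file"])
        if names is None:
            names = region_names
        elif names != region_names:
            raise ParseError(f"{row['file']}: region names differ from first subject")
        mats.append(m)
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise ParseError(f"{manifest_path}: subjects have differing shapes {shapes}")
    return RoiTimeSeriesDataset(
        data=np.stack(mats),
        labels=man["label"].to_numpy(dtype=int),
        region_names=names,
        provenance=f"loaded from {manifest_path}",
    )


def write_entropy_matrix(path, mat: EntropyMatrix, region_names: list[str] | None = None) -> None:
    """Entropy matrix TSV (rows=subjects, cols=regions) + JSON sidecar."""
    path = Path(path)
    names = region_names or [f"ROI{g + 1:03d}" for g in range(mat.n_regions)]
    df = pd.DataFrame(mat.values, columns=names)
    df.index = [f"sub-{s + 1:03d}" for s in range(mat.n_subjects)]
    df.index.name = "subject"
    df.to_csv(path, sep="\t", float_format="%.17g")
    sidecar = {
        "m": mat.params.m,
        "r": mat.params.r,
        "tau": mat.params.tau,
        "n_undefined": mat.n_undefined,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_entropy_matrix(path) -> tuple[EntropyMatrix, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    params = MseParams(m=sidecar["m"], r=sidecar["r"], tau=sidecar["tau"])
    return EntropyMatrix(values=df.to_numpy(dtype=float), params=params), list(df.columns)


def extract_roi_timeseries(func_4d: np.ndarray, atlas: AtlasSpec) -> tuple[np.ndarray, list[str]]:
    """Mean time series per atlas region from a 4D functional volume.

    ``func_4d`` is (x, y, z, t); the atlas volume must share the
    spatial grid.  Regions with no voxels yield NaN rows and a warning.
    """
    func_4d = np.asarray(func_4d, dtype=float)
    vol = np.asarray(atlas.atlas_volume)
    if func_4d.ndim != 4:
        raise ValueError(f"functional volume must be 4D, got shape {func_4d.shape}")
    if func_4d.shape[:3] != vol.shape:
        raise ValueError(
            f"spatial grids differ: functional {func_4d.shape[:3]} vs atlas {vol.shape}"
        )
    n_t = func_4d.shape[3]
    out = np.full((len(atlas.region_ids), n_t), np.nan)
    flat_func = func_4d.reshape(-1, n_t)
    flat_lab = vol.reshape(-1)
    for i, rid in enumerate(atlas.region_ids):
        mask = flat_lab == rid
        if not mask.any():
            logger.warning("extract_roi_timeseries: label %d has no voxels", rid)
            continue
        out[i] = flat_func[mask].mean(axis=0)
    return out, list(atlas.region_names)


def extract_roi_timeseries_nifti(func_path, atlas_path, region_ids=None, region_names=None):
    """NIfTI front-end of :func:`extract_roi_timeseries`.

    Loads a 4D functional image and a 3D integer atlas with nibabel.
    ``region_ids`` defaults to 1..90 (the cortical parcels of the AAL
    atlas); the volumes must already share a grid — no resampling is
    attempted.
    """
    import nibabel as nib

    func = np.asanyarray(nib.load(str(func_path)).dataobj)
    vol = np.asanyarray(nib.load(str(atlas_path)).dataobj).astype(int)
    if region_ids is None:
        region_ids = tuple(range(1, 91))
    if region_names is None:
        region_names = tuple(f"AAL{i}" for i in region_ids)
    atlas = AtlasSpec(atlas_volume=vol, region_ids=tuple(region_ids), region_names=tuple(region_names))
    return extract_roi_timeseries(func, atlas)


# ---------------------------------------------------------------------------
# config + run_all

_DEFAULT_CONFIG = {
    "simulate": {},  # SyntheticConfig fields; mutually exclusive with "data"
    "mse_grid": {},  # ParamGrid fields
    "biomarkers": {"alpha_final": 0.01, "fdr": False},
    "classification": {},  # SvmGridConfig fields + selection_scope + holdout
    "output": {},
}


def load_config(path) -> dict:
    """Load and validate a pipeline YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    unknown = set(cfg) - {"data", "simulate", "mse_grid", "biomarkers", "classification", "output"}
    if unknown:
        raise ParseError(f"{path}: unknown config blocks {sorted(unknown)}")
    if "data" in cfg and "simulate" in cfg:
        raise ParseError(f"{path}: give either a 'data' or a 'simulate' block, not both")
    if "data" not in cfg and "simulate" not in cfg:
        raise ParseError(f"{path}: a 'data' (manifest) or 'simulate' block is required")
    if "data" in cfg and "manifest" not in cfg["data"]:
        raise ParseError(f"{path}: the 'data' block needs a 'manifest' path")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_all(config, out_dir, seed: int | None = None) -> dict:
    """Execute the full pipeline from a config (path or dict).

    Stages: dataset -> parameter optimization -> entropy at the optimum
    -> biomarker selection -> LOOCV (and optional holdout).  All
    artifacts are written under ``out_dir``; the returned dict holds the
    in-memory results.  Deterministic given config + seed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings = {}

    def _stage(name):
        timings[name] = time.time()

    try:
        _stage("dataset")
        if "simulate" in config:
            sim_kwargs = dict(config.get("simulate") or {})
            if seed is not None:
                sim_kwargs["seed"] = seed
            if "planted_regions" in sim_kwargs:
                sim_kwargs["planted_regions"] = tuple(sim_kwargs["planted_regions"])
            sim_cfg = SyntheticConfig(**sim_kwargs)
            ds = generate_dataset(sim_cfg)
            write_dataset(ds, out_dir / "dataset", sim_cfg)
        else:
            ds = read_dataset(config["data"]["manifest"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'dataset' failed: {exc}") from exc

    try:
        _stage("optimize")
        grid_kwargs = dict(config.get("mse_grid") or {})
        for key in ("m_values", "r_values", "tau_values"):
            if key in grid_kwargs:
                grid_kwargs[key] = tuple(grid_kwargs[key])
        grid = ParamGrid(**grid_kwargs)
        search = optimize_all(ds, grid)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'optimize' failed: {exc}") from exc
    _write_search(out_dir, search, ds)

    try:
        _stage("biomarkers")
        bio_cfg = dict(config.get("biomarkers") or {})
        mat = entropy_matrix(ds, search.selected)
        bs = select_biomarkers(
            mat,
            ds.labels,
            alpha_final=bio_cfg.get("alpha_final", 0.01),
            region_names=ds.region_names,
            fdr=bio_cfg.get("fdr", False),
        )
        report = biomarker_report(bs, mat, ds.labels)
        report.to_csv(out_dir / "biomarkers.tsv", sep="\t", index=False, float_format="%.17g")
        (out_dir / "biomarkers.json").write_text(
            json.dumps(
                {
                    "region_indices": bs.region_indices,
                    "region_names": bs.region_names,
                    "pvalues": [float(p) for p in bs.pvalues],
                    "aucs": [float(a) for a in bs.aucs],
                    "alpha_final": bs.alpha_final,
                    "params": {"m": bs.params.m, "r": bs.params.r, "tau": bs.params.tau},
                },
                indent=2,
            )
        )
        write_entropy_matrix(out_dir / "entropy_matrix.tsv", mat, ds.region_names)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'biomarkers' failed: {exc}") from exc

    try:
        _stage("classify")
        cls_cfg = dict(config.get("classification") or {})
        scope = cls_cfg.pop("selection_scope", "fixed_biomarkers")
        holdout_train_n = cls_cfg.pop("holdout_train_n", None)
        svm_cfg_kwargs = dict(cls_cfg)
        if "exponent_range" in svm_cfg_kwargs:
            svm_cfg_kwargs["exponent_range"] = tuple(svm_cfg_kwargs["exponent_range"])
        svm_cfg = SvmGridConfig(**svm_cfg_kwargs)
        if scope == "nested":
            selector = NestedSelection(alpha=bio_cfg.get("alpha_final", 0.01))
        elif scope == "fixed_biomarkers":
            selector = bs
        else:
            raise ValueError(f"unknown selection_scope {scope!r}")
        result = loocv(mat, selector, ds.labels, svm_cfg, region_names=ds.region_names)
        _write_loocv(out_dir, result)
        holdout_acc = None
        if holdout_train_n:
            holdout_acc = holdout_eval(
                mat, bs, ds.labels, train_n=int(holdout_train_n),
                seed=seed if seed is not None else 0, cfg=svm_cfg,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'classify' failed: {exc}") from exc

    import mselat

    provenance = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "selected_params": {"m": search.selected.m, "r": search.selected.r, "tau": search.selected.tau},
        "n_biomarkers": len(bs),
        "loocv_accuracy": result.mean_accuracy,
        "holdout_accuracy": holdout_acc,
        "versions": {"mselat": mselat.__version__, "numpy": np.__version__},
        "stage_seconds": {
            name: round((list(timings.values()) + [time.time()])[i + 1] - t, 3)
            for i, (name, t) in enumerate(timings.items())
        },
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    logger.info("run_all: wrote artifacts to %s (%.1f s)", out_dir, time.time() - t_start)
    return {
        "dataset": ds,
        "search": search,
        "entropy_matrix": mat,
        "biomarkers": bs,
        "loocv": result,
        "holdout_accuracy": holdout_acc,
    }


def _write_search(out_dir: Path, search, ds) -> None:
    grid = search.grid
    rows = []
    for mi, m in enumerate(grid.m_values):
        for ti, tau in enumerate(grid.tau_values):
            row = {"m": m, "tau": tau}
            row.update(
                {f"r={r:g}": int(search.sig_counts[mi, ti, ri]) for ri, r in enumerate(grid.r_values)}
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "sig_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        search.auc_table_r,
        index=ds.region_names,
        columns=[f"r={r:g}" for r in grid.r_values],
    ).to_csv(out_dir / "auc_by_r.tsv", sep="\t", float_format="%.17g")
    pd.DataFrame(
        search.auc_table_tau,
        index=ds.region_names,
        columns=[f"tau={t}" for t in grid.tau_values],
    ).to_csv(out_dir / "auc_by_tau.tsv", sep="\t", float_format="%.17g")
    (out_dir / "selected_params.json").write_text(
        json.dumps(
            {
                "m": search.selected.m,
                "r": search.selected.r,
                "tau": search.selected.tau,
                "tau_candidates": list(search.tau_candidates),
                "audit": search.audit,
            },
            indent=2,
        )
    )


def _write_loocv(out_dir: Path, result: LoocvResult) -> None:
    rows = [
        {
            "subject": f"sub-{sid + 1:03d}",
            "true_label": t,
            "predicted_label": p,
            "correct": "T" if t == p else "F",
            "C": c,
            "g": g,
        }
        for sid, t, p, c, g in result.per_subject
    ]
    pd.DataFrame(rows).to_csv(out_dir / "loocv_predictions.tsv", sep="\t", index=False, float_format="%.17g")
    (out_dir / "loocv_summary.json").write_text(
        json.dumps(
            {
                "mean_accuracy": result.mean_accuracy,
                "n_subjects": len(result.per_subject),
                "selection_scope": result.selection_scope,
                "config": {
                    "exponent_range": list(result.config.exponent_range),
                    "exponent_step": result.config.exponent_step,
                    "base": result.config.base,
                    "inner_cv_folds": result.config.inner_cv_folds,
                    "standardize": result.config.standardize,
                },
            },
            indent=2,
        )
    )
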