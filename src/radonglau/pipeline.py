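"""End-to-end orchestration: manifest -> preprocessing -> Radon -> DWT ->
PCA -> SVM cross-validation, with reproducible run artifacts.

A run reads a CSV manifest (``path,label`` plus optional ground-truth
columns from the synthetic generator), extracts one feature vector per
image, evaluates the classifier under stratified cross-validation and
writes a JSON report, a per-image predictions CSV and a config snapshot
sufficient to reproduce the run byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from radonglau.classify import EvalReport, SvmConfig, cross_validate
from radonglau.preprocessing import ClaheConfig, clahe, to_grayscale
from radonglau.radon import (
    DEFAULT_UNIFIED_LENGTH,
    radon_project,
    resolve_angles,
    unified_signals,
)
from radonglau.wavelets import WaveletConfig, build_feature_vector

logger = logging.getLogger("radonglau")

VALID_LABELS = {"normal", "glaucoma"}

_KNOWN_KEYS = {
    "preprocessing": {"clip_limit", "tile_grid"},
    "radon": {"angles", "unified_length"},
    "wavelet": {"family", "mode"},
    "pca": {"variance_threshold", "paper_mode"},
    "svm": {"kernel", "C", "sigma", "search"},
    "cv": {"folds", "seed"},
}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration with the defaults of the method."""

    clip_limit: float = 0.01
    tile_grid: tuple[int, int] = (8, 8)
    angles: str | tuple[float, ...] = "9-even"
    unified_length: int = DEFAULT_UNIFIED_LENGTH
    wavelet_family: str = "bior1.5"
    wavelet_mode: str = "periodization"
    variance_threshold: float = 0.94
    paper_mode: bool = False
    svm_kernel: str = "rbf"
    svm_C: float = 11.313
    svm_sigma: float = 6.727
    svm_search: bool = False
    cv_folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "preprocessing": {"clip_limit": self.clip_limit, "tile_grid": list(self.tile_grid)},
            "radon": {
                "angles": self.angles if isinstance(self.angles, str) else list(self.angles),
                "unified_length": self.unified_length,
            },
            "wavelet": {"family": self.wavelet_family, "mode": self.wavelet_mode},
            "pca": {
                "variance_threshold": self.variance_threshold,
                "paper_mode": self.paper_mode,
            },
            "svm": {
                "kernel": self.svm_kernel,
                "C": self.svm_C,
                "sigma": self.svm_sigma,
                "search": self.svm_search,
            },
            "cv": {"folds": self.cv_folds, "seed": self.seed},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build a config from a nested dict, rejecting unknown keys."""
        unknown = set(data) - set(_KNOWN_KEYS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for section, keys in data.items():
            bad = set(keys) - _KNOWN_KEYS[section]
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        pre = data.get("preprocessing", {})
        rad = data.get("radon", {})
        wav = data.get("wavelet", {})
        pca = data.get("pca", {})
        svm = data.get("svm", {})
        cv = data.get("cv", {})
        kwargs: dict = {}
        if "clip_limit" in pre:
            kwargs["clip_limit"] = float(pre["clip_limit"])
        if "tile_grid" in pre:
            kwargs["tile_grid"] = tuple(int(v) for v in pre["tile_grid"])
        if "angles" in rad:
            a = rad["angles"]
            kwargs["angles"] = a if isinstance(a, str) else tuple(float(v) for v in a)
        if "unified_length" in rad:
            kwargs["unified_length"] = int(rad["unified_length"])
        if "family" in wav:
            kwargs["wavelet_family"] = str(wav["family"])
        if "mode" in wav:
            kwargs["wavelet_mode"] = str(wav["mode"])
        if "variance_threshold" in pca:
            kwargs["variance_threshold"] = float(pca["variance_threshold"])
        if "paper_mode" in pca:
            kwargs["paper_mode"] = bool(pca["paper_mode"])
        if "kernel" in svm:
            kwargs["svm_kernel"] = str(svm["kernel"])
        if "C" in svm:
            kwargs["svm_C"] = float(svm["C"])
        if "sigma" in svm:
            kwargs["svm_sigma"] = float(svm["sigma"])
        if "search" in svm:
            kwargs["svm_search"] = bool(svm["search"])
        if "folds" in cv:
            kwargs["cv_folds"] = int(cv["folds"])
        if "seed" in cv:
            kwargs["seed"] = int(cv["seed"])
        return cls(**kwargs)

    def wavelet_config(self) -> WaveletConfig:
        return WaveletConfig(family=self.wavelet_family, extension_mode=self.wavelet_mode)

    def clahe_config(self) -> ClaheConfig:
        return ClaheConfig(clip_limit=self.clip_limit, tile_grid=self.tile_grid)

    def svm_config(self) -> SvmConfig:
        return SvmConfig(kernel=self.svm_kernel, C=self.svm_C, sigma=self.svm_sigma)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a CSV manifest.

    Requires ``path`` and ``label`` columns; labels are normalized to
    lower case and must be ``normal`` or ``glaucoma``; duplicate paths are
    rejected.  A header-only CSV yields an empty manifest.
    """
    df = pd.read_csv(path, dtype={"path": str})
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing required columns: {sorted(missing)}")
    if len(df):
        df["label"] = df["label"].astype(str).str.strip().str.lower()
        bad = sorted(set(df["label"]) - VALID_LABELS)
        if bad:
            raise ValueError(f"unknown labels in manifest: {bad}")
        dup = df["path"][df["path"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate manifest paths: {dup}")
    return df


def image_features(
    gray: np.ndarray, config: RunConfig, preprocessed: bool = False
) -> np.ndarray:
    """Feature vector of one grayscale image (CLAHE -> Radon -> resample -> DWT)."""
    if not preprocessed:
        gray = clahe(gray, config.clahe_config())
    sino = radon_project(gray, config.angles)
    signals = unified_signals(sino, config.unified_length)
    return build_feature_vector(list(signals), config.wavelet_config())


def extract_features(
    manifest: pd.DataFrame,
    config: RunConfig,
    base_dir: str | Path = ".",
) -> tuple[np.ndarray, list[str], list[str], list[str], dict]:
    """Compute the feature matrix for every readable manifest image.

    Returns ``(X, labels, paths, skipped, dims)`` where ``skipped`` lists
    unreadable image paths (each skipped with a warning) and ``dims`` logs
    the per-stage dimensions: image shapes, sinogram rows, unified length,
    feature length.
    """
    base = Path(base_dir)
    angles = resolve_angles(config.angles)
    missing = [str(rec.path) for rec in manifest.itertuples(index=False)
               if not (base / rec.path).is_file()]
    if missing:
        raise FileNotFoundError(f"manifest images not found under {base}: {missing}")
    rows, labels, paths, skipped = [], [], [], []
    shapes = set()
    sino_rows = set()
    for rec in manifest.itertuples(index=False):
        p = base / rec.path
        try:
            with Image.open(p) as im:
                arr = np.asarray(im.convert("RGB"))
        except (OSError, ValueError) as exc:
            warnings.warn(f"skipping unreadable image {p}: {exc}")
            skipped.append(str(rec.path))
            continue
        gray = to_grayscale(arr)
        shapes.add(gray.shape)
        sino_rows.add(radon_project(gray, (0.0,)).values.shape[0])
        rows.append(image_features(gray, config))
        labels.append(rec.label)
        paths.append(str(rec.path))
    X = np.vstack(rows) if rows else np.empty((0, 0))
    dims = {
        "n_images": len(rows),
        "image_shapes": sorted(shapes),
        "sinogram_rows": sorted(sino_rows),
        "n_angles": len(angles),
        "unified_length": config.unified_length,
        "feature_length": int(X.shape[1]) if len(rows) else 0,
    }
    logger.info(
        "extracted %d images -> sinogram rows %s -> %d angles x L=%d -> %d features",
        dims["n_images"], dims["sinogram_rows"], dims["n_angles"],
        dims["unified_length"], dims["feature_length"],
    )
    return X, labels, paths, skipped, dims


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    base_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> EvalReport:
    """Execute all stages and (optionally) write run artifacts.

    ``manifest`` may be a path (then ``base_dir`` defaults to its parent) or
    a pre-loaded frame.  When ``out_dir`` is given, writes ``report.json``,
    ``predictions.csv`` and ``config.json`` there; the JSON is
    key-sorted, so identical runs produce byte-identical artifacts.
    """
    config = config or RunConfig()
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        manifest = load_manifest(mpath)
        if base_dir is None:
            base_dir = mpath.parent
    base_dir = Path(base_dir) if base_dir is not None else Path(".")
    if manifest.empty:
        raise ValueError("empty manifest: nothing to evaluate")

    X, labels, paths, skipped, dims = extract_features(manifest, config, base_dir)
    if not len(X):
        raise ValueError("no readable images in manifest")

    report = cross_validate(
        X,
        labels,
        config.svm_config(),
        k=config.cv_folds,
        seed=config.seed,
        variance_threshold=config.variance_threshold,
        paper_mode=config.paper_mode,
        search=config.svm_search,
    )
    report.aggregate["skipped_images"] = skipped
    report.aggregate["stage_dimensions"] = dims

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        pred = pd.DataFrame(
            {
                "path": paths,
                "label": labels,
                "score": report.scores,
                "prediction": np.where(report.predictions == 1, "glaucoma", "normal"),
                "fold": report.fold_assignment,
            }
        )
        pred.to_csv(out / "predictions.csv", index=False)
    return report


def run_sweep(
    manifest: pd.DataFrame | str | Path,
    base_config: RunConfig,
    angle_sets: list[str],
    unified_lengths: list[int],
    base_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Ablation grid over angle presets and unified signal lengths.

    Runs the pipeline once per (angles, length) cell and returns a tidy
    frame of aggregate metrics; when ``out_dir`` is given, each cell's
    report lands in ``<out_dir>/<angles>_<length>/`` and the summary in
    ``sweep.csv``.
    """
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        manifest = load_manifest(mpath)
        if base_dir is None:
            base_dir = mpath.parent
    records = []
    for angles in angle_sets:
        for length in unified_lengths:
            cfg = dataclasses.replace(base_config, angles=angles, unified_length=length)
            cell_dir = Path(out_dir) / f"{angles}_{length}" if out_dir else None
            rep = run_pipeline(manifest, cfg, base_dir=base_dir, out_dir=cell_dir)
            records.append(
                {
                    "angles": angles,
                    "unified_length": length,
                    "accuracy_pct": rep.aggregate["accuracy_pct"],
                    "auc": rep.aggregate["auc"],
                    "sensitivity": rep.aggregate["sensitivity"],
                    "specificity": rep.aggregate["specificity"],
                }
            )
    summary = pd.DataFrame(records)
    if out_dir is not None:
        summary.to_csv(Path(out_dir) / "sweep.csv", index=False)
    return summary
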