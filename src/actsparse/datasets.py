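"""Scored-image dataset input and tabular result output.

A dataset is a CSV manifest listing image paths and mean opinion scores
(MOS), together with the bounds of the rating instrument.  Scores on
heterogeneous Likert/percentage scales (1-7, 1-5, 0-100, ...) are
rescaled affinely to a common [0, 5] scale so datasets are comparable:
``score_05 = 5 * (raw - scale_min) / (scale_max - scale_min)``.

Manifest format: UTF-8 CSV with header columns ``image_path,score``,
preceded by ``#``-prefixed metadata lines::

    # dataset_name: demo
    # scale_min: 1
    # scale_max: 7
    image_path,score
    img/001.png,4.2

Bounds come from the declared instrument, never from the empirical
min/max (which would make rescaled scores dataset-dependent).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ValidationError

__all__ = [
    "ScoredDataset",
    "load_manifest",
    "rescale_scores",
    "write_results",
    "read_sparsity_table",
    "run_metadata",
]


@dataclass
class ScoredDataset:
    """Image references plus ratings rescaled to the common [0, 5] scale."""

    name: str
    frame: pd.DataFrame  # columns: image_path, score, score_05 (row order kept)
    scale_min: float
    scale_max: float

    @property
    def n_images(self) -> int:
        return len(self.frame)

    @property
    def image_paths(self) -> list[str]:
        return self.frame["image_path"].tolist()

    @property
    def scores_05(self) -> np.ndarray:
        return self.frame["score_05"].to_numpy()


def rescale_scores(raw, scale_min: float, scale_max: float):
    """Affinely map raw instrument scores onto [0, 5].

    The map is strictly monotone and invertible:
    ``raw = scale_min + score_05 * (scale_max - scale_min) / 5``.
    """
    if not scale_min < scale_max:
        raise DomainError(f"scale_min {scale_min} must be < scale_max {scale_max}")
    raw_arr = np.asarray(raw, dtype=np.float64)
    if np.any(raw_arr < scale_min) or np.any(raw_arr > scale_max):
        raise DomainError(
            f"raw score outside declared bounds [{scale_min}, {scale_max}]"
        )
    out = 5.0 * (raw_arr - scale_min) / (scale_max - scale_min)
    return float(out) if np.isscalar(raw) or raw_arr.ndim == 0 else out


def load_manifest(path: str | Path) -> ScoredDataset:
    """Read a scored-image manifest CSV into a :class:`ScoredDataset`.

    Image paths are resolved relative to the manifest's directory; row
    order is preserved.  Raises :class:`FormatError` for structural
    problems and :class:`ValidationError` for out-of-bounds scores or
    too few rows.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_rows = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    for key in ("dataset_name", "scale_min", "scale_max"):
        if key not in meta:
            raise FormatError(f"manifest {path} missing metadata line '# {key}: ...'")
    scale_min = float(meta["scale_min"])
    scale_max = float(meta["scale_max"])

    df = pd.read_csv(path, skiprows=header_rows)
    for col in ("image_path", "score"):
        if col not in df.columns:
            raise FormatError(f"manifest {path} missing required column {col!r}")
    if len(df) < 2:
        raise ValidationError(
            f"manifest {path} has {len(df)} data row(s); at least 2 required"
        )
    dupes = df["image_path"][df["image_path"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"duplicate image paths in manifest: {list(dupes)[:5]}")
    scores = df["score"].to_numpy(dtype=np.float64)
    bad = np.flatnonzero((scores < scale_min) | (scores > scale_max) |
                         ~np.isfinite(scores))
    if bad.size:
        raise ValidationError(
            f"manifest row {bad[0] + 1}: score {scores[bad[0]]} outside "
            f"declared bounds [{scale_min}, {scale_max}]"
        )
    base = path.parent
    frame = pd.DataFrame(
        {
            "image_path": [str((base / p)) for p in df["image_path"]],
            "score": scores,
            "score_05": rescale_scores(scores, scale_min, scale_max),
        }
    )
    return ScoredDataset(name=meta["dataset_name"], frame=frame,
                         scale_min=scale_min, scale_max=scale_max)


def run_metadata(config: dict, *, backend: str | None = None,
                 seeds: dict | None = None) -> dict:
    """Assemble the reproducibility metadata written beside every run."""
    import sklearn

    from . import __version__

    return {
        "created": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds or {},
        "backend": backend,
        "versions": {
            "actsparse": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def _float_repr(v) -> str:
    return repr(float(v))


def write_results(
    out_dir: str | Path,
    *,
    sparsity: pd.DataFrame | None = None,
    metric: str | None = None,
    battery: pd.DataFrame | None = None,
    per_layer: pd.DataFrame | None = None,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the tabular pipeline outputs to ``out_dir``.

    Emits whichever of the four artifacts are supplied:

    * ``sparsity_<metric>.csv`` — rows = images, columns = layer ids;
    * ``model_battery.csv`` — one row per model family;
    * ``per_layer.csv`` — per-layer R2, coefficient, p-value;
    * ``run_metadata.json`` — seeds, config, backend, versions.

    Floats are written with shortest-roundtrip repr, so reading a table
    back reproduces the values exactly.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}
    if sparsity is not None:
        metric = metric or sparsity.attrs.get("metric", "gini")
        p = out_dir / f"sparsity_{metric}.csv"
        tab = sparsity.copy()
        tab.insert(0, "metric", metric)
        tab.insert(0, "image", range(len(tab)))
        tab.to_csv(p, index=False, float_format=_float_repr)
        written["sparsity"] = p
    if battery is not None:
        p = out_dir / "model_battery.csv"
        battery.to_csv(p, index=False, float_format=_float_repr)
        written["battery"] = p
    if per_layer is not None:
        p = out_dir / "per_layer.csv"
        per_layer.to_csv(p, index=False, float_format=_float_repr)
        written["per_layer"] = p
    if metadata is not None:
        p = out_dir / "run_metadata.json"
        p.write_text(json.dumps(metadata, indent=2, sort_keys=True,
                                default=str) + "\n")
        written["metadata"] = p
    return written


def read_sparsity_table(path: str | Path) -> pd.DataFrame:
    """Read back a sparsity CSV written by :func:`write_results`."""
    df = pd.read_csv(path, float_precision="round_trip")
    metric = df["metric"].iloc[0] if "metric" in df.columns else "gini"
    layer_cols = [c for c in df.columns if c not in ("image", "metric")]
    out = df[layer_cols].copy()
    out.attrs["metric"] = metric
    return out
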