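"""Readers, writers and configuration.

Formats: PNG/JPEG images; single-channel 0/255 PNG masks; annotation
rectangles as CSV with columns ``image_id, row_min, col_min, row_max,
col_max`` (0-based, half-open); MST references, reports and pipeline
configuration as JSON (configuration also round-trips through YAML).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, UnidentifiedImageError

from ._validate import as_mask, as_rgb_image
from .color_density import MixtureDensity
from .errors import ReadWriteError, ValidationError
from .membership import MstReference, build_reference

SCHEMA_VERSION = 1

ANNOTATION_COLUMNS = ["image_id", "row_min", "col_min", "row_max", "col_max"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as uint8 RGB; grayscale is replicated, alpha dropped."""
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            if img.mode in ("RGBA", "LA", "PA"):
                warnings.warn(f"{path}: dropping alpha channel", stacklevel=2)
            if img.mode != "RGB":
                img = img.convert("RGB")
            return np.asarray(img, dtype=np.uint8)
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise ReadWriteError(f"cannot read image {path}: {exc}") from exc


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    try:
        Image.fromarray(as_rgb_image(image), mode="RGB").save(path)
    except OSError as exc:
        raise ReadWriteError(f"cannot write image {path}: {exc}") from exc


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG; pixels above half intensity are foreground."""
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            arr = np.asarray(img.convert("L"))
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise ReadWriteError(f"cannot read mask {path}: {exc}") from exc
    return arr > 0.5 * 255


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    try:
        Image.fromarray((as_mask(mask) * np.uint8(255)), mode="L").save(path)
    except OSError as exc:
        raise ReadWriteError(f"cannot write mask {path}: {exc}") from exc


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Annotation rectangles CSV -> DataFrame with the canonical columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise ReadWriteError(f"cannot read annotations {path}: {exc}") from exc
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotations {path}: missing columns {missing}")
    return df[ANNOTATION_COLUMNS]


# -- MST reference ------------------------------------------------------


def default_swatch_path() -> Path:
    """Path of the packaged Monk-scale swatch JSON."""
    return Path(str(resources.files("mstai").joinpath("data/mst_swatches.json")))


def _read_swatch_json(path: Path) -> list[np.ndarray]:
    try:
        payload = json.loads(path.read_text())
    except OSError as exc:
        raise ReadWriteError(f"cannot read reference {path}: {exc}") from exc
    scales = payload.get("scales")
    if not isinstance(scales, list) or len(scales) != 10:
        raise ValidationError(f"reference {path}: expected exactly 10 scales")
    ordered = sorted(scales, key=lambda s: s["id"])
    if [s["id"] for s in ordered] != list(range(1, 11)):
        raise ValidationError(f"reference {path}: scale ids must be 1..10")
    out = []
    for s in ordered:
        arr = np.asarray(s["rgbs"], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.min() < 0 or arr.max() > 255:
            raise ValidationError(f"reference {path}: scale {s['id']} needs RGB triples in [0, 255]")
        out.append(arr)
    return out


def load_reference(
    path: str | Path | None = None,
    spread: float = 0.02,
    n_pixels: int = 4000,
    n_components: int = 8,
    seed: int = 0,
    cache: bool = True,
) -> MstReference:
    """Load swatch RGBs and build (or reload) the fitted reference densities.

    Fitted densities are cached in a sidecar JSON next to the swatch file,
    keyed by a hash of the swatches and fit settings, so repeated loads
    skip the mixture fits; a cache reload is bit-identical to a fresh fit
    with the same seed.
    """
    path = Path(path) if path is not None else default_swatch_path()
    swatches = _read_swatch_json(path)
    config_key = hashlib.sha256(
        json.dumps(
            {
                "swatches": [s.tolist() for s in swatches],
                "spread": spread,
                "n_pixels": n_pixels,
                "n_components": n_components,
                "seed": seed,
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()
    cache_path = path.with_suffix(".densities.json")
    if cache and cache_path.exists():
        try:
            payload = json.loads(cache_path.read_text())
            if payload.get("config_key") == config_key:
                densities = [MixtureDensity.from_dict(d) for d in payload["densities"]]
                means = np.asarray([s.mean(axis=0) for s in swatches])
                return MstReference(swatch_rgbs=swatches, mean_rgbs=means, densities=densities)
        except (OSError, KeyError, ValueError):
            pass  # stale or unreadable cache: refit below
    ref = build_reference(
        swatches, spread=spread, n_pixels=n_pixels, n_components=n_components, seed=seed
    )
    if cache:
        try:
            cache_path.write_text(
                json.dumps(
                    {
                        "schema_version": SCHEMA_VERSION,
                        "config_key": config_key,
                        "densities": [d.to_dict() for d in ref.densities],
                    }
                )
            )
        except OSError:
            pass  # caching is best-effort; a read-only location is fine
    return ref


# -- results ------------------------------------------------------------


def result_to_record(image_id: str, result) -> dict:
    """Flatten an EstimateResult into one report row."""
    row: dict = {"image_id": image_id, "excluded": bool(result.excluded)}
    if result.membership is not None:
        for m in range(result.membership.n_scales):
            row[f"M_{m + 1}"] = float(result.membership.scores[m])
        for i, sid in enumerate(result.membership.ranking, start=1):
            row[f"rank_{i}"] = int(sid)
    row["reason"] = result.reason or ""
    return row


def write_report(results: list[dict], path: str | Path) -> None:
    """Write result rows as CSV (by extension) or schema-versioned JSON."""
    path = Path(path)
    for row in results:
        scores = [v for k, v in row.items() if k.startswith("M_")]
        if scores and abs(sum(scores) - 1.0) > 1e-6:
            raise ValidationError(f"results: membership row {row.get('image_id')} does not sum to 1")
    try:
        if path.suffix.lower() == ".csv":
            pd.DataFrame(results).to_csv(path, index=False)
        else:
            path.write_text(
                json.dumps({"schema_version": SCHEMA_VERSION, "results": results}, indent=2)
            )
    except OSError as exc:
        raise ReadWriteError(f"cannot write report {path}: {exc}") from exc


# -- configuration ------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed to re-run the pipeline bit-identically."""

    white_threshold: float = 0.95
    black_threshold: float = 0.05
    object_threshold: int = 64
    hole_threshold: int = 64
    provider_mode: str = "none"
    provider_source: str | None = None
    n_components: int = 8
    subsample_cap: int = 100_000
    grid_samples_per_axis: int = 100
    reference_path: str | None = None
    reference_spread: float = 0.02
    seed: int = 0
    log_level: str = "INFO"

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = dataclasses.asdict(self)
        text = (
            yaml.safe_dump(payload, sort_keys=True)
            if path.suffix.lower() in (".yaml", ".yml")
            else json.dumps(payload, indent=2, sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ReadWriteError(f"cannot read config {path}: {exc}") from exc
        payload = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"config {path}: unknown fields {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
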