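"""Configuration, image/manifest I/O and checkpointing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field


class PhantomSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    modality: str = "fundus"
    image_size: int = Field(default=64, ge=32)
    n_per_class: int = Field(default=50, ge=1)
    images_per_subject: int = Field(default=1, ge=1)
    split_fractions: tuple[float, float, float] = (0.75, 0.15, 0.10)


class DiffusionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    T: int = Field(default=250, ge=2)
    base_channels: int = Field(default=8, ge=2)
    n_iter: int = Field(default=2000, ge=1)
    batch_size: int = Field(default=16, ge=1)
    lr: float = Field(default=2e-3, gt=0)


class ClassifierSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = Field(default=30, ge=1)
    lr: float = Field(default=0.01, gt=0)
    eps: float = Field(default=0.25, gt=0)
    p: float = 2.0
    beta_trades: float = Field(default=6.0, ge=0)
    attack_steps: int = Field(default=5, ge=1)


class DvcSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lambda_d: float = Field(default=0.5, ge=0)
    cone_alpha_deg: float = Field(default=30.0, gt=0, lt=90)
    start_fraction: float = Field(default=0.5, gt=0, le=1)
    mode: str = "cone"
    guidance_scale: float = Field(default=1.0, gt=0)


class SvcSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    eps: float = Field(default=4.0, gt=0)
    p: float = 4.0
    steps: int = Field(default=50, ge=1)
    ensemble: bool = True


class RunConfig(BaseModel):
    """Validated tool configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    phantom: PhantomSection = PhantomSection()
    diffusion: DiffusionSection = DiffusionSection()
    classifier: ClassifierSection = ClassifierSection()
    dvc: DvcSection = DvcSection()
    svc: SvcSection = SvcSection()

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON configuration file; empty file -> all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    return RunConfig.model_validate(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


# ---------------------------------------------------------------------------
# images + manifests

MANIFEST_COLUMNS = ("path", "subject_id", "split", "label")


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """8-bit PNG; (1,H,W) is written single-channel, (3,H,W) as RGB."""
    pixels = np.asarray(pixels)
    arr = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[0] in (1, 3):
        arr = arr[0] if arr.shape[0] == 1 else arr.transpose(1, 2, 0)
    iio.imwrite(Path(path), arr)


def read_image(path: str | Path) -> np.ndarray:
    """PNG -> (C,H,W) float32 in [0,1]."""
    arr = iio.imread(Path(path))
    x = arr.astype(np.float32) / 255.0
    if x.ndim == 2:
        return x[None]
    return x.transpose(2, 0, 1)


def write_dataset(dataset, out_dir: str | Path) -> Path:
    """PNG images + masks and a CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (im, split) in enumerate(zip(dataset.images, dataset.splits)):
        rel = f"images/{i:05d}.png"
        write_image(out / rel, im.pixels)
        for t, m in im.lesion_masks.items():
            write_image(out / "masks" / f"{i:05d}_{t}.png", m.astype(np.float32)[None])
        row = {"path": rel, "subject_id": im.subject_id, "split": split,
               "label": im.label, "grade": im.grade, "modality": im.modality}
        row.update({f"n_{t}": c for t, c in im.lesion_counts.items()})
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_image_dir(manifest_path: str | Path):
    """Load (pixels list, manifest frame); validates required columns."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    root = manifest_path.parent
    return [read_image(root / p) for p in df["path"]], df


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path: str | Path, arrays: dict, meta: dict) -> None:
    """Named arrays plus a JSON metadata block in one .npz container."""
    np.savez_compressed(Path(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict, dict]:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    return arrays, meta
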