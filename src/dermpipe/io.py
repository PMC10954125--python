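"""Manifest and image IO.

A dataset on disk is a directory of PNG/JPEG images plus a CSV manifest
with columns ``image_path,label[,split]``; labels come from the fixed
eight-diagnosis vocabulary and split is one of train/test/val or empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import DomainError
from .synthgen import CLASS_NAMES

VALID_SPLITS = {"train", "test", "val", "unassigned"}


@dataclass
class Manifest:
    frame: pd.DataFrame  # columns: image_path, label, split
    root: Path

    def __len__(self) -> int:
        return len(self.frame)

    def paths(self) -> list[Path]:
        return [self.root / p for p in self.frame["image_path"]]


def read_manifest(path: str | Path, check_files: bool = True) -> Manifest:
    """Load and validate a manifest CSV.

    Unknown labels, duplicate paths, bad split values and (optionally)
    missing image files are rejected with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise DomainError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "image_path" not in df.columns or "label" not in df.columns:
        raise DomainError("manifest must have columns image_path,label[,split]")
    if "split" not in df.columns:
        df["split"] = "unassigned"
    df.loc[df["split"] == "", "split"] = "unassigned"

    root = path.parent
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        if row.label not in CLASS_NAMES:
            raise DomainError(f"row {row_no}: unknown label {row.label!r}")
        if row.image_path in seen:
            raise DomainError(f"row {row_no}: duplicate path {row.image_path!r}")
        seen.add(row.image_path)
        if row.split not in VALID_SPLITS:
            raise DomainError(f"row {row_no}: bad split {row.split!r}")
        if check_files and not (root / row.image_path).exists():
            raise DomainError(f"row {row_no}: missing file {row.image_path!r}")
    return Manifest(frame=df.reset_index(drop=True), root=root)


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as float RGB on the 0-255 scale."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64)


def load_images(manifest: Manifest) -> list[np.ndarray]:
    return [load_image(p) for p in manifest.paths()]


def save_gray_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.clip(np.round(image), 0, 255).astype(np.uint8)).save(path)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)
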