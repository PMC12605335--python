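"""Dataset directory layout and split manifests.

Layout::

    <root>/images/<id>.png   RGB frame
    <root>/masks/<id>.png    mask stored as {0, 255}, loaded as {0, 1}
    <root>/split.json        manifest listing train/test/labeled ids

"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .splits import DatasetSplit
from .synthetic import ImageSample


def write_dataset(samples: list[ImageSample], root: str | Path) -> None:
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        Image.fromarray(s.image).save(root / "images" / f"{s.id}.png")
        if s.mask is not None:
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(
                root / "masks" / f"{s.id}.png")


def read_dataset(root: str | Path) -> list[ImageSample]:
    root = Path(root)
    samples = []
    for img_path in sorted((root / "images").glob("*.png")):
        sid = img_path.stem
        image = np.asarray(Image.open(img_path).convert("RGB"))
        mask_path = root / "masks" / f"{sid}.png"
        mask = None
        if mask_path.exists():
            mask = (np.asarray(Image.open(mask_path).convert("L")) > 127).astype(np.uint8)
        samples.append(ImageSample(id=sid, image=image, mask=mask))
    return samples


def write_manifest(split: DatasetSplit, path: str | Path) -> None:
    manifest = {
        "train": [s.id for s in split.train],
        "test": [s.id for s in split.test],
        "labeled": sorted(split.labeled_ids),
        "label_ratio": split.label_ratio,
    }
    Path(path).write_text(json.dumps(manifest, indent=1))


def read_split(root: str | Path, manifest: str | Path | None = None) -> DatasetSplit:
    root = Path(root)
    manifest = Path(manifest) if manifest else root / "split.json"
    meta = json.loads(manifest.read_text())
    by_id = {s.id: s for s in read_dataset(root)}
    return DatasetSplit(
        train=[by_id[i] for i in meta["train"]],
        test=[by_id[i] for i in meta["test"]],
        labeled_ids=set(meta["labeled"]),
        label_ratio=float(meta["label_ratio"]),
    )
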