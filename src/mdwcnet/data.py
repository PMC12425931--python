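"""Loading, resizing, splitting and augmenting image/mask pairs.

Dataset layout on disk: an ``images/`` and a ``masks/`` directory with
matching PNG filenames, plus a ``manifest.csv`` with columns
``filename,split`` assigning each pair to train/val/test.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InvalidInputError

#: 8-bit threshold above which a mask pixel counts as foreground.
MASK_THRESHOLD = 128


@dataclasses.dataclass
class SamplePair:
    """One image (float [0,1], shape 1xHxW) with its binary mask (HxW)."""

    image: np.ndarray
    mask: np.ndarray
    id: str = ""

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[0] != 1:
            raise InvalidInputError(f"image must be 1xHxW, got {self.image.shape}")
        if self.mask.shape != self.image.shape[1:]:
            raise InvalidInputError(
                f"mask {self.mask.shape} does not match image {self.image.shape[1:]}"
            )


def load_pair(image_path, mask_path) -> SamplePair:
    """Load a PNG pair: image to single-channel [0,1] (RGB via luminance),
    mask binarised at 128/255."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        img = Image.open(image_path).convert("L")
        msk = Image.open(mask_path).convert("L")
    except OSError as e:
        raise OSError(f"cannot decode {image_path} / {mask_path}: {e}") from e
    if img.size != msk.size:
        raise InvalidInputError(
            f"size mismatch: image {img.size} vs mask {msk.size} for {image_path.name}"
        )
    image = np.asarray(img, dtype=np.float32)[None] / 255.0
    mask = (np.asarray(msk) >= MASK_THRESHOLD).astype(np.uint8)
    return SamplePair(image=image, mask=mask, id=image_path.stem)


def resize_proportional(s: SamplePair, target: int) -> SamplePair:
    """Scale the longer side to ``target`` preserving aspect ratio (bilinear
    for the image, nearest for the mask), then zero-pad symmetrically to a
    ``target x target`` canvas."""
    if target <= 0:
        raise InvalidInputError("target size must be positive")
    h, w = s.mask.shape
    scale = target / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    img = Image.fromarray((s.image[0] * 255).astype(np.uint8), mode="L").resize(
        (nw, nh), Image.BILINEAR
    )
    msk = Image.fromarray((s.mask * 255).astype(np.uint8), mode="L").resize(
        (nw, nh), Image.NEAREST
    )
    image = np.zeros((1, target, target), dtype=np.float32)
    mask = np.zeros((target, target), dtype=np.uint8)
    py, px = (target - nh) // 2, (target - nw) // 2
    image[0, py : py + nh, px : px + nw] = np.asarray(img, dtype=np.float32) / 255.0
    mask[py : py + nh, px : px + nw] = (np.asarray(msk) >= MASK_THRESHOLD).astype(np.uint8)
    return SamplePair(image=image, mask=mask, id=s.id)


def random_hflip(s: SamplePair, prob: float, rng: np.random.Generator) -> SamplePair:
    """Jointly mirror image and mask left-right with probability ``prob``."""
    if not (0.0 <= prob <= 1.0):
        raise InvalidInputError("flip probability must lie in [0, 1]")
    if prob > 0 and rng.random() < prob:
        return SamplePair(
            image=np.ascontiguousarray(s.image[:, :, ::-1]),
            mask=np.ascontiguousarray(s.mask[:, ::-1]),
            id=s.id,
        )
    return s


def split_dataset(ids, ratios: tuple[int, int, int] = (7, 1, 2), seed: int = 0) -> dict[str, str]:
    """Seeded shuffle then contiguous assignment to train/val/test.

    Val and test sizes are floored; the remainder goes to train (280 items
    at 7:1:2 give 196/28/56).  Returns ``{id: split}``.
    """
    ids = list(ids)
    if len(ids) < len(ratios):
        raise InvalidInputError(f"cannot split {len(ids)} ids into {len(ratios)} parts")
    total = sum(ratios)
    n_val = int(len(ids) * ratios[1] / total)
    n_test = int(len(ids) * ratios[2] / total)
    n_train = len(ids) - n_val - n_test
    order = list(np.random.default_rng(seed).permutation(len(ids)))
    manifest = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split = "train"
        elif rank < n_train + n_val:
            split = "val"
        else:
            split = "test"
        manifest[ids[idx]] = split
    return {i: manifest[i] for i in ids}


def write_manifest(manifest: dict[str, str], path) -> None:
    with open(path, "w", newline="") as f:
        wr = csv.writer(f)
        wr.writerow(["filename", "split"])
        for name, split in manifest.items():
            wr.writerow([name, split])


def read_manifest(path) -> dict[str, str]:
    with open(path, newline="") as f:
        rows = list(csv.DictReader(f))
    if not rows or "filename" not in rows[0] or "split" not in rows[0]:
        raise InvalidInputError(f"malformed manifest {path}")
    return {r["filename"]: r["split"] for r in rows}


class SegmentationDataset:
    """In-memory dataset over the images/masks/manifest.csv layout."""

    def __init__(self, root, split: str, target_size: int | None = None):
        root = Path(root)
        manifest = read_manifest(root / "manifest.csv")
        names = sorted(n for n, s in manifest.items() if s == split)
        if not names:
            raise InvalidInputError(f"no items in split {split!r} under {root}")
        self.split = split
        self.samples = []
        for name in names:
            pair = load_pair(root / "images" / name, root / "masks" / name)
            if target_size is not None and pair.mask.shape != (target_size, target_size):
                pair = resize_proportional(pair, target_size)
            self.samples.append(pair)

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, i) -> SamplePair:
        return self.samples[i]

    def batches(self, batch_size: int, rng: np.random.Generator | None = None,
                augment: bool = False, flip_prob: float = 0.5):
        """Yield (images NxCxHxW, masks NxHxW) batches; shuffles and applies
        the horizontal-flip augmentation only when an rng is supplied."""
        order = np.arange(len(self.samples))
        if rng is not None:
            order = rng.permutation(order)
        for start in range(0, len(order), batch_size):
            chunk = [self.samples[i] for i in order[start : start + batch_size]]
            if augment:
                if rng is None:
                    raise InvalidInputError("augmentation requires an rng")
                chunk = [random_hflip(s, flip_prob, rng) for s in chunk]
            yield (
                np.stack([s.image for s in chunk]).astype(np.float32),
                np.stack([s.mask for s in chunk]).astype(np.int64),
            )
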