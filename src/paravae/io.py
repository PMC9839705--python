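"""Image, mask, and manifest I/O.

Images travel on disk as 8-bit grayscale PNG and are re-normalized to
[0, 1] floats on read; ground-truth masks are 1-bit PNG.  The manifest is a
CSV with one row per image: subject_id, age, tooth_type (A/B), side (L/R),
path, mask_path (empty for real data).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phantom import SubjectRecord, mirror_image

MANIFEST_COLUMNS = ["subject_id", "age", "tooth_type", "side", "path", "mask_path"]


def write_image(img: np.ndarray, path) -> None:
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def read_image(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return arr / 255.0


def write_mask(mask: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(mask, dtype=bool)).save(path)


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im, dtype=bool)


def write_manifest(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_id": str, "tooth_type": str,
                                     "side": str})
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if (frame["age"] <= 0).any():
        raise ValueError("manifest contains non-positive ages")
    root = Path(path).parent
    frame["path"] = [str((root / p)) if not Path(p).is_absolute() else p
                     for p in frame["path"]]
    frame["mask_path"] = [
        "" if (isinstance(p, float) and np.isnan(p)) or p == "" else
        (str(root / p) if not Path(p).is_absolute() else p)
        for p in frame["mask_path"]]
    if check_paths:
        for p in frame["path"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest image not found: {p}")
    return frame


def write_dataset(records: list[SubjectRecord], out_dir) -> pd.DataFrame:
    """Write a synthetic dataset (images + masks + manifest) to ``out_dir``.

    Returns the manifest frame with paths relative to ``out_dir``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for ttype, img, mask in (("A", rec.image_a, rec.mask_age_region_a),
                                 ("B", rec.image_b, rec.mask_age_region_b)):
            stem = f"{rec.subject_id}_{ttype}_{rec.side}"
            ipath = f"images/{stem}.png"
            mpath = f"masks/{stem}_mask.png"
            write_image(img, out / ipath)
            write_mask(mask, out / mpath)
            rows.append({"subject_id": rec.subject_id, "age": rec.age,
                         "tooth_type": ttype, "side": rec.side,
                         "path": ipath, "mask_path": mpath})
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    write_manifest(frame, out / "manifest.csv")
    return frame


def load_pairs(manifest: pd.DataFrame, mirror_left: bool = True,
               with_masks: bool = False) -> list[SubjectRecord]:
    """Assemble one record per (subject, side) with both tooth types present.

    Left-side images are mirrored at load time so stored files keep their
    original orientation.  Incomplete pairs are dropped (the caller may warn).
    """
    records = []
    for (sid, side), grp in manifest.groupby(["subject_id", "side"], sort=True):
        by_type = {t: row for t, row in
                   ((row["tooth_type"], row) for _, row in grp.iterrows())}
        if "A" not in by_type or "B" not in by_type:
            continue
        img_a = read_image(by_type["A"]["path"])
        img_b = read_image(by_type["B"]["path"])
        if mirror_left and side == "L":
            img_a = mirror_image(img_a)
            img_b = mirror_image(img_b)
        rec = SubjectRecord(subject_id=sid, age=float(by_type["A"]["age"]),
                            side=side, image_a=img_a, image_b=img_b)
        if with_masks:
            for attr, row in (("mask_age_region_a", by_type["A"]),
                              ("mask_age_region_b", by_type["B"])):
                if row["mask_path"]:
                    mask = read_mask(row["mask_path"])
                    if mirror_left and side == "L":
                        mask = mask[:, ::-1]
                    setattr(rec, attr, mask)
        records.append(rec)
    return records


def load_images(manifest: pd.DataFrame, mirror_left: bool = True):
    """All images pooled (single-VAE mode) with their ages."""
    images, ages, sids = [], [], []
    for _, row in manifest.iterrows():
        img = read_image(row["path"])
        if mirror_left and row["side"] == "L":
            img = mirror_image(img)
        images.append(img)
        ages.append(float(row["age"]))
        sids.append(row["subject_id"])
    return images, np.asarray(ages), sids
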