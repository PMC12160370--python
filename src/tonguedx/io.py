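"""File-format adapters: PNG images/masks, CSV tables, JSON reports.

Masks round-trip losslessly through PNG (stored as 0/255, read back as 0/1).
Cohort manifests are CSV with columns path, mask_path, label, seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .constitutions import Constitution
from .synthetic import TongueSample

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_cohort",
    "read_cohort",
    "write_json",
    "read_json",
]


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_image(path: str | Path) -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return np.asarray(Image.open(p).convert("RGB"))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, dtype=np.uint8) * 255)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def write_cohort(samples: list[TongueSample], outdir: str | Path) -> Path:
    """Write images, masks, a manifest CSV, and a questionnaire CSV.

    Returns the manifest path.  Questionnaire item responses (when present)
    go to ``questionnaires.csv`` with one row per sample.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    qrows = {}
    for s in samples:
        img_path = outdir / "images" / f"{s.sample_id}.png"
        mask_path = outdir / "masks" / f"{s.sample_id}.png"
        write_image(s.image, img_path)
        write_mask(s.mask, mask_path)
        rows.append(
            {
                "path": str(img_path.relative_to(outdir)),
                "mask_path": str(mask_path.relative_to(outdir)),
                "label": s.label.value,
                "seed": s.seed,
            }
        )
        if s.questionnaire is not None:
            qrows[s.sample_id] = s.questionnaire
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows, index=[s.sample_id for s in samples]).to_csv(
        manifest, index_label="sample_id"
    )
    if qrows:
        pd.DataFrame.from_dict(qrows, orient="index").to_csv(
            outdir / "questionnaires.csv", index_label="sample_id"
        )
    return manifest


def read_cohort(manifest_path: str | Path) -> list[TongueSample]:
    """Read a cohort back from its manifest (absolute or relative paths)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, index_col="sample_id")
    required = {"path", "mask_path", "label"}
    if not required <= set(df.columns):
        raise ValueError(
            f"manifest missing required columns {sorted(required - set(df.columns))}"
        )
    qpath = base / "questionnaires.csv"
    questionnaires = (
        pd.read_csv(qpath, index_col="sample_id") if qpath.exists() else None
    )
    samples = []
    for sid, row in df.iterrows():
        img_p = Path(row["path"])
        mask_p = Path(row["mask_path"])
        img = read_image(img_p if img_p.is_absolute() else base / img_p)
        mask = read_mask(mask_p if mask_p.is_absolute() else base / mask_p)
        q = None
        if questionnaires is not None and sid in questionnaires.index:
            q = {k: int(v) for k, v in questionnaires.loc[sid].items()}
        samples.append(
            TongueSample(
                image=img,
                mask=mask,
                label=Constitution(row["label"]),
                questionnaire=q,
                sample_id=str(sid),
                seed=int(row.get("seed", 0)),
            )
        )
    return samples


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
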