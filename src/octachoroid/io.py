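"""File-format plumbing: TIFF volume stacks, PNG slabs and maps, CSV tables.

Volumes are written as multi-page 8-bit grayscale TIFFs (one page per
axial step) with a YAML sidecar recording axial step, SCT and seed.
Rosters, depth profiles and CVD tables are plain CSV.  Depth labels in
filenames use one decimal place with zero padding (``098.8``) so that a
lexicographic sort is a depth sort.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .compare import ComparisonMap, DepthProfileRow
from .phantom import EyeRecord, VesselGroundTruth, VolumePair
from .quantify import CvdResult

__all__ = [
    "depth_tag",
    "save_volume_pair",
    "load_volume_pair",
    "save_ground_truth",
    "save_slab_pair",
    "save_comparison_map",
    "roster_to_csv",
    "roster_from_csv",
    "profile_to_frame",
    "cvd_results_to_frame",
]


def depth_tag(depth_um: float) -> str:
    """Zero-padded depth label for filenames, e.g. 98.8 -> '098.8um'."""
    return f"{depth_um:05.1f}um"


def save_volume_pair(
    directory: str | Path, eye_id: str, pair: VolumePair, *, sct: float, seed: int
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{eye_id}_oct.tif", pair.oct_volume)
    tifffile.imwrite(directory / f"{eye_id}_octa.tif", pair.octa_volume)
    tifffile.imwrite(
        directory / f"{eye_id}_bm_depth.tif", pair.bm_depth_map.astype(np.float32)
    )
    meta = {
        "eye_id": eye_id,
        "axial_step_um": float(pair.axial_step),
        "sct_um": float(sct),
        "seed": int(seed),
        "n_pages": int(pair.n_pages),
        "grid": list(pair.grid_shape),
    }
    (directory / f"{eye_id}_meta.yaml").write_text(yaml.safe_dump(meta))


def load_volume_pair(directory: str | Path, eye_id: str) -> tuple[VolumePair, dict]:
    directory = Path(directory)
    meta = yaml.safe_load((directory / f"{eye_id}_meta.yaml").read_text())
    oct_vol = tifffile.imread(directory / f"{eye_id}_oct.tif")
    octa_vol = tifffile.imread(directory / f"{eye_id}_octa.tif")
    bm = tifffile.imread(directory / f"{eye_id}_bm_depth.tif").astype(float)
    pair = VolumePair(
        oct_volume=oct_vol,
        octa_volume=octa_vol,
        bm_depth_map=bm,
        axial_step=float(meta["axial_step_um"]),
    )
    return pair, meta


def save_ground_truth(
    directory: str | Path, eye_id: str, truth: VesselGroundTruth
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        directory / f"{eye_id}_lumen.tif",
        (truth.lumen_mask_volume.astype(np.uint8) * 255),
    )


def save_slab_pair(
    directory: str | Path,
    eye_id: str,
    series: str,
    actual_depth: float,
    octa_image: np.ndarray,
    oct_image: np.ndarray,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{eye_id}_{series}_{depth_tag(actual_depth)}"
    iio.imwrite(directory / f"{stem}_octa.png", octa_image)
    iio.imwrite(directory / f"{stem}_oct.png", oct_image)


def save_comparison_map(
    path: str | Path, cmap: ComparisonMap
) -> None:
    iio.imwrite(Path(path), cmap.to_rgb())


def roster_to_csv(roster: Sequence[EyeRecord], path: str | Path) -> None:
    rows = []
    for eye in roster:
        d = dataclasses.asdict(eye)
        d["artefact_flags"] = ";".join(sorted(eye.artefact_flags))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def roster_from_csv(path: str | Path) -> list[EyeRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    roster = []
    for _, row in df.iterrows():
        flags = frozenset(f for f in str(row["artefact_flags"]).split(";") if f)
        roster.append(
            EyeRecord(
                eye_id=str(row["eye_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                axial_length=float(row["axial_length"]),
                sct=float(row["sct"]),
                group=str(row["group"]),
                image_score=float(row["image_score"]),
                artefact_flags=flags,
                wide_motion_artefact_count=int(row["wide_motion_artefact_count"]),
            )
        )
    return roster


def profile_to_frame(rows: Iterable[DepthProfileRow]) -> pd.DataFrame:
    """Depth profile as a table mirroring the per-depth report layout."""
    out = []
    for r in rows:
        out.append(
            {
                "depth": r.depth_label,
                "n_eyes": r.n_eyes,
                "n_displaying": r.n_displaying,
                "pct_displaying": 100.0 * r.display_fraction if r.n_eyes else float("nan"),
                "similarity_mean_pct": r.similarity_mean,
                "similarity_sd_pct": r.similarity_sd if r.similarity_sd is not None else float("nan"),
            }
        )
    return pd.DataFrame(out)


def cvd_results_to_frame(results: Iterable[CvdResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
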