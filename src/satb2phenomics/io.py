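"""Reading and writing the pipeline's on-disk formats.

Landmarks: CSV (point_index, x, y) with an optional JSON sidecar.
FLIP traces: CSV (time_s, intensity, bleach_event).
Variant tables and phenotype matrices: TSV.  Images: 8-bit PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .face_geometry import LandmarkConstellation, RoleMap
from .flip_quant import FlipTrace
from .image import FaceImage
from .phenotype_stats import PhenotypeMatrix, phenotype_matrix_from_frame
from .variant_spectrum import VariantRecord, variants_from_frame


def write_landmarks_csv(path, c: LandmarkConstellation) -> None:
    df = pd.DataFrame({
        "point_index": np.arange(len(c.points)),
        "x": c.points[:, 0], "y": c.points[:, 1],
    })
    df.to_csv(path, index=False)


def read_landmarks_csv(path, subject_id: str = "", image_id: str = ""
                       ) -> LandmarkConstellation:
    df = pd.read_csv(path).sort_values("point_index")
    return LandmarkConstellation(df[["x", "y"]].to_numpy(float),
                                 subject_id, image_id)


def write_landmarks_json(path, c: LandmarkConstellation) -> None:
    Path(path).write_text(json.dumps({
        "subject_id": c.subject_id, "image_id": c.image_id,
        "points": c.points.tolist(),
    }, indent=1))


def write_role_map_json(path, roles: RoleMap) -> None:
    Path(path).write_text(json.dumps({
        "midline": list(roles.midline),
        "pairs": [list(p) for p in roles.pairs],
    }, indent=1))


def write_png(path, pixels: np.ndarray) -> None:
    iio.imwrite(path, np.clip(pixels, 0, 255).astype(np.uint8))


def write_face(out_dir, name: str, face: FaceImage) -> None:
    out_dir = Path(out_dir)
    write_png(out_dir / f"{name}.png", face.pixels)
    write_landmarks_csv(out_dir / f"{name}.csv", face.constellation)


def write_trace_csv(path, tr: FlipTrace) -> None:
    flags = np.zeros(len(tr.time_s), dtype=int)
    flags[tr.bleach_events] = 1
    pd.DataFrame({"time_s": tr.time_s, "intensity": tr.intensity,
                  "bleach_event": flags}).to_csv(path, index=False)


def read_trace_csv(path, cell_id: str = "", construct: str = "") -> FlipTrace:
    df = pd.read_csv(path)
    events = np.flatnonzero(df["bleach_event"].to_numpy(int))
    return FlipTrace(df["time_s"].to_numpy(float),
                     df["intensity"].to_numpy(float), events,
                     cell_id=cell_id, construct=construct)


def write_variants_tsv(path, recs: list[VariantRecord]) -> None:
    from .synthetic_data import variant_table_to_frame
    variant_table_to_frame(recs).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    return variants_from_frame(pd.read_csv(path, sep="\t", na_values=["."]))


def write_phenotypes_tsv(path, m: PhenotypeMatrix) -> None:
    df = m.values.copy()
    df.insert(0, "mutation_class", m.mutation_class)
    out = df.reset_index(names="individual_id")
    for term in m.values.columns:
        out[term] = out[term].map(
            lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return phenotype_matrix_from_frame(df)
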