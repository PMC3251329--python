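"""On-disk formats: TSV tables with provenance headers, NIfTI-1 images.

Tables are UTF-8 TSV with '.' decimal separator.  Every written table starts
with ``#``-prefixed metadata lines (seed, config hash, conventions) so a run
can be reproduced from its outputs; readers skip them.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import AnimalRecord, Phantom4D
from .tac import FramingScheme, TimeActivityCurve

__all__ = [
    "write_table",
    "read_table",
    "cohort_to_frame",
    "frame_to_records",
    "write_cohort",
    "read_cohort",
    "write_tacs",
    "read_tacs",
    "write_timing",
    "read_timing",
    "save_phantom",
    "load_phantom",
]

COHORT_COLUMNS = [
    "animal_id", "dose_ug", "ki_ipsi", "ki_contra", "da_ipsi", "da_contra", "rotations",
]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a TSV with optional ``# key: value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def cohort_to_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "dose_ug": r.dose_ug,
                "ki_ipsi": r.ki_ipsi,
                "ki_contra": r.ki_contra,
                "da_ipsi": r.da_ipsi,
                "da_contra": r.da_contra,
                "rotations": r.rotations,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[AnimalRecord]:
    return [
        AnimalRecord(
            animal_id=str(row.animal_id),
            dose_ug=int(row.dose_ug),
            ki_ipsi=float(row.ki_ipsi),
            ki_contra=float(row.ki_contra),
            da_ipsi=float(row.da_ipsi),
            da_contra=float(row.da_contra),
            rotations=int(row.rotations),
        )
        for row in df.itertuples(index=False)
    ]


def write_cohort(records: list[AnimalRecord], path, metadata: dict | None = None) -> None:
    write_table(cohort_to_frame(records), path, metadata)


def read_cohort(path) -> list[AnimalRecord]:
    return frame_to_records(read_table(path))


def _tac_frame(tacs: list[TimeActivityCurve]) -> pd.DataFrame:
    rows = []
    for tac in tacs:
        scheme = tac.scheme
        for i in range(scheme.n_frames):
            rows.append(
                {
                    "region": tac.region or "unnamed",
                    "frame_index": i,
                    "start_s": scheme.starts_s[i],
                    "duration_s": scheme.durations_s[i],
                    "mid_min": scheme.mid_times_min[i],
                    "value": tac.values[i],
                    "decay_corrected": int(tac.decay_corrected),
                }
            )
    return pd.DataFrame(rows)


def write_tacs(tacs: list[TimeActivityCurve], path, metadata: dict | None = None) -> None:
    """Long-format TAC table: one row per (region, frame)."""
    write_table(_tac_frame(tacs), path, metadata)


def read_tacs(path) -> dict[str, TimeActivityCurve]:
    df = read_table(path)
    out: dict[str, TimeActivityCurve] = {}
    for region, sub in df.groupby("region", sort=False):
        sub = sub.sort_values("frame_index")
        scheme = FramingScheme(
            tuple(float(s) for s in sub.start_s),
            tuple(float(d) for d in sub.duration_s),
        )
        out[str(region)] = TimeActivityCurve(
            scheme,
            sub.value.to_numpy(dtype=float),
            decay_corrected=bool(sub.decay_corrected.iloc[0]),
            region=str(region),
        )
    return out


def write_timing(scheme: FramingScheme, path) -> None:
    df = pd.DataFrame(
        {
            "frame_index": np.arange(scheme.n_frames),
            "start_s": scheme.starts_s,
            "duration_s": scheme.durations_s,
        }
    )
    write_table(df, path)


def read_timing(path) -> FramingScheme:
    df = read_table(path).sort_values("frame_index")
    return FramingScheme(
        tuple(float(s) for s in df.start_s), tuple(float(d) for d in df.duration_s)
    )


def save_phantom(phantom: Phantom4D, out_dir) -> dict[str, Path]:
    """Write image.nii + mask.nii + timing.tsv into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(phantom.spacing_mm) + [1.0])
    paths = {
        "image": out_dir / "image.nii",
        "mask": out_dir / "mask.nii",
        "timing": out_dir / "timing.tsv",
    }
    nib.save(nib.Nifti1Image(phantom.frames.astype(np.float32), affine), paths["image"])
    nib.save(nib.Nifti1Image(phantom.mask.astype(np.int16), affine), paths["mask"])
    write_timing(phantom.scheme, paths["timing"])
    return paths


def load_phantom(image_path, mask_path, timing_path) -> Phantom4D:
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    scheme = read_timing(timing_path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    frames = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj).astype(np.int16)
    return Phantom4D(frames=frames, mask=mask, scheme=scheme, spacing_mm=spacing)
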