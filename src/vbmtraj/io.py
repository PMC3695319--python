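"""File formats and run configuration.

Cohort tables travel as tab-separated text with a header; GM data as
NIfTI-1 images (one 4-D file, or one 3-D file per subject plus a manifest).
All writes are atomic: content goes to a temporary file in the target
directory which is then renamed into place, so interrupted runs never leave
half-written outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from vbmtraj.simulate import GMDataset

MANDATORY_COLUMNS = ("subject_id", "group", "age", "fsiq", "viq", "piq", "tbv")
NUMERIC_COLUMNS = ("age", "fsiq", "viq", "piq", "tbv")


class SchemaError(ValueError):
    """A cohort file does not match the expected schema."""


@contextmanager
def atomic_write(path: str | Path, mode: str = "w") -> Iterator:
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated cohort table, validating the schema.

    Mandatory columns: subject_id, group, age, fsiq, viq, piq, tbv.
    Unknown columns are preserved untouched.  A non-numeric value in a
    numeric column raises an error naming the 1-based file line.
    """
    table = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str})
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"cohort file {path} is missing mandatory column {col!r}")
    for col in NUMERIC_COLUMNS:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SchemaError(
                f"non-numeric value {table[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line} of {path}"
            )
        table[col] = converted
    if "scanner" not in table.columns:
        table["scanner"] = "A"
    if table["subject_id"].duplicated().any():
        dupes = table["subject_id"][table["subject_id"].duplicated()].tolist()
        raise SchemaError(f"duplicate subject_id values: {dupes}")
    return table


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as tab-separated text (atomic)."""
    with atomic_write(path) as handle:
        cohort.to_csv(handle, sep="\t", index=False)


def _grid_dataset(
    values: np.ndarray, shape: tuple[int, int, int], affine: np.ndarray, zooms
) -> GMDataset:
    return GMDataset(
        values=values,
        kind="voxel_grid",
        grid_dims=tuple(int(d) for d in shape),
        voxel_size=tuple(float(z) for z in zooms[:3]),
        affine=np.asarray(affine, dtype=float),
    )


def write_gm_maps(
    dataset: GMDataset,
    path: str | Path,
    subject_ids: Sequence[str] | None = None,
    mode: str = "4d",
) -> Path:
    """Write a voxel-grid dataset as NIfTI-1.

    ``mode="4d"`` writes a single 4-D image at ``path``; ``mode="per-subject"``
    treats ``path`` as a directory and writes one 3-D image per subject plus
    a ``manifest.tsv`` mapping subject ids to file names.
    """
    if dataset.kind != "voxel_grid":
        raise ValueError("only voxel_grid datasets can be written as NIfTI")
    path = Path(path)
    dims = dataset.grid_dims
    if mode == "4d":
        data = np.stack(
            [dataset.values[i].reshape(dims) for i in range(dataset.n_subjects)],
            axis=-1,
        )
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(data, dataset.affine), str(path))
        return path
    if mode == "per-subject":
        path.mkdir(parents=True, exist_ok=True)
        ids = list(subject_ids) if subject_ids is not None else [
            f"sub{i:03d}" for i in range(dataset.n_subjects)
        ]
        rows = []
        for i, sid in enumerate(ids):
            fname = f"{sid}.nii"
            nib.save(
                nib.Nifti1Image(dataset.values[i].reshape(dims), dataset.affine),
                str(path / fname),
            )
            rows.append({"subject_id": sid, "filename": fname})
        with atomic_write(path / "manifest.tsv") as handle:
            pd.DataFrame(rows).to_csv(handle, sep="\t", index=False)
        return path
    raise ValueError(f"unknown mode {mode!r}")


def read_gm_maps(source: str | Path | Sequence[str | Path]) -> GMDataset:
    """Read GM maps into a subjects x voxels matrix.

    ``source`` is either one NIfTI path (3-D: single subject; 4-D: subjects
    along the last axis) or a sequence of 3-D per-subject paths, which must
    all share grid shape and affine.
    """
    if isinstance(source, (str, Path)):
        img = nib.load(str(source))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(f"{source}: expected a 3-D or 4-D image")
        shape = data.shape[:3]
        values = np.stack(
            [data[..., i].ravel() for i in range(data.shape[-1])], axis=0
        )
        return _grid_dataset(values, shape, img.affine, img.header.get_zooms())

    paths = [Path(p) for p in source]
    if not paths:
        raise ValueError("no input images given")
    first = nib.load(str(paths[0]))
    shape, affine = first.shape[:3], first.affine
    offenders = []
    rows = []
    for p in paths:
        img = nib.load(str(p))
        if img.shape[:3] != shape or not np.allclose(img.affine, affine):
            offenders.append(str(p))
            continue
        rows.append(np.asarray(img.dataobj, dtype=float).ravel())
    if offenders:
        raise ValueError(
            "images do not share the first image's grid/affine: "
            + ", ".join(offenders)
        )
    return _grid_dataset(
        np.stack(rows, axis=0), shape, affine, first.header.get_zooms()
    )


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run.

    When ``cohort_path``/``gm_path`` are unset, the run simulates its own
    cohort and GM images from ``seed`` (the built-in two-blob study layout:
    one inverted-U region whose peak is shifted ``delta`` years earlier in
    ASD, one region that is U-shaped in controls but declines linearly in
    ASD).  Thresholds carry the conventional defaults: posterior probability
    cut 0.99, FDR q 0.05, cluster extent 100 voxels.
    """

    cohort_path: str | None = None
    gm_path: str | None = None
    covariates: list[str] = field(
        default_factory=lambda: ["tbv", "fsiq", "viq", "piq"]
    )
    stages: dict = field(
        default_factory=lambda: {
            "global_ancova": True,
            "ppm": True,
            "f_age": True,
            "trajectory": True,
            "shift": True,
            "ados": True,
        }
    )
    n_asd: int = 47
    n_ctrl: int = 51
    delta: float = 5.0
    fwhm: float = 8.0
    pp_cut: float = 0.99
    gamma: float | str = "auto"
    fdr_q: float = 0.05
    extent: int = 100
    connectivity: int = 18
    k_neighbours: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pp_cut < 1:
            raise ValueError("pp_cut must lie in (0, 1)")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.extent < 0:
            raise ValueError("extent must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.k_neighbours < 1:
            raise ValueError("k_neighbours must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_yaml(self, path: str | Path) -> None:
        with atomic_write(path) as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (provenance key)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
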