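"""Core volume containers and NIfTI I/O.

The package works on axial multi-echo magnitude volumes: a 4D array whose
fourth axis indexes the T2-prep echo, together with the physical voxel size
and the echo-time schedule in milliseconds.  Label volumes carry an integer
tissue code per voxel.  Both round-trip through NIfTI-1 via nibabel, with
the echo schedule stored in a small JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Integer tissue codes used throughout the package.
BACKGROUND = 0
CEREBRAL_WM = 1
CORTEX = 2
DEEP_GM = 3
VENTRICLES = 4
SUBARACHNOID = 5

LABEL_NAMES = {
    BACKGROUND: "background",
    CEREBRAL_WM: "cerebral_wm",
    CORTEX: "cortex",
    DEEP_GM: "deep_gm",
    VENTRICLES: "lateral_ventricles",
    SUBARACHNOID: "subarachnoid_csf",
}

#: Labels that contain pure CSF (used for distance-based mask erosion).
CSF_LABELS = (VENTRICLES, SUBARACHNOID)

#: Nominal T2-prep times of the six-echo acquisition, in ms.  The first
#: echo is acquired with the preparation turned off and counts as TE = 0.
DEFAULT_TE_MS = (0.0, 7.5, 17.5, 67.5, 147.5, 307.5)

#: In-plane x in-plane x through-plane voxel size of the acquisition, mm.
DEFAULT_VOXEL_SIZE = (1.3, 1.3, 5.0)


@dataclass
class EchoVolume:
    """4D multi-echo magnitude data.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz, n_echoes)``, nonnegative magnitudes.
    voxel_size
        Physical voxel dimensions ``(dx, dy, dz)`` in mm; the third axis is
        the slice (through-plane) direction.
    te_ms
        Echo-time schedule, one entry per 4th-axis index, ascending, ms.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    te_ms: tuple[float, ...] = DEFAULT_TE_MS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"EchoVolume data must be 4D, got {self.data.ndim}D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.te_ms = tuple(float(t) for t in self.te_ms)
        if len(self.te_ms) != self.data.shape[3]:
            raise ValueError(
                f"{len(self.te_ms)} echo times for {self.data.shape[3]} volumes"
            )
        te = np.asarray(self.te_ms)
        if te[0] < 0 or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be ascending with first entry >= 0")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class LabelVolume:
    """Integer tissue-label volume on the acquisition grid."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        extra = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if extra:
            raise ValueError(f"unknown label values {sorted(extra)}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")

    def mask(self, *labels: int) -> np.ndarray:
        """Binary mask of the union of the given label codes."""
        return np.isin(self.labels, labels)

    def counts(self) -> dict[int, int]:
        vals, n = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), n.tolist()))


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def save_echo_volume(vol: EchoVolume, path: str | Path) -> None:
    """Write a 4D NIfTI plus a ``.te.json`` sidecar with the schedule."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = Path(str(sidecar) + ".te.json")
    sidecar.write_text(json.dumps({"te_ms": list(vol.te_ms)}))


def load_echo_volume(path: str | Path, te_ms=None) -> EchoVolume:
    """Read a 4D NIfTI; the schedule comes from the sidecar unless given."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if te_ms is None:
        sidecar = path.with_suffix("").with_suffix("")
        sidecar = Path(str(sidecar) + ".te.json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no echo schedule: pass te_ms or provide sidecar {sidecar}"
            )
        te_ms = json.loads(sidecar.read_text())["te_ms"]
    return EchoVolume(data, voxel_size=voxel_size, te_ms=tuple(te_ms))


def save_labels(vol: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.labels.astype(np.int16), _affine(vol.voxel_size))
    nib.save(img, str(path))


def load_labels(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return LabelVolume(
        np.rint(data).astype(np.int16),
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
    )


def save_map(data: np.ndarray, voxel_size, path: str | Path) -> None:
    """Write a scalar 3D map as NIfTI."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(tuple(voxel_size)))
    nib.save(img, str(path))


def load_map(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    return (
        np.asanyarray(img.dataobj, dtype=float),
        tuple(float(z) for z in img.header.get_zooms()[:3]),
    )
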