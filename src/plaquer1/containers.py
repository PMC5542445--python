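"""In-memory containers shared across the simulation and fitting layers."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import Grid, load_nifti, save_nifti

__all__ = ["ImageSeries"]


@dataclass
class ImageSeries:
    """A saturation-recovery acquisition: one 3D magnitude volume per delay.

    Parameters
    ----------
    volumes : list of ndarray
        One 3D intensity volume per saturation delay, all on ``grid``.
    delays_ms : array-like
        Saturation delay of each volume, ms, strictly positive.
    tr_ms : float
        Repetition time, ms.
    grid : Grid
        Voxel size and field-of-view origin shared by all volumes.
    """

    volumes: list[np.ndarray]
    delays_ms: np.ndarray
    tr_ms: float
    grid: Grid

    def __post_init__(self) -> None:
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        if len(self.volumes) != len(self.delays_ms):
            raise ValueError("one volume per delay required")
        if len(self.volumes) == 0:
            raise ValueError("series is empty")
        if np.any(self.delays_ms <= 0):
            raise ValueError("saturation delays must be strictly positive")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        for v in self.volumes:
            if v.shape != self.grid.shape:
                raise ValueError("all volumes must share the series grid")

    @property
    def n_delays(self) -> int:
        return len(self.volumes)

    def as_4d(self) -> np.ndarray:
        """Stack volumes into a (x, y, z, delay) array."""
        return np.stack(self.volumes, axis=-1)

    def voxel_signal(self, index: tuple[int, int, int]) -> np.ndarray:
        """The per-delay intensity vector of one voxel."""
        i, j, k = index
        return np.array([v[i, j, k] for v in self.volumes])

    # -- I/O ---------------------------------------------------------------

    def save(self, directory, stem: str = "sr") -> None:
        """Write the series as one 4D NIfTI plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_nifti(self.as_4d(), self.grid, directory / f"{stem}.nii")
        manifest = {
            "delays_ms": self.delays_ms.tolist(),
            "tr_ms": float(self.tr_ms),
            "voxel_size_mm": list(self.grid.voxel_size),
            "fov_origin_mm": list(self.grid.fov_origin),
        }
        (directory / f"{stem}.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory, stem: str = "sr") -> "ImageSeries":
        directory = Path(directory)
        arr, grid = load_nifti(directory / f"{stem}.nii")
        manifest = json.loads((directory / f"{stem}.json").read_text())
        if arr.ndim == 3:
            arr = arr[..., None]
        return cls(
            volumes=[np.asarray(arr[..., i], dtype=float) for i in range(arr.shape[-1])],
            delays_ms=np.asarray(manifest["delays_ms"], dtype=float),
            tr_ms=float(manifest["tr_ms"]),
            grid=grid,
        )
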