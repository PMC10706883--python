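"""Core data containers shared by all pipeline stages.

The pipeline operates on three kinds of objects:

* :class:`AcquisitionSeries` — a 4D voxel array (x, y, z, volume) together
  with one acquisition-parameter value per volume (inversion time, b-value
  and diffusion direction, echo time, or ASL label type and post-label
  delay) and the voxel geometry.
* :class:`ParameterMap` — a 3D map of a single fitted quantity (T1, M0,
  ADC, T2*, ΔM, perfusion, ...) in physical units, with an optional
  goodness-of-fit companion and an integer fit-status volume.
* :class:`TissueMasks` — kidney / cortex / medulla boolean volumes with
  the disjointness and containment invariants enforced at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "FIT_OK",
    "FIT_FAIL",
    "FIT_LOW_CONFIDENCE",
    "AcquisitionSeries",
    "ParameterMap",
    "TissueMasks",
    "TissueSummary",
]

# Integer fit-status codes stored alongside every fitted map.
FIT_OK = 0
FIT_FAIL = 1
FIT_LOW_CONFIDENCE = 2


def _default_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class AcquisitionSeries:
    """A 4D acquisition (x, y, z, n_volumes) with per-volume parameters.

    Parameters are held in ``params``: a mapping from parameter name
    (``"TI_ms"``, ``"b_s_mm2"``, ``"direction"``, ``"TE_ms"``,
    ``"label"``, ``"PLD_ms"``) to a length-``n_volumes`` array.  This is
    the in-memory mirror of a NIfTI series plus its JSON sidecar.
    """

    data: np.ndarray
    params: dict[str, np.ndarray]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 5.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"series data must be 4D, got shape {self.data.shape}")
        n = self.data.shape[3]
        self.params = {k: np.asarray(v) for k, v in self.params.items()}
        for key, vec in self.params.items():
            if len(vec) != n:
                raise ValueError(
                    f"parameter vector {key!r} has length {len(vec)}, "
                    f"but series has {n} volumes"
                )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        return _default_affine(self.voxel_size_mm)

    def subset(self, idx: np.ndarray) -> "AcquisitionSeries":
        """Return a new series containing only the volumes in ``idx``."""
        idx = np.asarray(idx)
        return AcquisitionSeries(
            data=self.data[..., idx],
            params={k: v[idx] for k, v in self.params.items()},
            voxel_size_mm=self.voxel_size_mm,
            meta=dict(self.meta),
        )


@dataclass
class ParameterMap:
    """A 3D map of one fitted quantity with units and fit diagnostics."""

    data: np.ndarray
    units: str
    name: str = ""
    gof: np.ndarray | None = None  # residual SSE or R², documented per fit
    status: np.ndarray | None = None  # FIT_* codes, None means all-OK
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 5.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"parameter map must be 3D, got shape {self.data.shape}")
        if self.status is not None:
            self.status = np.asarray(self.status)
            if self.status.shape != self.data.shape:
                raise ValueError("status shape mismatch")

    @property
    def ok(self) -> np.ndarray:
        """Boolean volume of voxels whose fit succeeded."""
        if self.status is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.status == FIT_OK

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        return _default_affine(self.voxel_size_mm)


@dataclass
class TissueMasks:
    """Kidney / cortex / medulla boolean volumes.

    Invariants (checked at construction): cortex and medulla are disjoint
    and both contained in the kidney mask.
    """

    kidney: np.ndarray
    cortex: np.ndarray
    medulla: np.ndarray
    voxel_volume_mm3: float
    t1_threshold_ms: float | None = None

    def __post_init__(self) -> None:
        self.kidney = np.asarray(self.kidney, dtype=bool)
        self.cortex = np.asarray(self.cortex, dtype=bool)
        self.medulla = np.asarray(self.medulla, dtype=bool)
        if not (self.kidney.shape == self.cortex.shape == self.medulla.shape):
            raise ValueError("mask shapes differ")
        if np.any(self.cortex & self.medulla):
            raise ValueError("cortex and medulla masks overlap")
        if np.any(self.cortex & ~self.kidney) or np.any(self.medulla & ~self.kidney):
            raise ValueError("cortex/medulla must be contained in the kidney mask")

    def volume_ml(self, which: str = "kidney") -> float:
        mask = getattr(self, which)
        return float(mask.sum()) * self.voxel_volume_mm3 / 1000.0


@dataclass
class TissueSummary:
    """Gaussian-histogram summary of one measure in one tissue."""

    tissue: str
    measure: str
    mode: float
    fwhm: float
    n_voxels: int
    r_squared: float
    units: str = ""
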