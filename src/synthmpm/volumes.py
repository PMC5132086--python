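"""Core in-memory containers for weighted volumes and quantitative maps.

All internal units are SI: seconds, radians, s^-1.  MT saturation is the one
exception and is carried in percent units (p.u.), i.e. the fractional
steady-state saturation multiplied by 100, which is how the quantity is
conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTRASTS = ("PD", "T1", "MT")

MAP_KINDS = {
    "R1": "s^-1",
    "R2star": "s^-1",
    "MTsat": "p.u.",
    "PDstar": "a.u.",
    "efficiency": "dimensionless",
    "residual": "s^-1",
}

PROVENANCES = ("measured", "synthetic", "ground_truth")


@dataclass
class WeightedVolume:
    """One contrast-weighted multi-echo image stack plus acquisition metadata.

    Parameters
    ----------
    echoes : ndarray, shape (n_echoes, nx, ny, nz)
        Magnitude echo images in arbitrary signal units.
    te_s : tuple of float
        Echo times in seconds, strictly increasing, one per echo image.
    tr_s : float
        Repetition time in seconds.
    flip_rad : float
        Nominal excitation flip angle in radians.
    contrast : {"PD", "T1", "MT"}
        Dominant contrast weighting of the acquisition.
    mt_pulse : bool
        Whether an off-resonance MT pre-pulse was applied.
    """

    echoes: np.ndarray
    te_s: tuple
    tr_s: float
    flip_rad: float
    contrast: str
    mt_pulse: bool = False

    def __post_init__(self):
        self.echoes = np.asarray(self.echoes, dtype=float)
        self.te_s = tuple(float(t) for t in self.te_s)
        if self.echoes.ndim != 4:
            raise ValueError(
                f"echoes must be a 4-D (n_echoes, nx, ny, nz) array, got ndim={self.echoes.ndim}"
            )
        if len(self.te_s) != self.echoes.shape[0]:
            raise ValueError(
                f"{len(self.te_s)} echo times for {self.echoes.shape[0]} echo images"
            )
        if len(self.te_s) > 1 and np.any(np.diff(self.te_s) <= 0):
            raise ValueError(f"echo times must be strictly increasing, got {self.te_s}")
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}, got {self.contrast!r}")
        if not (self.tr_s > 0):
            raise ValueError("TR must be positive")
        if not (0 < self.flip_rad < np.pi):
            raise ValueError("flip angle must lie in (0, pi) radians")

    @property
    def n_echoes(self) -> int:
        return self.echoes.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.echoes.shape[1:]


@dataclass
class QuantitativeMap:
    """A 3-D scalar field of one physical parameter.

    ``aux`` carries per-voxel side products of the fit that produced the map
    (e.g. a validity mask under ``"valid"``, or ``"ln_s0"`` for an R2* fit);
    it is never required to be present.
    """

    values: np.ndarray
    kind: str
    provenance: str = "measured"
    aux: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {sorted(MAP_KINDS)}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def units(self) -> str:
        return MAP_KINDS[self.kind]

    @property
    def valid(self) -> np.ndarray:
        """Per-voxel validity; defaults to finiteness when no fit flag exists."""
        if "valid" in self.aux:
            return np.asarray(self.aux["valid"], dtype=bool)
        return np.isfinite(self.values)


@dataclass
class TransmitFieldMap:
    """Transmit efficiency (achieved / nominal flip angle), with validity flags."""

    efficiency: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.efficiency) & (self.efficiency > 0)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.efficiency.shape:
            raise ValueError("validity flags must match the efficiency grid")
        if np.any(self.efficiency[self.valid] <= 0):
            raise ValueError("transmit efficiency must be positive where valid")

    def as_map(self) -> QuantitativeMap:
        return QuantitativeMap(self.efficiency, kind="efficiency", aux={"valid": self.valid})


def check_aligned(*arrays: np.ndarray) -> tuple:
    """Raise if the arrays do not share a grid; return the common shape."""
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"misaligned grids: {sorted(shapes)}")
    return shapes.pop()
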