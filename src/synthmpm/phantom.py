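"""Digital phantom: ground-truth parameter maps, MPM session simulation and
k-space motion corruption.

The phantom stands in for a head: concentric ellipsoidal shells of
CSF-, GM- and WM-like tissue on a 3-D grid, with a smooth multiplicative
transmit-efficiency field.  The tissue R2*, MT saturation and proton density
are piecewise constant per class; R1 is constructed to satisfy the linear
relaxometry relationship R1 = beta0 + beta1*MT + beta2*R2* + eps, with eps a
zero-mean Gaussian field of standard deviation ``residual_sigma`` (so the
relaxometry fit has a known ground truth), unless the derivation direction is
flipped to construct MT from R1 instead.

Default tissue values are plausible 3 T literature values for healthy adult
brain (e.g. WM R2* ~ 21 s^-1, MTsat ~ 2 p.u.; GM R2* ~ 15 s^-1, MTsat
~ 1 p.u.), not values printed in any particular study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .flash import AcquisitionProtocol, default_protocol, ernst_signal, mt_attenuation
from .volumes import WeightedVolume

__all__ = [
    "CorruptionPlan",
    "MPMSession",
    "PhantomSpec",
    "PhantomTruth",
    "TissueParams",
    "build_phantom",
    "default_tissues",
    "inject_motion",
    "simulate_mpm_session",
]


@dataclass(frozen=True)
class TissueParams:
    """Per-class ground-truth parameters (R1 s^-1, R2* s^-1, MTsat p.u., PD a.u.)."""

    name: str
    R1: float
    R2star: float
    MTsat: float
    PD: float

    def __post_init__(self):
        if not self.R1 > 0:
            raise ValueError(f"{self.name}: R1 must be positive")
        if self.R2star < 0 or self.MTsat < 0:
            raise ValueError(f"{self.name}: R2* and MTsat must be non-negative")
        if not self.PD > 0:
            raise ValueError(f"{self.name}: PD must be positive")


def default_tissues() -> tuple:
    """WM/GM/CSF-like classes with plausible 3 T values.

    The R1 entries equal beta0 + beta1*MT + beta2*R2* under the default
    coefficients (0.32, 0.22, 0.009) so that phantoms are model-consistent
    whichever derivation direction is chosen.
    """
    return (
        TissueParams("WM", R1=0.949, R2star=21.0, MTsat=2.0, PD=700.0),
        TissueParams("GM", R1=0.675, R2star=15.0, MTsat=1.0, PD=850.0),
        TissueParams("CSF", R1=0.3334, R2star=1.0, MTsat=0.02, PD=1000.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one synthetic ground-truth map set.

    ``b1_field_params`` parameterizes a smooth transmit-efficiency dome
    ``eff(r) = center + radial * rho^2`` with rho the normalized distance from
    the grid centre (rho = 1 at the corner of the bounding ellipsoid); the
    default spans roughly 0.78..1.08, typical of a 3 T body-coil transmit
    field.  ``beta`` are the linear-relaxometry coefficients used to tie the
    ground-truth maps together, and ``derive`` selects which map is computed
    from the relationship ("R1" or "MT").
    """

    grid_shape: tuple = (32, 32, 32)
    voxel_size_mm: float = 1.0
    tissues: tuple = field(default_factory=default_tissues)
    geometry: np.ndarray = None   # optional user label field (0 = background)
    b1_field_params: dict = field(default_factory=lambda: {"center": 1.08, "radial": -0.30})
    noise_sigma: float = 1.0
    residual_sigma: float = 0.01
    beta: tuple = (0.32, 0.22, 0.009)
    derive: str = "R1"
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if self.noise_sigma < 0 or self.residual_sigma < 0:
            raise ValueError("noise_sigma and residual_sigma must be non-negative")
        if self.derive not in ("R1", "MT"):
            raise ValueError("derive must be 'R1' or 'MT'")
        if self.derive == "MT" and self.beta[1] == 0:
            raise ValueError("beta1 must be nonzero to derive MT from R1")
        if self.geometry is not None:
            geom = np.asarray(self.geometry)
            if geom.shape != tuple(self.grid_shape):
                raise ValueError("geometry labels must match grid_shape")
            if geom.max(initial=0) > len(self.tissues):
                raise ValueError("geometry references an undefined tissue class")


@dataclass
class PhantomTruth:
    """Aligned ground-truth scalar fields plus the generating spec."""

    r1: np.ndarray
    r2star: np.ndarray
    mtsat: np.ndarray
    pd: np.ndarray
    b1: np.ndarray
    labels: np.ndarray
    residual: np.ndarray
    spec: PhantomSpec

    @property
    def mask(self) -> np.ndarray:
        """Tissue (non-background) voxels."""
        return self.labels > 0


def _ellipsoid_labels(grid_shape) -> np.ndarray:
    """Concentric-ellipsoid label field: 0 bg, 1 WM core, 2 GM shell, 3 CSF rim."""
    nx, ny, nz = grid_shape
    coords = np.meshgrid(*(np.linspace(-1.0, 1.0, n) for n in (nx, ny, nz)),
                         indexing="ij")
    # mild anisotropy so no axis is privileged
    rho2 = (coords[0] / 0.95) ** 2 + (coords[1] / 0.85) ** 2 + (coords[2] / 0.90) ** 2
    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[rho2 <= 1.0] = 3          # CSF rim
    labels[rho2 <= 0.70 ** 2] = 2    # GM shell
    labels[rho2 <= 0.45 ** 2] = 1    # WM core
    return labels


def _b1_field(grid_shape, params) -> np.ndarray:
    nx, ny, nz = grid_shape
    coords = np.meshgrid(*(np.linspace(-1.0, 1.0, n) for n in (nx, ny, nz)),
                         indexing="ij")
    rho2 = sum(c ** 2 for c in coords) / 3.0
    eff = params.get("center", 1.0) + params.get("radial", 0.0) * rho2
    for axis, key in enumerate(("linear_x", "linear_y", "linear_z")):
        if key in params:
            eff = eff + params[key] * coords[axis]
    if np.any(eff <= 0):
        raise ValueError("transmit-efficiency field must be strictly positive")
    return eff


def build_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate the aligned ground-truth map set for ``spec``.

    Deterministic given ``spec.seed``.  With ``derive='R1'`` the R1 field is
    beta0 + beta1*MT + beta2*R2* + eps at tissue voxels; with ``derive='MT'``
    the MT field is (R1 - beta0 - beta2*R2* - eps)/beta1, so the linear
    relationship holds with residual eps either way.  Background voxels carry
    zeros and are excluded via the label field.
    """
    rng = np.random.default_rng(spec.seed)
    labels = (np.asarray(spec.geometry, dtype=np.int16) if spec.geometry is not None
              else _ellipsoid_labels(spec.grid_shape))
    mask = labels > 0

    r2star = np.zeros(spec.grid_shape)
    mtsat = np.zeros(spec.grid_shape)
    pd = np.zeros(spec.grid_shape)
    r1 = np.zeros(spec.grid_shape)
    for i, tissue in enumerate(spec.tissues, start=1):
        sel = labels == i
        r2star[sel] = tissue.R2star
        mtsat[sel] = tissue.MTsat
        pd[sel] = tissue.PD
        r1[sel] = tissue.R1

    residual = np.zeros(spec.grid_shape)
    residual[mask] = spec.residual_sigma * rng.standard_normal(int(mask.sum()))
    b0, b1c, b2 = spec.beta
    if spec.derive == "R1":
        r1[mask] = (b0 + b1c * mtsat[mask] + b2 * r2star[mask] + residual[mask])
    else:
        mtsat[mask] = (r1[mask] - b0 - b2 * r2star[mask] - residual[mask]) / b1c
    if np.any(r1[mask] <= 0):
        raise ValueError("derived R1 non-positive at tissue voxels; "
                         "check beta/residual_sigma")

    b1 = _b1_field(spec.grid_shape, spec.b1_field_params)
    return PhantomTruth(r1=r1, r2star=r2star, mtsat=mtsat, pd=pd, b1=b1,
                        labels=labels, residual=residual, spec=spec)


# --------------------------------------------------------------------------
# session simulation
# --------------------------------------------------------------------------

@dataclass
class MPMSession:
    """Simulated weighted volumes plus the SE/STE B1-mapping series."""

    pd_w: WeightedVolume
    t1_w: WeightedVolume
    mt_w: WeightedVolume
    se_images: list
    ste_images: list
    b1_nominal_rad: tuple
    protocol: AcquisitionProtocol

    def volume(self, contrast: str) -> WeightedVolume:
        return {"PD": self.pd_w, "T1": self.t1_w, "MT": self.mt_w}[contrast]

    def with_volume(self, contrast: str, vol: WeightedVolume) -> "MPMSession":
        kw = {"PD": "pd_w", "T1": "t1_w", "MT": "mt_w"}[contrast]
        return replace(self, **{kw: vol})


def _add_noise(signal, sigma, rng, model):
    if sigma == 0:
        return signal
    if model == "rician":
        re = signal + sigma * rng.standard_normal(signal.shape)
        im = sigma * rng.standard_normal(signal.shape)
        return np.hypot(re, im)
    if model == "gaussian":
        return signal + sigma * rng.standard_normal(signal.shape)
    raise ValueError(f"unknown noise model {model!r}")


def simulate_mpm_session(truth: PhantomTruth,
                         protocol: AcquisitionProtocol = None,
                         noise_sigma: float = None,
                         seed: int = 0,
                         noise_model: str = "rician") -> MPMSession:
    """Simulate the three multi-echo FLASH stacks and the SE/STE pairs.

    Each echo image is the ideally spoiled steady-state amplitude (Ernst
    equation at the B1-scaled flip angle) decayed by exp(-TE*R2*); the
    MT-weighted stack is additionally attenuated by the ground-truth MT
    saturation (see :func:`synthmpm.flash.mt_attenuation`).  Complex Gaussian
    noise of standard deviation ``noise_sigma`` is applied before the
    magnitude operation ("rician"; "gaussian" adds real noise to the
    magnitude instead).  SE/STE pairs are simulated per B1-mapping nominal
    angle with STE/SE = cos(actual flip angle).
    """
    protocol = protocol or default_protocol()
    if noise_sigma is None:
        noise_sigma = truth.spec.noise_sigma
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    rng = np.random.default_rng(seed)

    volumes = {}
    for label in ("PD", "T1", "MT"):
        cp = protocol.contrast(label)
        flip = truth.b1 * cp.flip_rad
        with np.errstate(divide="ignore", invalid="ignore"):
            s0 = np.where(truth.pd > 0,
                          ernst_signal(truth.pd, np.where(truth.r1 > 0, truth.r1, 1.0),
                                       np.clip(flip, 1e-9, np.pi - 1e-9), cp.tr_s),
                          0.0)
        if label == "MT":
            s0 = s0 * np.where(truth.pd > 0,
                               mt_attenuation(truth.mtsat,
                                              np.where(truth.r1 > 0, truth.r1, 1.0),
                                              flip, cp.tr_s),
                               1.0)
        echoes = s0[None] * np.exp(-np.asarray(cp.te_s)[:, None, None, None]
                                   * truth.r2star[None])
        echoes = _add_noise(echoes, noise_sigma, rng, noise_model)
        volumes[label] = WeightedVolume(echoes=echoes, te_s=cp.te_s, tr_s=cp.tr_s,
                                        flip_rad=cp.flip_rad, contrast=label,
                                        mt_pulse=(label == "MT"))

    se_images, ste_images = [], []
    for nominal in protocol.b1_nominal_rad:
        actual = truth.b1 * nominal
        se = truth.pd.copy()
        ste = truth.pd * np.cos(actual)
        se_images.append(_add_noise(se, noise_sigma, rng, noise_model))
        # STE can be negative; magnitude noise would rectify it, so B1-mapping
        # noise is always additive Gaussian (signed images, as after phase
        # correction on a scanner).
        ste_images.append(_add_noise(ste, noise_sigma, rng, "gaussian")
                          if noise_sigma else ste)

    return MPMSession(pd_w=volumes["PD"], t1_w=volumes["T1"], mt_w=volumes["MT"],
                      se_images=se_images, ste_images=ste_images,
                      b1_nominal_rad=protocol.b1_nominal_rad, protocol=protocol)


# --------------------------------------------------------------------------
# motion corruption
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorruptionPlan:
    """K-space motion-corruption settings for one weighted acquisition.

    ``severity`` scales both the per-segment translations (voxels) and the
    per-segment constant phase errors (radians); 0 is the identity.  The
    phase-encode axis is split into ``n_segments`` contiguous k-space bands,
    emulating inter-shot motion in a segmented 3-D acquisition.
    """

    target_contrast: tuple = ("MT",)
    severity: float = 1.0
    phase_axis: int = 1
    n_segments: int = 8
    seed: int = 0

    def __post_init__(self):
        targets = ((self.target_contrast,) if isinstance(self.target_contrast, str)
                   else tuple(self.target_contrast))
        object.__setattr__(self, "target_contrast", targets)
        if not targets:
            raise ValueError("target_contrast must be non-empty")
        for t in targets:
            if t not in ("PD", "T1", "MT"):
                raise ValueError(f"unknown contrast {t!r}")
        if self.severity < 0:
            raise ValueError("severity must be non-negative")
        if self.n_segments < 2:
            raise ValueError("need at least 2 k-space segments")


def inject_motion(volume: WeightedVolume, plan: CorruptionPlan) -> WeightedVolume:
    """Corrupt one weighted volume with inter-segment k-space phase errors.

    The volume is Fourier-transformed along ``plan.phase_axis``; contiguous
    k-space segments receive random rigid in-plane translations (linear phase
    ramps) and constant phase offsets whose magnitudes scale linearly with
    ``plan.severity``; the inverse transform's magnitude is returned.  The
    random draws depend only on ``plan.seed``, so for a fixed seed the
    injected error grows monotonically with severity.  Severity 0 returns an
    unmodified copy.
    """
    axis = plan.phase_axis
    if axis not in (0, 1, 2):
        raise ValueError(f"unknown phase axis {axis}; expected 0, 1 or 2")
    if plan.severity == 0:
        return WeightedVolume(echoes=volume.echoes.copy(), te_s=volume.te_s,
                              tr_s=volume.tr_s, flip_rad=volume.flip_rad,
                              contrast=volume.contrast, mt_pulse=volume.mt_pulse)

    rng = np.random.default_rng(plan.seed)
    n = volume.grid_shape[axis]
    # contiguous segments of centred k-space; random interior boundaries
    bounds = np.sort(rng.choice(np.arange(1, n), size=plan.n_segments - 1,
                                replace=False))
    edges = np.concatenate([[0], bounds, [n]])
    shifts = rng.standard_normal(plan.n_segments) * plan.severity          # voxels
    phases = rng.standard_normal(plan.n_segments) * 0.5 * plan.severity   # rad
    # keep one reference segment (the one holding the k-space centre) clean,
    # as the artefact-free shots of a partially corrupted acquisition
    centre_seg = int(np.searchsorted(edges, n // 2, side="right") - 1)
    shifts[centre_seg] = 0.0
    phases[centre_seg] = 0.0

    k = np.fft.fftshift(np.fft.fftfreq(n))  # cycles/voxel, centred ordering
    phase_err = np.zeros(n)
    for s in range(plan.n_segments):
        sl = slice(edges[s], edges[s + 1])
        phase_err[sl] = 2.0 * np.pi * k[sl] * shifts[s] + phases[s]
    shape = [1, 1, 1, 1]
    shape[axis + 1] = n
    modulation = np.exp(-1j * phase_err).reshape(shape)

    kspace = np.fft.fftshift(np.fft.fft(volume.echoes, axis=axis + 1), axes=axis + 1)
    corrupted = np.fft.ifft(np.fft.ifftshift(kspace * modulation, axes=axis + 1),
                            axis=axis + 1)
    return WeightedVolume(echoes=np.abs(corrupted), te_s=volume.te_s,
                          tr_s=volume.tr_s, flip_rad=volume.flip_rad,
                          contrast=volume.contrast, mt_pulse=volume.mt_pulse)


def corrupt_session(session: MPMSession, plan: CorruptionPlan) -> MPMSession:
    """Apply ``plan`` to its target contrasts, leaving the others untouched."""
    out = session
    for contrast in plan.target_contrast:
        out = out.with_volume(contrast, inject_motion(session.volume(contrast), plan))
    return out
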