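"""Digital plaque phantoms and spoiled gradient-echo acquisition simulation.

The phantom is a 3D label volume (four tissue classes plus background) with
per-voxel ground-truth T1, T2* and M0 fields drawn from truncated normal
distributions. The forward model covers the two protocols used downstream:
a variable-flip-angle (VFA) series for T1 mapping and a multi-echo series
for T2* mapping, with optional Gaussian or Rician noise and Fourier
zero-filling interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from plaquemap.errors import ConfigurationError, DomainError

TISSUE_CLASSES = ("fibrous", "lipid", "inflammation", "hemorrhage")
BACKGROUND = "background"


@dataclass(frozen=True)
class TissueClassSpec:
    """Generative parameters for one tissue class.

    T1/T2* are drawn per voxel from a normal distribution with the given
    mean/sd, truncated at the class min/max. M0 is drawn untruncated
    (clipped at zero) since no bounds are defined for it.
    """

    name: str
    t1_mean: float
    t1_sd: float
    t1_min: float
    t1_max: float
    t2s_mean: float
    t2s_sd: float
    t2s_min: float
    t2s_max: float
    m0_mean: float = 1.0
    m0_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.t1_min <= self.t1_mean <= self.t1_max):
            raise ConfigurationError(
                f"class {self.name!r}: need 0 < t1_min <= t1_mean <= t1_max"
            )
        if not (0 < self.t2s_min <= self.t2s_mean <= self.t2s_max):
            raise ConfigurationError(
                f"class {self.name!r}: need 0 < t2s_min <= t2s_mean <= t2s_max"
            )
        if self.t1_sd < 0 or self.t2s_sd < 0 or self.m0_sd < 0:
            raise ConfigurationError(f"class {self.name!r}: sd must be >= 0")
        if self.m0_mean <= 0:
            raise ConfigurationError(f"class {self.name!r}: m0_mean must be > 0")


def _truncnorm_sample(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(mean))
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# Per-class defaults: summary statistics of the measured ROI-mean distributions
# (n, min, max, mean, sd in ms for each of T1 and T2*). Background models a
# near-void fixative bath: long T1, moderate T2*, very low M0.
DEFAULT_CLASSES: dict[str, TissueClassSpec] = {
    "fibrous": TissueClassSpec(
        "fibrous",
        t1_mean=836.18, t1_sd=322.36, t1_min=239.36, t1_max=1970.11,
        t2s_mean=13.23, t2s_sd=7.14, t2s_min=2.04, t2s_max=71.64,
        m0_mean=1.0, m0_sd=0.03,
    ),
    "lipid": TissueClassSpec(
        "lipid",
        t1_mean=994.98, t1_sd=338.93, t1_min=241.03, t1_max=2290.56,
        t2s_mean=11.38, t2s_sd=5.17, t2s_min=3.59, t2s_max=31.00,
        m0_mean=1.0, m0_sd=0.03,
    ),
    "inflammation": TissueClassSpec(
        "inflammation",
        t1_mean=1317.74, t1_sd=555.95, t1_min=317.14, t1_max=2670.81,
        t2s_mean=11.35, t2s_sd=11.26, t2s_min=1.14, t2s_max=68.15,
        m0_mean=1.0, m0_sd=0.03,
    ),
    "hemorrhage": TissueClassSpec(
        "hemorrhage",
        t1_mean=1393.45, t1_sd=774.46, t1_min=406.08, t1_max=3560.94,
        t2s_mean=8.10, t2s_sd=3.77, t2s_min=1.55, t2s_max=28.98,
        m0_mean=1.0, m0_sd=0.03,
    ),
    BACKGROUND: TissueClassSpec(
        BACKGROUND,
        t1_mean=2000.0, t1_sd=0.0, t1_min=2000.0, t1_max=2000.0,
        t2s_mean=40.0, t2s_sd=0.0, t2s_min=40.0, t2s_max=40.0,
        m0_mean=0.05, m0_sd=0.0,
    ),
}


@dataclass(frozen=True)
class Region:
    """One painted region: an axis-aligned box or an ellipsoid.

    ``center`` and ``half_size`` are 0-based voxel coordinates (slice, row,
    col). A box covers voxels with |idx - center| <= half_size on every
    axis; an ellipsoid covers voxels with sum(((idx-center)/half_size)^2) <= 1.
    """

    shape: Literal["box", "ellipsoid"]
    label: str
    center: tuple[float, float, float]
    half_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.shape not in ("box", "ellipsoid"):
            raise ConfigurationError(f"unknown region shape {self.shape!r}")
        if len(self.center) != 3 or len(self.half_size) != 3:
            raise ConfigurationError("center and half_size must have 3 components")
        if any(h <= 0 for h in self.half_size):
            raise ConfigurationError("half_size components must be > 0")

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=float)
        d = [idx[i] - self.center[i] for i in range(3)]
        if self.shape == "box":
            m = np.ones(grid_shape, dtype=bool)
            for i in range(3):
                m &= np.abs(d[i]) <= self.half_size[i]
            return m
        r2 = sum((d[i] / self.half_size[i]) ** 2 for i in range(3))
        return r2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic plaque: grid, voxel size and painted regions.

    Regions are painted in order; later regions overwrite earlier ones.
    """

    grid_shape: tuple[int, int, int]
    regions: tuple[Region, ...]
    voxel_size_um: tuple[float, float, float] = (120.0, 120.0, 120.0)
    background_class: str = BACKGROUND
    seed: int = 0
    plaque_id: str = "phantom"

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(
            int(n) != n or n <= 0 for n in self.grid_shape
        ):
            raise ConfigurationError("grid_shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ConfigurationError("voxel_size_um must be positive")
        for reg in self.regions:
            for i in range(3):
                lo = reg.center[i] - reg.half_size[i]
                hi = reg.center[i] + reg.half_size[i]
                if lo < -0.5 or hi > self.grid_shape[i] - 0.5:
                    raise ConfigurationError(
                        f"region {reg.label!r} extends outside the grid on axis {i}"
                    )


@dataclass
class Phantom:
    """Label volume plus ground-truth T1/T2*/M0 scalar fields (ms, ms, a.u.)."""

    labels: np.ndarray
    t1_true: np.ndarray
    t2s_true: np.ndarray
    m0_true: np.ndarray
    class_ids: dict[str, int]
    voxel_size_um: tuple[float, float, float] = (120.0, 120.0, 120.0)
    plaque_id: str = "phantom"

    def __post_init__(self) -> None:
        shapes = {
            self.labels.shape,
            self.t1_true.shape,
            self.t2s_true.shape,
            self.m0_true.shape,
        }
        if len(shapes) != 1:
            raise ConfigurationError("phantom fields must share one grid shape")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_name(self, class_id: int) -> str:
        for name, cid in self.class_ids.items():
            if cid == class_id:
                return name
        raise KeyError(class_id)


def generate_phantom(
    spec: PhantomSpec, classes: Sequence[TissueClassSpec] | dict[str, TissueClassSpec]
) -> Phantom:
    """Paint the regions of ``spec`` and draw per-voxel ground truth.

    T1 and T2* are truncated-normal draws within each class's [min, max];
    M0 is a normal draw clipped at a small positive floor. Deterministic
    given ``spec.seed``.
    """
    if isinstance(classes, dict):
        class_map = dict(classes)
    else:
        class_map = {c.name: c for c in classes}
    if spec.background_class not in class_map:
        raise ConfigurationError(
            f"background class {spec.background_class!r} has no class spec"
        )
    for reg in spec.regions:
        if reg.label not in class_map:
            raise ConfigurationError(f"region label {reg.label!r} has no class spec")

    # stable id assignment: background is 0, tissues follow declared order
    names = [spec.background_class] + [
        n for n in class_map if n != spec.background_class
    ]
    class_ids = {name: i for i, name in enumerate(names)}

    labels = np.full(spec.grid_shape, class_ids[spec.background_class], dtype=np.int16)
    for reg in spec.regions:  # painter's order
        labels[reg.mask(spec.grid_shape)] = class_ids[reg.label]

    rng = np.random.default_rng(spec.seed)
    t1 = np.zeros(spec.grid_shape)
    t2s = np.zeros(spec.grid_shape)
    m0 = np.zeros(spec.grid_shape)
    for name in names:  # fixed order => seed determinism
        sel = labels == class_ids[name]
        n = int(sel.sum())
        if n == 0:
            continue
        cs = class_map[name]
        t1[sel] = _truncnorm_sample(cs.t1_mean, cs.t1_sd, cs.t1_min, cs.t1_max, n, rng)
        t2s[sel] = _truncnorm_sample(
            cs.t2s_mean, cs.t2s_sd, cs.t2s_min, cs.t2s_max, n, rng
        )
        if cs.m0_sd == 0:
            m0[sel] = cs.m0_mean
        else:
            m0[sel] = np.clip(
                rng.normal(cs.m0_mean, cs.m0_sd, size=n), 1e-6 * cs.m0_mean, None
            )
    return Phantom(
        labels=labels,
        t1_true=t1,
        t2s_true=t2s,
        m0_true=m0,
        class_ids=class_ids,
        voxel_size_um=spec.voxel_size_um,
        plaque_id=spec.plaque_id,
    )


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Spoiled gradient-echo protocol: a VFA series or a multi-echo series.

    ``te_fixed`` is the echo time of the VFA frames (enters the forward model
    through A = exp(-TE/T2*)); ``flip_angle`` is the flip angle of the
    multi-echo frames (sets the steady-state amplitude S0).
    ``noise_sigma`` is expressed as a fraction of the maximum noiseless
    signal in the stack.
    """

    mode: Literal["vfa", "multiecho"]
    tr: float
    flip_angles: tuple[float, ...] = ()
    echo_times: tuple[float, ...] = ()
    te_fixed: float = 2.0
    flip_angle: float = 10.0
    noise_model: Literal["none", "gaussian", "rician"] = "rician"
    noise_sigma: float = 0.0
    zero_fill_factor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("vfa", "multiecho"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.tr <= 0:
            raise ConfigurationError("tr must be > 0")
        if self.mode == "vfa" and len(set(self.flip_angles)) < 2:
            raise ConfigurationError("vfa mode needs >= 2 distinct flip angles")
        if self.mode == "multiecho" and len(set(self.echo_times)) < 2:
            raise ConfigurationError("multiecho mode needs >= 2 distinct echo times")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if int(self.zero_fill_factor) != self.zero_fill_factor or self.zero_fill_factor < 1:
            raise ConfigurationError("zero_fill_factor must be an integer >= 1")

    @property
    def n_frames(self) -> int:
        return len(self.flip_angles) if self.mode == "vfa" else len(self.echo_times)


@dataclass
class SignalStack:
    """4D magnitude-signal stack; axis 0 indexes flip angle or echo time."""

    frames: np.ndarray
    protocol: AcquisitionProtocol
    phantom_id: str = "phantom"

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise ConfigurationError("frames must be 4D (frame, slice, row, col)")
        if self.frames.shape[0] != self.protocol.n_frames:
            raise ConfigurationError(
                f"stack has {self.frames.shape[0]} frames but the protocol "
                f"defines {self.protocol.n_frames}"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[1:]


def vfa_signal(m0, t1, tr: float, alpha: float, a_factor=1.0):
    """Spoiled gradient-echo steady-state signal at flip angle ``alpha`` (deg).

    S = M0 * (1 - E) / (1 - E cos a) * sin(a) * A  with  E = exp(-TR/T1).
    ``a_factor`` carries the echo-time attenuation A = exp(-TE/T2*); pass 1
    to model the TE << T2* regime where A is ignored.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise DomainError("t1 must be > 0")
    if tr <= 0:
        raise DomainError("tr must be > 0")
    if not 0 <= alpha < 180:
        raise DomainError("alpha must lie in [0, 180) degrees")
    a = np.deg2rad(alpha)
    e1 = np.exp(-tr / t1)
    return np.asarray(m0, dtype=float) * (1 - e1) / (1 - e1 * np.cos(a)) * np.sin(a) * a_factor


def t2star_signal(s0, t2s, te: float):
    """Mono-exponential decay S = S0 * exp(-TE/T2*)."""
    t2s = np.asarray(t2s, dtype=float)
    if np.any(t2s <= 0):
        raise DomainError("t2s must be > 0")
    if te < 0:
        raise DomainError("te must be >= 0")
    return np.asarray(s0, dtype=float) * np.exp(-te / t2s)


def _apply_noise(
    frames: np.ndarray, protocol: AcquisitionProtocol, rng: np.random.Generator
) -> np.ndarray:
    if protocol.noise_model == "none" or protocol.noise_sigma == 0:
        return frames
    sigma = protocol.noise_sigma * float(frames.max())
    if protocol.noise_model == "gaussian":
        return frames + rng.normal(0.0, sigma, size=frames.shape)
    # rician: magnitude of the complex signal plus complex Gaussian noise
    n1 = rng.normal(0.0, sigma, size=frames.shape)
    n2 = rng.normal(0.0, sigma, size=frames.shape)
    return np.sqrt((frames + n1) ** 2 + n2**2)


def simulate_acquisition(
    phantom: Phantom, protocol: AcquisitionProtocol
) -> SignalStack:
    """Evaluate the forward model voxel-wise for every frame of ``protocol``.

    VFA mode: one frame per flip angle, A computed from ``te_fixed`` and the
    true T2*. Multi-echo mode: S0 is the spoiled-GRE steady-state amplitude
    at the protocol's single flip angle, decayed over the echo train.
    Deterministic given ``protocol.seed``.
    """
    if protocol.mode == "vfa":
        a = np.exp(-protocol.te_fixed / phantom.t2s_true)
        frames = np.stack(
            [
                vfa_signal(phantom.m0_true, phantom.t1_true, protocol.tr, fa, a)
                for fa in protocol.flip_angles
            ]
        )
    else:
        s0 = vfa_signal(
            phantom.m0_true, phantom.t1_true, protocol.tr, protocol.flip_angle, 1.0
        )
        frames = np.stack(
            [t2star_signal(s0, phantom.t2s_true, te) for te in protocol.echo_times]
        )
    rng = np.random.default_rng(protocol.seed)
    frames = _apply_noise(frames, protocol, rng)
    return SignalStack(frames=frames, protocol=protocol, phantom_id=phantom.plaque_id)


def _zero_pad_axis(spectrum: np.ndarray, axis: int, factor: int) -> np.ndarray:
    """Symmetric zero-padding of one FFT axis with even-length Nyquist splitting."""
    n = spectrum.shape[axis]
    m = n * factor
    if m == n:
        return spectrum
    s = np.fft.fftshift(spectrum, axes=axis)
    pad = [(0, 0)] * spectrum.ndim
    lo = (m - n) // 2
    pad[axis] = (lo, m - n - lo)
    z = np.pad(s, pad)
    if n % 2 == 0:
        # the single -N/2 bin is split half-and-half onto the +-N/2 bins
        src = [slice(None)] * z.ndim
        dst = [slice(None)] * z.ndim
        src[axis] = slice(lo, lo + 1)
        dst[axis] = slice(lo + n, lo + n + 1)
        half = z[tuple(src)] * 0.5
        z[tuple(src)] = half
        z[tuple(dst)] = half
    return np.fft.ifftshift(z, axes=axis)


def zero_fill(volume: np.ndarray, factor: int) -> np.ndarray:
    """Interpolate a 3D volume by k-space zero-filling.

    Fourier-transforms the volume, pads each axis symmetrically to
    ``factor`` times its length (splitting the Nyquist bin of even-length
    axes so the padded spectrum stays Hermitian), and returns the magnitude
    of the inverse transform, rescaled to preserve intensities.
    """
    if int(factor) != factor or factor < 1:
        raise DomainError("factor must be an integer >= 1")
    factor = int(factor)
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise DomainError("volume must be 3D")
    if factor == 1:
        return volume.copy()
    spectrum = np.fft.fftn(volume)
    for axis in range(3):
        spectrum = _zero_pad_axis(spectrum, axis, factor)
    out = np.fft.ifftn(spectrum) * factor**3
    return np.abs(out)
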