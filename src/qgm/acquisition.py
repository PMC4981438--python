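"""Forward simulation of the three quantitative acquisitions.

Three contrasts are generated from a subject's ground-truth maps:

* a variable-flip-angle (VFA) pair of ideally spoiled 3D gradient-echo
  volumes at low (PD-weighted) and high (T1-weighted) excitation angle;
* a B1-mapping pair: a reference volume after full spin relaxation and a
  magnetization-prepared volume whose longitudinal magnetization was
  rotated by a nominal preparation angle, so the voxelwise quotient is
  the cosine of the locally realized angle;
* a dual-echo gradient-echo pair whose ratio encodes T2* decay.

Transmit (B1) inhomogeneity scales all flip angles multiplicatively;
receive-coil sensitivity scales all signals multiplicatively; noise is
additive Gaussian on the magnitude signal (Rician effects are negligible
at the simulated SNRs).  Spoiling is ideal by construction, so the
spoiling-correction hook downstream defaults to identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from qgm.phantom import SubjectTruth

__all__ = [
    "VfaParams",
    "B1MapParams",
    "DualEchoParams",
    "AcquisitionProtocol",
    "BiasFields",
    "polynomial_field",
    "spgr_signal",
    "simulate_vfa_pair",
    "simulate_b1_pair",
    "simulate_dual_echo",
    "simulate_subject",
]


@dataclass(frozen=True)
class VfaParams:
    tr: float = 16.4  # ms
    te: float = 6.7  # ms
    alpha1: float = 4.0  # degrees, PD-weighted
    alpha2: float = 24.0  # degrees, T1-weighted

    def __post_init__(self) -> None:
        if not (0 < self.alpha1 < self.alpha2 < 90):
            raise ValueError("flip angles must satisfy 0 < alpha1 < alpha2 < 90")
        if self.tr <= 0 or self.te <= 0:
            raise ValueError("TR and TE must be positive")


@dataclass(frozen=True)
class B1MapParams:
    nominal_prep_angle: float = 45.0  # degrees


@dataclass(frozen=True)
class DualEchoParams:
    te1: float = 4.3  # ms
    te2: float = 11.0  # ms

    def __post_init__(self) -> None:
        if not (0 < self.te1 < self.te2):
            raise ValueError("echo times must satisfy 0 < te1 < te2")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence parameters for the three simulated acquisitions."""

    vfa: VfaParams = field(default_factory=VfaParams)
    b1map: B1MapParams = field(default_factory=B1MapParams)
    dual_echo: DualEchoParams = field(default_factory=DualEchoParams)
    noise_sd: float = 0.0  # additive Gaussian sd, signal units (pd scaled 0-100)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class BiasFields:
    """Multiplicative transmit (B1) and receive-sensitivity fields."""

    b1_field: np.ndarray  # actual/nominal flip-angle ratio, dimensionless
    receive_field: np.ndarray  # coil sensitivity, dimensionless

    def __post_init__(self) -> None:
        if self.b1_field.shape != self.receive_field.shape:
            raise ValueError("bias fields must share one grid")
        if np.any(self.b1_field <= 0) or np.any(self.receive_field <= 0):
            raise ValueError("bias fields must be strictly positive")

    @classmethod
    def uniform(cls, shape: tuple[int, ...]) -> "BiasFields":
        return cls(np.ones(shape), np.ones(shape))


def polynomial_field(
    shape: tuple[int, int, int],
    coeffs: dict[tuple[int, int, int], float],
    offset: float = 1.0,
) -> np.ndarray:
    """Smooth low-order polynomial field over normalized [-1, 1] coordinates.

    ``coeffs`` maps exponent triples (i, j, k) to coefficients of
    x^i y^j z^k; the constant ``offset`` is added so a mild perturbation
    around 1 is the natural parameterization.
    """
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    out = np.full(shape, float(offset))
    for (i, j, k), c in coeffs.items():
        out = out + c * x**i * y**j * z**k
    if np.any(out <= 0):
        raise ValueError("polynomial field must remain strictly positive")
    return out


def spgr_signal(
    pd: np.ndarray | float,
    t1: np.ndarray | float,
    t2star: np.ndarray | float,
    alpha_nominal: float,
    b1: np.ndarray | float,
    tr: float,
    te: float,
) -> np.ndarray | float:
    """Ideally spoiled gradient-echo steady-state signal.

    S = pd sin(b1 a) (1 - E1) / (1 - cos(b1 a) E1) exp(-te/t2star),
    with E1 = exp(-tr/t1) and the effective angle b1 times nominal.
    Voxels with pd = 0 (background) return 0 regardless of t1/t2star.
    """
    pd = np.asarray(pd, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2star = np.asarray(t2star, dtype=float)
    scalar_in = pd.ndim == 0 and t1.ndim == 0
    if np.any((pd > 0) & (t1 <= 0)) or np.any((pd > 0) & (t2star <= 0)):
        raise ValueError("t1 and t2star must be positive where pd > 0")
    alpha = np.deg2rad(alpha_nominal) * np.asarray(b1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(t1 > 0, np.exp(-tr / np.where(t1 > 0, t1, 1.0)), 0.0)
        decay = np.where(t2star > 0, np.exp(-te / np.where(t2star > 0, t2star, 1.0)), 0.0)
        s = pd * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1) * decay
    s = np.where(pd > 0, s, 0.0)
    return float(s) if scalar_in and np.ndim(s) == 0 else s


def _check_grids(truth: SubjectTruth, bias: BiasFields) -> None:
    if truth.labels.shape != bias.b1_field.shape:
        raise ValueError(
            f"grid mismatch: truth {truth.labels.shape} vs bias {bias.b1_field.shape}"
        )


def _add_noise(rng: np.random.Generator, vol: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0:
        return vol
    return vol + rng.normal(0.0, sd, size=vol.shape)


def simulate_vfa_pair(
    truth: SubjectTruth,
    protocol: AcquisitionProtocol,
    bias: BiasFields,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the PD-weighted / T1-weighted spoiled gradient-echo pair."""
    _check_grids(truth, bias)
    rng = np.random.default_rng(seed)
    p = protocol.vfa
    out = []
    for alpha in (p.alpha1, p.alpha2):
        s = spgr_signal(
            truth.true_pd, truth.true_t1, truth.true_t2star,
            alpha, bias.b1_field, p.tr, p.te,
        )
        out.append(_add_noise(rng, s * bias.receive_field, protocol.noise_sd))
    return out[0], out[1]


def simulate_b1_pair(
    truth: SubjectTruth,
    bias: BiasFields,
    nominal_prep_angle: float = 45.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the B1-mapping pair.

    The reference volume is acquired after full relaxation and is
    proportional to pd times the receive field; the prepared volume is
    the reference scaled by cos of the locally realized preparation
    angle (b1 times nominal).
    """
    _check_grids(truth, bias)
    rng = np.random.default_rng(seed)
    s_ref = truth.true_pd * bias.receive_field
    prep = np.deg2rad(nominal_prep_angle) * bias.b1_field
    s_prep = s_ref * np.cos(prep)
    return _add_noise(rng, s_ref, noise_sd), _add_noise(rng, s_prep, noise_sd)


def simulate_dual_echo(
    truth: SubjectTruth,
    bias: BiasFields,
    te1: float = 4.3,
    te2: float = 11.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the dual-echo gradient-echo pair for T2* estimation."""
    _check_grids(truth, bias)
    if te2 < te1:
        raise ValueError("te2 must be >= te1")
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        inv_t2s = np.where(truth.true_t2star > 0, 1.0 / np.where(truth.true_t2star > 0, truth.true_t2star, 1.0), 0.0)
    base = truth.true_pd * bias.receive_field
    s1 = base * np.exp(-te1 * inv_t2s)
    s2 = base * np.exp(-te2 * inv_t2s)
    return _add_noise(rng, s1, noise_sd), _add_noise(rng, s2, noise_sd)


def simulate_subject(
    truth: SubjectTruth,
    protocol: AcquisitionProtocol,
    bias: BiasFields,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """All six contrasts for one subject, keyed pdw/t1w/b1ref/b1prep/te1/te2."""
    ss = np.random.SeedSequence(seed)
    s_vfa, s_b1, s_de = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3))
    pdw, t1w = simulate_vfa_pair(truth, protocol, bias, seed=s_vfa)
    b1ref, b1prep = simulate_b1_pair(
        truth, bias, protocol.b1map.nominal_prep_angle, protocol.noise_sd, seed=s_b1
    )
    te1, te2 = simulate_dual_echo(
        truth, bias, protocol.dual_echo.te1, protocol.dual_echo.te2,
        protocol.noise_sd, seed=s_de,
    )
    return {"pdw": pdw, "t1w": t1w, "b1ref": b1ref, "b1prep": b1prep, "te1": te1, "te2": te2}
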