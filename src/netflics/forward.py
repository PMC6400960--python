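"""Forward model: scene -> noisy time-resolved single-pixel measurements.

The simulated acquisition follows the physical chain of a structured-light
single-pixel lifetime imager: every pixel emits a mono-exponential decay
``A exp(-t/tau)`` sampled on a gate grid, the decay is convolved with the
instrument response function (IRF) to give the pixel's temporal point
spread function (TPSF), each binary Hadamard illumination pattern sums the
TPSFs of its lit pixels into one detector trace, and photon counting adds
Poisson noise.  The default acquisition records 512 patterns x 256 time
gates.

Conventions
-----------
* "CW intensity" of a pixel is the time-integrated count of its TPSF; the
  per-pixel decay-IRF kernel is normalized to unit sum over the gate
  window before scaling, so the noiseless chain conserves photons exactly.
* Patterns are binarized rows ``(H + 1) / 2`` of a Sylvester Hadamard
  matrix reshaped row-major to the frame; ``ranking="sequency"`` reorders
  rows by sign-change count (the spatial-frequency analogue) before
  taking the first ``k``.
* ``source="hadamard_pair"`` models complementary-pair acquisition: each
  pattern is measured together with its complement and the difference is
  recorded, which recovers the signed Hadamard weights (used for the
  reduced 400-pair configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hadamard as _sylvester_hadamard
from scipy.signal import fftconvolve

from .phantoms import LifetimeScene

__all__ = [
    "TemporalAxis",
    "IRF",
    "PatternBank",
    "MeasurementSet",
    "TPSFCube",
    "gaussian_irf",
    "load_irf",
    "sequency",
    "build_hadamard_bank",
    "simulate_decay",
    "convolve_irf",
    "tpsf_kernel",
    "build_tpsf_cube",
    "project_measurements",
    "add_poisson_noise",
    "simulate_sample",
    "invert_complete_bank",
]

#: largest ground-truth lifetime the generator emits, ns
MAX_LIFETIME_NS = 1.5


@dataclass(frozen=True)
class TemporalAxis:
    """Uniform time-gate grid; defaults give a 256 x 40 ps = 10.24 ns window."""

    n_gates: int = 256
    gate_width: float = 0.040  # ns
    origin: float = 0.0  # ns, time of gate 0

    def __post_init__(self) -> None:
        if self.n_gates < 2:
            raise ValueError("n_gates must be >= 2")
        if self.gate_width <= 0:
            raise ValueError("gate_width must be positive")
        if self.span < 4 * MAX_LIFETIME_NS:
            raise ValueError(
                f"window span {self.span:.3g} ns under-samples {MAX_LIFETIME_NS} ns "
                f"decays; need >= {4 * MAX_LIFETIME_NS} ns"
            )

    @property
    def span(self) -> float:
        return self.n_gates * self.gate_width

    @property
    def times(self) -> np.ndarray:
        return self.origin + np.arange(self.n_gates) * self.gate_width


@dataclass(frozen=True)
class IRF:
    """Instrument response function discretized on the gate grid (unit sum)."""

    kernel: np.ndarray
    fwhm: float  # ns
    t0: float  # ns, peak position
    irf_id: str = "gaussian"

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=np.float64)
        if np.any(k < 0):
            raise ValueError("IRF kernel must be nonnegative")
        if abs(k.sum() - 1.0) > 1e-9:
            raise ValueError("IRF kernel must sum to 1 (photon conservation)")
        object.__setattr__(self, "kernel", k)


def gaussian_irf(axis: TemporalAxis, fwhm: float = 0.2, t0: float = 1.0) -> IRF:
    """Gaussian IRF (default FWHM 0.2 ns peaking at 1.0 ns), unit-normalized."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    k = np.exp(-0.5 * ((axis.times - t0) / sigma) ** 2)
    return IRF(kernel=k / k.sum(), fwhm=fwhm, t0=t0)


def load_irf(path: str, axis: TemporalAxis) -> IRF:
    """Read a measured IRF from two-column ASCII (time_ns, value).

    The curve is interpolated onto the gate grid and unit-normalized.
    """
    raw = np.loadtxt(path)
    if raw.ndim != 2 or raw.shape[1] != 2:
        raise ValueError("IRF file must have two columns: time_ns, value")
    t, v = raw[:, 0], np.clip(raw[:, 1], 0.0, None)
    k = np.interp(axis.times, t, v, left=0.0, right=0.0)
    if k.sum() <= 0:
        raise ValueError("IRF has no support inside the gate window")
    peak = axis.times[int(np.argmax(k))]
    # FWHM from the half-maximum crossings of the gridded curve
    above = np.where(k >= 0.5 * k.max())[0]
    fwhm = (above[-1] - above[0] + 1) * axis.gate_width
    return IRF(kernel=k / k.sum(), fwhm=float(fwhm), t0=float(peak), irf_id=path)


# ---------------------------------------------------------------------------
# Hadamard pattern bank
# ---------------------------------------------------------------------------

def sequency(rows: np.ndarray) -> np.ndarray:
    """Sign-change count of each +-1 row — the Walsh spatial-frequency proxy."""
    return np.count_nonzero(np.diff(np.sign(rows), axis=1), axis=1)


@dataclass(frozen=True)
class PatternBank:
    """Ordered binary illumination patterns cut from a Hadamard matrix."""

    patterns: np.ndarray  # (k, side, side) in {0, 1}
    order: np.ndarray  # Hadamard row index of each pattern
    source: str  # hadamard_pos | hadamard_pair
    hadamard_order: int

    @property
    def k(self) -> int:
        return self.patterns.shape[0]

    @property
    def side(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.side * self.side

    @property
    def matrix(self) -> np.ndarray:
        """Sensing matrix P of shape (k, n_pixels); rows are flattened patterns."""
        return self.patterns.reshape(self.k, -1).astype(np.float64)

    @property
    def signed_matrix(self) -> np.ndarray:
        """+-1 Hadamard rows 2P - 1; the weights recovered in pair mode."""
        return 2.0 * self.matrix - 1.0

    @property
    def bank_id(self) -> str:
        return f"{self.source}-o{self.hadamard_order}-k{self.k}"


def build_hadamard_bank(
    order: int = 1024,
    k: int = 512,
    ranking: str = "sequency",
    source: str = "hadamard_pos",
) -> PatternBank:
    """Binarize the first ``k`` (optionally sequency-ranked) Hadamard rows.

    ``order`` must be a power of two with an integer square root so rows
    reshape to a square frame (1024 -> 32x32).  The all-ones (sequency-0)
    row always ranks first, providing the full-field pattern.
    """
    if order < 1 or order & (order - 1):
        raise ValueError(f"Hadamard order must be a power of 2, got {order}")
    if k > order:
        raise ValueError(f"k={k} exceeds Hadamard order {order}")
    if k < 1:
        raise ValueError("k must be >= 1")
    side = int(round(np.sqrt(order)))
    if side * side != order:
        raise ValueError(f"order {order} is not a square; rows cannot form square patterns")
    if source not in ("hadamard_pos", "hadamard_pair"):
        raise ValueError(f"unknown source {source!r}")
    H = _sylvester_hadamard(order)
    if ranking == "sequency":
        idx = np.argsort(sequency(H), kind="stable")[:k]
    elif ranking == "natural":
        idx = np.arange(k)
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    rows = H[idx]
    patterns = ((rows + 1) // 2).astype(np.uint8).reshape(k, side, side)
    return PatternBank(patterns=patterns, order=idx, source=source, hadamard_order=order)


# ---------------------------------------------------------------------------
# decay / IRF / TPSF
# ---------------------------------------------------------------------------

def simulate_decay(amplitude: float, tau: float, axis: TemporalAxis) -> np.ndarray:
    """Mono-exponential decay sampled on the gate grid.

    Normalized so the gate sum equals ``amplitude`` (the pixel's CW
    intensity on the time-integrated scale).  Zero amplitude returns the
    zero vector regardless of ``tau``.
    """
    if amplitude == 0:
        return np.zeros(axis.n_gates)
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if tau <= 0:
        raise ValueError(f"tau must be positive for a nonzero pixel, got {tau}")
    d = np.exp(-(axis.times - axis.origin) / tau)
    return d * (amplitude / d.sum())


def convolve_irf(decay: np.ndarray, irf: IRF) -> np.ndarray:
    """Discrete linear convolution with the IRF, truncated to the window.

    With a unit-sum IRF the output sum never exceeds the input sum; mass is
    lost only when the convolution tail falls past the last gate.
    """
    decay = np.asarray(decay, dtype=np.float64)
    if decay.shape != irf.kernel.shape:
        raise ValueError(f"decay length {decay.shape} != IRF length {irf.kernel.shape}")
    return np.convolve(decay, irf.kernel)[: decay.size]


def tpsf_kernel(tau: float, axis: TemporalAxis, irf: IRF) -> np.ndarray:
    """Unit-sum temporal shape of a pixel with lifetime ``tau``.

    The decay-IRF convolution is renormalized over the gate window so that
    scaling by a pixel's CW intensity conserves photons exactly.
    """
    shape = convolve_irf(simulate_decay(1.0, tau, axis), irf)
    return shape / shape.sum()


@dataclass
class TPSFCube:
    """Per-pixel TPSFs, shape (side, side, n_gates); time-sum = CW intensity."""

    cube: np.ndarray
    axis: TemporalAxis

    @property
    def intensity(self) -> np.ndarray:
        return self.cube.sum(axis=2)


def build_tpsf_cube(scene: LifetimeScene, axis: TemporalAxis, irf: IRF) -> TPSFCube:
    """Scene -> noiseless TPSF cube (decay per pixel, IRF convolution)."""
    side = scene.intensity.shape[0]
    cube = np.zeros((side, side, axis.n_gates))
    taus = np.unique(scene.lifetime[scene.mask])
    if taus.size == 0:
        return TPSFCube(cube=cube, axis=axis)
    # one temporal kernel per distinct lifetime (piecewise-constant scenes
    # have only a handful); batch-convolve for per-pixel-lifetime scenes
    decays = np.exp(-(axis.times - axis.origin)[None, :] / taus[:, None])
    decays /= decays.sum(axis=1, keepdims=True)
    shapes = fftconvolve(decays, irf.kernel[None, :], axes=1)[:, : axis.n_gates]
    shapes = np.clip(shapes, 0.0, None)
    shapes /= shapes.sum(axis=1, keepdims=True)
    for t, shape in zip(taus, shapes):
        sel = scene.mask & (scene.lifetime == t)
        cube[sel] = scene.intensity[sel, None] * shape[None, :]
    return TPSFCube(cube=cube, axis=axis)


# ---------------------------------------------------------------------------
# projection and noise
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSet:
    """Time-resolved single-pixel data: (n_gates, k) counts plus metadata."""

    data: np.ndarray
    axis: TemporalAxis
    bank_id: str
    irf_id: str
    noisy: bool
    scene_id: str = ""


def project_measurements(cube: TPSFCube, bank: PatternBank) -> MeasurementSet:
    """Pattern-weighted sums of the TPSFs: data[g, k] = sum_px P[k, px] C[px, g].

    In ``hadamard_pair`` mode the recorded value is the difference between
    the pattern and its complement, i.e. the signed Hadamard projection.
    """
    side = cube.cube.shape[0]
    if side != bank.side:
        raise ValueError(f"cube side {side} != bank side {bank.side}")
    flat = cube.cube.reshape(-1, cube.axis.n_gates)  # (n_px, G)
    P = bank.signed_matrix if bank.source == "hadamard_pair" else bank.matrix
    data = (P @ flat).T  # (G, k)
    return MeasurementSet(
        data=data,
        axis=cube.axis,
        bank_id=bank.bank_id,
        irf_id="",
        noisy=False,
    )


def add_poisson_noise(m: MeasurementSet, rng_seed: int) -> MeasurementSet:
    """Replace every entry by a Poisson draw with that entry as its mean."""
    if m.noisy:
        raise ValueError("measurements are already noisy")
    if np.any(m.data < 0):
        raise ValueError(
            "negative measurement means; Poisson noise applies to nonnegative "
            "counts (pair-mode differencing must noise each arm separately)"
        )
    rng = np.random.default_rng(rng_seed)
    data = rng.poisson(m.data).astype(np.float64)
    return MeasurementSet(
        data=data, axis=m.axis, bank_id=m.bank_id, irf_id=m.irf_id,
        noisy=True, scene_id=m.scene_id,
    )


def simulate_sample(
    scene: LifetimeScene,
    bank: PatternBank,
    irf: IRF,
    axis: TemporalAxis,
    rng_seed: int,
    noisy: bool = True,
) -> tuple[MeasurementSet, LifetimeScene]:
    """Full generator chain: decay -> IRF -> Hadamard projection -> Poisson.

    Returns the paired (measurements, ground-truth scene) sample.  In pair
    mode each complementary arm is noised independently before differencing.
    """
    cube = build_tpsf_cube(scene, axis, irf)
    if bank.source == "hadamard_pair":
        flat = cube.cube.reshape(-1, axis.n_gates)
        pos = (bank.matrix @ flat).T
        neg = ((1.0 - bank.matrix) @ flat).T
        if noisy:
            rng = np.random.default_rng(rng_seed)
            pos = rng.poisson(pos).astype(np.float64)
            neg = rng.poisson(neg).astype(np.float64)
        m = MeasurementSet(
            data=pos - neg, axis=axis, bank_id=bank.bank_id,
            irf_id=irf.irf_id, noisy=noisy, scene_id=scene.scene_id,
        )
        return m, scene
    m = project_measurements(cube, bank)
    m.irf_id = irf.irf_id
    m.scene_id = scene.scene_id
    if noisy:
        m = add_poisson_noise(m, rng_seed)
    return m, scene


def invert_complete_bank(data: np.ndarray, bank: PatternBank) -> np.ndarray:
    """Exact linear inversion when the bank holds all ``order`` patterns.

    For binarized patterns P = (H + 1)/2 with the all-ones row included,
    the signed projections are ``2 s - s_dc`` and orthogonality of H gives
    the pixel cube as ``H^T (2 s - s_dc) / order`` per gate.  Serves as the
    analytic oracle for the iterative solvers.
    """
    if bank.k != bank.hadamard_order:
        raise ValueError("complete-bank inversion needs k == Hadamard order")
    G = data.shape[0]
    H = bank.signed_matrix  # (k, n_px), true +-1 rows in bank order
    if bank.source == "hadamard_pair":
        signed = data.T  # (k, G), already signed projections
    else:
        dc = np.flatnonzero(bank.matrix.min(axis=1) > 0)
        if dc.size != 1:
            raise ValueError("complete bank lacks the all-ones pattern")
        signed = 2.0 * data.T - data.T[dc[0]][None, :]
    cube = (H.T @ signed) / bank.hadamard_order  # (n_px, G)
    side = bank.side
    return cube.reshape(side, side, G)
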