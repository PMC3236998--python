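"""Jansen-Rit neural field forward model for steady-state spectra.

A single cortical source is modeled as three interacting populations
(excitatory spiny stellate cells, inhibitory interneurons and pyramidal
output cells) laid out as layers on a one-dimensional patch of normalized
radius ``ell = 1``.  Lateral connections between layers are exponential
kernels with a distance-proportional conduction delay, parameterized by a
transit time ``upsilon`` (the time for activity to travel from the patch
centre to its boundary).  Linearizing the second-order synaptic dynamics
around the resting state gives a closed-form transfer function ``T(k, w)``
per spatial frequency ``k``; under periodic boundary conditions the
predicted sensor spectrum is a lead-field-weighted sum over standing-wave
modes ``k_j = j*pi/ell``.

Setting ``upsilon = 0`` collapses delays to zero and recovers the classical
point-source (neural mass) Jansen-Rit model as a special case.

All temporal quantities are in SI units internally: rate constants in 1/s,
angular frequency ``w = 2*pi*f`` in rad/s; spatial quantities are per
normalized patch radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray


class SingularKernelError(ValueError):
    """Connectivity kernel transfer function has a vanishing denominator."""


class InstabilityError(RuntimeError):
    """Linearized dynamics are at (or beyond) a resonance for some mode."""

    def __init__(self, message: str, mode: int | None = None,
                 freq_hz: float | None = None):
        super().__init__(message)
        self.mode = mode
        self.freq_hz = freq_hz


@dataclass(frozen=True)
class SynapticParams:
    """Synaptic and firing-rate parameters of the three-population circuit.

    ``m_e``/``m_i`` are maximum postsynaptic depolarizations (mV),
    ``kappa_e``/``kappa_i`` postsynaptic rate constants (1/s), and
    ``r`` (1/mV), ``eta`` (mV) the slope and inflection point of the
    sigmoid depolarization-to-firing-rate function.
    """

    m_e: float = 8.0
    m_i: float = 32.0
    kappa_e: float = 250.0
    kappa_i: float = 1000.0 / 28.0
    r: float = 0.54
    eta: float = 0.0

    def __post_init__(self):
        for name in ("m_e", "m_i", "kappa_e", "kappa_i", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class SpatialParams:
    """Lateral-connectivity kernel parameters on the normalized patch.

    ``alpha_ij`` are kernel amplitudes (connection strengths) and ``c_ij``
    exponential decay constants per normalized patch radius, for the
    connections stellate<-pyramidal (13), interneuron<-pyramidal (23) and
    pyramidal<-stellate / pyramidal<-interneuron (31 / 32; these two share
    a decay constant).  ``upsilon`` is the centre-to-boundary transit time
    in seconds (inverse conduction velocity under the ``ell = 1``
    normalization); ``ell`` is the patch radius and is fixed at 1.
    """

    alpha_13: float = 2000.0
    alpha_23: float = 8000.0
    alpha_31: float = 2000.0
    alpha_32: float = 1000.0
    c_13: float = 16.0
    c_23: float = 16.0
    c_31: float = 16.0
    upsilon: float = 0.05 / 3.0
    ell: float = 1.0

    @property
    def c_32(self) -> float:
        return self.c_31

    def __post_init__(self):
        for name in ("alpha_13", "alpha_23", "alpha_31", "alpha_32",
                     "c_13", "c_23", "c_31", "upsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.ell != 1.0:
            raise ValueError("ell is fixed to 1 (normalized patch radius)")


@dataclass(frozen=True)
class ObservationParams:
    """Lead-field and input/channel-noise spectral parameters.

    The sensor lead field is Gaussian with amplitude ``phi_1`` and width
    ``phi_2`` (normalized length squared); its spatial-frequency weight is
    ``L(k) = phi_1 * exp(-phi_2 * pi^2 * k^2)``.  Input and channel-noise
    spectra are mixtures of white and pink (1/w) components with
    coefficients ``alpha_U, beta_U`` and ``alpha_N, beta_N``.
    """

    phi_1: float = 1.0
    phi_2: float = 0.01
    alpha_U: float = 1.0
    beta_U: float = 1.0
    alpha_N: float = 1e-7
    beta_N: float = 1e-7

    def __post_init__(self):
        if self.phi_2 <= 0:
            raise ValueError("phi_2 must be strictly positive")
        for name in ("alpha_U", "beta_U", "alpha_N", "beta_N"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the neural field observation model."""

    synaptic: SynapticParams = field(default_factory=SynapticParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    observation: ObservationParams = field(default_factory=ObservationParams)
    n_modes: int = 32
    mass_limit: bool = False

    def __post_init__(self):
        if self.n_modes < 1:
            raise ValueError("n_modes must be at least 1")

    @property
    def effective_upsilon(self) -> float:
        """Transit time actually used: structurally 0 in the mass limit."""
        return 0.0 if self.mass_limit else self.spatial.upsilon

    def mode_wavenumbers(self) -> NDArray[np.float64]:
        """Standing-wave wavenumbers k_j = j*pi/ell, j = 1..n_modes."""
        j = np.arange(1, self.n_modes + 1, dtype=float)
        return j * np.pi / self.spatial.ell


@dataclass(frozen=True)
class TransferEval:
    """Transfer-function value: response of the three populations' mean
    depolarization to unit input at spatial frequency ``k`` and angular
    temporal frequency ``omega``."""

    k: float
    omega: float
    value: NDArray[np.complex128]


def sigmoid(v: ArrayLike, r: float, eta: float) -> NDArray[np.float64]:
    """Population firing rate (fraction of maximum) at depolarization ``v``.

    Logistic in ``v`` with slope ``r`` and inflection at ``v = eta``.
    """
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(r * (eta - v)))


def sigmoid_gain(r: float, eta: float) -> float:
    """Slope of the firing-rate sigmoid at the working point v = 0.

    This is the gain ``gamma = r * exp(r*eta) / (1 + exp(r*eta))**2`` that
    scales every connection in the linearized dynamics.
    """
    # exp(x)/(1+exp(x))^2 is even in x; evaluate at -|x| to avoid overflow
    e = np.exp(-abs(r * eta))
    return r * e / (1.0 + e) ** 2


def kernel_transfer(alpha: float, c: float, upsilon: float,
                    k: ArrayLike, omega: ArrayLike) -> NDArray[np.complex128]:
    """Spatiotemporal Fourier transform of one delayed exponential kernel.

    The kernel is ``d(x, t) = (alpha/2) * exp(-c*|x|) * delta(t - upsilon*|x|)``;
    its transform is ``alpha*(c + i*upsilon*w) / ((c + i*upsilon*w)**2 + k**2)``.

    Even in ``k``; conjugate-symmetric in ``omega``.
    """
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    ci = c + 1j * upsilon * omega
    denom = ci * ci + k * k
    scale = c * c + upsilon * upsilon * omega * omega + k * k
    if np.any(np.abs(denom) <= 1e-300 + 1e-14 * scale):
        raise SingularKernelError(
            "kernel transfer denominator vanishes "
            f"(c={c}, upsilon={upsilon})")
    return alpha * ci / denom


def _kernel_transfers(params: ModelParams, k: ArrayLike, omega: ArrayLike):
    """The four connectivity transfer values D13, D23, D31, D32."""
    sp = params.spatial
    ups = params.effective_upsilon
    d13 = kernel_transfer(sp.alpha_13, sp.c_13, ups, k, omega)
    d23 = kernel_transfer(sp.alpha_23, sp.c_23, ups, k, omega)
    d31 = kernel_transfer(sp.alpha_31, sp.c_31, ups, k, omega)
    d32 = kernel_transfer(sp.alpha_32, sp.c_32, ups, k, omega)
    return d13, d23, d31, d32


def coupling_matrix(k: float, omega: float,
                    params: ModelParams) -> NDArray[np.complex128]:
    """Linearized coupling matrix J(k, w) = A @ B @ D(k, w) * gamma.

    Only the entries (0,2), (1,2), (2,0), (2,1) are nonzero, following the
    microcircuit wiring; the (2,1) entry (pyramidal <- interneuron) is
    negative, being the single inhibitory connection.
    """
    syn = params.synaptic
    gamma = sigmoid_gain(syn.r, syn.eta)
    d13, d23, d31, d32 = _kernel_transfers(params, k, omega)
    j = np.zeros((3, 3), dtype=complex)
    j[0, 2] = syn.m_e * syn.kappa_e * d13 * gamma
    j[1, 2] = syn.m_i * syn.kappa_i * d23 * gamma
    j[2, 0] = syn.m_e * syn.kappa_e * d31 * gamma
    j[2, 1] = -syn.m_e * syn.kappa_e * d32 * gamma
    return j


def _system_matrix(k: float, omega: float,
                   params: ModelParams) -> NDArray[np.complex128]:
    """M(k, w) = 2iwB + B^2 - w^2 I - J(k, w); T = M^{-1} G."""
    syn = params.synaptic
    b = np.diag([syn.kappa_e, syn.kappa_i, syn.kappa_e]).astype(complex)
    m = 2j * omega * b + b @ b - omega ** 2 * np.eye(3) - \
        coupling_matrix(k, omega, params)
    return m


def transfer_vector(k: float, omega: float, params: ModelParams) -> TransferEval:
    """Solve the linearized frequency-domain system for the response of the
    three populations to unit input (which enters the stellate population).
    """
    syn = params.synaptic
    g = np.array([syn.kappa_e * syn.m_e, 0.0, 0.0], dtype=complex)
    m = _system_matrix(k, omega, params)
    try:
        value = np.linalg.solve(m, g)
    except np.linalg.LinAlgError as err:
        raise InstabilityError(
            f"singular system matrix at k={k}, omega={omega}") from err
    return TransferEval(k=float(k), omega=float(omega), value=value)


def transfer_pyramidal(k: ArrayLike, omega: ArrayLike,
                       params: ModelParams) -> NDArray[np.complex128]:
    """Closed-form pyramidal (observed) component of the transfer function.

    Obtained from the cofactor expansion of the 3x3 system matrix:

        T3 = D31 * gamma * kappa_e^2 * m_e^2 * (kappa_i + iw)^2 / R
        R  = (kappa_e + iw)^4 (kappa_i + iw)^2
             + (kappa_e + iw)^2 kappa_e kappa_i m_e m_i D23 D32 gamma^2
             - (kappa_i + iw)^2 kappa_e^2 m_e^2 D13 D31 gamma^2

    Broadcasts over ``k`` and ``omega``.
    """
    syn = params.synaptic
    gamma = sigmoid_gain(syn.r, syn.eta)
    omega = np.asarray(omega, dtype=float)
    d13, d23, d31, d32 = _kernel_transfers(params, k, omega)
    be = (syn.kappa_e + 1j * omega) ** 2
    bi = (syn.kappa_i + 1j * omega) ** 2
    r_det = (be * be * bi
             + be * syn.kappa_e * syn.kappa_i * syn.m_e * syn.m_i
             * d23 * d32 * gamma ** 2
             - bi * syn.kappa_e ** 2 * syn.m_e ** 2 * d13 * d31 * gamma ** 2)
    return (d31 * gamma * syn.kappa_e ** 2 * syn.m_e ** 2 * bi) / r_det


def lead_field_weight(k: ArrayLike, phi_1: float,
                      phi_2: float) -> NDArray[np.float64]:
    """Spatial-frequency weight of the Gaussian sensor lead field,
    ``L(k) = phi_1 * exp(-phi_2 * pi^2 * k^2)``."""
    if phi_2 < 0:
        raise ValueError("phi_2 must be nonnegative")
    k = np.asarray(k, dtype=float)
    return phi_1 * np.exp(-phi_2 * np.pi ** 2 * k ** 2)


def _white_pink(omega: ArrayLike, alpha: float, beta: float,
                what: str) -> NDArray[np.float64]:
    omega = np.asarray(omega, dtype=float)
    if beta > 0 and np.any(omega <= 0):
        raise ValueError(
            f"{what} with a pink component requires omega > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        pink = np.where(omega > 0, beta / np.where(omega > 0, omega, 1.0), 0.0)
    return alpha + pink


def input_spectrum(omega: ArrayLike, alpha_U: float,
                   beta_U: float) -> NDArray[np.float64]:
    """Spectral density of the exogenous input fluctuations,
    white + pink: ``g_U(w) = alpha_U + beta_U / w`` (spatially white,
    independent of k)."""
    return _white_pink(omega, alpha_U, beta_U, "input spectrum")


def noise_spectrum(omega: ArrayLike, alpha_N: float,
                   beta_N: float) -> NDArray[np.float64]:
    """Spectral density of additive channel noise, white + pink."""
    return _white_pink(omega, alpha_N, beta_N, "noise spectrum")


def predict_spectrum(params: ModelParams, freqs_hz: ArrayLike, *,
                     check: bool = True) -> NDArray[np.float64]:
    """Predicted single-channel auto-spectrum of the source, g_Y(w, theta).

    Sums squared lead-field-weighted pyramidal transfer magnitudes times
    the input spectrum over the standing-wave modes:

        g_Y(w) = (pi/ell) * sum_j |L(k_j)|^2 |T3(k_j, w)|^2 g_U(w)

    ``freqs_hz`` is the temporal frequency grid in Hz.  Channel noise is
    *not* included here; callers add ``noise_spectrum`` per the generative
    model.  Raises :class:`InstabilityError` if ``check`` is set and some
    mode is at resonance on this grid.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    omega = 2.0 * np.pi * freqs_hz
    if check:
        stable, diag = check_stability(params, freqs_hz)
        if not stable:
            raise InstabilityError(
                f"unstable mode j={diag['mode']} ({diag['reason']})",
                mode=diag["mode"], freq_hz=diag.get("freq_hz"))
    obs = params.observation
    ks = params.mode_wavenumbers()
    # The Gaussian lead-field weight is the transform of L(x) in the
    # cycles-per-length convention, so it is evaluated at k/(2*pi); the
    # connectivity transfer functions use angular wavenumber k directly.
    lw = lead_field_weight(ks / (2.0 * np.pi), obs.phi_1, obs.phi_2)
    t3 = transfer_pyramidal(ks[:, None], omega[None, :], params)
    g_u = input_spectrum(omega, obs.alpha_U, obs.beta_U)
    power = (np.pi / params.spatial.ell) * np.einsum(
        "j,jw->w", lw ** 2, np.abs(t3) ** 2)
    return power * g_u


def mass_limit_spectrum(params: ModelParams,
                        freqs_hz: ArrayLike, *,
                        check: bool = True) -> NDArray[np.float64]:
    """Predicted spectrum of the homologous neural mass model.

    Identical to :func:`predict_spectrum` with the transit time structurally
    forced to zero (instantaneous lateral propagation)."""
    return predict_spectrum(replace(params, mass_limit=True), freqs_hz,
                            check=check)


def check_stability(params: ModelParams,
                    freqs_hz: ArrayLike) -> tuple[bool, dict]:
    """Stability screen of the linearized spectral model, per mode.

    The predicted spectrum is well defined as long as no characteristic
    root of any retained mode sits on the real-frequency axis.  A mode
    ``k_j`` is flagged unstable when either (a) its DC characteristic
    determinant ``det(B^2 - J(k_j, 0))`` is nonpositive — a sign flip
    means a real root has crossed into the right half plane, the
    zero-frequency bifurcation that strong excitatory loop gain produces —
    or (b) the smallest singular value of the system matrix dips below
    ``1e-8`` times its median over the frequency grid (a resonance at a
    sampled real frequency).

    Returns ``(stable, diagnostic)``; the diagnostic names the first
    offending mode and criterion.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    omega = 2.0 * np.pi * freqs_hz
    syn = params.synaptic
    gamma = sigmoid_gain(syn.r, syn.eta)
    ks = params.mode_wavenumbers()

    # batched system matrices, shape (n_modes, n_freq, 3, 3)
    d13, d23, d31, d32 = _kernel_transfers(
        params, ks[:, None], omega[None, :])
    nm, nw = d13.shape
    m = np.zeros((nm, nw, 3, 3), dtype=complex)
    kap = np.array([syn.kappa_e, syn.kappa_i, syn.kappa_e])
    diag = (kap ** 2)[None, None, :] + 2j * omega[None, :, None] * \
        kap[None, None, :] - (omega ** 2)[None, :, None]
    m[..., 0, 0] = diag[..., 0]
    m[..., 1, 1] = diag[..., 1]
    m[..., 2, 2] = diag[..., 2]
    m[..., 0, 2] = -syn.m_e * syn.kappa_e * d13 * gamma
    m[..., 1, 2] = -syn.m_i * syn.kappa_i * d23 * gamma
    m[..., 2, 0] = -syn.m_e * syn.kappa_e * d31 * gamma
    m[..., 2, 1] = syn.m_e * syn.kappa_e * d32 * gamma
    # DC determinant per mode: at omega = 0 the delay terms drop and the
    # characteristic determinant is real; it must stay positive.
    sp = params.spatial
    d13_0 = sp.alpha_13 * sp.c_13 / (sp.c_13 ** 2 + ks ** 2)
    d23_0 = sp.alpha_23 * sp.c_23 / (sp.c_23 ** 2 + ks ** 2)
    d31_0 = sp.alpha_31 * sp.c_31 / (sp.c_31 ** 2 + ks ** 2)
    d32_0 = sp.alpha_32 * sp.c_32 / (sp.c_32 ** 2 + ks ** 2)
    ke2, ki2 = syn.kappa_e ** 2, syn.kappa_i ** 2
    det0 = (ke2 ** 2 * ki2
            + ke2 * syn.kappa_e * syn.kappa_i * syn.m_e * syn.m_i
            * d23_0 * d32_0 * gamma ** 2
            - ki2 * ke2 * syn.m_e ** 2 * d13_0 * d31_0 * gamma ** 2)
    if np.any(det0 <= 0):
        j = int(np.argmax(det0 <= 0))
        return False, {"mode": j + 1,
                       "reason": "zero-frequency determinant nonpositive"}

    smin = np.linalg.svd(m, compute_uv=False)[..., -1]
    med = np.median(smin, axis=1)
    dips = smin.min(axis=1) < 1e-8 * med
    if np.any(dips):
        j = int(np.argmax(dips))
        w_idx = int(np.argmin(smin[j]))
        return False, {"mode": j + 1, "reason": "resonance on frequency grid",
                       "freq_hz": float(freqs_hz[w_idx])}
    return True, {"mode": None, "reason": "stable"}
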