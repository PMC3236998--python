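"""Variational-Laplace inversion of the spectral generative model.

Physical parameters are estimated through log-scale deviations from their
prior expectations: theta_i = P_i * exp(mu_i), with independent Gaussian
priors mu_i ~ N(0, 1/16).  The observation model treats the observed
(complex) cross-spectra as the model prediction plus channel noise plus
Gaussian error whose real and imaginary parts are independently
N(0, Sigma(w, lambda)).  The scheme maximizes the Gibbs energy

    G = -1/2 Re(e)' S^-1 Re(e) - 1/2 Im(e)' S^-1 Im(e)
        - 1/2 rho' W^-1 rho - 1/2 ln|S| - 1/2 ln|W|

over the conditional means mu (Gauss-Newton with Levenberg-Marquardt
damping) and the noise log-precision lambda (coordinate ascent, closed
form), where e is the prediction error, rho = mu - phi the deviation from
the prior mean, S the error covariance and W the prior covariance.  The
free energy reported for model comparison is the Laplace bound

    F = G(mu) - 1/2 ln|-ddG| + p/2 ln(2 pi).

Real and imaginary parts of the errors are handled separately throughout;
for real single-channel auto-spectra the imaginary terms are identically
zero.  Candidate steps whose parameters fail the stability screen are
rejected and the previous estimate retained.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from .model_core import (InstabilityError, ModelParams, check_stability,
                         noise_spectrum, predict_spectrum)
from .spectral_features import SpectralData

logger = logging.getLogger(__name__)

#: free parameters of the field model, in canonical order
FIELD_PARAM_NAMES: tuple[str, ...] = (
    "m_e", "m_i", "kappa_e", "kappa_i",
    "alpha_13", "alpha_23", "alpha_31", "alpha_32",
    "c", "upsilon", "r",
    "phi_1", "phi_2", "alpha_U", "beta_U", "alpha_N", "beta_N",
)

_SYNAPTIC = {"m_e", "m_i", "kappa_e", "kappa_i", "r"}
_SPATIAL = {"alpha_13", "alpha_23", "alpha_31", "alpha_32", "upsilon"}
_OBSERVATION = {"phi_1", "phi_2", "alpha_U", "beta_U", "alpha_N", "beta_N"}

# Cap on the noise log-precision hyperparameter.  Some parameter pairs
# (e.g. lead-field gain vs input amplitude) are exactly confounded, so the
# Gauss-Newton Gram is singular and only the prior precision regularizes
# the curvature; the cap keeps exp(lam) * roundoff well below that
# regularization when residuals vanish.
LAMBDA_BOUND = 40.0


@dataclass(frozen=True)
class ParameterMap:
    """Mapping from named log-scale deviations to a full parameter set.

    ``base`` holds the prior expectations; ``names`` the free parameters.
    The single name ``c`` scales all kernel decay constants jointly (one
    lateral-extent prior for every connection).
    """

    base: ModelParams = field(default_factory=ModelParams)
    names: tuple[str, ...] = FIELD_PARAM_NAMES

    @classmethod
    def for_variant(cls, base: ModelParams | None = None,
                    variant: str = "field") -> "ParameterMap":
        """Field variant estimates the transit time; the mass variant
        removes it from the free set and fixes it structurally to zero."""
        base = base if base is not None else ModelParams()
        if variant == "field":
            return cls(replace(base, mass_limit=False), FIELD_PARAM_NAMES)
        if variant == "mass":
            names = tuple(n for n in FIELD_PARAM_NAMES if n != "upsilon")
            return cls(replace(base, mass_limit=True), names)
        raise ValueError(f"unknown variant {variant!r}")

    @property
    def n_params(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def apply(self, mu: NDArray[np.float64]) -> ModelParams:
        """Parameter set at log-scalings ``mu``: theta_i = P_i exp(mu_i)."""
        mu = np.asarray(mu, dtype=float)
        if mu.shape != (self.n_params,):
            raise ValueError("mu has wrong length for this parameter map")
        scale = dict(zip(self.names, np.exp(mu)))
        syn = self.base.synaptic
        syn = replace(syn, **{n: getattr(syn, n) * scale[n]
                              for n in _SYNAPTIC if n in scale})
        sp = self.base.spatial
        updates = {n: getattr(sp, n) * scale[n]
                   for n in _SPATIAL if n in scale}
        if "c" in scale:
            updates.update({n: getattr(sp, n) * scale["c"]
                            for n in ("c_13", "c_23", "c_31")})
        sp = replace(sp, **updates)
        obs = self.base.observation
        obs = replace(obs, **{n: getattr(obs, n) * scale[n]
                              for n in _OBSERVATION if n in scale})
        return replace(self.base, synaptic=syn, spatial=sp, observation=obs)


@dataclass(frozen=True)
class PriorDensity:
    """Gaussian prior over log-scale parameters: N(phi, Omega) with
    precision ``Omega_inv`` (default 16 on every parameter)."""

    phi: NDArray[np.float64]
    Omega_inv: NDArray[np.float64]

    @classmethod
    def default(cls, n_params: int,
                precision: float = 16.0) -> "PriorDensity":
        return cls(np.zeros(n_params), precision * np.eye(n_params))

    def __post_init__(self):
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        object.__setattr__(self, "Omega_inv",
                           np.asarray(self.Omega_inv, dtype=float))
        w = self.Omega_inv
        if w.shape != (self.phi.size, self.phi.size):
            raise ValueError("precision matrix shape mismatch")
        if not np.allclose(w, w.T):
            raise ValueError("prior precision must be symmetric")
        if np.any(np.linalg.eigvalsh(w) <= 0):
            raise ValueError("prior precision must be positive definite")

    def shrink(self, pmap: ParameterMap, name: str,
               precision: float = 1e8) -> "PriorDensity":
        """Very precise shrinkage prior on one parameter (e.g. pinning the
        transit-time scaling near zero to emulate the mass model)."""
        w = self.Omega_inv.copy()
        i = pmap.index(name)
        w[i, i] = precision
        return replace(self, Omega_inv=w)


@dataclass
class ErrorModel:
    """Observation-error covariance over frequency bins:
    Sigma(w, lambda) = exp(-lambda) * I (a single log-precision
    hyperparameter)."""

    lam: float = 0.0

    def variance(self) -> float:
        return float(np.exp(-self.lam))


@dataclass
class PosteriorDensity:
    """Gaussian conditional density over log-scale parameters plus the
    free energy (log-evidence bound) attached to it."""

    mu: NDArray[np.float64]
    C: NDArray[np.float64]
    F: float
    lam: float
    names: tuple[str, ...]
    trace: list = field(default_factory=list)
    data_hash: str = ""
    settings: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(self.mu[self.names.index(name)])

    def sd(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.C[i, i]))

    def credible_interval(self, name: str,
                          level: float = 0.90) -> tuple[float, float]:
        """Central credible interval on one log-scaling (Gaussian)."""
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        m, s = self.mean(name), self.sd(name)
        return (m - z * s, m + z * s)


@dataclass(frozen=True)
class InversionSettings:
    max_iter: int = 128
    f_tol: float = 1e-3          # nats; convergence on consecutive dF
    converged_runs: int = 3
    jac_step: float = 1e-3       # central-difference step on log-scalings
    damping_init: float = 1.0
    damping_max: float = 1e10


def data_fingerprint(data: SpectralData) -> str:
    """Hash identifying the data a posterior was fitted to."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data.freqs_hz).tobytes())
    h.update(np.ascontiguousarray(data.values).tobytes())
    return h.hexdigest()[:16]


def _predict(mu: NDArray[np.float64], freqs_hz: NDArray[np.float64],
             pmap: ParameterMap) -> NDArray[np.float64]:
    """Full prediction g_Y(w, mu) + g_N(w, mu) (stability not rechecked)."""
    params = pmap.apply(mu)
    omega = 2.0 * np.pi * freqs_hz
    obs = params.observation
    return (predict_spectrum(params, freqs_hz, check=False)
            + noise_spectrum(omega, obs.alpha_N, obs.beta_N))


def prediction_error(mu: NDArray[np.float64], data: SpectralData,
                     pmap: ParameterMap) -> NDArray[np.complex128]:
    """Prediction error e = g_Y(w, mu) + g_N(w, mu) - g_Y(w), stacked over
    frequencies (real for single-channel auto-spectra)."""
    if data.n_channels != 1:
        raise NotImplementedError(
            "inversion currently supports single-channel spectra")
    y = data.values[:, 0, 0]
    pred = _predict(mu, data.freqs_hz, pmap)
    return pred.astype(complex) - y


def gibbs_energy(mu: NDArray[np.float64], data: SpectralData,
                 error_model: ErrorModel, prior: PriorDensity,
                 pmap: ParameterMap,
                 eps: NDArray[np.complex128] | None = None) -> float:
    """Gibbs energy G(mu, lambda): log joint of data and parameters under
    the Laplace observation model (see module docstring)."""
    if eps is None:
        eps = prediction_error(mu, data, pmap)
    n = eps.size
    rho = np.asarray(mu, dtype=float) - prior.phi
    prec = np.exp(error_model.lam)
    sign, logdet_w = np.linalg.slogdet(prior.Omega_inv)
    if sign <= 0:
        raise ValueError("prior precision not positive definite")
    quad = prec * (eps.real @ eps.real + eps.imag @ eps.imag)
    return float(-0.5 * quad - 0.5 * rho @ prior.Omega_inv @ rho
                 + 0.5 * n * error_model.lam + 0.5 * logdet_w)


def _jacobian(mu: NDArray[np.float64], data: SpectralData,
              pmap: ParameterMap, step: float) -> NDArray[np.complex128]:
    """Central finite-difference Jacobian d(eps)/d(mu), shape (n, p).

    If a perturbed prediction fails (instability), the step for that
    parameter is halved and retried a few times.
    """
    p = pmap.n_params
    base = np.asarray(mu, dtype=float)
    cols = []
    for i in range(p):
        h = step
        for _ in range(4):
            try:
                up, dn = base.copy(), base.copy()
                up[i] += h
                dn[i] -= h
                col = (_predict(up, data.freqs_hz, pmap)
                       - _predict(dn, data.freqs_hz, pmap)) / (2.0 * h)
                break
            except (InstabilityError, FloatingPointError):
                h *= 0.5
        else:
            raise InstabilityError(
                f"prediction failed around mu for parameter {pmap.names[i]}")
        cols.append(col)
    return np.stack(cols, axis=1).astype(complex)


def energy_gradients(mu: NDArray[np.float64], data: SpectralData,
                     error_model: ErrorModel, prior: PriorDensity,
                     pmap: ParameterMap,
                     eps: NDArray[np.complex128] | None = None,
                     jac: NDArray[np.complex128] | None = None,
                     step: float = 1e-3):
    """Gradient and Gauss-Newton curvature of the Gibbs energy at ``mu``.

        dG  = -Re(J)' S^-1 Re(e) - Im(J)' S^-1 Im(e) - W^-1 rho
        ddG = -Re(J)' S^-1 Re(J) - Im(J)' S^-1 Im(J) - W^-1
    """
    if eps is None:
        eps = prediction_error(mu, data, pmap)
    if jac is None:
        jac = _jacobian(mu, data, pmap, step)
    rho = np.asarray(mu, dtype=float) - prior.phi
    prec = np.exp(error_model.lam)
    grad = (-prec * (jac.real.T @ eps.real + jac.imag.T @ eps.imag)
            - prior.Omega_inv @ rho)
    curv = (-prec * (jac.real.T @ jac.real + jac.imag.T @ jac.imag)
            - prior.Omega_inv)
    curv = 0.5 * (curv + curv.T)
    return grad, curv


def update_hyperparameters(mu: NDArray[np.float64], data: SpectralData,
                           error_model: ErrorModel, pmap: ParameterMap,
                           eps: NDArray[np.complex128] | None = None
                           ) -> ErrorModel:
    """Closed-form coordinate-ascent update of the noise log-precision.

    Maximizing G over lambda with Sigma = exp(-lambda) I gives
    exp(-lambda) = (|Re e|^2 + |Im e|^2) / n; the precision is capped when
    residuals vanish.
    """
    if eps is None:
        eps = prediction_error(mu, data, pmap)
    n = eps.size
    s = float(eps.real @ eps.real + eps.imag @ eps.imag)
    if s <= 0 or not np.isfinite(s):
        lam = LAMBDA_BOUND
    else:
        lam = float(np.clip(np.log(n / s), -LAMBDA_BOUND, LAMBDA_BOUND))
    return ErrorModel(lam=lam)


def _free_energy(g: float, curv: NDArray[np.float64]) -> float:
    """Laplace bound F = G - 1/2 ln|-ddG| + p/2 ln(2 pi)."""
    p = curv.shape[0]
    eig = np.linalg.eigvalsh(-curv)
    if eig.min() <= 0:
        raise np.linalg.LinAlgError("curvature not negative definite")
    return float(g - 0.5 * np.log(eig).sum()
                 + 0.5 * p * np.log(2.0 * np.pi))


def _evaluate(mu, data, prior, pmap, settings):
    """Residual, hyperparameter update, Jacobian, curvature and F at mu."""
    eps = prediction_error(mu, data, pmap)
    error_model = update_hyperparameters(mu, data, ErrorModel(), pmap,
                                         eps=eps)
    g = gibbs_energy(mu, data, error_model, prior, pmap, eps=eps)
    jac = _jacobian(mu, data, pmap, settings.jac_step)
    grad, curv = energy_gradients(mu, data, error_model, prior, pmap,
                                  eps=eps, jac=jac)
    f = _free_energy(g, curv)
    return {"mu": mu, "eps": eps, "error_model": error_model, "G": g,
            "jac": jac, "grad": grad, "curv": curv, "F": f}


def invert_model(data: SpectralData, prior: PriorDensity | None = None,
                 pmap: ParameterMap | None = None,
                 settings: InversionSettings | None = None
                 ) -> PosteriorDensity:
    """Variational-Laplace estimation of the log-scale parameters.

    Gauss-Newton ascent on the free energy with Levenberg-Marquardt
    damping; candidate steps are rejected (and damping increased tenfold)
    when they lower the free energy or land on unstable parameters.
    Returns the conditional density, noise hyperparameter and free-energy
    trace over accepted iterations.
    """
    pmap = pmap if pmap is not None else ParameterMap.for_variant()
    prior = prior if prior is not None else PriorDensity.default(
        pmap.n_params)
    settings = settings if settings is not None else InversionSettings()
    data.validate()

    mu0 = prior.phi.copy()
    stable, diag = check_stability(pmap.apply(mu0), data.freqs_hz)
    if not stable:
        raise InstabilityError(
            f"prior parameters are unstable: {diag['reason']}",
            mode=diag.get("mode"))

    state = _evaluate(mu0, data, prior, pmap, settings)
    trace = [state["F"]]
    damping = settings.damping_init
    slow = 0
    for it in range(settings.max_iter):
        h = state["curv"]
        m = -h + damping * np.diag(np.abs(np.diag(h)))
        try:
            step_vec = np.linalg.solve(m, state["grad"])
        except np.linalg.LinAlgError:
            damping *= 10.0
            continue
        cand_mu = state["mu"] + step_vec
        accepted = False
        stable, _ = check_stability(pmap.apply(cand_mu), data.freqs_hz)
        if stable:
            try:
                cand = _evaluate(cand_mu, data, prior, pmap, settings)
                if np.isfinite(cand["F"]) and cand["F"] >= state["F"] - 1e-8:
                    accepted = True
            except (InstabilityError, np.linalg.LinAlgError,
                    FloatingPointError):
                accepted = False
        if accepted:
            df = cand["F"] - state["F"]
            state = cand
            trace.append(state["F"])
            damping = max(damping / 10.0, 1e-8)
            logger.info("iter %3d  F=%.4f  dF=%.3e  |step|=%.3e  accepted",
                        it, state["F"], df, np.linalg.norm(step_vec))
            slow = slow + 1 if df < settings.f_tol else 0
            if slow >= settings.converged_runs:
                break
        else:
            damping *= 10.0
            logger.info("iter %3d  rejected (damping -> %.1e)", it, damping)
            if damping > settings.damping_max:
                break

    c = np.linalg.inv(-state["curv"])
    c = 0.5 * (c + c.T)
    return PosteriorDensity(
        mu=state["mu"], C=c, F=state["F"],
        lam=state["error_model"].lam, names=pmap.names, trace=trace,
        data_hash=data_fingerprint(data),
        settings={"max_iter": settings.max_iter, "f_tol": settings.f_tol,
                  "jac_step": settings.jac_step,
                  "variant": "mass" if pmap.base.mass_limit else "field"})
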