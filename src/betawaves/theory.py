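"""Linear-response theory of the E-I lattice: steady states, bifurcation
lines, and fluctuation spectra/correlations.

All closed forms live here; they serve both as scientific output (operating
point diagrams, theoretical LFP spectra) and as oracles for the stochastic
simulator.  Internally frequencies are handled in rad/s and times in seconds;
the public API takes Hz and the parameter tables' ms/mV/Hz units.

The local-module excitatory input current IE is the model's proxy-LFP, so
"LFP spectrum" below means the spectral density of IE fluctuations at one
lattice site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kernels import ConnectivityKernel, build_connectivity_kernel
from .params import NetworkParams
from .transfer import TransferFunction, default_transfer

__all__ = [
    "OperatingPoint", "BifurcationLine", "SpectrumResult",
    "synaptic_transfer", "coupling_transform", "loop_gains",
    "find_operating_point", "hopf_boundary", "hopf_frequency_at_alpha",
    "real_instability_boundary", "classify_operating_point",
    "characteristic_w", "external_spectral_density", "finite_size_spectral_density",
    "lfp_power_spectrum", "lfp_cross_correlation",
]


# ---------------------------------------------------------------------------
# elementary transforms

def synaptic_transfer(sigma, tau_r_s, tau_d_s, tau_l_s, tau_s=None):
    """Laplace transform of the synaptic kernel, S~(sigma), and optionally
    the membrane-filtered version T~(sigma) = S~/(1 + tau*sigma).

    ``sigma`` is the complex growth rate in 1/s (use ``1j*2*pi*f``).
    Returns ``S~`` if ``tau_s`` is None, else ``(S~, T~)``.
    """
    sigma = np.asarray(sigma, dtype=complex)
    s_t = np.exp(-sigma * tau_l_s) / ((1 + sigma * tau_r_s) * (1 + sigma * tau_d_s))
    if tau_s is None:
        return s_t
    return s_t, s_t / (1 + tau_s * sigma)


def coupling_transform(q, sigma, kernel: ConnectivityKernel):
    """Lattice Fourier transform of the coupling with conduction delays,
    C(q, sigma) = sum_x C(x) exp(-i q.x - sigma D |x|).

    ``q`` is a pair of wavenumbers in rad per grid unit, ``sigma`` in 1/s;
    the per-offset delays stored in the kernel (ms) supply D|x|.
    """
    qx, qy = q
    sigma = np.asarray(sigma, dtype=complex)
    phase = (-1j * (qx * kernel.offsets[:, 0] + qy * kernel.offsets[:, 1])
             - sigma[..., None] * (kernel.delay_ms * 1e-3))
    return (np.exp(phase) * kernel.weights).sum(axis=-1)


def _coupling_grid(kernel, qx, qy, omegas):
    """C(q, i*omega) for flattened q arrays [nq] x omega array [nw] -> [nq, nw].

    Groups kernel offsets by unique delay so the cost is nq*nd + nd*nw
    instead of nq*nw*K.
    """
    delays_s = kernel.delay_ms * 1e-3
    ud, inv = np.unique(delays_s, return_inverse=True)
    phase = np.exp(-1j * (np.outer(qx, kernel.offsets[:, 0])
                          + np.outer(qy, kernel.offsets[:, 1])))
    spatial = np.zeros((len(qx), len(ud)), dtype=complex)
    for g in range(len(ud)):
        sel = inv == g
        spatial[:, g] = phase[:, sel] @ kernel.weights[sel]
    tdep = np.exp(-1j * np.outer(ud, omegas))
    return spatial @ tdep


# ---------------------------------------------------------------------------
# operating point

@dataclass
class OperatingPoint:
    """Linearization data at a fixed point of the deterministic network."""

    r_e: float
    r_i: float
    i_e: float
    i_i: float
    gain_e: float   # Phi_E'(I_Es), Hz/mV
    gain_i: float
    tau_e_ms: float
    tau_i_ms: float
    alpha: float    # w_EE * Phi_E' : monosynaptic recurrent excitation gain
    beta: float     # w_IE * w_EI * Phi_E' * Phi_I' : disynaptic inhibition gain
    gamma: float    # w_II * Phi_I' : recurrent interneuron inhibition gain


def loop_gains(params: NetworkParams, gain_e: float, gain_i: float):
    """Dimensionless loop gains (alpha, beta, gamma) from weights and gains."""
    alpha = params.w_ee * gain_e
    beta = params.w_ie * params.w_ei * gain_e * gain_i
    gamma = params.w_ii * gain_i
    return alpha, beta, gamma


def find_operating_point(params: NetworkParams,
                         external_currents=None,
                         transfer_e: TransferFunction | None = None,
                         transfer_i: TransferFunction | None = None,
                         tol=1e-10, max_iter=200) -> OperatingPoint:
    """Locate the deterministic fixed point by damped Newton on (IE, II).

    ``external_currents`` defaults to the preset baseline
    ``(i_e_ext0, i_i_ext0)``.  Raises if no fixed point is found inside the
    transfer-table domain.
    """
    te = transfer_e or default_transfer("E")
    ti = transfer_i or default_transfer("I")
    if external_currents is None:
        external_currents = (params.i_e_ext0, params.i_i_ext0)
    ie_ext, ii_ext = external_currents

    def residual(v):
        ie, ii = v
        re_, ri_ = float(te.rate(ie)), float(ti.rate(ii))
        return np.array([
            ie - ie_ext - params.w_ee * re_ + params.w_ei * ri_,
            ii - ii_ext - params.w_ie * re_ + params.w_ii * ri_,
        ])

    v = np.array([float(te.inverse_rate(params.r_e_target)),
                  float(ti.inverse_rate(params.r_i_target))])
    f = residual(v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamping during line search is fine
        for _ in range(max_iter):
            if np.max(np.abs(f)) < tol:
                break
            ge, gi = float(te.gain(v[0])), float(ti.gain(v[1]))
            jac = np.array([[1 - params.w_ee * ge, params.w_ei * gi],
                            [-params.w_ie * ge, 1 + params.w_ii * gi]])
            try:
                step = np.linalg.solve(jac, -f)
            except np.linalg.LinAlgError:
                raise RuntimeError("singular Jacobian in fixed-point solve")
            lam = 1.0
            for _bt in range(40):
                v_new = v + lam * step
                f_new = residual(v_new)
                if np.linalg.norm(f_new) < np.linalg.norm(f):
                    break
                lam *= 0.5
            else:
                raise RuntimeError("fixed-point line search failed")
            v, f = v_new, f_new
        else:
            raise RuntimeError("fixed-point iteration did not converge")
    lo = min(te.currents[0], ti.currents[0])
    hi = max(te.currents[-1], ti.currents[-1])
    if not (lo <= v[0] <= hi and lo <= v[1] <= hi):
        raise RuntimeError("fixed point outside transfer-table domain")
    ge, gi = float(te.gain(v[0])), float(ti.gain(v[1]))
    alpha, beta, gamma = loop_gains(params, ge, gi)
    return OperatingPoint(
        r_e=float(te.rate(v[0])), r_i=float(ti.rate(v[1])),
        i_e=float(v[0]), i_i=float(v[1]), gain_e=ge, gain_i=gi,
        tau_e_ms=float(te.tau(v[0])), tau_i_ms=float(ti.tau(v[1])),
        alpha=alpha, beta=beta, gamma=gamma,
    )


# ---------------------------------------------------------------------------
# bifurcation lines

def _kinetics(params: NetworkParams, op: OperatingPoint):
    """Second-scale kinetic constants (tau_r/d/l of E and I, tau_E, tau_I)."""
    ms = 1e-3
    return ((params.tau_r_e * ms, params.tau_d_e * ms, params.tau_l_e * ms),
            (params.tau_r_i * ms, params.tau_d_i * ms, params.tau_l_i * ms),
            op.tau_e_ms * ms, op.tau_i_ms * ms)


def characteristic_w(q, sigma, alpha, beta, gamma, params, op,
                     kernel: ConnectivityKernel):
    """Characteristic function W(q, sigma) whose zeros are the linear modes."""
    (ke, ki, tau_e, tau_i) = _kinetics(params, op)
    _, t_e = synaptic_transfer(sigma, *ke, tau_e)
    _, t_i = synaptic_transfer(sigma, *ki, tau_i)
    c = coupling_transform(q, np.asarray(sigma, dtype=complex), kernel)
    return (1 - alpha * c * t_e) * (1 + gamma * t_i) + beta * c * t_e * t_i


@dataclass
class BifurcationLine:
    freq_hz: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    residual: np.ndarray   # |W| at each returned point
    valid: np.ndarray      # residual below tolerance and finite
    q: tuple
    gamma: float


def _hopf_point(omega, gamma, q, params, op, kernel):
    """Solve the two real equations Re W = Im W = 0 linearly for (alpha, beta)
    at growth rate i*omega."""
    (ke, ki, tau_e, tau_i) = _kinetics(params, op)
    s = np.asarray(1j * omega, dtype=complex)
    _, t_e = synaptic_transfer(s, *ke, tau_e)
    _, t_i = synaptic_transfer(s, *ki, tau_i)
    c = coupling_transform(q, s, kernel)
    a_coef = c * t_e * (1 + gamma * t_i)
    b_coef = -c * t_e * t_i
    rhs = 1 + gamma * t_i
    det = a_coef.real * b_coef.imag - a_coef.imag * b_coef.real
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (rhs.real * b_coef.imag - rhs.imag * b_coef.real) / det
        beta = (a_coef.real * rhs.imag - a_coef.imag * rhs.real) / det
    w = (1 - alpha * c * t_e) * (1 + gamma * t_i) + beta * c * t_e * t_i
    return alpha, beta, np.abs(w)


def hopf_boundary(freqs_hz, gamma, *, params: NetworkParams,
                  op: OperatingPoint | None = None,
                  q=(0.0, 0.0), kernel: ConnectivityKernel | None = None,
                  residual_tol=1e-8) -> BifurcationLine:
    """Oscillatory-instability (Hopf) line in the (alpha, beta) plane,
    parametrized by the oscillation frequency.

    Points where the residual of the characteristic equation exceeds
    ``residual_tol`` (singular denominators) are flagged invalid.
    """
    if op is None:
        op = find_operating_point(params)
    if kernel is None:
        kernel = build_connectivity_kernel(
            params.l_x, params.l_y, delay_slope_ms=params.delay_ms_per_unit)
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    omega = 2 * np.pi * freqs_hz
    alpha, beta, res = _hopf_point(omega, gamma, q, params, op, kernel)
    valid = np.isfinite(alpha) & np.isfinite(beta) & (res < residual_tol)
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} Hopf-line points dropped "
                      "(singular or inaccurate)")
    return BifurcationLine(freq_hz=freqs_hz, alpha=alpha, beta=beta,
                           residual=res, valid=valid, q=tuple(q), gamma=gamma)


def hopf_frequency_at_alpha(alpha_target, gamma, *, params: NetworkParams,
                            op: OperatingPoint | None = None,
                            q=(0.0, 0.0),
                            kernel: ConnectivityKernel | None = None,
                            f_lo=1.0, f_hi=200.0, tol_hz=1e-3):
    """Oscillation frequency where the Hopf line reaches the given alpha
    (physical branch, beta > 0), found by monotone bracketing.

    Returns ``(freq_hz, beta_at_crossing)``.
    """
    if op is None:
        op = find_operating_point(params)
    if kernel is None:
        kernel = build_connectivity_kernel(
            params.l_x, params.l_y, delay_slope_ms=params.delay_ms_per_unit)
    grid = np.linspace(f_lo, f_hi, 2000)
    line = hopf_boundary(grid, gamma, params=params, op=op, q=q, kernel=kernel)
    a = np.where(line.valid, line.alpha, np.nan)
    good = np.isfinite(a) & (line.beta > 0)
    sign = np.sign(a - alpha_target)
    crossings = np.where(good[:-1] & good[1:] & (sign[:-1] * sign[1:] < 0))[0]
    if len(crossings) == 0:
        raise ValueError("Hopf line does not reach the requested alpha on the "
                         f"physical branch in [{f_lo}, {f_hi}] Hz")

    def f_of(freq):
        al, _, _ = _hopf_point(2 * np.pi * freq, gamma, q, params, op, kernel)
        return float(al) - alpha_target

    i = crossings[0]
    freq = brentq(f_of, grid[i], grid[i + 1], xtol=tol_hz)
    _, beta, _ = _hopf_point(2 * np.pi * freq, gamma, q, params, op, kernel)
    return float(freq), float(beta)


def real_instability_boundary(alpha, gamma, *, q=(0.0, 0.0),
                              kernel: ConnectivityKernel | None = None):
    """Boundary of the runaway (real) instability:
    beta = [alpha - 1/C(q, 0)] (1 + gamma); kinetics-independent."""
    if kernel is None or (q[0] == 0 and q[1] == 0):
        c0 = 1.0
    else:
        c0 = float(np.real(coupling_transform(q, np.array(0.0 + 0j), kernel)))
    return (np.asarray(alpha) - 1.0 / c0) * (1.0 + gamma)


def classify_operating_point(params: NetworkParams,
                             external_currents=None,
                             transfer_e=None, transfer_i=None) -> dict:
    """Regime of the steady state reached under the given external currents.

    Locates the fixed point, computes the loop gains there, and compares the
    disynaptic gain beta against the oscillatory (Hopf) and runaway (real)
    boundaries at q=0.  Margins are signed distances in beta at fixed
    (alpha, gamma); positive margins mean the stable side.
    """
    op = find_operating_point(params, external_currents, transfer_e, transfer_i)
    kernel = build_connectivity_kernel(
        params.l_x, params.l_y, delay_slope_ms=params.delay_ms_per_unit)
    beta_real = float(real_instability_boundary(op.alpha, op.gamma))
    try:
        f_hopf, beta_hopf = hopf_frequency_at_alpha(
            op.alpha, op.gamma, params=params, op=op, kernel=kernel)
    except ValueError:
        f_hopf, beta_hopf = np.nan, np.inf
    if op.beta <= beta_real:
        regime = "runaway"
    elif op.beta >= beta_hopf:
        regime = "oscillatory"
    else:
        regime = "stable"
    return {
        "regime": regime,
        "operating_point": op,
        "frequency_hz": f_hopf,
        "beta_margin_hopf": beta_hopf - op.beta,
        "beta_margin_real": op.beta - beta_real,
    }


# ---------------------------------------------------------------------------
# fluctuation spectra

def _forcing_coefs(omega, params, op):
    """Frequency-dependent pieces shared by the spectral densities."""
    (ke, ki, tau_e, tau_i) = _kinetics(params, op)
    s = 1j * np.asarray(omega, dtype=float)
    s_e, t_e = synaptic_transfer(s, *ke, tau_e)
    s_i, t_i = synaptic_transfer(s, *ki, tau_i)
    return s, s_e, t_e, s_i, t_i, tau_e, tau_i


def external_spectral_density(q, omega, params: NetworkParams,
                              op: OperatingPoint,
                              kernel: ConnectivityKernel, c_q=None):
    """S_EE_ext(q, omega): spectral density (mV^2 s) of IE fluctuations
    driven by a unit-density OU input branch at wavevector q.

    Assumes point-like local input targets (no input-kernel spread).
    """
    s, s_e, t_e, s_i, t_i, tau_e, _ = _forcing_coefs(omega, params, op)
    if c_q is None:
        c_q = coupling_transform(q, s, kernel)
    w = ((1 - op.alpha * c_q * t_e) * (1 + op.gamma * t_i)
         + op.beta * c_q * t_e * t_i)
    sig_e = params.w_e_ext * params.nu_ext_hz
    sig_i = params.w_i_ext * params.nu_ext_hz
    tau_ext = params.tau_ext_ms * 1e-3
    num = np.abs(sig_e + (op.gamma * sig_e - sig_i * params.w_ei * op.gain_i)
                 * t_i) ** 2
    omega = np.asarray(omega, dtype=float)
    return tau_ext * num / ((1 + (omega * tau_ext) ** 2)
                            * (1 + (omega * tau_e) ** 2) * np.abs(w) ** 2)


def finite_size_spectral_density(q, omega, params: NetworkParams,
                                 op: OperatingPoint,
                                 kernel: ConnectivityKernel, c_q=None):
    """S_EE_N(q, omega): finite-size (1/N) contribution to the IE spectral
    density at wavevector q."""
    s, s_e, t_e, s_i, t_i, tau_e, _ = _forcing_coefs(omega, params, op)
    if c_q is None:
        c_q = coupling_transform(q, s, kernel)
    w = ((1 - op.alpha * c_q * t_e) * (1 + op.gamma * t_i)
         + op.beta * c_q * t_e * t_i)
    # E-noise route: written without dividing by alpha so w_EE = 0 is allowed
    coef_e = (params.w_ee * (1 + op.gamma * t_i)
              - params.w_ie * params.w_ei * op.gain_i * t_i)
    omega = np.asarray(omega, dtype=float)
    term_e = (op.r_e / params.n_e) * np.abs(coef_e * c_q * t_e) ** 2
    term_i = ((op.r_i / params.n_i) * params.w_ei ** 2 * np.abs(s_i) ** 2
              / (1 + (omega * tau_e) ** 2))
    return (term_e + term_i) / np.abs(w) ** 2


@dataclass
class SpectrumResult:
    freq_hz: np.ndarray
    s_total: np.ndarray       # single-module IE spectral density, mV^2 s
    s_global: np.ndarray      # c * S_ext(q=0, w) shared-input part
    s_local_ext: np.ndarray   # integrated (1-c) local external part
    s_finite_size: np.ndarray  # integrated finite-size part
    n_q: int
    meta: dict

    def one_sided_per_hz(self):
        """PSD against f >= 0 in mV^2/Hz (Welch convention)."""
        return 2.0 * self.s_total


def _q_nodes(n_q):
    q = np.linspace(-np.pi, np.pi, n_q)
    wts = np.full(n_q, q[1] - q[0])
    wts[0] = wts[-1] = 0.5 * (q[1] - q[0])
    return q, wts


def lfp_power_spectrum(params: NetworkParams, op: OperatingPoint | None = None,
                       freqs_hz=None, *, n_q=129,
                       kernel: ConnectivityKernel | None = None,
                       check_stability=True) -> SpectrumResult:
    """Single-module proxy-LFP power spectrum:

    S(w) = c S_ext(0,w) + int dq/(2pi)^2 [(1-c) S_ext(q,w) + S_N(q,w)]

    with a tensor-trapezoid quadrature over the Brillouin zone [-pi, pi]^2.
    """
    if op is None:
        op = find_operating_point(params)
    if kernel is None:
        kernel = build_connectivity_kernel(
            params.l_x, params.l_y, delay_slope_ms=params.delay_ms_per_unit)
    if check_stability:
        cls = classify_operating_point(params)
        if cls["regime"] != "stable":
            raise ValueError(f"operating point is {cls['regime']}; the "
                             "linear spectrum is undefined")
    if freqs_hz is None:
        freqs_hz = np.linspace(0.0, 100.0, 401)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    omega = 2 * np.pi * freqs_hz

    qs, wts = _q_nodes(n_q)
    qx = np.repeat(qs, n_q)
    qy = np.tile(qs, n_q)
    wq = (np.repeat(wts, n_q) * np.tile(wts, n_q)) / (2 * np.pi) ** 2

    s_loc = np.zeros_like(freqs_hz)
    s_fs = np.zeros_like(freqs_hz)
    chunk = 64
    for i0 in range(0, len(omega), chunk):
        om = omega[i0:i0 + chunk]
        c_q = _coupling_grid(kernel, qx, qy, om)          # [nq2, nw]
        s_ext = external_spectral_density(None, om[None, :], params, op,
                                          kernel, c_q=c_q)
        s_n = finite_size_spectral_density(None, om[None, :], params, op,
                                           kernel, c_q=c_q)
        s_loc[i0:i0 + chunk] = (1 - params.c) * (wq @ s_ext)
        s_fs[i0:i0 + chunk] = wq @ s_n
    s_glob = params.c * external_spectral_density((0.0, 0.0), omega, params,
                                                  op, kernel)
    total = s_glob + s_loc + s_fs
    return SpectrumResult(
        freq_hz=freqs_hz, s_total=total, s_global=s_glob,
        s_local_ext=s_loc, s_finite_size=s_fs, n_q=n_q,
        meta={"preset": params.preset_name, "c": params.c,
              "nu_ext_hz": params.nu_ext_hz,
              "n_e": params.n_e, "n_i": params.n_i},
    )


def lfp_cross_correlation(params: NetworkParams,
                          op: OperatingPoint | None = None,
                          displacement=(0, 0), lags_ms=None, *,
                          n_q=65, f_max_hz=250.0, n_f=1024,
                          kernel: ConnectivityKernel | None = None):
    """Equal- and lagged-time IE-IE correlation between two modules separated
    by ``displacement`` grid units.

    Returns ``(lags_ms, correlation, imag_residual)``; the correlation is the
    inverse Fourier transform of the cross-spectral density and should be
    real up to quadrature error (max imaginary part reported).
    """
    if op is None:
        op = find_operating_point(params)
    if kernel is None:
        kernel = build_connectivity_kernel(
            params.l_x, params.l_y, delay_slope_ms=params.delay_ms_per_unit)
    if lags_ms is None:
        lags_ms = np.linspace(-200.0, 200.0, 81)
    lags_ms = np.asarray(lags_ms, dtype=float)
    omega = 2 * np.pi * np.linspace(-f_max_hz, f_max_hz, n_f)

    qs, wts = _q_nodes(n_q)
    qx = np.repeat(qs, n_q)
    qy = np.tile(qs, n_q)
    wq = (np.repeat(wts, n_q) * np.tile(wts, n_q)) / (2 * np.pi) ** 2
    dx, dy = displacement
    phase_q = np.exp(1j * (qx * dx + qy * dy))

    cross = np.zeros(len(omega), dtype=complex)
    chunk = 64
    for i0 in range(0, len(omega), chunk):
        om = omega[i0:i0 + chunk]
        c_q = _coupling_grid(kernel, qx, qy, om)
        s_ext = external_spectral_density(None, om[None, :], params, op,
                                          kernel, c_q=c_q)
        s_n = finite_size_spectral_density(None, om[None, :], params, op,
                                           kernel, c_q=c_q)
        integrand = (1 - params.c) * s_ext + s_n
        cross[i0:i0 + chunk] = (wq * phase_q) @ integrand
    cross += params.c * external_spectral_density((0.0, 0.0), omega, params,
                                                  op, kernel)
    tau_s = lags_ms[:, None] * 1e-3
    corr = np.trapezoid(np.exp(1j * omega * tau_s) * cross, omega,
                        axis=1) / (2 * np.pi)
    return lags_ms, corr.real, float(np.abs(corr.imag).max())
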