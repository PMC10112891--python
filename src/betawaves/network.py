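"""Stochastic simulation of the 2-D lattice of E-I rate modules.

Each lattice site holds an excitatory and an inhibitory population described
by currents ``I_A`` with adaptive relaxation times ``tau_A(I_A)`` and rates
``r_A = Phi_A[I_A] + sqrt(Phi_A/N_A) xi_A`` (Ito), coupled locally (E-I loop)
and across the lattice by long-range excitation with distance-proportional
conduction delays.  External drive is an Ornstein-Uhlenbeck process mixing a
shared (global) component with per-module (local) components in power
fractions c : 1-c.

Integration is first-order Euler-Maruyama for the network equations, with an
exact exponential update for the OU input.  The heavy inner loop is compiled
with numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .kernels import ConnectivityKernel, InputKernel, build_connectivity_kernel, build_input_kernel
from .params import NetworkParams
from .transfer import TransferFunction, default_transfer

__all__ = [
    "StimulationProtocol", "ExternalInputState", "SimulationRecord",
    "steady_state_external_currents", "ou_input_step", "apply_stimulation",
    "evolve_network",
]


# ---------------------------------------------------------------------------
# stimulation

@dataclass
class StimulationProtocol:
    """Uniform current steps applied to all modules.

    ``steps`` is a list of (onset_ms, duration_ms, amplitude) tuples; the
    amplitude is expressed in units of the shared external input (i.e. it
    offsets the dimensionless OU variable eta, so the injected current on
    population A is ``amplitude * w_A_ext * nu_ext``).  Default step duration
    is 50 ms.
    """

    steps: list = field(default_factory=list)

    def __post_init__(self):
        ordered = sorted(self.steps, key=lambda s: s[0])
        for onset, dur, _amp in ordered:
            if dur <= 0:
                raise ValueError("stimulation step duration must be positive")
        for (o1, d1, _), (o2, _, _) in zip(ordered, ordered[1:]):
            if o1 + d1 > o2:
                raise ValueError("stimulation steps must not overlap")
        self.steps = ordered

    @classmethod
    def periodic(cls, amplitude, *, period_ms, duration_ms=50.0,
                 t_start_ms=0.0, t_stop_ms=np.inf, first_onset_ms=None):
        """Regularly repeated steps of the given amplitude."""
        steps = []
        t = first_onset_ms if first_onset_ms is not None else t_start_ms + period_ms / 2
        while t + duration_ms <= t_stop_ms:
            steps.append((t, duration_ms, amplitude))
            t += period_ms
        return cls(steps)

    def amplitude_at(self, t_ms: float) -> float:
        for onset, dur, amp in self.steps:
            if onset <= t_ms < onset + dur:
                return amp
        return 0.0

    def sample(self, n_steps: int, dt_ms: float) -> np.ndarray:
        out = np.zeros(n_steps)
        for onset, dur, amp in self.steps:
            i0 = max(0, int(np.ceil(onset / dt_ms)))
            i1 = min(n_steps, int(np.ceil((onset + dur) / dt_ms)))
            out[i0:i1] = amp
        return out


def apply_stimulation(protocol: StimulationProtocol | None, t_ms: float) -> float:
    """Stimulation offset (shared-input units) at time ``t_ms``; 0 if none."""
    if protocol is None:
        return 0.0
    return protocol.amplitude_at(t_ms)


# ---------------------------------------------------------------------------
# external OU input

@dataclass
class ExternalInputState:
    """Per-module OU field eta plus its RNG stream.

    The written normalization gives each eta a stationary variance of 1/2;
    the external current is ``I_A_ext0 + w_A_ext * nu_ext * eta``.
    """

    eta: np.ndarray
    rng: np.random.Generator

    @classmethod
    def stationary(cls, shape, seed, c=0.0):
        """Draw from the stationary law: a shared component of variance c/2
        plus independent components of variance (1-c)/2 per module."""
        rng = np.random.default_rng(seed)
        eta = (np.sqrt((1 - c) * 0.5) * rng.normal(size=shape)
               + np.sqrt(c * 0.5) * rng.normal())
        return cls(eta=eta, rng=rng)


def ou_input_step(state: ExternalInputState, dt_ms: float, tau_ext_ms: float,
                  c: float, input_kernel: InputKernel | None = None,
                  periodic: bool = True) -> ExternalInputState:
    """Advance the OU input field by one step (exact exponential update).

    With ``c=1`` every module receives the identical shared noise; with
    ``c=0`` modules are independent unless an input kernel spreads the local
    sources over neighboring modules.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("c must lie in [0, 1]")
    if dt_ms >= tau_ext_ms / 5:
        raise ValueError("dt must resolve the OU correlation time (dt < tau/5)")
    e = np.exp(-dt_ms / tau_ext_ms)
    sd = np.sqrt((1.0 - e * e) / 2.0)
    z_local = state.rng.normal(size=state.eta.shape)
    if input_kernel is not None and len(input_kernel.weights) > 1:
        spread = np.zeros_like(z_local)
        for (ox, oy), w in zip(input_kernel.offsets, input_kernel.weights):
            spread += w * np.roll(np.roll(z_local, ox, axis=0), oy, axis=1)
        z_local = spread  # periodic spreading preserves unit variance
    z_g = state.rng.normal()
    state.eta = state.eta * e + sd * (np.sqrt(1.0 - c) * z_local + np.sqrt(c) * z_g)
    return state


# ---------------------------------------------------------------------------
# steady state

def steady_state_external_currents(r_e, r_i, params: NetworkParams,
                                   transfer_e: TransferFunction | None = None,
                                   transfer_i: TransferFunction | None = None):
    """Constant external currents (mV) holding the network at rates (r_e, r_i).

    ``I_A_ext = Phi_A^-1(r_A) - w_AE r_E + w_AI r_I`` with rates in Hz and
    weights in mV*s.
    """
    te = transfer_e or default_transfer("E")
    ti = transfer_i or default_transfer("I")
    i_e = te.inverse_rate(r_e) - params.w_ee * r_e + params.w_ei * r_i
    i_i = ti.inverse_rate(r_i) - params.w_ie * r_e + params.w_ii * r_i
    return i_e, i_i


# ---------------------------------------------------------------------------
# simulation record

@dataclass
class SimulationRecord:
    t_ms: np.ndarray           # recorded time axis (ms)
    ie: np.ndarray             # [nt, nx, ny] excitatory-population current (mV)
    ii: np.ndarray             # [nt, nx, ny]
    eta_mean: np.ndarray       # [nt] lattice average of the OU input field
    stim: np.ndarray           # [nt] stimulation offset (shared-input units)
    dt_ms: float
    seed: int
    params: NetworkParams
    re: np.ndarray | None = None   # optional recorded rates
    eta: np.ndarray | None = None  # optional full OU field

    def __post_init__(self):
        if not (np.isfinite(self.ie).all() and np.isfinite(self.ii).all()):
            raise FloatingPointError("non-finite values in simulation record")

    @property
    def frame_rate_hz(self) -> float:
        return 1000.0 / (self.t_ms[1] - self.t_ms[0])

    def measurement_slice(self):
        p = self.params
        off = (p.total_grid - p.measure_size) // 2
        return slice(off, off + p.measure_size)

    def measurement_movie(self, which="ie") -> np.ndarray:
        """Proxy-LFP movie [nx, ny, nt] restricted to the measurement window.

        The default proxy-LFP is the total excitatory-population input
        current IE.
        """
        s = self.measurement_slice()
        arr = {"ie": self.ie, "ii": self.ii}[which][:, s, s]
        return np.ascontiguousarray(np.moveaxis(arr, 0, -1))


# ---------------------------------------------------------------------------
# numba core

@njit(cache=True)
def _simulate_core(n_steps, dt, seed,
                   dyn, periodic,
                   tab_i0, tab_di, tab_re, tab_te, tab_ri, tab_ti,
                   w_ee, w_ei, w_ie, w_ii,
                   tr_e, td_e, tr_i, td_i, lat_i_steps,
                   kox, koy, kw, kdel,
                   iox, ioy, iw,
                   i_e_ext0, i_i_ext0, sig_e, sig_i, tau_ext, c,
                   inv_ne, inv_ni,
                   stim, r_e_frozen, r_i_frozen,
                   ie0, ii0, eta0,
                   rec_stride, rec_re, rec_eta):
    np.random.seed(seed)
    nx, ny = dyn.shape
    K = kw.shape[0]
    KI = iw.shape[0]
    H = int(kdel.max()) + 1
    HI = lat_i_steps + 1
    nrec = (n_steps + rec_stride - 1) // rec_stride

    ie = ie0.copy()
    ii = ii0.copy()
    se = np.full((nx, ny), r_e_frozen)
    je = np.full((nx, ny), r_e_frozen)
    si = np.full((nx, ny), r_i_frozen)
    ji = np.full((nx, ny), r_i_frozen)
    eta = eta0.copy()
    re_hist = np.full((H, nx, ny), r_e_frozen)
    ri_hist = np.full((HI, nx, ny), r_i_frozen)
    drive = np.zeros((nx, ny))
    zloc = np.zeros((nx, ny))
    zspread = np.zeros((nx, ny))

    out_ie = np.empty((nrec, nx, ny))
    out_ii = np.empty((nrec, nx, ny))
    out_eta_mean = np.empty(nrec)
    out_re = np.empty((nrec, nx, ny)) if rec_re else np.empty((1, 1, 1))
    out_eta = np.empty((nrec, nx, ny)) if rec_eta else np.empty((1, 1, 1))

    noise_on = inv_ne > 0.0
    ext_on = (sig_e != 0.0) or (sig_i != 0.0)
    e_ou = np.exp(-dt / tau_ext)
    sd_ou = np.sqrt((1.0 - e_ou * e_ou) / 2.0)
    sq_c = np.sqrt(c)
    sq_1c = np.sqrt(1.0 - c)
    inv_dt_s = 1000.0 / dt  # white-noise variance per step, time in seconds
    n_tab = tab_re.shape[0]

    rec_i = 0
    for t in range(n_steps):
        # rates at time t (with finite-size noise), written into history
        row_e = t % H
        row_i = t % HI
        for x in range(nx):
            for y in range(ny):
                if dyn[x, y]:
                    # linear interpolation in the dense uniform tables
                    u = (ie[x, y] - tab_i0) / tab_di
                    if u < 0.0:
                        u = 0.0
                    elif u > n_tab - 1.001:
                        u = n_tab - 1.001
                    k0 = int(u)
                    f = u - k0
                    phe = tab_re[k0] * (1.0 - f) + tab_re[k0 + 1] * f
                    u = (ii[x, y] - tab_i0) / tab_di
                    if u < 0.0:
                        u = 0.0
                    elif u > n_tab - 1.001:
                        u = n_tab - 1.001
                    k0 = int(u)
                    f = u - k0
                    phi = tab_ri[k0] * (1.0 - f) + tab_ri[k0 + 1] * f
                    r_e = phe
                    r_i = phi
                    if noise_on:
                        r_e += np.sqrt(max(phe, 0.0) * inv_ne * inv_dt_s) * np.random.normal()
                        r_i += np.sqrt(max(phi, 0.0) * inv_ni * inv_dt_s) * np.random.normal()
                    re_hist[row_e, x, y] = r_e
                    ri_hist[row_i, x, y] = r_i
                else:
                    re_hist[row_e, x, y] = r_e_frozen
                    ri_hist[row_i, x, y] = r_i_frozen

        # delayed long-range excitatory drive
        for x in range(nx):
            for y in range(ny):
                if not dyn[x, y]:
                    continue
                acc = 0.0
                if periodic:
                    for k in range(K):
                        xs = (x - kox[k]) % nx
                        ys = (y - koy[k]) % ny
                        acc += kw[k] * re_hist[(t - kdel[k]) % H, xs, ys]
                else:
                    for k in range(K):
                        xs = x - kox[k]
                        ys = y - koy[k]
                        if xs < 0 or xs >= nx or ys < 0 or ys >= ny:
                            continue
                        acc += kw[k] * re_hist[(t - kdel[k]) % H, xs, ys]
                drive[x, y] = acc

        # synaptic cascades and currents (Euler), OU input (exact step)
        row_i_del = (t - lat_i_steps) % HI
        if ext_on:
            zg = np.random.normal()
            for x in range(nx):
                for y in range(ny):
                    zloc[x, y] = np.random.normal()
            if KI > 1:
                for x in range(nx):
                    for y in range(ny):
                        acc = 0.0
                        for k in range(KI):
                            xs = (x - iox[k]) % nx
                            ys = (y - ioy[k]) % ny
                            acc += iw[k] * zloc[xs, ys]
                        zspread[x, y] = acc
            else:
                for x in range(nx):
                    for y in range(ny):
                        zspread[x, y] = zloc[x, y]
        stim_t = stim[t]

        if rec_i < nrec and t % rec_stride == 0:
            out_ie[rec_i] = ie
            out_ii[rec_i] = ii
            s_eta = 0.0
            n_dyn = 0
            for x in range(nx):
                for y in range(ny):
                    if dyn[x, y]:
                        s_eta += eta[x, y]
                        n_dyn += 1
            out_eta_mean[rec_i] = s_eta / max(n_dyn, 1)
            if rec_re:
                out_re[rec_i] = re_hist[row_e]
            if rec_eta:
                out_eta[rec_i] = eta
            rec_i += 1

        for x in range(nx):
            for y in range(ny):
                if not dyn[x, y]:
                    continue
                je[x, y] += dt / tr_e * (-je[x, y] + drive[x, y])
                se[x, y] += dt / td_e * (-se[x, y] + je[x, y])
                ji[x, y] += dt / tr_i * (-ji[x, y] + ri_hist[row_i_del, x, y])
                si[x, y] += dt / td_i * (-si[x, y] + ji[x, y])

                eta_eff = eta[x, y] + stim_t
                i_ext_e = i_e_ext0 + sig_e * eta_eff
                i_ext_i = i_i_ext0 + sig_i * eta_eff

                u = (ie[x, y] - tab_i0) / tab_di
                if u < 0.0:
                    u = 0.0
                elif u > n_tab - 1.001:
                    u = n_tab - 1.001
                k0 = int(u)
                f = u - k0
                tau_e = tab_te[k0] * (1.0 - f) + tab_te[k0 + 1] * f
                u = (ii[x, y] - tab_i0) / tab_di
                if u < 0.0:
                    u = 0.0
                elif u > n_tab - 1.001:
                    u = n_tab - 1.001
                k0 = int(u)
                f = u - k0
                tau_i = tab_ti[k0] * (1.0 - f) + tab_ti[k0 + 1] * f

                ie[x, y] += dt / tau_e * (
                    -ie[x, y] + i_ext_e + w_ee * se[x, y] - w_ei * si[x, y])
                ii[x, y] += dt / tau_i * (
                    -ii[x, y] + i_ext_i + w_ie * se[x, y] - w_ii * si[x, y])

                if ext_on:
                    eta[x, y] = eta[x, y] * e_ou + sd_ou * (
                        sq_1c * zspread[x, y] + sq_c * zg)

        if not np.isfinite(ie[nx // 2, ny // 2]):
            return out_ie[:rec_i], out_ii[:rec_i], out_eta_mean[:rec_i], \
                out_re[:rec_i] if rec_re else out_re, \
                out_eta[:rec_i] if rec_eta else out_eta, 1

    return out_ie, out_ii, out_eta_mean, out_re, out_eta, 0


# ---------------------------------------------------------------------------
# driver

def evolve_network(params: NetworkParams, duration_ms: float, *,
                   dt_ms: float = 0.01, seed: int = 0,
                   protocol: StimulationProtocol | None = None,
                   transfer_e: TransferFunction | None = None,
                   transfer_i: TransferFunction | None = None,
                   finite_size_noise: bool = True,
                   record_ms: float = 1.0,
                   record_rates: bool = False,
                   record_eta: bool = False) -> SimulationRecord:
    """Integrate the full lattice model and return a decimated record.

    Finite-size noise is disabled either with ``finite_size_noise=False`` or
    by setting infinite population sizes; external fluctuations are disabled
    by ``params.nu_ext_hz = 0``.  State is recorded every ``record_ms``
    (default 1 ms frames).
    """
    if dt_ms > 0.05:
        raise ValueError("dt must be <= 0.05 ms for a faithful integration")
    p = params
    te = transfer_e or default_transfer("E")
    ti = transfer_i or default_transfer("I")

    n_total = p.total_grid
    dyn = np.ones((n_total, n_total), dtype=np.uint8)
    periodic = p.boundary == "periodic"
    if not periodic and p.boundary_depth > 0:
        d = p.boundary_depth
        dyn[:, :] = 0
        dyn[d:-d, d:-d] = 1

    kern = build_connectivity_kernel(p.l_x, p.l_y,
                                     delay_slope_ms=p.delay_ms_per_unit)
    kdel = np.rint((p.tau_l_e + kern.delay_ms) / dt_ms).astype(np.int64)
    ikern = build_input_kernel(p.l_input_x, p.l_input_y)
    lat_i_steps = int(round(p.tau_l_i / dt_ms))

    # dense uniform tables for the compiled loop
    i_lo = min(te.currents[0], ti.currents[0])
    i_hi = max(te.currents[-1], ti.currents[-1])
    n_tab = 6001
    tab_i = np.linspace(i_lo, i_hi, n_tab)
    tab_re_, tab_te_ = te.rate(tab_i), te.tau(tab_i)
    tab_ri_, tab_ti_ = ti.rate(tab_i), ti.tau(tab_i)

    inv_ne = 0.0 if (not finite_size_noise or not np.isfinite(p.n_e)) else 1.0 / p.n_e
    inv_ni = 0.0 if (not finite_size_noise or not np.isfinite(p.n_i)) else 1.0 / p.n_i
    sig_e = p.w_e_ext * p.nu_ext_hz
    sig_i = p.w_i_ext * p.nu_ext_hz

    n_steps = int(round(duration_ms / dt_ms))
    stim = (protocol.sample(n_steps, dt_ms) if protocol is not None
            else np.zeros(n_steps))
    rec_stride = max(1, int(round(record_ms / dt_ms)))

    rng = np.random.default_rng(seed)
    ie0 = np.full((n_total, n_total), float(te.inverse_rate(p.r_e_target)))
    ii0 = np.full((n_total, n_total), float(ti.inverse_rate(p.r_i_target)))
    if sig_e or sig_i:
        eta0 = (np.sqrt((1 - p.c) * 0.5)
                * rng.normal(size=(n_total, n_total))
                + np.sqrt(p.c * 0.5) * rng.normal())
    else:
        eta0 = np.zeros((n_total, n_total))
    numba_seed = int(rng.integers(0, 2**31 - 1))

    out = _simulate_core(
        n_steps, dt_ms, numba_seed, dyn, periodic,
        tab_i[0], tab_i[1] - tab_i[0], tab_re_, tab_te_, tab_ri_, tab_ti_,
        p.w_ee, p.w_ei, p.w_ie, p.w_ii,
        p.tau_r_e, p.tau_d_e, p.tau_r_i, p.tau_d_i, lat_i_steps,
        kern.offsets[:, 0], kern.offsets[:, 1], kern.weights, kdel,
        ikern.offsets[:, 0], ikern.offsets[:, 1], ikern.weights,
        p.i_e_ext0, p.i_i_ext0, sig_e, sig_i, p.tau_ext_ms, p.c,
        inv_ne, inv_ni,
        stim, p.r_e_target, p.r_i_target,
        ie0, ii0, eta0,
        rec_stride, record_rates, record_eta,
    )
    ie, ii, eta_mean, re, eta, status = out
    if status != 0:
        raise FloatingPointError(
            "simulation diverged (non-finite state); recorded "
            f"{ie.shape[0]} frames before abort")
    nrec = ie.shape[0]
    t_ms = np.arange(nrec) * rec_stride * dt_ms
    return SimulationRecord(
        t_ms=t_ms, ie=ie, ii=ii, eta_mean=eta_mean,
        stim=stim[::rec_stride][:nrec].copy(), dt_ms=dt_ms, seed=seed,
        params=p, re=re if record_rates else None,
        eta=eta if record_eta else None,
    )
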