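"""Epileptor network dynamics.

The 6D Epileptor couples a fast population (x1, y1; seizure discharges),
an intermediate population (x2, y2; spike-wave events) and a slow
permittivity variable z that moves the node in and out of the ictal
state; g low-pass filters x1 into x2.  The excitability parameter x0
sets the regime of an isolated node:

* x0 < -2.062 : stable down-state equilibrium (interictal),
* -2.062 < x0 : seizure-like events (sustained up-state oscillation),
* x0 >= -1.025 : an up-state equilibrium exists (the node no longer
  returns to the down state once that equilibrium is reached).

A 7th variable m turns the constant m of the base model into a slow
accumulator of stimulus charge: when m crosses the per-region seizure
threshold m_thresh, the excitability is effectively shifted by +1 via a
Heaviside term in the z equation, which can trigger a seizure.

Nodes are coupled through a linear approximation of permittivity
coupling, K * sum_j C_ij (x1_j - x1_i), acting inside the z equation.
Integration is explicit Euler (Euler-Maruyama with additive noise); the
default step of 0.05 ms resolves the fast subsystem, whose relaxation
rates reach about 13/ms at the down state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .anatomy import Connectome

#: boundary below which an isolated default-parameter node has a stable
#: down state -- produced by simulation, exposed for reference in docs
DEFAULT_DT_MS = 0.05


def _as_vector(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"expected scalar or ({n},) vector, got {arr.shape}")
    return arr.copy()


@dataclass
class EpileptorParameters:
    """Parameters of the base Epileptor (defaults as commonly published)."""

    r: float = 0.00035      # slow permittivity timescale (1/ms)
    tau: float = 10.0       # intermediate-population timescale (ms)
    Iext1: float = 3.1      # drive of the fast population
    Iext2: float = 0.45     # drive of the intermediate population
    a: float = 1.0
    a2: float = 6.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    m: float = 0.0
    x0: float | np.ndarray = -2.2  # excitability, scalar or per region

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.r <= 0:
            raise ValueError("tau and r must be positive")

    def x0_vector(self, n: int) -> np.ndarray:
        return _as_vector(self.x0, n)


@dataclass
class StimulationExtensionParameters:
    """Extra parameters of the stimulation variant."""

    mthresh: float | np.ndarray = 1.5  # seizure threshold on m, per region
    k: float = 20.0                    # stimulus gain into m
    r2: float = 0.006                  # m timescale (1/ms)
    n: float = 3.0                     # direct stimulus gain into x1

    def __post_init__(self) -> None:
        if self.r2 <= 0:
            raise ValueError("r2 must be positive")
        if np.any(np.asarray(self.mthresh) <= 0):
            raise ValueError("mthresh must be positive")

    def mthresh_vector(self, n: int) -> np.ndarray:
        return _as_vector(self.mthresh, n)


@dataclass
class NetworkModelSpec:
    """Everything needed to integrate one network simulation."""

    connectome: Connectome | np.ndarray
    K: float = 1.0
    params: EpileptorParameters = field(default_factory=EpileptorParameters)
    stim_params: StimulationExtensionParameters | None = None
    noise: float | np.ndarray = 0.0   # additive noise std per state variable
    dt: float = DEFAULT_DT_MS         # ms
    seed: int = 0
    z_floor: float | None = 1.0       # lower state bound on z (None disables)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.K < 0:
            raise ValueError("K must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        if isinstance(self.connectome, Connectome):
            return self.connectome.weights
        return np.asarray(self.connectome, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def noise_vector(self) -> np.ndarray:
        """Noise std per core state variable (x1, y1, x2, y2, z, g)."""
        arr = np.asarray(self.noise, dtype=float)
        if arr.ndim == 0:
            return np.full(6, float(arr))
        if arr.shape == (6,):
            return arr.astype(float)
        raise ValueError("noise must be scalar or length-6 (x1,y1,x2,y2,z,g)")


#: interictal default: noise drives the fast population, whose proximity
#: to the seizure threshold depends on x0 (x2/y2 noise cannot reach x1
#: on the resting branch, where f1 has no x2 dependence)
INTERICTAL_NOISE = np.array([0.1, 0.1, 0.0, 0.0, 0.0, 0.0])

STATE_VARIABLES = ("x1", "y1", "x2", "y2", "z", "g")
STATE_VARIABLES_STIM = STATE_VARIABLES + ("m",)


def coupling_term(x1: np.ndarray, weights: np.ndarray, K: float) -> np.ndarray:
    """Permittivity-coupling input per region: K * sum_j C_ij (x1_j - x1_i)."""
    x1 = np.asarray(x1, dtype=float)
    W = np.asarray(weights, dtype=float)
    if x1.shape != (W.shape[0],):
        raise ValueError("x1 length must match connectome size")
    return K * (W @ x1 - W.sum(axis=1) * x1)


def _f1(x1, x2, z, m, a, b):
    return np.where(x1 < 0,
                    a * x1 ** 3 - b * x1 ** 2,
                    -(m - x2 + 0.6 * (z - 4.0) ** 2) * x1)


def _f2(x2, a2):
    return np.where(x2 < -0.25, 0.0, a2 * (x2 + 0.25))


def _f3(z):
    return np.where(z < 0, -0.1 * z ** 7, 0.0)


def epileptor_deriv(state: np.ndarray, params: EpileptorParameters,
                    coupling: np.ndarray | float = 0.0) -> np.ndarray:
    """Time derivative of the base 6D Epileptor.

    ``state`` is (6, R) ordered (x1, y1, x2, y2, z, g); ``coupling`` is
    the precomputed permittivity-coupling input (see
    :func:`coupling_term`).  It is subtracted inside the z equation, so
    input from seizing neighbours (higher x1) lowers z and recruits the
    region, while quiescent neighbours act as seizure inhibitors.
    """
    state = np.atleast_2d(np.asarray(state, dtype=float))
    if state.shape[0] != 6:
        raise ValueError("base Epileptor state must have 6 variables")
    p = params
    x1, y1, x2, y2, z, g = state
    x0 = p.x0_vector(state.shape[1])
    I1 = _as_vector(p.Iext1, state.shape[1])
    dx1 = y1 - _f1(x1, x2, z, p.m, p.a, p.b) - z + I1
    dy1 = p.c - p.d * x1 ** 2 - y1
    dx2 = -y2 + x2 - x2 ** 3 + p.Iext2 + 0.002 * g - 0.3 * (z - 3.5)
    dy2 = (-y2 + _f2(x2, p.a2)) / p.tau
    dz = p.r * (4.0 * (x1 - x0) - z + _f3(z) - coupling)
    dg = -0.01 * (g - 0.1 * x1)
    return np.vstack([dx1, dy1, dx2, dy2, dz, dg])


def stim_epileptor_deriv(state: np.ndarray, params: EpileptorParameters,
                         stim_params: StimulationExtensionParameters,
                         coupling: np.ndarray | float = 0.0,
                         istim: np.ndarray | float = 0.0) -> np.ndarray:
    """Time derivative of the 7D Epileptor-stimulation model.

    The 7th variable m accumulates rectified stimulus charge,
    dm = r2 (k |Istim| - 0.3 m); crossing m_thresh engages a Heaviside
    excitability shift in the z equation (H(0) = 1), and the stimulus
    further enters x1 directly as +n Istim.
    """
    state = np.atleast_2d(np.asarray(state, dtype=float))
    if state.shape[0] != 7:
        raise ValueError("stimulation Epileptor state must have 7 variables")
    p, sp = params, stim_params
    R = state.shape[1]
    x1, y1, x2, y2, z, g, m = state
    x0 = p.x0_vector(R)
    I1 = _as_vector(p.Iext1, R)
    istim = _as_vector(istim, R)
    mth = sp.mthresh_vector(R)
    H = (m >= mth).astype(float)
    dx1 = y1 - _f1(x1, x2, z, m, p.a, p.b) - z + I1 + sp.n * istim
    dy1 = p.c - p.d * x1 ** 2 - y1
    dx2 = -y2 + x2 - x2 ** 3 + p.Iext2 + 0.002 * g - 0.3 * (z - 3.5)
    dy2 = (-y2 + _f2(x2, p.a2)) / p.tau
    dz = p.r * (4.0 * (x1 - x0 - H) - z + _f3(z) - coupling)
    dg = -0.01 * (g - 0.1 * x1)
    dm = sp.r2 * (sp.k * np.abs(istim) - 0.3 * m)
    return np.vstack([dx1, dy1, dx2, dy2, dz, dg, dm])


# ---------------------------------------------------------------------------
# compiled Euler-Maruyama core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _euler_core(y, W, K, rowsum, x0, r, tau, I1, I2, a, a2, b, c, d, m_const,
                use_stim, n_gain, k_gain, r2, mthresh,
                stim_mode, stim_weights, stim_wave, istim_full,
                sigma, dt, n_steps, record_every, seed, z_floor, out):
    """In-place Euler(-Maruyama) loop.  Returns -1 on success, else the
    first step index at which the state became non-finite."""
    R = y.shape[1]
    np.random.seed(seed)
    sq = np.sqrt(dt)
    has_noise = sigma.sum() > 0.0
    rec = 0
    for s in range(n_steps):
        x1 = y[0]
        if K > 0.0:
            coup = K * (np.dot(W, x1) - rowsum * x1)
        else:
            coup = np.zeros(R)
        for i in range(R):
            x1i = y[0, i]; y1i = y[1, i]; x2i = y[2, i]
            y2i = y[3, i]; zi = y[4, i]; gi = y[5, i]
            mi = y[6, i] if use_stim else m_const
            if use_stim:
                if stim_mode == 1:
                    ist = stim_weights[i] * stim_wave[s]
                elif stim_mode == 2:
                    ist = istim_full[i, s]
                else:
                    ist = 0.0
            else:
                ist = 0.0
            if x1i < 0.0:
                f1 = a * x1i ** 3 - b * x1i ** 2
            else:
                f1 = -(mi - x2i + 0.6 * (zi - 4.0) ** 2) * x1i
            f2 = 0.0 if x2i < -0.25 else a2 * (x2i + 0.25)
            f3 = -0.1 * zi ** 7 if zi < 0.0 else 0.0
            if use_stim:
                hshift = 1.0 if mi >= mthresh[i] else 0.0
            else:
                hshift = 0.0
            dx1 = y1i - f1 - zi + I1[i] + (n_gain * ist if use_stim else 0.0)
            dy1 = c - d * x1i ** 2 - y1i
            dx2 = -y2i + x2i - x2i ** 3 + I2 + 0.002 * gi - 0.3 * (zi - 3.5)
            dy2 = (-y2i + f2) / tau
            dz = r * (4.0 * (x1i - x0[i] - hshift) - zi + f3 - coup[i])
            dg = -0.01 * (gi - 0.1 * x1i)
            y[0, i] = x1i + dt * dx1
            y[1, i] = y1i + dt * dy1
            y[2, i] = x2i + dt * dx2
            y[3, i] = y2i + dt * dy2
            y[4, i] = zi + dt * dz
            y[5, i] = gi + dt * dg
            if use_stim:
                y[6, i] = mi + dt * r2 * (k_gain * abs(ist) - 0.3 * mi)
            if y[4, i] < z_floor:
                y[4, i] = z_floor
        if has_noise:
            # same draw order for both variants so that the stimulation
            # model with Istim = 0 reproduces base trajectories exactly
            noise = np.random.randn(6, R)
            for v in range(6):
                if sigma[v] > 0.0:
                    for i in range(R):
                        y[v, i] += sq * sigma[v] * noise[v, i]
        if (s + 1) % record_every == 0:
            ok = True
            for i in range(R):
                if not np.isfinite(y[0, i]):
                    ok = False
            if not ok:
                return s
            for v in range(y.shape[0]):
                for i in range(R):
                    out[v, i, rec] = y[v, i]
            rec += 1
    return -1


@dataclass
class SimResult:
    """Recorded trajectory of one network integration."""

    data: np.ndarray        # (n_vars, R, T)
    dt: float               # integration step, ms
    record_every: int
    variables: tuple[str, ...]

    @property
    def fs(self) -> float:
        """Sampling frequency of the recorded samples, Hz."""
        return 1000.0 / (self.dt * self.record_every)

    @property
    def time_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return (np.arange(1, n + 1)) * self.dt * self.record_every

    def var(self, name: str) -> np.ndarray:
        return self.data[self.variables.index(name)]

    def source_signal(self) -> np.ndarray:
        """SEEG source proxy x2 - x1 per region (R x T)."""
        return self.var("x2") - self.var("x1")


def default_initial_state(n_regions: int, with_m: bool = False) -> np.ndarray:
    """Nodes start at (0, 0, 0, 0, 3, 0[, 0]) and are relaxed during burn-in."""
    nv = 7 if with_m else 6
    y = np.zeros((nv, n_regions))
    y[4] = 3.0
    return y


def integrate(spec: NetworkModelSpec, duration_ms: float,
              initial_state: np.ndarray | None = None,
              stimulus: tuple[np.ndarray, np.ndarray] | np.ndarray | None = None,
              burn_in_ms: float = 10000.0,
              record_every: int = 20) -> SimResult:
    """Integrate the network with explicit Euler (Euler-Maruyama).

    The burn-in is integrated without noise or stimulus and discarded;
    noise starts afterwards, seeded by ``spec.seed``.  ``stimulus`` is
    either ``(weights, waveform)`` with per-region weights and a
    waveform sampled at ``spec.dt`` over the main run, or a full
    (R, n_steps) Istim array.  Raises on numerical divergence, naming
    the offending step.
    """
    if duration_ms < spec.dt:
        raise ValueError("duration must be at least one time step")
    R = spec.n_regions
    use_stim = spec.stim_params is not None
    p = spec.params
    sp = spec.stim_params or StimulationExtensionParameters()
    W = np.ascontiguousarray(spec.weights)
    rowsum = W.sum(axis=1)
    x0 = p.x0_vector(R)
    I1 = _as_vector(p.Iext1, R)
    mth = sp.mthresh_vector(R)
    sigma = spec.noise_vector()
    n_steps = int(round(duration_ms / spec.dt))

    if initial_state is None:
        y = default_initial_state(R, with_m=use_stim)
    else:
        y = np.array(initial_state, dtype=float)
        expected = 7 if use_stim else 6
        if y.shape != (expected, R):
            raise ValueError(f"initial_state must be ({expected}, {R})")
    nv = y.shape[0]

    stim_mode = 0
    stim_weights = np.zeros(1)
    stim_wave = np.zeros(1)
    istim_full = np.zeros((1, 1))
    if stimulus is not None:
        if not use_stim:
            raise ValueError("stimulus requires stim_params on the spec")
        if isinstance(stimulus, tuple):
            stim_weights = np.ascontiguousarray(stimulus[0], dtype=float)
            stim_wave = np.ascontiguousarray(stimulus[1], dtype=float)
            if stim_weights.shape != (R,):
                raise ValueError("stimulus weights must have length R")
            if len(stim_wave) < n_steps:
                stim_wave = np.concatenate(
                    [stim_wave, np.zeros(n_steps - len(stim_wave))])
            stim_mode = 1
        else:
            istim_full = np.ascontiguousarray(stimulus, dtype=float)
            if istim_full.shape != (R, n_steps):
                raise ValueError(f"Istim array must be ({R}, {n_steps})")
            stim_mode = 2

    seed32 = int(spec.seed) % (2 ** 32 - 1)
    zero_sigma = np.zeros(6)
    z_floor = -np.inf if spec.z_floor is None else float(spec.z_floor)

    if burn_in_ms > 0:
        nb = int(round(burn_in_ms / spec.dt))
        out_b = np.empty((nv, R, 1))
        status = _euler_core(
            y, W, spec.K, rowsum, x0, p.r, p.tau, I1, p.Iext2, p.a, p.a2,
            p.b, p.c, p.d, p.m, use_stim, sp.n, sp.k, sp.r2, mth,
            0, stim_weights, stim_wave, istim_full,
            zero_sigma, spec.dt, nb, nb, seed32, z_floor, out_b)
        if status >= 0:
            raise RuntimeError(f"state diverged at burn-in step {status}")

    n_rec = n_steps // record_every
    out = np.empty((nv, R, n_rec))
    status = _euler_core(
        y, W, spec.K, rowsum, x0, p.r, p.tau, I1, p.Iext2, p.a, p.a2,
        p.b, p.c, p.d, p.m, use_stim, sp.n, sp.k, sp.r2, mth,
        stim_mode, stim_weights, stim_wave, istim_full,
        sigma, spec.dt, n_steps, record_every, seed32, z_floor, out)
    if status >= 0:
        raise RuntimeError(f"state diverged (non-finite) at step {status}")
    variables = STATE_VARIABLES_STIM if use_stim else STATE_VARIABLES
    return SimResult(out, spec.dt, record_every, variables)


# ---------------------------------------------------------------------------
# excitability regimes of the isolated node
# ---------------------------------------------------------------------------

def classify_regime(x0_values, params: EpileptorParameters | None = None,
                    duration_ms: float = 200000.0,
                    tail_ms: float = 20000.0,
                    dt: float = DEFAULT_DT_MS) -> list[str]:
    """Classify isolated (K = 0, noise-free) nodes by simulation.

    Returns one of ``"down"`` (down-state fixed point), ``"oscillating"``
    (seizure-like events) or ``"up"`` (trajectory confined to the upper
    branch) per x0 value.  Classification uses x1: the intermediate
    population oscillates autonomously even at rest, so x2-based
    measures cannot separate the regimes.
    """
    x0_arr = np.atleast_1d(np.asarray(x0_values, dtype=float))
    n = len(x0_arr)
    base = params or EpileptorParameters()
    p = EpileptorParameters(r=base.r, tau=base.tau, Iext1=base.Iext1,
                            Iext2=base.Iext2, a=base.a, a2=base.a2, b=base.b,
                            c=base.c, d=base.d, m=base.m, x0=x0_arr)
    spec = NetworkModelSpec(connectome=np.zeros((n, n)), K=0.0, params=p,
                            noise=0.0, dt=dt, seed=0)
    res = integrate(spec, duration_ms, burn_in_ms=10000.0, record_every=20)
    x1 = res.var("x1")
    tail = x1[:, -int(tail_ms / 1000.0 * res.fs):]
    labels = []
    for i in range(n):
        ptp = tail[i].max() - tail[i].min()
        if ptp < 0.5:
            labels.append("down" if tail[i].min() < -0.5 else "up")
        elif tail[i].min() > -0.5:
            labels.append("up")
        else:
            labels.append("oscillating")
    return labels


def seizure_onset_boundary(params: EpileptorParameters | None = None,
                           lo: float = -2.2, hi: float = -1.6,
                           resolution: float = 0.0025,
                           duration_ms: float = 200000.0,
                           dt: float = DEFAULT_DT_MS) -> float:
    """Largest x0 with a stable down state, by bisection on simulations.

    Below the boundary the isolated node converges to the down-state
    fixed point; above it, seizure-like oscillations are sustained.
    Returns the bracket midpoint once the bracket is narrower than
    ``resolution``.
    """
    lab_lo, lab_hi = classify_regime([lo, hi], params, duration_ms, dt=dt)
    if lab_lo != "down" or lab_hi != "oscillating":
        raise ValueError(
            f"bracket does not straddle the boundary: {lab_lo}/{lab_hi}")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if classify_regime([mid], params, duration_ms, dt=dt)[0] == "down":
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def resting_x1(x0: float, params: EpileptorParameters | None = None,
               bracket: tuple[float, float] = (-2.0, 0.0)) -> float:
    """x1 of the quiescent-branch equilibrium of the isolated node.

    On the quiescent branch (x1 <= 0) the stationary x1 satisfies
    dx1/dt = 0 with y1, z and g at their own stationary values; the x1
    derivative there does not involve the intermediate population, and
    is strictly decreasing in x1, so the root is unique.  Raises if
    the equilibrium has left the bracket (x1 > 0).
    """
    rho_lo = _quiescent_dx1(bracket[0], x0, params)
    rho_hi = _quiescent_dx1(bracket[1], x0, params)
    if rho_lo < 0 or rho_hi > 0:
        raise ValueError("quiescent equilibrium not inside bracket")
    return float(brentq(_quiescent_dx1, bracket[0], bracket[1],
                        args=(x0, params), xtol=1e-12))


def _quiescent_dx1(x1: float, x0: float,
                   params: EpileptorParameters | None) -> float:
    base = params or EpileptorParameters()
    p = EpileptorParameters(r=base.r, tau=base.tau, Iext1=base.Iext1,
                            Iext2=base.Iext2, a=base.a, a2=base.a2, b=base.b,
                            c=base.c, d=base.d, m=base.m, x0=float(x0))
    # y1, z, g stationary given x1; x2/y2 do not enter dx1 for x1 <= 0
    state = np.array([x1, p.c - p.d * x1 ** 2, 0.0, 0.0,
                      4.0 * (x1 - x0), 0.1 * x1]).reshape(6, 1)
    return float(epileptor_deriv(state, p, 0.0)[0, 0])


def up_state_boundary(params: EpileptorParameters | None = None,
                      lo: float = -1.2, hi: float = -0.9,
                      resolution: float = 1e-4) -> float:
    """x0 at which the up-state equilibrium is born, by bisection.

    The quiescent equilibrium branch (continuous in x0 from the down
    state) rises with x0 and reaches x1 = 0 at this boundary; beyond it
    the node has an up-state equilibrium and no longer returns to the
    down state from there.  (Dynamically the newly born equilibrium is
    at first unstable, so forward simulation keeps bursting somewhat
    past this point; the boundary reported is the equilibrium one.)
    """
    def below(x0: float) -> bool:
        # equilibrium still on the negative-x1 side of the branch
        return _quiescent_dx1(0.0, x0, params) < 0

    if not below(lo) or below(hi):
        raise ValueError("bracket does not straddle the up-state birth")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if below(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
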