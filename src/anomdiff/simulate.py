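"""Generators for the candidate stochastic mechanisms of anomalous diffusion.

Three processes produce subdiffusive (or superdiffusive) sample paths through
very different microscopic mechanisms:

* **FBM** — fractional Brownian motion: Gaussian, self-similar with Hurst
  index H; long-memory *correlated* increments.  Simulated exactly by
  Davies–Harte circulant embedding of the fractional-Gaussian-noise
  covariance, with a Hosking (Durbin–Levinson) fallback when the embedding
  is not nonnegative definite.
* **FLSM** — fractional Lévy α-stable motion: self-similar with index H and
  stability index α; memory parameter d = H − 1/α.  Simulated by a truncated
  moving-average of i.i.d. α-stable innovations with kernel
  c_j = (j+1)^d − j^d.  α = 2 recovers (an approximation of) FBM.
* **CTRW** — continuous-time random walk: i.i.d. jumps separated by
  heavy-tailed Pareto waiting times with survival tail ∝ (t/τ0)^{−β},
  β ∈ (0,1) (infinite mean — the trapping regime); *non-stationary*
  increments, ensemble subdiffusion with exponent β.

Also provided: a bead-chain trajectory builder ("parallel" vs "coiled"
initial geometries) whose beads move under any of the above mechanisms, and
a scalar-observable wrapper emulating signals such as hydrogen-bond counts.

All generators draw every random number from a single integer seed per call
and are bit-reproducible; no global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .errors import GenerationError, ParameterError
from .observables import TimeSeries, Trajectory

__all__ = [
    "WaitingTimeModel",
    "StableParams",
    "ProcessPath",
    "BeadChainTrajectorySpec",
    "simulate_fbm",
    "sample_stable",
    "simulate_flsm",
    "simulate_ctrw",
    "simulate_bead_chains",
    "simulate_observable_series",
]

MECHANISMS = ("FBM", "FLSM", "CTRW", "BM", "CUSTOM")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class WaitingTimeModel:
    """Pareto waiting-time law ψ(t) = β τ0^β t^{−(1+β)} for t ≥ τ0.

    ``beta_tail`` is the survival-tail exponent: P(T > t) = (t/τ0)^{−β}.
    For β ∈ (0,1) the mean waiting time is infinite, which is the mechanism
    behind CTRW subdiffusion (ensemble MSD ∝ t^β).
    """

    beta_tail: float
    tau0: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.beta_tail < 1:
            raise ParameterError(
                f"beta_tail must lie in (0,1), got {self.beta_tail}"
            )
        if self.tau0 <= 0:
            raise ParameterError(f"tau0 must be > 0, got {self.tau0}")

    @property
    def c_norm(self) -> float:
        """PDF normalization constant β τ0^β."""
        return self.beta_tail * self.tau0**self.beta_tail

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n waiting times by inverse-CDF: τ0 · U^{−1/β}, U ∈ (0,1]."""
        u = 1.0 - rng.random(n)
        return self.tau0 * u ** (-1.0 / self.beta_tail)


@dataclass(frozen=True)
class StableParams:
    """Parameters of an α-stable law in the S1 parameterization.

    ``alpha_stab = 2`` is the Gaussian case (variance ``2·scale²``);
    ``alpha_stab = 1, skew = 0`` is Cauchy.
    """

    alpha_stab: float = 2.0
    skew: float = 0.0
    scale: float = 1.0
    loc: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_stab <= 2:
            raise ParameterError(
                f"alpha_stab must lie in (0,2], got {self.alpha_stab}"
            )
        if not -1 <= self.skew <= 1:
            raise ParameterError(f"skew must lie in [-1,1], got {self.skew}")
        if self.scale <= 0:
            raise ParameterError(f"scale must be > 0, got {self.scale}")


@dataclass
class ProcessPath:
    """A discretely observed process realization on a uniform time grid."""

    times: np.ndarray
    values: np.ndarray
    mechanism: str
    params: dict
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ParameterError("times and values must have equal length")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ParameterError("times must be strictly increasing")
        if self.mechanism not in MECHANISMS:
            raise ParameterError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_timeseries(self, label: str | None = None) -> TimeSeries:
        return TimeSeries(self.times, self.values, label=label or self.mechanism)


@dataclass(frozen=True)
class BeadChainTrajectorySpec:
    """Specification of a toy bead-chain system.

    ``geometry="parallel"`` lays straight equidistant chains side by side
    (an inter-molecular network); ``"coiled"`` builds each chain as a
    self-avoiding random-walk coil (an intra-molecular network).  Every bead
    coordinate then evolves independently under ``mechanism``.
    """

    n_chains: int = 16
    beads_per_chain: int = 20
    geometry: str = "parallel"
    mechanism: str = "FBM"
    motion_params: dict = field(default_factory=dict)
    n_frames: int = 100
    frame_dt: float = 1.0
    bond_length: float = 1.0
    chain_spacing: float = 3.0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.beads_per_chain < 1 or self.n_frames < 1:
            raise ParameterError("counts must be positive")
        if self.geometry not in ("parallel", "coiled"):
            raise ParameterError(
                f"geometry must be 'parallel' or 'coiled', got {self.geometry!r}"
            )
        if self.mechanism not in ("FBM", "FLSM", "CTRW", "BM"):
            raise ParameterError(f"unknown motion mechanism {self.mechanism!r}")
        if self.bond_length <= 0 or self.chain_spacing <= 0 or self.frame_dt <= 0:
            raise ParameterError("lengths and time step must be positive")


# ---------------------------------------------------------------------------
# fractional Gaussian noise


def _fgn_autocov(hurst: float, n: int) -> np.ndarray:
    """Autocovariance γ(k), k=0..n, of unit-variance fGn."""
    k = np.arange(n + 1, dtype=float)
    return 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )


def _fgn_davies_harte(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn sample via circulant embedding; GenerationError if the
    embedding spectrum is negative."""
    gamma = _fgn_autocov(hurst, n)
    circ = np.concatenate([gamma[:-1], gamma[-1:], gamma[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8 * lam.max():
        raise GenerationError(
            f"circulant embedding not nonnegative definite for H={hurst}, n={n}"
        )
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    a = rng.standard_normal(n + 1)
    b = rng.standard_normal(n - 1)
    w = np.empty(m, dtype=complex)
    w[0] = math.sqrt(lam[0] / m) * a[0]
    w[n] = math.sqrt(lam[n] / m) * a[n]
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (a[1:n] + 1j * b)
    w[n + 1:] = np.conj(w[n - 1:0:-1])
    return np.fft.fft(w).real[:n]


def _fgn_hosking(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """fGn by the Durbin–Levinson recursion (exact, O(n²))."""
    gamma = _fgn_autocov(hurst, n)
    z = rng.standard_normal(n)
    out = np.empty(n)
    phi = np.zeros(n)
    v = gamma[0]
    out[0] = math.sqrt(v) * z[0]
    for t in range(1, n):
        if t == 1:
            kappa = gamma[1] / gamma[0]
        else:
            kappa = (gamma[t] - phi[: t - 1] @ gamma[t - 1:0:-1]) / v
            phi[: t - 1] = phi[: t - 1] - kappa * phi[t - 2::-1]
        phi[t - 1] = kappa
        v = v * (1 - kappa * kappa)
        out[t] = phi[:t] @ out[t - 1::-1] + math.sqrt(v) * z[t]
    return out


def simulate_fbm(
    hurst: float,
    n_steps: int,
    dt: float = 1.0,
    sigma: float = 1.0,
    seed: int = 0,
    method: str = "auto",
) -> ProcessPath:
    """Exact fractional Brownian motion starting at 0.

    The path has covariance R(s,t) = (σ²/2)(s^{2H} + t^{2H} − |t−s|^{2H}).
    ``method`` is ``"auto"`` (circulant embedding, Hosking fallback),
    ``"davies-harte"`` or ``"hosking"``.
    """
    if not 0 < hurst < 1:
        raise ParameterError(f"hurst must lie in (0,1), got {hurst}")
    if n_steps < 2:
        raise ParameterError(f"n_steps must be >= 2, got {n_steps}")
    if dt <= 0 or sigma <= 0:
        raise ParameterError("dt and sigma must be positive")
    rng = np.random.default_rng(seed)
    if method == "davies-harte":
        fgn = _fgn_davies_harte(hurst, n_steps, rng)
    elif method == "hosking":
        fgn = _fgn_hosking(hurst, n_steps, rng)
    elif method == "auto":
        try:
            fgn = _fgn_davies_harte(hurst, n_steps, rng)
        except GenerationError:
            rng = np.random.default_rng(seed)
            fgn = _fgn_hosking(hurst, n_steps, rng)
    else:
        raise ParameterError(f"unknown method {method!r}")
    increments = sigma * dt**hurst * fgn
    values = np.concatenate([[0.0], np.cumsum(increments)])
    times = np.arange(n_steps + 1) * dt
    return ProcessPath(
        times,
        values,
        mechanism="FBM" if hurst != 0.5 else "BM",
        params={"hurst": hurst, "sigma": sigma, "dt": dt, "method": method},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# α-stable sampling (Chambers–Mallows–Stuck)


def _stable_standard(
    alpha: float, skew: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    u = rng.uniform(-math.pi / 2, math.pi / 2, n)
    w = rng.exponential(1.0, n)
    if abs(alpha - 1.0) < 1e-12:
        half_pi = math.pi / 2
        x = (
            (half_pi + skew * u) * np.tan(u)
            - skew * np.log((half_pi * w * np.cos(u)) / (half_pi + skew * u))
        ) / half_pi
        return x
    zeta = -skew * math.tan(math.pi * alpha / 2)
    xi = math.atan(-zeta) / alpha
    factor = (1 + zeta * zeta) ** (1 / (2 * alpha))
    x = (
        factor
        * np.sin(alpha * (u + xi))
        / np.cos(u) ** (1 / alpha)
        * (np.cos(u - alpha * (u + xi)) / w) ** ((1 - alpha) / alpha)
    )
    return x


def sample_stable(
    params: StableParams, n: int, seed: int | None = 0, rng=None
) -> np.ndarray:
    """i.i.d. α-stable variates by the Chambers–Mallows–Stuck transform
    (trigonometric transform of a uniform angle and an exponential variate).

    S1 parameterization: for α ≠ 1 the returned variates are
    ``loc + scale · Z`` with ``Z`` standard stable; at α = 1 with skew ≠ 0
    the standard S1 scale-log correction ``(2/π)·skew·scale·ln(scale)`` is
    applied.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    z = _stable_standard(params.alpha_stab, params.skew, int(n), rng)
    x = params.scale * z + params.loc
    if abs(params.alpha_stab - 1.0) < 1e-12 and params.skew != 0:
        x = x + (2 / math.pi) * params.skew * params.scale * math.log(params.scale)
    return x


# ---------------------------------------------------------------------------
# fractional Lévy α-stable motion


def simulate_flsm(
    stable: StableParams,
    hurst: float,
    n_steps: int,
    dt: float = 1.0,
    kernel_len: int | None = None,
    seed: int = 0,
    oversample: int = 4,
) -> ProcessPath:
    """FLSM by a truncated moving-average of stable innovations.

    Increments are the convolution of i.i.d. α-stable innovations with the
    kernel c_j = (j+1)^d − j^d, d = H − 1/α, evaluated on an internal grid
    ``oversample`` times finer than the output grid (micro-increments are
    aggregated per output step; the refinement reduces the small-lag
    discretization bias of the Riemann scheme).  The kernel is truncated
    at ``kernel_len`` micro steps (default 4× the micro-grid length).  The
    innovation scale is normalized so the end point X(T) is *exactly*
    α-stable with scale ``scale · T^H``; with α = 2 the end-point law
    therefore coincides with that of the exact FBM generator at
    σ = √2·scale.
    """
    if not 0 < hurst < 1:
        raise ParameterError(f"hurst must lie in (0,1), got {hurst}")
    if n_steps < 2:
        raise ParameterError(f"n_steps must be >= 2, got {n_steps}")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if oversample < 1:
        raise ParameterError(f"oversample must be >= 1, got {oversample}")
    alpha = stable.alpha_stab
    d = hurst - 1.0 / alpha
    if d <= -1.0 / alpha:
        raise ParameterError(
            f"memory parameter d = H - 1/alpha = {d:.4f} must exceed -1/alpha"
        )
    n_micro = n_steps * oversample
    if kernel_len is None:
        kernel_len = 4 * n_micro
    if kernel_len < n_micro:
        raise ParameterError(
            f"kernel_len ({kernel_len}) must cover the simulated grid "
            f"({n_micro} micro steps)"
        )
    rng = np.random.default_rng(seed)
    j = np.arange(kernel_len, dtype=float)
    with np.errstate(divide="ignore"):
        kernel = (j + 1) ** d - j**d
    kernel[0] = 1.0  # 0^d is taken as 0 (the (−s)_+^d branch vanishes at s=0)
    # weights of each innovation in X(T): window sums of the kernel
    w = np.convolve(kernel, np.ones(n_micro))
    norm = float(np.sum(np.abs(w) ** alpha) ** (1.0 / alpha))
    scale_z = stable.scale * (n_steps * dt) ** hurst / norm
    innov = _stable_standard(alpha, stable.skew, n_micro + kernel_len - 1, rng)
    micro = scale_z * fftconvolve(kernel, innov)[kernel_len - 1: kernel_len - 1 + n_micro]
    increments = micro.reshape(n_steps, oversample).sum(axis=1)
    times = np.arange(n_steps + 1) * dt
    values = np.concatenate([[0.0], np.cumsum(increments)]) + stable.loc * times
    return ProcessPath(
        times,
        values,
        mechanism="FLSM",
        params={
            "alpha_stab": alpha,
            "skew": stable.skew,
            "scale": stable.scale,
            "loc": stable.loc,
            "hurst": hurst,
            "d": d,
            "dt": dt,
            "kernel_len": kernel_len,
            "oversample": oversample,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# continuous-time random walk


def simulate_ctrw(
    wt: WaitingTimeModel,
    jump: StableParams,
    t_max: float,
    grid_dt: float = 1.0,
    seed: int = 0,
) -> ProcessPath:
    """CTRW rendered on a uniform grid by last-observation-carried-forward.

    The walker waits a Pareto time, jumps by an i.i.d. increment from
    ``jump``, and repeats; the grid value at time t is the position after
    the last jump at or before t (piecewise constant — the physical picture
    of trapping).  True jump times and sizes are recorded in ``meta``.
    """
    if grid_dt <= 0:
        raise ParameterError(f"grid_dt must be > 0, got {grid_dt}")
    if t_max <= wt.tau0:
        raise ParameterError(
            f"t_max ({t_max}) must exceed the minimum waiting time tau0 ({wt.tau0})"
        )
    rng = np.random.default_rng(seed)
    waits = []
    total = 0.0
    # typical number of renewals grows like t^beta; draw in geometric chunks
    chunk = max(16, int((t_max / wt.tau0) ** wt.beta_tail) + 16)
    while total <= t_max:
        block = wt.sample(chunk, rng)
        waits.append(block)
        total += float(block.sum())
    waits = np.concatenate(waits)
    jump_times = np.cumsum(waits)
    n_jumps = int(np.searchsorted(jump_times, t_max, side="right"))
    jump_times = jump_times[:n_jumps]
    jumps = sample_stable(jump, n_jumps, rng=rng) if n_jumps else np.empty(0)
    positions = np.concatenate([[0.0], np.cumsum(jumps)])
    n_grid = int(math.floor(t_max / grid_dt))
    times = np.arange(n_grid + 1) * grid_dt
    idx = np.searchsorted(jump_times, times, side="right")
    values = positions[idx]
    return ProcessPath(
        times,
        values,
        mechanism="CTRW",
        params={
            "beta_tail": wt.beta_tail,
            "tau0": wt.tau0,
            "jump_alpha": jump.alpha_stab,
            "jump_scale": jump.scale,
            "t_max": t_max,
            "grid_dt": grid_dt,
        },
        seed=seed,
        meta={"jump_times": jump_times, "jump_sizes": jumps},
    )


# ---------------------------------------------------------------------------
# bead chains


def _parallel_geometry(spec: BeadChainTrajectorySpec) -> np.ndarray:
    coords = np.zeros((spec.n_chains, spec.beads_per_chain, 3))
    for c in range(spec.n_chains):
        coords[c, :, 0] = np.arange(spec.beads_per_chain) * spec.bond_length
        coords[c, :, 1] = c * spec.chain_spacing
    return coords


def _coiled_chain(
    n_beads: int, bond: float, rng: np.random.Generator, max_tries: int = 200
) -> np.ndarray:
    """Self-avoiding random walk with fixed bond length; beads closer than
    0.9·bond are rejected, with backtracking when a step gets stuck."""
    pts = [np.zeros(3)]
    tries_here = 0
    while len(pts) < n_beads:
        v = rng.standard_normal(3)
        v *= bond / np.linalg.norm(v)
        cand = pts[-1] + v
        dists = np.linalg.norm(np.array(pts) - cand, axis=1)
        if np.all(dists >= 0.9 * bond - 1e-12):
            pts.append(cand)
            tries_here = 0
        else:
            tries_here += 1
            if tries_here > max_tries:
                if len(pts) > 1:
                    pts.pop()
                    tries_here = 0
                else:
                    raise GenerationError("self-avoiding walk failed to start")
    return np.array(pts)


def _coiled_geometry(
    spec: BeadChainTrajectorySpec, rng: np.random.Generator
) -> np.ndarray:
    coords = np.empty((spec.n_chains, spec.beads_per_chain, 3))
    # place coil origins on a cubic grid wide enough to keep coils apart
    per_side = int(math.ceil(spec.n_chains ** (1 / 3)))
    pitch = 2.0 * spec.bond_length * max(2.0, spec.beads_per_chain**0.6)
    for c in range(spec.n_chains):
        origin = (
            np.array(
                [
                    c % per_side,
                    (c // per_side) % per_side,
                    c // (per_side * per_side),
                ],
                dtype=float,
            )
            * pitch
        )
        coords[c] = origin + _coiled_chain(spec.beads_per_chain, spec.bond_length, rng)
    return coords


def _displacement_paths(
    mechanism: str,
    motion_params: dict,
    n_paths: int,
    n_steps: int,
    dt: float,
    seeds: np.ndarray,
) -> np.ndarray:
    """(n_paths, n_steps+1) displacement paths, one child seed each."""
    out = np.empty((n_paths, n_steps + 1))
    p = dict(motion_params)
    for i in range(n_paths):
        s = int(seeds[i])
        if mechanism in ("FBM", "BM"):
            hurst = 0.5 if mechanism == "BM" else p.get("hurst", 0.3)
            path = simulate_fbm(
                hurst, n_steps, dt=dt, sigma=p.get("sigma", 1.0), seed=s
            )
        elif mechanism == "FLSM":
            stable = StableParams(
                alpha_stab=p.get("alpha_stab", 1.8),
                skew=p.get("skew", 0.0),
                scale=p.get("scale", 1.0),
            )
            path = simulate_flsm(stable, p.get("hurst", 0.3), n_steps, dt=dt, seed=s)
        elif mechanism == "CTRW":
            wt = WaitingTimeModel(p.get("beta_tail", 0.7), p.get("tau0", dt))
            jump = StableParams(scale=p.get("jump_scale", 1.0))
            path = simulate_ctrw(wt, jump, t_max=n_steps * dt, grid_dt=dt, seed=s)
        else:
            raise ParameterError(f"unknown motion mechanism {mechanism!r}")
        out[i] = path.values[: n_steps + 1]
    return out


def simulate_bead_chains(spec: BeadChainTrajectorySpec, seed: int = 0) -> Trajectory:
    """Build the initial geometry and advance every bead coordinate
    independently under the spec's motion mechanism."""
    ss = np.random.SeedSequence(seed)
    geom_seed, motion_seed = ss.spawn(2)
    rng = np.random.default_rng(geom_seed)
    if spec.geometry == "parallel":
        init = _parallel_geometry(spec)
    else:
        init = _coiled_geometry(spec, rng)
    n_atoms = spec.n_chains * spec.beads_per_chain
    init = init.reshape(n_atoms, 3)
    n_steps = spec.n_frames - 1
    coords = np.empty((spec.n_frames, n_atoms, 3))
    if n_steps == 0:
        coords[0] = init
    else:
        child_seeds = np.random.default_rng(motion_seed).integers(
            0, 2**31 - 1, size=3 * n_atoms
        )
        disp = _displacement_paths(
            spec.mechanism, spec.motion_params, 3 * n_atoms, n_steps,
            spec.frame_dt, child_seeds,
        )
        disp = disp.reshape(n_atoms, 3, spec.n_frames).transpose(2, 0, 1)
        coords = init[None, :, :] + disp
    chain_ids = np.repeat(
        [f"c{c:02d}" for c in range(spec.n_chains)], spec.beads_per_chain
    ).astype(object)
    return Trajectory(coords, frame_dt=spec.frame_dt, chain_ids=chain_ids)


# ---------------------------------------------------------------------------
# scalar observables


def simulate_observable_series(
    mechanism: str,
    params: dict | None = None,
    n_steps: int = 1024,
    seed: int = 0,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    dt: float = 1.0,
    label: str = "",
) -> TimeSeries:
    """A scalar observable series driven by one of the mechanisms.

    Wraps the corresponding path generator, then adds a constant ``offset``
    and optional i.i.d. Gaussian observation noise — emulating signals such
    as a per-frame hydrogen-bond count treated as a stochastic variable.
    """
    params = dict(params or {})
    ss = np.random.SeedSequence(seed)
    path_seed, noise_seed = ss.spawn(2)
    path_seed = int(np.random.default_rng(path_seed).integers(0, 2**31 - 1))
    if mechanism == "BM":
        path = simulate_fbm(0.5, n_steps, dt=dt,
                            sigma=params.get("sigma", 1.0), seed=path_seed)
    elif mechanism == "FBM":
        path = simulate_fbm(params.get("hurst", 0.3), n_steps, dt=dt,
                            sigma=params.get("sigma", 1.0), seed=path_seed)
    elif mechanism == "FLSM":
        stable = StableParams(
            alpha_stab=params.get("alpha_stab", 1.8),
            skew=params.get("skew", 0.0),
            scale=params.get("scale", 1.0),
        )
        path = simulate_flsm(
            stable, params.get("hurst", 0.3), n_steps, dt=dt,
            kernel_len=params.get("kernel_len"), seed=path_seed,
        )
    elif mechanism == "CTRW":
        wt = WaitingTimeModel(params.get("beta_tail", 0.7), params.get("tau0", dt))
        jump = StableParams(scale=params.get("jump_scale", 1.0))
        path = simulate_ctrw(wt, jump, t_max=n_steps * dt, grid_dt=dt, seed=path_seed)
    else:
        raise ParameterError(
            f"mechanism must be one of ('FBM', 'FLSM', 'CTRW', 'BM'), got {mechanism!r}"
        )
    values = path.values[: n_steps + 1].copy() + offset
    if noise_sd > 0:
        noise_rng = np.random.default_rng(noise_seed)
        values = values + noise_sd * noise_rng.standard_normal(len(values))
    return TimeSeries(
        path.times[: n_steps + 1], values,
        label=label or f"{mechanism} observable",
    )
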