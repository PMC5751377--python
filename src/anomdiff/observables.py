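"""Trajectory containers and geometric observables.

A :class:`Trajectory` is a stack of Cartesian frames with a per-atom chain
assignment; a :class:`TimeSeries` is a uniformly sampled scalar observable —
the unit on which the statistical tests in :mod:`anomdiff.scaling` and
:mod:`anomdiff.pvariation` operate.

Two mean-square-displacement estimators are provided:

* ``fixed-origin`` (default): ``MSD(δt) = (1/N) Σ_i |r_i(δt) − r_i(0)|²``,
  the displacement of each atom from its position in the first frame,
  averaged over atoms.
* ``time-averaged``: a sliding-origin average over all start frames, the
  single-trajectory estimator that underlies the sample-MSD test.

Coordinates are Cartesian in arbitrary length units; no periodic-boundary
handling is performed (a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "Frame",
    "Trajectory",
    "TimeSeries",
    "MsdCurve",
    "center_of_mass",
    "radius_of_gyration",
    "rg_timeseries",
    "msd_curve",
    "read_xyz_trajectory",
]


@dataclass
class Frame:
    """A single snapshot: per-atom 3-D Cartesian positions."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ParameterError(
                f"frame coordinates must have shape (n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ParameterError("frame must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError("frame contains non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered frames with a chain assignment per atom.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)``.
    frame_dt
        Time between consecutive frames (arbitrary units, > 0).
    chain_ids
        Per-atom chain labels; defaults to a single chain ``"A"``.
    """

    coords: np.ndarray
    frame_dt: float = 1.0
    chain_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParameterError(
                f"trajectory coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coords.shape}"
            )
        if self.frame_dt <= 0:
            raise ParameterError(f"frame_dt must be > 0, got {self.frame_dt}")
        if self.chain_ids is None:
            self.chain_ids = np.full(self.n_atoms, "A", dtype=object)
        else:
            self.chain_ids = np.asarray(self.chain_ids, dtype=object)
            if self.chain_ids.shape != (self.n_atoms,):
                raise ParameterError(
                    f"chain_ids must have one label per atom "
                    f"({self.n_atoms}), got shape {self.chain_ids.shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chains(self) -> list[str]:
        """Sorted distinct chain labels."""
        return sorted({str(c) for c in self.chain_ids})

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i])

    def chain_atoms(self, chain: str) -> np.ndarray:
        """Indices of the atoms belonging to ``chain``."""
        idx = np.flatnonzero(np.array([str(c) for c in self.chain_ids]) == str(chain))
        if idx.size == 0:
            raise ParameterError(
                f"unknown chain id {chain!r}; known chains: {self.chains}"
            )
        return idx


@dataclass
class TimeSeries:
    """Uniformly sampled scalar observable X_0, X_1, …, X_N."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ParameterError("times and values must be one-dimensional")
        if len(self.times) != len(self.values):
            raise ParameterError(
                f"length mismatch: {len(self.times)} times vs {len(self.values)} values"
            )
        if len(self.times) < 2:
            raise ParameterError("a time series needs at least two samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ParameterError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12 * abs(steps[0])):
            raise ParameterError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MsdCurve:
    """Mean square displacement per lag; ``msd[0]`` is identically 0."""

    lags: np.ndarray
    msd: np.ndarray
    estimator: str = "fixed-origin"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if len(self.lags) != len(self.msd):
            raise ParameterError("lags and msd must have equal length")
        if np.any(self.msd < -1e-12):
            raise ParameterError("MSD values must be nonnegative")


def _resolve_selection(n_atoms: int, selection) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    sel = sel.astype(int)
    if sel.size == 0:
        raise ParameterError("selection must be nonempty")
    if sel.min() < 0 or sel.max() >= n_atoms:
        raise ParameterError(
            f"selection indices out of range for {n_atoms} atoms"
        )
    return sel


def center_of_mass(frame: Frame, selection=None, masses=None) -> np.ndarray:
    """Center of the selected atoms.

    Unweighted (atom-uniform) by default; pass per-atom ``masses`` for a
    mass-weighted center.
    """
    sel = _resolve_selection(frame.n_atoms, selection)
    pts = frame.coords[sel]
    if masses is None:
        return pts.mean(axis=0)
    w = np.asarray(masses, dtype=float)[sel]
    if np.any(w <= 0):
        raise ParameterError("masses must be positive")
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def radius_of_gyration(frame: Frame, selection=None) -> float:
    """Root-mean-square distance of the selected atoms from their center,
    Rg = sqrt((1/N) Σ_i |R_i − C|²)."""
    sel = _resolve_selection(frame.n_atoms, selection)
    pts = frame.coords[sel]
    c = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1))))


def rg_timeseries(traj: Trajectory, chain: str | None = None) -> TimeSeries:
    """Per-frame radius of gyration of one chain.

    With ``chain=None`` (or ``"average"``) returns the per-frame mean of Rg
    over all chains — the "average chain" curve.
    """
    if chain is None or chain == "average":
        per_chain = [
            [radius_of_gyration(traj.frame(i), traj.chain_atoms(c))
             for c in traj.chains]
            for i in range(traj.n_frames)
        ]
        values = np.mean(per_chain, axis=1)
        label = "Rg(average chain)"
    else:
        sel = traj.chain_atoms(chain)
        values = np.array(
            [radius_of_gyration(traj.frame(i), sel) for i in range(traj.n_frames)]
        )
        label = f"Rg(chain {chain})"
    times = np.arange(traj.n_frames) * traj.frame_dt
    return TimeSeries(times, values, label=label)


def msd_curve(
    traj: Trajectory,
    selection=None,
    max_lag: int | None = None,
    estimator: str = "fixed-origin",
) -> MsdCurve:
    """Atom-averaged mean square displacement over lags 0…max_lag.

    ``fixed-origin`` measures displacement from frame 0;
    ``time-averaged`` slides the origin over all admissible start frames.
    """
    if estimator not in ("fixed-origin", "time-averaged"):
        raise ParameterError(
            f"estimator must be 'fixed-origin' or 'time-averaged', got {estimator!r}"
        )
    sel = _resolve_selection(traj.n_atoms, selection)
    n = traj.n_frames
    if max_lag is None:
        max_lag = n - 1
    if not (0 <= max_lag < n):
        raise ParameterError(
            f"max_lag must satisfy 0 <= max_lag < n_frames ({n}), got {max_lag}"
        )
    x = traj.coords[:, sel, :]
    msd = np.zeros(max_lag + 1)
    if estimator == "fixed-origin":
        disp = x[: max_lag + 1] - x[0]
        msd = np.mean(np.sum(disp**2, axis=2), axis=1)
    else:
        for k in range(1, max_lag + 1):
            d = x[k:] - x[:-k]
            msd[k] = np.mean(np.sum(d**2, axis=2))
    lags = np.arange(max_lag + 1) * traj.frame_dt
    return MsdCurve(lags, msd, estimator=estimator)


def read_xyz_trajectory(path, chain_sidecar=None, frame_dt: float = 1.0) -> Trajectory:
    """Read a multi-frame XYZ file (re-exported from :mod:`anomdiff.io`)."""
    from .io import read_xyz_trajectory as _impl

    return _impl(path, chain_sidecar=chain_sidecar, frame_dt=frame_dt)
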