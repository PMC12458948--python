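"""Online similarity-matching network for low-dimensional population trajectories.

The network linearly projects each binned population activity vector x_t
(d_in units) to a low-dimensional output y_t (d_out) through a feedforward
matrix W, while a lateral inhibition matrix M keeps the output dimensions
competitive: y_t solves M y = W x.  Both matrices learn online with
Hebbian / anti-Hebbian rules,

    W <- W + eta (y x^T - W),      M <- M + eta (y y^T - M),

so W tracks <y x^T> and M tracks <y y^T>; at the fixed point the row space
of M^{-1} W spans the top-d_out principal subspace of the input
covariance.  Trajectories are optionally smoothed with a normalized
Gaussian kernel (truncated at +/-4 sigma, reflect-padded boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spikesight.ephys_features import NeuronRecord

#: Cell-type groups used for per-group population matrices: inhibitory
#: subtypes (SST and non-SST GABAergic) are pooled, matching the
#: limited-unit-count regime of chronic recordings.
TYPE_GROUPS = {
    "Pyramidal": ("Pyramidal",),
    "Inhibitory": ("SST", "GABA_nonSST"),
    "Juxtacellular": ("Juxtacellular",),
    "Unknown": ("Unknown", None),
}


@dataclass
class PopulationActivityMatrix:
    """Binned population activity: time x units counts (or rates)."""

    bin_times: np.ndarray
    counts: np.ndarray
    bin_width: float
    unit_ids: tuple = ()
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.bin_times.size:
            raise ValueError("counts must be (n_bins, n_units) aligned to bin_times")

    @property
    def n_units(self) -> int:
        return int(self.counts.shape[1])


@dataclass
class SMAState:
    """Similarity-matching network state: W (d_out x d_in), M (d_out x d_out)."""

    W: np.ndarray
    M: np.ndarray
    learning_rate: float = 1e-3
    decay: bool = False  # True -> eta_t = eta / (1 + t)
    step_count: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        d_out, d_in = self.W.shape
        if self.M.shape != (d_out, d_out):
            raise ValueError("M must be d_out x d_out")
        if d_out > d_in:
            raise ValueError("d_out must not exceed d_in")
        if not np.allclose(self.M, self.M.T):
            raise ValueError("M must be symmetric")
        if np.any(np.diag(self.M) <= 0):
            raise ValueError("M must have a strictly positive diagonal")

    @property
    def d_out(self) -> int:
        return int(self.W.shape[0])

    @property
    def d_in(self) -> int:
        return int(self.W.shape[1])

    def eta(self) -> float:
        if self.decay:
            return self.learning_rate / (1.0 + self.step_count)
        return self.learning_rate

    def forward_map(self) -> np.ndarray:
        """The effective linear map M^{-1} W."""
        return np.linalg.solve(self.M, self.W)

    @classmethod
    def initialize(
        cls, d_in: int, d_out: int, seed: int = 0, learning_rate: float = 1e-3,
        decay: bool = False,
    ) -> "SMAState":
        """Small seeded Gaussian W; M = identity (solvable from step 0)."""
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((d_out, d_in)) * 0.1 / np.sqrt(d_in)
        return cls(W=W, M=np.eye(d_out), learning_rate=learning_rate, decay=decay)


@dataclass
class TrajectorySegment:
    """Low-dimensional population trajectory over time."""

    times: np.ndarray
    coords: np.ndarray
    smoothing_sigma: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[0] != self.times.size:
            raise ValueError("coords rows must align with times")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")


def sma_step(state: SMAState, x: np.ndarray) -> np.ndarray:
    """One online similarity-matching update (in place); returns the output y.

    Solves the lateral system M y = W x, then applies the Hebbian updates
    with the current learning rate; M stays symmetric with positive
    diagonal.  ``eta = 0`` leaves the state exactly unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (state.d_in,):
        raise ValueError("input length must equal d_in")
    if not np.all(np.isfinite(x)):
        raise ValueError("invalid input: non-finite activity vector")
    try:
        y = np.linalg.solve(state.M, state.W @ x)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"lateral degeneracy: M singular at step {state.step_count}") from exc
    eta = state.eta()
    if eta != 0.0:
        state.W += eta * (np.outer(y, x) - state.W)
        M_new = state.M + eta * (np.outer(y, y) - state.M)
        state.M = 0.5 * (M_new + M_new.T)
        if np.any(np.diag(state.M) <= 0):
            raise RuntimeError("lateral degeneracy: non-positive diagonal in M")
    state.step_count += 1
    return y


def run_sma(
    activity: PopulationActivityMatrix,
    d_out: int = 3,
    learning_rate: float = 1e-3,
    decay: bool = False,
    seed: int = 0,
    n_passes: int = 1,
    state: SMAState | None = None,
    center: bool = True,
) -> tuple[TrajectorySegment, SMAState]:
    """Run the online network over the activity matrix row by row.

    Column means are subtracted first (``center=True``), so the network
    tracks the principal subspace of the activity *covariance* rather than
    the mean-rate direction that dominates raw spike counts.  With
    ``n_passes > 1`` the matrix is replayed to let the subspace converge;
    the returned trajectory is from the final pass, unsmoothed.
    """
    if d_out > activity.n_units:
        raise ValueError("dimension error: d_out exceeds n_units")
    if activity.counts.shape[0] < 1:
        raise ValueError("need >= 1 time bin")
    if state is None:
        state = SMAState.initialize(
            activity.n_units, d_out, seed=seed, learning_rate=learning_rate, decay=decay
        )
    data = activity.counts
    if center:
        data = data - data.mean(axis=0)
    coords = np.empty((data.shape[0], state.d_out))
    for _ in range(max(1, n_passes)):
        for t, x in enumerate(data):
            coords[t] = sma_step(state, x)
    traj = TrajectorySegment(
        times=activity.bin_times,
        coords=coords,
        smoothing_sigma=None,
        provenance=f"sma:d_out={d_out}:seed={seed}:steps={state.step_count}",
    )
    return traj, state


def gaussian_kernel(sigma_bins: float) -> np.ndarray:
    """Discrete Gaussian kernel, truncated at +/-4 sigma, normalized to sum 1."""
    if sigma_bins <= 0:
        return np.ones(1)
    half = int(np.ceil(4 * sigma_bins))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma_bins) ** 2)
    return k / k.sum()


def smooth_trajectory(traj: TrajectorySegment, sigma_s: float) -> TrajectorySegment:
    """Gaussian-smooth each output dimension over time (reflect padding)."""
    if sigma_s < 0:
        raise ValueError("sigma_s must be >= 0")
    if sigma_s == 0 or traj.times.size < 2:
        return TrajectorySegment(traj.times, traj.coords.copy(), 0.0, traj.provenance)
    dt = np.diff(traj.times)
    if not np.allclose(dt, dt[0]):
        raise ValueError("resample required: non-uniform bin spacing")
    kernel = gaussian_kernel(sigma_s / dt[0])
    half = kernel.size // 2
    out = np.empty_like(traj.coords)
    for d in range(traj.coords.shape[1]):
        padded = np.pad(traj.coords[:, d], half, mode="reflect")
        out[:, d] = np.convolve(padded, kernel, mode="valid")
    return TrajectorySegment(traj.times, out, sigma_s, traj.provenance)


def bin_population_activity(
    records: list[NeuronRecord], bin_width_s: float = 0.1, group_by_type: bool = True
) -> dict:
    """Bin unit spike trains into per-cell-type-group activity matrices.

    Groups pool inhibitory subtypes (SST with non-SST GABAergic); with
    ``group_by_type=False`` all units land in a single ``"all"`` group.
    Counts cover ``[0, duration)`` with half-open bins.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    if not records:
        return {}
    duration = max(r.spike_train.duration for r in records)
    n_bins = int(np.ceil(duration / bin_width_s))
    edges = np.arange(n_bins + 1) * bin_width_s
    bin_times = edges[:-1] + bin_width_s / 2

    def group_of(label):
        if not group_by_type:
            return "all"
        for g, members in TYPE_GROUPS.items():
            if label in members:
                return g
        return "Unknown"

    grouped: dict = {}
    for r in records:
        grouped.setdefault(group_of(r.label), []).append(r)
    matrices = {}
    for g, members in grouped.items():
        counts = np.zeros((n_bins, len(members)))
        for j, r in enumerate(members):
            t = r.spike_train.spike_times
            t = t[(t >= 0) & (t < n_bins * bin_width_s)]
            idx = np.floor(t / bin_width_s).astype(int)
            counts[:, j] = np.bincount(idx, minlength=n_bins)
        matrices[g] = PopulationActivityMatrix(
            bin_times=bin_times,
            counts=counts,
            bin_width=bin_width_s,
            unit_ids=tuple(r.unit_id for r in members),
            labels=tuple(r.label for r in members),
        )
    return matrices


def subspace_alignment_error(state: SMAState, activity: np.ndarray) -> float:
    """Distance in [0, 1] between the learned subspace and the PCA subspace.

    Compares the row space of the effective map M^{-1} W against the
    top-d_out principal subspace of the activity covariance:
    ``1 - ||U^T V||_F^2 / d_out`` with U, V orthonormal bases.  0 means
    identical subspaces, 1 means orthogonal.
    """
    X = np.asarray(activity, dtype=float)
    if X.ndim != 2 or X.shape[1] != state.d_in:
        raise ValueError("activity must be (n_samples, d_in)")
    F = state.forward_map()
    # orthonormal basis of the learned row space
    q, r = np.linalg.qr(F.T)
    if np.linalg.matrix_rank(F) < state.d_out:
        raise ValueError("degenerate state: forward map is rank-deficient")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / max(1, X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    U = evecs[:, ::-1][:, : state.d_out]
    overlap = np.linalg.norm(U.T @ q, ord="fro") ** 2 / state.d_out
    return float(np.clip(1.0 - overlap, 0.0, 1.0))
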