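"""Canonical Langevin dynamics of the coarse-grained chain.

The dynamical particles are the anchor points; site, head and tail positions
are rigid functions of the anchors and their force contributions are folded
into the anchor forces analytically.  The integrator is the BAOAB splitting
of Langevin dynamics (half-kick, half-drift, Ornstein–Uhlenbeck velocity
update, half-drift, half-kick), which reduces to symplectic velocity-Verlet
when the friction is zero and gives accurate configurational averages at
large time steps.

Internal units: Å, fs, amu, kcal/mol.  The default time step of 4.89 fs and
the default run length of 2,000,000 steps are the production protocol; note
that coarse-grained effective time runs faster than nominal time (the full
protocol corresponds to roughly a microsecond of real time), so reported
times are nominal integration times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .errors import ConfigurationError, SimulationBlowupError
from .params import CGParameters, K_B, Weights
from .topology import HeparinChain, chain_from_anchors

logger = logging.getLogger(__name__)

#: Production defaults: 4.89 fs step, 2,000,000 steps.
DEFAULT_DT_FS = 4.89
DEFAULT_N_STEPS = 2_000_000


@dataclass
class RunConfig:
    """Configuration of one Langevin run.

    friction is in 1/ps; snapshot_stride in steps.  ``weights`` and ``kappa``
    override the corresponding entries of the force-field parameters for this
    run (the calibration sweep varies exactly these two).
    """

    n_steps: int = DEFAULT_N_STEPS
    dt: float = DEFAULT_DT_FS
    temperature: float = 300.0
    friction: float = 1.0
    seed: int = 0
    snapshot_stride: int = 1000
    weights: Weights | None = None
    kappa: float | None = None
    remove_com: bool = True

    def __post_init__(self):
        if self.n_steps < 1:
            raise ConfigurationError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if self.friction < 0:
            raise ConfigurationError(f"friction must be >= 0, got {self.friction}")
        if self.snapshot_stride < 1:
            raise ConfigurationError("snapshot_stride must be >= 1")
        if self.temperature <= 0:
            raise ConfigurationError(f"temperature must be > 0, got {self.temperature}")

    def to_dict(self) -> dict:
        d = {
            "n_steps": self.n_steps,
            "dt": self.dt,
            "temperature": self.temperature,
            "friction": self.friction,
            "seed": self.seed,
            "snapshot_stride": self.snapshot_stride,
            "remove_com": self.remove_com,
            "kappa": self.kappa,
        }
        if self.weights is not None:
            d["weights"] = {
                k: getattr(self.weights, k) for k in Weights.__dataclass_fields__
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        w = d.pop("weights", None)
        cfg = cls(**d)
        if w is not None:
            cfg = replace(cfg, weights=Weights(**w))
        return cfg


@dataclass
class Trajectory:
    """Snapshots of one run: anchor coordinates, times and energy series."""

    frames: np.ndarray           # (n_frames, n_anchors, 3), Å
    times: np.ndarray            # (n_frames,), fs (nominal integration time)
    config: RunConfig
    potential: np.ndarray        # weighted total potential energy per frame
    kinetic: np.ndarray          # kinetic energy per frame, kcal/mol

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential + self.kinetic

    def kinetic_temperature(self) -> np.ndarray:
        """Instantaneous kinetic temperature per frame, K.

        Uses 3N − 3 degrees of freedom (center-of-mass motion is removed
        during the run).
        """
        ndof = 3 * self.frames.shape[1] - 3
        return 2.0 * self.kinetic / (K_B * ndof)

    def chain(self, index: int, params: CGParameters) -> HeparinChain:
        return chain_from_anchors(self.frames[index], params)


@dataclass
class SimState:
    """Instantaneous integrator state for the single-step API."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    forces: np.ndarray = field(default=None)  # kcal/mol/Å at ``positions``


def _effective_params(params: CGParameters, config: RunConfig) -> CGParameters:
    kwargs = {"T": config.temperature}
    if config.kappa is not None:
        kwargs["kappa"] = config.kappa
    p = params.replace(**kwargs)
    if config.weights is not None:
        p = p.replace(weights=config.weights)
    return p


def langevin_step(state: SimState, force_fn, config: RunConfig, rng: np.random.Generator) -> SimState:
    """Advance one BAOAB step.

    ``force_fn(positions) -> forces`` supplies forces in kcal/mol/Å;
    ``state.forces`` must hold the forces at the current positions (computed
    on first call if absent).  With ``config.friction == 0`` the update is
    deterministic velocity-Verlet (``rng`` unused).
    """
    x = state.positions.copy()
    v = state.velocities.copy()
    m = state.masses[:, None]
    dt = config.dt
    f = state.forces
    if f is None:
        f = force_fn(x)
    if not np.all(np.isfinite(f)):
        raise SimulationBlowupError("non-finite force", last_good_frame=state.positions)

    v = v + 0.5 * dt * _kernel.FCONV * f / m
    x = x + 0.5 * dt * v
    gamma_fs = config.friction * 1e-3
    if gamma_fs > 0.0:
        c1 = math.exp(-gamma_fs * dt)
        c2 = math.sqrt(1.0 - c1 * c1)
        vs = np.sqrt(K_B * config.temperature * _kernel.FCONV / state.masses)[:, None]
        v = c1 * v + c2 * vs * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    f_new = force_fn(x)
    v = v + 0.5 * dt * _kernel.FCONV * f_new / m
    return SimState(positions=x, velocities=v, masses=state.masses, forces=f_new)


def run_simulation(
    chain: HeparinChain,
    params: CGParameters,
    config: RunConfig,
    velocities: np.ndarray | None = None,
) -> Trajectory:
    """Run unrestrained Langevin dynamics and return the trajectory.

    Starts from the chain's current anchor coordinates, at rest unless
    initial ``velocities`` are given.  Snapshots (including frame 0) are
    recorded every ``config.snapshot_stride`` steps; center-of-mass velocity
    is removed at every snapshot.  Per-block energy statistics are emitted on
    the module logger.
    """
    p = _effective_params(params, config)
    anchors = np.ascontiguousarray(chain.anchors, dtype=np.float64)
    n = anchors.shape[0]
    v0 = np.zeros_like(anchors) if velocities is None else np.asarray(velocities, float)
    masses = np.full(n, p.site_mass)
    wf = p.weights.as_array() * p.fn_array()
    frames, epot, ekin, fail_step = _kernel.integrate(
        anchors,
        v0,
        masses,
        chain.charges,
        p.site_born_radii(chain.dp),
        p.kernel_vector(),
        wf,
        float(config.dt),
        float(config.friction) * 1e-3,
        K_B * config.temperature,
        int(config.n_steps),
        int(config.snapshot_stride),
        int(config.seed),
        config.remove_com,
    )
    if fail_step >= 0:
        raise SimulationBlowupError(
            f"simulation blew up at step {fail_step} "
            f"(non-finite coordinates or forces)",
            last_good_frame=frames[-1] if len(frames) else None,
            step=fail_step,
        )
    times = np.arange(frames.shape[0]) * config.snapshot_stride * config.dt
    traj = Trajectory(frames=frames, times=times, config=config, potential=epot, kinetic=ekin)
    n_blocks = min(10, traj.n_frames)
    if n_blocks > 1:
        for block in np.array_split(np.arange(traj.n_frames), n_blocks):
            logger.info(
                "block %d-%d: <U> = %.3f kcal/mol, <T_kin> = %.1f K",
                block[0],
                block[-1],
                float(epot[block].mean()),
                float(traj.kinetic_temperature()[block].mean()),
            )
    return traj
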