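"""Euler–Maruyama integration of the overdamped Langevin equation and
first-passage detection.

The particle obeys ``zeta dx/dt = F(x) + xi(t)`` with Gaussian white
noise of variance ``2 zeta T``; using the Einstein relation
``D = T/zeta`` the discrete update is

    x' = x + (F(x)/zeta) dt + sqrt(2 D dt) z,   z ~ N(0, 1).

A trajectory starts at ``x_start`` (default: the pre-synaptic membrane,
x = 0) and is absorbed the first time it reaches ``x >= d``.  Runs not
absorbed by ``t_max`` are censored: counted, excluded from the sample,
and reported.

Randomness contract: every (member, run) pair owns an independent
substream derived from the master seed via ``numpy``'s SeedSequence
spawn keys, so results are bit-identical regardless of internal chunk
size, and the two members of a pair are driven by independent noise
unless the shared-noise test hook is engaged.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .forces import drift_force, wall_force
from .params import CleftParams, SimConfig, WallParams

__all__ = [
    "FPTSample",
    "PairedResult",
    "em_step",
    "simulate_fpt",
    "simulate_paired",
    "sample_trajectory",
    "occupancy_below",
]

logger = logging.getLogger(__name__)

# chunk of runs advanced together / noise block length (steps); these
# trade python-loop overhead against memory and have no effect on results
_RUN_CHUNK = 16384
_NOISE_BLOCK = 160

#: censored fraction above which a warning is logged
_CENSOR_WARN_FRACTION = 1e-3


def _fingerprint(p: CleftParams, w: WallParams, cfg: SimConfig) -> str:
    return hashlib.sha1(repr((p, w, cfg)).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FPTSample:
    """A batch of first-passage times from one cleft.

    ``times_by_run`` holds one entry per run in run order, NaN where the
    run was censored; ``times`` is the uncensored subset.
    """

    times_by_run: np.ndarray
    n_runs: int
    params_fingerprint: str
    n_censored: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "n_censored", int(np.count_nonzero(~np.isfinite(self.times_by_run)))
        )

    @property
    def times(self) -> np.ndarray:
        return self.times_by_run[np.isfinite(self.times_by_run)]

    @property
    def mean(self) -> float:
        return float(np.mean(self.times))


@dataclass(frozen=True)
class PairedResult:
    """Difference of first-passage times for simultaneously released pairs.

    ``delta_times`` collects ``t1 - t2`` over pairs in which both members
    were absorbed; pairs with either member censored are excluded and
    counted in ``n_pairs_censored``.
    """

    delta_times: np.ndarray
    t1: FPTSample
    t2: FPTSample
    n_runs: int

    @property
    def n_pairs_censored(self) -> int:
        return self.n_runs - len(self.delta_times)

    @property
    def summary(self) -> tuple[float, float, float]:
        """(mean, std, skewness) of the ΔT sample; std uses the unbiased
        sample variance, skewness is the plain third standardized moment."""
        d = self.delta_times
        return (
            float(np.mean(d)),
            float(np.std(d, ddof=1)),
            float(stats.skew(d, bias=True)),
        )


def em_step(x, p: CleftParams, w: WallParams, dt: float, z):
    """One Euler–Maruyama update; ``x`` and ``z`` may be arrays."""
    x = np.asarray(x, dtype=float)
    f = drift_force(p) + wall_force(x, w)
    return x + (f / p.zeta) * dt + np.sqrt(2.0 * p.D * dt) * np.asarray(z, float)


def _member_generators(seed: int, member: int, run_ids: np.ndarray):
    return [
        np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(member, int(i))))
        )
        for i in run_ids
    ]


def _simulate_member(
    p: CleftParams,
    w: WallParams,
    cfg: SimConfig,
    member: int,
    track_below: float | None = None,
) -> tuple[np.ndarray, int, int]:
    """Integrate ``cfg.n_runs`` trajectories for one pair member.

    Returns ``(times_by_run, steps_below, steps_total)``; the last two
    are occupancy counters for positions below ``track_below`` (0 when
    tracking is off).
    """
    cfg.validate_against(p)
    dt = cfg.dt
    max_steps = int(np.ceil(cfg.t_max / dt))
    drift_step = (drift_force(p) / p.zeta) * dt
    wall_scale = dt / p.zeta
    sigma = np.sqrt(2.0 * p.D * dt)
    wall_on = w.variant != "off"
    d = p.d

    times = np.full(cfg.n_runs, np.nan)
    below = 0
    total = 0

    for lo in range(0, cfg.n_runs, _RUN_CHUNK):
        hi = min(lo + _RUN_CHUNK, cfg.n_runs)
        run_ids = np.arange(lo, hi)
        gens = _member_generators(cfg.seed, member, run_ids)
        x = np.full(hi - lo, cfg.x_start, dtype=float)
        active = np.arange(hi - lo)
        step = 0
        while active.size and step < max_steps:
            m = min(_NOISE_BLOCK, max_steps - step)
            z = np.empty((active.size, m))
            for k, a in enumerate(active):
                z[k] = gens[a].standard_normal(m)
            for j in range(m):
                if wall_on:
                    fw = wall_force(x, w)
                    x_new = x + drift_step + fw * wall_scale + sigma * z[:, j]
                else:
                    x_new = x + drift_step + sigma * z[:, j]
                if not np.all(np.isfinite(x_new)):
                    bad = run_ids[active[~np.isfinite(x_new)]]
                    raise FloatingPointError(
                        f"non-finite position at step {step + j + 1} "
                        f"for runs {bad[:5].tolist()}; check dt and force parameters"
                    )
                crossed = x_new >= d
                if crossed.any():
                    t_end = (step + j + 1) * dt
                    if cfg.interpolate_crossing:
                        frac = (d - x[crossed]) / (x_new[crossed] - x[crossed])
                        times[run_ids[active[crossed]]] = t_end - dt + dt * frac
                    else:
                        times[run_ids[active[crossed]]] = t_end
                    keep = ~crossed
                    x = x_new[keep]
                    active = active[keep]
                    z = z[keep]
                    if active.size == 0:
                        break
                else:
                    x = x_new
                if track_below is not None:
                    below += int(np.count_nonzero(x < track_below))
                    total += x.size
            step += m
        # runs still active here are censored (times stay NaN)
    if track_below is None:
        total = 0
    return times, below, total


def simulate_fpt(p: CleftParams, w: WallParams, cfg: SimConfig, member: int = 0) -> FPTSample:
    """Simulate ``cfg.n_runs`` independent first-passage times for one cleft."""
    times, _, _ = _simulate_member(p, w, cfg, member)
    sample = FPTSample(times_by_run=times, n_runs=cfg.n_runs,
                       params_fingerprint=_fingerprint(p, w, cfg))
    frac = sample.n_censored / cfg.n_runs
    if frac > 0.5:
        logger.warning("t_max=%g s exceeded for %.0f%% of runs", cfg.t_max, 100 * frac)
    elif frac > _CENSOR_WARN_FRACTION:
        logger.warning("censored fraction %.2e exceeds %.0e", frac, _CENSOR_WARN_FRACTION)
    return sample


def simulate_paired(
    p1: CleftParams,
    p2: CleftParams,
    w1: WallParams,
    w2: WallParams,
    cfg: SimConfig,
    shared_noise: bool = False,
) -> PairedResult:
    """Simulate paired releases and return the ΔT = t1 - t2 sample.

    The two members use independent noise substreams (members 0 and 1 of
    the master seed).  ``shared_noise=True`` drives both members with the
    same stream — a test hook: identical clefts then yield ΔT ≡ 0.
    """
    s1 = simulate_fpt(p1, w1, cfg, member=0)
    s2 = simulate_fpt(p2, w2, cfg, member=0 if shared_noise else 1)
    both = np.isfinite(s1.times_by_run) & np.isfinite(s2.times_by_run)
    delta = s1.times_by_run[both] - s2.times_by_run[both]
    return PairedResult(delta_times=delta, t1=s1, t2=s2, n_runs=cfg.n_runs)


def sample_trajectory(
    p: CleftParams, w: WallParams, cfg: SimConfig, run: int = 0, member: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a single run, returning ``(t, x)`` up to absorption or t_max.

    Uses the same substream as run ``run`` of :func:`simulate_fpt`, so the
    returned path is the one that produced that run's recorded time.
    """
    cfg.validate_against(p)
    gen = _member_generators(cfg.seed, member, np.array([run]))[0]
    dt = cfg.dt
    max_steps = int(np.ceil(cfg.t_max / dt))
    xs = [cfg.x_start]
    x = cfg.x_start
    for step in range(max_steps):
        if step % _NOISE_BLOCK == 0:
            z = gen.standard_normal(min(_NOISE_BLOCK, max_steps - step))
        x = float(em_step(x, p, w, dt, z[step % _NOISE_BLOCK]))
        xs.append(x)
        if x >= p.d:
            break
    ts = np.arange(len(xs)) * dt
    return ts, np.asarray(xs)


def occupancy_below(
    p: CleftParams, w: WallParams, cfg: SimConfig, threshold: float, member: int = 0
) -> float:
    """Fraction of all simulated trajectory steps spent at x < ``threshold``.

    Measures how effectively the soft wall confines the particle to the
    cleft: with the wall on, time spent well behind the pre-synaptic
    membrane should be a small fraction of the transit time.
    """
    _, below, total = _simulate_member(p, w, cfg, member, track_below=threshold)
    return below / total if total else 0.0
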