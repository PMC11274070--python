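"""Parameter containers, validation and unit handling.

Everything downstream of this module works in SI units. Values in the
field's customary units (nm, um^2/ms, mV, ns, ...) are converted exactly
once, at the config/CLI boundary, through :func:`to_si`.

The thermal energy ``T`` is stored as an energy (J), i.e. k_B times the
absolute temperature: with that convention the Einstein relation reads
``D = T / zeta`` and the noise variance is ``2 zeta T``.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from .constants import (
    D_CLEFT,
    D_DIFF,
    DT,
    E_CHARGE,
    F_MAX,
    K_B,
    N_RUNS,
    T_BODY_K,
    T_MAX,
    V_CLEFT,
    WALL_LC,
    WALL_X0,
)

__all__ = [
    "CleftParams",
    "WallParams",
    "SimConfig",
    "make_cleft_params",
    "to_si",
    "load_config",
    "default_cleft",
    "default_wall",
    "default_sim",
]

# Exact power-of-ten factors to SI.  Both the Greek and the ASCII
# spelling of micro are accepted.
_UNIT_FACTORS = {
    "m": 1.0,
    "nm": 1e-9,
    "um": 1e-6,
    "μm": 1e-6,
    "s": 1.0,
    "ns": 1e-9,
    "us": 1e-6,
    "μs": 1e-6,
    "ms": 1e-3,
    "V": 1.0,
    "mV": 1e-3,
    "N": 1.0,
    "m²/s": 1.0,
    "m2/s": 1.0,
    "um2/ms": 1e-9,
    "μm²/ms": 1e-9,
    "um²/ms": 1e-9,
    "μm2/ms": 1e-9,
}


def to_si(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to the SI equivalent.

    Conversions are exact powers of ten, so round-tripping through
    :func:`to_si` and its inverse factor loses no precision.

    Raises
    ------
    ValueError
        If the unit name is not recognised; the message lists the
        supported names.
    """
    try:
        factor = _UNIT_FACTORS[unit]
    except KeyError:
        supported = ", ".join(sorted(set(_UNIT_FACTORS)))
        raise ValueError(
            f"unknown unit {unit!r}; supported units: {supported}"
        ) from None
    return value * factor


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class CleftParams:
    """Physical description of one synaptic cleft (SI units).

    Parameters
    ----------
    d : float
        Cleft width (m); the absorbing boundary sits at ``x = d``.
    D : float
        Diffusion coefficient of the neurotransmitter (m^2/s).
    V : float
        Trans-cleft voltage (V); negative under physiological conditions.
    T : float
        Thermal energy k_B * temperature (J).
    q : float
        Carrier charge (C); glutamate carries ``-e``.

    Derived attributes
    ------------------
    zeta : float
        Drag coefficient ``T / D`` (kg/s), from the Einstein relation.
    v_drift : float
        Drift velocity ``(q V / d) / zeta`` (m/s); for glutamate
        (q = -e) under negative V this is ``e|V|/(zeta d) > 0``, toward
        the post-synaptic membrane.
    """

    d: float
    D: float
    V: float
    T: float
    q: float = -E_CHARGE
    zeta: float = field(init=False)
    v_drift: float = field(init=False)

    def __post_init__(self) -> None:
        _require_positive("d", self.d)
        _require_positive("D", self.D)
        _require_positive("T", self.T)
        if not math.isfinite(self.V):
            raise ValueError(f"V must be finite, got {self.V!r}")
        object.__setattr__(self, "zeta", self.T / self.D)
        object.__setattr__(self, "v_drift", (self.q * self.V / self.d) / self.zeta)

    @property
    def drift_force(self) -> float:
        """Constant electrostatic force ``q V / d`` (N); for glutamate
        this is ``-e V / d``, positive under negative V."""
        return self.q * self.V / self.d


WallVariant = Literal["anti_return", "literal", "zero_offset", "off"]


@dataclass(frozen=True)
class WallParams:
    """Soft-wall force parameters (SI units).

    ``variant`` selects the algebraic form: ``anti_return`` (default)
    is the magnitude of the two-bump field, always directed toward the
    post-synaptic side; ``zero_offset`` is the signed (odd) difference
    of the two sech^2 bumps; ``literal`` keeps the additional constant
    ``-F_max`` offset; ``off`` disables the wall.  See
    :mod:`cleftsim.forces` for why ``anti_return`` is the default.
    """

    F_max: float = F_MAX
    x0: float = WALL_X0
    lC: float = WALL_LC
    variant: WallVariant = "anti_return"

    def __post_init__(self) -> None:
        if not math.isfinite(self.F_max) or self.F_max < 0:
            raise ValueError(f"F_max must be finite and >= 0, got {self.F_max!r}")
        _require_positive("x0", self.x0)
        if self.lC == 0 or not math.isfinite(self.lC):
            raise ValueError(f"lC must be finite and nonzero, got {self.lC!r}")
        if self.variant not in ("anti_return", "literal", "zero_offset", "off"):
            raise ValueError(f"unknown wall variant {self.variant!r}")


@dataclass(frozen=True)
class SimConfig:
    """Numerical protocol for the Euler–Maruyama integration.

    ``t_max`` is the censoring horizon: runs not absorbed by then are
    counted, reported, and excluded from the first-passage sample.
    ``interpolate_crossing`` linearly interpolates the boundary-crossing
    time within the final step instead of recording the step-end time.
    """

    dt: float = DT
    n_runs: int = N_RUNS
    t_max: float = T_MAX
    x_start: float = 0.0
    interpolate_crossing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        _require_positive("dt", self.dt)
        if self.n_runs < 1:
            raise ValueError(f"n_runs must be >= 1, got {self.n_runs!r}")
        if self.t_max < self.dt:
            raise ValueError("t_max must be >= dt")
        if not math.isfinite(self.x_start):
            raise ValueError("x_start must be finite")

    def validate_against(self, cleft: CleftParams) -> None:
        if not (0 <= self.x_start < cleft.d):
            raise ValueError(
                f"x_start must lie in [0, d), got {self.x_start!r} with d={cleft.d!r}"
            )


def make_cleft_params(
    d: float = D_CLEFT,
    D: float = D_DIFF,
    V: float = V_CLEFT,
    T: float = K_B * T_BODY_K,
) -> CleftParams:
    """Build a validated :class:`CleftParams` from SI-valued inputs.

    The drag coefficient and drift velocity are derived here and nowhere
    else: ``zeta = T/D`` and ``v_drift = e|V|/(zeta d)`` for negative V.
    """
    return CleftParams(d=d, D=D, V=V, T=T)


def default_cleft() -> CleftParams:
    """Physiological cleft: d=20 nm, D=0.33 um^2/ms, V=-4 mV, T=k_B·310 K."""
    return make_cleft_params()


def default_wall() -> WallParams:
    return WallParams()


def default_sim(**overrides) -> SimConfig:
    return SimConfig(**overrides)


def load_config(path: str | Path):
    """Read a TOML config and return ``(cleft1, cleft2, wall, sim)``.

    Expected sections/keys (units encoded in the key names)::

        [cleft1]           # and [cleft2]; cleft2 falls back to cleft1
        d_nm = 20.0
        D_um2_per_ms = 0.33
        V_mV = -4.0
        T_kelvin = 310.0

        [wall]
        Fmax_N = 9.6e-12
        x0_m = 2e-9
        lC_m = -3e-10
        wall_variant = "anti_return"

        [sim]
        dt_ns = 10.0
        n_runs = 50000
        t_max_ms = 5.0
        x_start_nm = 0.0
        interpolate_crossing = false
        seed = 0
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    def cleft_from(section: dict) -> CleftParams:
        return make_cleft_params(
            d=to_si(section.get("d_nm", 20.0), "nm"),
            D=to_si(section.get("D_um2_per_ms", 0.33), "um2/ms"),
            V=to_si(section.get("V_mV", -4.0), "mV"),
            T=K_B * section.get("T_kelvin", T_BODY_K),
        )

    c1_raw = raw.get("cleft1", {})
    cleft1 = cleft_from(c1_raw)
    cleft2 = cleft_from(raw.get("cleft2", c1_raw))

    w = raw.get("wall", {})
    wall = WallParams(
        F_max=w.get("Fmax_N", F_MAX),
        x0=w.get("x0_m", WALL_X0),
        lC=w.get("lC_m", WALL_LC),
        variant=w.get("wall_variant", "anti_return"),
    )

    s = raw.get("sim", {})
    sim = SimConfig(
        dt=to_si(s.get("dt_ns", 10.0), "ns"),
        n_runs=int(s.get("n_runs", N_RUNS)),
        t_max=to_si(s.get("t_max_ms", 5.0), "ms"),
        x_start=to_si(s.get("x_start_nm", 0.0), "nm"),
        interpolate_crossing=bool(s.get("interpolate_crossing", False)),
        seed=int(s.get("seed", 0)),
    )
    sim.validate_against(cleft1)
    sim.validate_against(cleft2)
    return cleft1, cleft2, wall, sim
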