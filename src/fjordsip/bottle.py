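"""Oxygen budget of a static incubation bottle.

A 1-L bottle with an air headspace holds an unstirred water column in which
dissolved O2 obeys a one-dimensional diffusion-respiration balance,

    dC/dt = D d2C/dz2 - R,

with the air-water interface pinned at the air-equilibrium concentration
(Dirichlet), a no-flux bottom, zero-order volumetric respiration R that
switches off wherever C = 0, and molecular diffusivity D (no turbulence:
the incubations are static).  Two questions are answered: when does an
isolated water parcel go anoxic (closed form, no diffusion), and what
fraction of the column volume stays below a hypoxia threshold over the
incubation (finite-difference solve).

Units: depth cm, time h, concentration uM; respiration is given in the
field-survey unit nmol O2 L^-1 h^-1 (= 1e-3 uM/h) and converted internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BottleModelParams",
    "OxygenProfile",
    "depletion_time",
    "simulate_bottle",
    "hypoxic_volume_fraction",
    "o2_saturation",
]

HYPOXIA_THRESHOLD_UM = 63.0
SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class BottleModelParams:
    """Geometry, transport and sink parameters of the bottle model.

    Defaults describe a 1-L bottle of cold hypoxic fjord water: a 12 cm
    column (1 L minus ~160 mL headspace in a 9-10 cm diameter bottle),
    initial O2 14 uM, air-equilibrium boundary 350 uM (~4-5 C, salinity
    ~19), molecular diffusivity 1.3e-5 cm2/s, respiration up to
    400 nmol O2 L^-1 h^-1.  ``headspace_ml`` is documentation only — the
    headspace O2 pool is treated as unlimited.
    """

    column_height: float = 12.0        # cm
    initial_o2: float = 14.0           # uM
    surface_o2: float = 350.0          # uM, air-equilibrium at the interface
    diffusivity: float = 1.3e-5        # cm^2/s
    respiration: float = 400.0         # nmol O2 L^-1 h^-1
    hypoxia_threshold: float = HYPOXIA_THRESHOLD_UM  # uM
    duration: float = 48.0             # h
    grid_dz: float = 0.1               # cm
    headspace_ml: float = 160.0        # mL, not used in the solve

    def __post_init__(self) -> None:
        for name in (
            "column_height", "initial_o2", "surface_o2", "diffusivity",
            "respiration", "hypoxia_threshold", "duration", "grid_dz",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.column_height <= 0 or self.grid_dz <= 0:
            raise ValueError("column_height and grid_dz must be positive")
        if self.grid_dz >= self.column_height / 10:
            raise ValueError("grid_dz must resolve the column (< height/10)")
        if self.respiration > 1e4:
            raise ValueError("respiration outside the sane band [0, 1e4]")


@dataclass(frozen=True)
class OxygenProfile:
    """C(z, t) on the solver grid: times in h, depths in cm, O2 in uM."""

    times: np.ndarray
    depths: np.ndarray
    concentration: np.ndarray  # shape (n_times, n_depths)
    params: BottleModelParams

    def at_time(self, t: float) -> np.ndarray:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(
                f"t = {t} h outside simulated range "
                f"[{self.times[0]}, {self.times[-1]}] h"
            )
        # linear interpolation between stored snapshots, per depth node
        out = np.empty_like(self.depths)
        for j in range(self.depths.size):
            out[j] = np.interp(t, self.times, self.concentration[:, j])
        return out


def depletion_time(initial_o2: float, respiration: float) -> float:
    """Hours until an isolated parcel is anoxic under zero-order respiration.

    ``t = 1000 * initial_o2 / respiration`` converts uM to nmol/L; with no
    respiration the parcel never depletes (returns ``inf``).
    """
    if initial_o2 < 0 or respiration < 0:
        raise ValueError("initial_o2 and respiration must be non-negative")
    if respiration == 0:
        return float("inf")
    return 1000.0 * initial_o2 / respiration


def simulate_bottle(
    p: BottleModelParams, dt: float | None = None, n_snapshots: int = 97
) -> OxygenProfile:
    """Explicit finite-difference solve of the diffusion-respiration PDE.

    The top node is held at ``surface_o2`` for t > 0, the bottom boundary is
    no-flux (mirrored ghost node), and concentrations are clamped at zero
    with respiration suppressed on depleted nodes.  The time step honours
    the explicit stability bound ``D dt / dz^2 <= 0.5`` (an unstable request
    is refined with a warning).
    """
    d_h = p.diffusivity * SECONDS_PER_HOUR       # cm^2/h
    r_h = p.respiration * 1e-3                   # uM/h
    dz = p.grid_dz
    stable = 0.4 * dz**2 / d_h if d_h > 0 else p.duration / 100
    if dt is None:
        dt = stable
    elif d_h > 0 and d_h * dt / dz**2 > 0.5:
        warnings.warn(
            f"dt = {dt} h violates D*dt/dz^2 <= 0.5; refined to {stable:.3g} h",
            stacklevel=2,
        )
        dt = stable
    n_steps = max(1, int(np.ceil(p.duration / dt)))
    dt = p.duration / n_steps

    depths = np.arange(0.0, p.column_height + dz / 2, dz)
    c = np.full(depths.size, float(p.initial_o2))
    lam = d_h * dt / dz**2

    snap_times = np.linspace(0.0, p.duration, n_snapshots)
    snaps = np.empty((n_snapshots, depths.size))
    snaps[0] = c
    next_snap = 1

    for step in range(1, n_steps + 1):
        c[0] = p.surface_o2
        lap = np.empty_like(c)
        lap[1:-1] = c[2:] - 2 * c[1:-1] + c[:-2]
        lap[-1] = 2 * (c[-2] - c[-1])            # mirrored ghost: no-flux bottom
        lap[0] = 0.0                             # Dirichlet, overwritten anyway
        resp = np.where(c > 0, r_h, 0.0)
        c = c + lam * lap - resp * dt
        c = np.maximum(c, 0.0)
        c[0] = p.surface_o2
        t = step * dt
        while next_snap < n_snapshots and snap_times[next_snap] <= t + 1e-12:
            snaps[next_snap] = c
            next_snap += 1
    while next_snap < n_snapshots:  # numerical guard
        snaps[next_snap] = c
        next_snap += 1
    return OxygenProfile(times=snap_times, depths=depths, concentration=snaps, params=p)


def hypoxic_volume_fraction(
    profile: OxygenProfile,
    threshold: float = HYPOXIA_THRESHOLD_UM,
    t: float | None = None,
) -> float:
    """Fraction of the water volume with C < threshold at time t.

    Trapezoidal depth integration of the below-threshold indicator over the
    column (uniform cross-section); defaults to the end of the simulation.
    """
    if t is None:
        t = float(profile.times[-1])
    c = profile.at_time(t)
    indicator = (c < threshold).astype(float)
    height = profile.depths[-1] - profile.depths[0]
    return float(np.trapezoid(indicator, profile.depths) / height)


def o2_saturation(temperature_C: float, salinity: float) -> float:
    """Air-equilibrium O2 (uM) from temperature and salinity.

    Garcia & Gordon (1992) combined fit, 'A' coefficients; helper only —
    the bottle model defaults to a fixed boundary concentration for
    reproducibility.
    """
    ts = np.log((298.15 - temperature_C) / (273.15 + temperature_C))
    a = [5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369]
    b = [-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3]
    c0 = -2.75915e-7
    ln_c = sum(ai * ts**i for i, ai in enumerate(a))
    ln_c += salinity * sum(bi * ts**i for i, bi in enumerate(b))
    ln_c += c0 * salinity**2
    return float(np.exp(ln_c))  # umol/kg ~ uM for this purpose
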