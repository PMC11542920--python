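"""Single-compartment osmotic volume model of an astrocyte.

The cell is a well-mixed compartment holding a conserved amount
``N_in = C0_in * V0`` of impermeant osmolytes.  Water crosses the membrane
through two parallel osmotic pathways — an aquaporin conductance ``g_aqp``
(blockable) and a residual leak ``g_leak`` — driven by the osmolarity
difference, plus a constant water source ``J_met`` standing for
cotransporter-coupled / metabolic water accumulation:

    dV/dt = [g_aqp * (1 - block(t)) + g_leak] * (N_in / V - C_out(t)) + J_met

At rest with all pathways open the source is balanced by a small tonic
osmotic efflux (the cell sits slightly hyposmotic to the bath); blocking the
aquaporin removes most of the efflux path and the cell swells — the
model-level counterpart of acute AQP4 inhibition.  With ``J_met = 0`` the
equilibrium is the van't Hoff volume ``V_eq = N_in / C_out``.

Units: volume µm³, osmolarity mOsM, conductance µm³ s⁻¹ mOsM⁻¹, time s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..core import TimeSeries

__all__ = [
    "OsmoticParams",
    "ChallengeProtocol",
    "VolumeTrace",
    "simulate_osmotic_volume",
]


@dataclass(frozen=True)
class OsmoticParams:
    """Ground-truth parameters of the osmotic volume model.

    Defaults describe a ~4000 µm³ astrocyte at physiological 300 mOsM with
    the aquaporin carrying ~4× the leak conductance and a small constitutive
    water source.
    """

    V0: float = 4000.0            # µm³
    C0_in: float = 300.0          # mOsM
    g_aqp: float = 2.0            # µm³ s⁻¹ mOsM⁻¹
    g_leak: float = 0.5           # µm³ s⁻¹ mOsM⁻¹
    block: float = 0.0            # fraction of g_aqp inhibited
    J_met: float = 0.0            # µm³ s⁻¹, constitutive water source

    def __post_init__(self) -> None:
        if self.g_aqp < 0 or self.g_leak < 0:
            raise ValueError("conductances must be >= 0")
        if not 0.0 <= self.block <= 1.0:
            raise ValueError("block must lie in [0, 1]")
        if self.g_aqp * (1.0 - self.block) + self.g_leak <= 0:
            raise ValueError("total open conductance must be > 0")
        if self.J_met < 0:
            raise ValueError("J_met must be >= 0")
        if self.V0 <= 0 or self.C0_in <= 0:
            raise ValueError("V0 and C0_in must be > 0")

    @property
    def N_in(self) -> float:
        """Conserved impermeant osmolyte amount (mOsM·µm³)."""
        return self.C0_in * self.V0


@dataclass(frozen=True)
class ChallengeProtocol:
    """Piecewise-constant bath osmolarity and aquaporin block schedule.

    ``breakpoints`` are the segment start times (first must be 0, strictly
    increasing); segment ``k`` runs from breakpoint ``k`` to ``k+1`` (the
    last to ``duration``).  ``block`` may be None, in which case the scalar
    ``OsmoticParams.block`` applies throughout.
    """

    c_out: tuple[float, ...]
    duration: float
    breakpoints: tuple[float, ...] = (0.0,)
    block: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp[0] != 0.0 or np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must start at 0 and increase strictly")
        if len(self.c_out) != bp.size:
            raise ValueError("one c_out value per segment required")
        if self.block is not None and len(self.block) != bp.size:
            raise ValueError("one block value per segment required")
        if any(c <= 0 for c in self.c_out):
            raise ValueError("C_out must be > 0 everywhere")
        if self.block is not None and any(not 0 <= b <= 1 for b in self.block):
            raise ValueError("block fractions must lie in [0, 1]")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")

    @classmethod
    def constant(cls, c_out: float, duration: float, block: float | None = None) -> "ChallengeProtocol":
        return cls(
            c_out=(c_out,),
            duration=duration,
            breakpoints=(0.0,),
            block=None if block is None else (block,),
        )

    @classmethod
    def step(
        cls,
        c_out_before: float,
        c_out_after: float,
        t_step: float,
        duration: float,
    ) -> "ChallengeProtocol":
        """Osmolarity step at ``t_step`` (e.g. 300→100 hypotonic challenge)."""
        return cls(c_out=(c_out_before, c_out_after), duration=duration, breakpoints=(0.0, t_step))

    def _segment(self, t: float) -> int:
        return int(np.searchsorted(self.breakpoints, t, side="right") - 1)

    def c_out_at(self, t: float) -> float:
        return self.c_out[self._segment(t)]

    def block_at(self, t: float, default: float) -> float:
        if self.block is None:
            return default
        return self.block[self._segment(t)]


@dataclass(frozen=True)
class VolumeTrace:
    """Simulated water volume V(t) plus the generating ground truth."""

    series: TimeSeries
    params: OsmoticParams
    protocol: ChallengeProtocol

    @property
    def dff_true(self) -> np.ndarray:
        """True dye-dilution dF/F0 = V0/V(t) − 1 implied by this volume."""
        return self.params.V0 / self.series.values - 1.0


def _dvdt(V: float, t: float, p: OsmoticParams, proto: ChallengeProtocol) -> float:
    g = p.g_aqp * (1.0 - proto.block_at(t, p.block)) + p.g_leak
    return g * (p.N_in / V - proto.c_out_at(t)) + p.J_met


def simulate_osmotic_volume(
    params: OsmoticParams,
    protocol: ChallengeProtocol,
    dt: float = 0.1,
) -> VolumeTrace:
    """Integrate the volume ODE with a fixed-step classical Runge-Kutta scheme.

    ``dt`` must resolve the fastest relaxation: the linearised time constant
    near V0 is ``tau = V0 / (g_total * C_max)``; dt > tau/10 is rejected.

    Raises ``ValueError`` if the trajectory reaches a non-positive volume
    (the parameter regime is rejected rather than clipped).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    g_max = params.g_aqp + params.g_leak
    c_max = max(params.C0_in, max(protocol.c_out))
    tau_min = params.V0 / (g_max * c_max)
    if dt > tau_min / 10.0:
        raise ValueError(
            f"dt={dt:g}s too coarse for pathway time constant {tau_min:.3g}s; need dt <= {tau_min/10:.3g}s"
        )
    n_steps = int(np.floor(protocol.duration / dt + 1e-9))
    if n_steps < 1:
        raise ValueError("protocol shorter than one integration step")
    V = np.empty(n_steps + 1)
    V[0] = params.V0
    v = params.V0
    for k in range(n_steps):
        t = k * dt
        k1 = _dvdt(v, t, params, protocol)
        k2 = _dvdt(v + 0.5 * dt * k1, t + 0.5 * dt, params, protocol)
        k3 = _dvdt(v + 0.5 * dt * k2, t + 0.5 * dt, params, protocol)
        k4 = _dvdt(v + dt * k3, t + dt, params, protocol)
        v = v + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not v > 0:
            raise ValueError("non-positive volume encountered; parameter regime rejected")
        V[k + 1] = v
    return VolumeTrace(
        series=TimeSeries(V, dt=dt, t0=0.0, unit_label="um^3"),
        params=params,
        protocol=protocol,
    )
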