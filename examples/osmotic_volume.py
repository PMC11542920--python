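"""Osmotic volume model: van't Hoff equilibria and swelling on AQP4 block.

Simulates a single astrocyte as a well-mixed osmometer and prints two
checks: the equilibrium volume after a hypotonic step (set by conserved
intracellular osmolytes alone) and the swelling produced by blocking the
aquaporin when a constitutive water source is present.
"""
import numpy as np

from aquaflux import synth

# hypotonic challenge: 300 -> 100 mOsM, no water source
p = synth.OsmoticParams(J_met=0.0)
trace = synth.simulate_osmotic_volume(
    p, synth.ChallengeProtocol.constant(100.0, 2500.0), dt=0.25
)
print(f"hypotonic 300->100 mOsM: V(end)/V0 = {trace.series.values[-1]/p.V0:.4f} "
      f"(van't Hoff predicts {p.C0_in/100.0:.1f})")

# tonic efflux: water source balanced by aquaporin efflux, then block at t=300 s
pb = synth.OsmoticParams(g_aqp=2.0, g_leak=0.5, J_met=1.0)
proto = synth.ChallengeProtocol(
    c_out=(300.0, 300.0), breakpoints=(0.0, 300.0), duration=900.0, block=(0.0, 1.0)
)
tr = synth.simulate_osmotic_volume(pb, proto, dt=0.2)
v = tr.series.values
i_b = tr.series.index_at(300.0)
v_star = pb.N_in / (300.0 - pb.J_met / pb.g_leak)
print(f"block at 300 s: V(300s) = {v[i_b]:.1f} um^3, V(end) = {v[-1]:.1f} um^3, "
      f"steady state N_in/(C_out - J/g_leak) = {v_star:.1f} um^3")
print(f"dV/dt just after block = {(v[i_b+5]-v[i_b+1])/(4*tr.series.dt):+.3f} um^3/s "
      "(positive: blocking the tonic efflux makes the cell swell)")
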