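"""How the miRNA-strength coefficients move the steady-state protein level.

Sweeps the translational-repression half-constant hp (Stop mechanism) and
the complex-degradation constant krs (Dual mechanism) on the 1In loop.
Raising hp weakens miRNA repression, so the protein level climbs; raising
krs removes target mRNA faster, so it falls.
"""

from mirffl import Mechanism, SweepGrid, Topology, default_parameters, sweep_deterministic
from mirffl.sweeps import DEFAULT_GRIDS

params = default_parameters()

_, table_hp = sweep_deterministic(
    Mechanism.STOP, Topology.IN1, SweepGrid("hp", DEFAULT_GRIDS["hp"], params)
)
print("Stop mechanism, 1In loop — hp sweep (weaker repression as hp grows):")
print(table_hp[["value", "p_star", "p_end"]].to_string(index=False))

_, table_krs = sweep_deterministic(
    Mechanism.DUAL_DEG, Topology.IN1, SweepGrid("krs", DEFAULT_GRIDS["krs"], params)
)
print("\nDual mechanism, 1In loop — krs sweep (faster complex decay as krs grows):")
print(table_krs[["value", "p_star", "p_end"]].to_string(index=False))

print(
    "\np_star is the algebraic fixed point, p_end the count after one 5000 s"
    "\ncell cycle from half-steady initial conditions; they agree closely"
    "\nbecause the slowest relaxation times are a few hundred seconds."
)
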