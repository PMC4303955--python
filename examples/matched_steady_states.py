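"""Same fixed point, different transients: calibrating across mechanisms.

The three miRNA mechanisms can be tuned (via their degradation
coefficients) so that a loop has the *same* steady-state protein level in
all of them — yet the early-time courses still differ, which is what makes
transient dynamics informative about the mechanism.  Here the 1C loop's
target-degradation and dual-degradation variants are calibrated to the Stop
model's protein level, then all three are simulated from identical initial
conditions.
"""

from mirffl import (
    Mechanism,
    Topology,
    calibrate_parameter_for_protein_ss,
    default_parameters,
    simulate,
    steady_state,
)

params = default_parameters()
loop = Topology.C1
p_target = steady_state(Mechanism.STOP, loop, params).state.p
print(f"common steady-state target: p* = {p_target:.1f} molecules (Stop model, 1C)\n")

calibrated = {Mechanism.STOP: params}
for mech, free in ((Mechanism.TARGET_DEG, "gmax"), (Mechanism.DUAL_DEG, "krs")):
    value = calibrate_parameter_for_protein_ss(mech, loop, params, free, p_target)
    calibrated[mech] = params.replace(**{free: value})
    print(f"  {mech.name:11s}: {free} calibrated to {value:.6g}")

init = None
print("\npeak and settling behaviour from the Stop model's half-steady start:")
for mech, p in calibrated.items():
    if init is None:
        from mirffl import initial_state

        init = initial_state(Mechanism.STOP, loop, params)
    traj = simulate(mech, loop, p, init=init)
    prot = traj.species("p")
    print(
        f"  {mech.name:11s}: max p(t) = {prot.max():7.1f} at t = {prot.argmax():4d} s, "
        f"p(5000) = {prot[-1]:7.1f}"
    )
print(
    "\nIdentical start, (near-)identical end — but the peak heights and times"
    "\ndiffer by mechanism, so a time course can discriminate them."
)
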