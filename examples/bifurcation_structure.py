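"""Map the deterministic skeleton of a single cortical column.

Finds the two Hopf bifurcations that delimit the alpha limit cycle and
the input window in which the large-amplitude spiky cycle coexists with
it, by eigenvalue bisection and by direct simulation respectively.
"""

import neuromass as nm

print("Equilibria at p = 90 Hz (y1 - y2, leading eigenvalue real part):")
for eq in nm.fixed_points(90.0):
    print(f"  y = {eq.y:7.3f} mV   Re(lambda_1) = {eq.leading_real:9.3f} 1/s")

print("\nHopf bifurcations of the equilibrium branch:")
for lo, hi in [(80.0, 100.0), (300.0, 330.0)]:
    for pt in nm.hopf_scan(lo, hi, tol=0.01):
        print(f"  p = {pt.p_exc:7.2f} Hz   cycle frequency {pt.frequency_hz:5.2f} Hz")

onset, offset = nm.coexistence_boundaries(tol=0.1)
print(f"\nSpiky-cycle coexistence window: {onset:.2f} Hz to {offset:.2f} Hz")
print(
    "Between these inputs the ~10 Hz alpha cycle coexists with a slower,\n"
    "much larger 'spiky' oscillation; which one the column settles on\n"
    "depends on the initial state."
)
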