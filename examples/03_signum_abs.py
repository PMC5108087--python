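"""Signum and absolute value from single covalent modification cycles.

Signum: an ultrasensitive cycle saturates at +/-1e-3 M for any input
beyond its switching threshold; a gain of 1000 rescales the output to
+/-1.  Absolute value: a threshold-hyperbolic cycle answers positive
inputs with unit slope and ignores negative ones (the dual-rail minus
pathway recycles and cancels), a signal-transducing cycle wired with
crossed input rails does the mirror job at slope 20 (scaled by 1/20),
and one subtraction combines the branches.
"""

from analogcrn import build_signum, build_abs, evaluate_circuit

sgn = build_signum("cmc", K=1000.0)
print(f"signum circuit: {sgn.total_count} reactions")
for x in (2.0e-6, 5.5e-6, -3.0e-6, -0.5e-6):
    rep = evaluate_circuit(sgn, {"x": x}, t_final=5000.0, settle_tol=1e-2)
    print(f"  sgn({x:+.1e} M) = {rep.outputs['sgn_x']:+.4f}")
print("Outputs are +/-1 to within a few percent: the switch saturates for "
      "any input larger than its ~1e-9 M threshold.")

absd = build_abs("cmc")
print(f"\nabsolute-value circuit: {absd.total_count} reactions")
for u in (3.0, -3.0, 5.0, -5.0, 1.0, 6.0):
    rep = evaluate_circuit(absd, {"u": u}, t_final=8000.0, settle_tol=1e-2)
    y = rep.outputs["abs_u"]
    print(f"  |{u:+.0f} M| = {y:.4f} M   error {100 * (y / abs(u) - 1):+.2f}%")
print("Accuracy is sub-percent across the +/-1..6 M working range with the "
      "fitted regime parameter sets.")
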