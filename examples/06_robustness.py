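"""Monte-Carlo robustness: why the CMC controller tolerates more
parameter uncertainty than the PI controller.

Every rate constant p in the loop is perturbed to p(1 + Delta*u) with
u ~ U(0,1), drawn independently per parameter.  A Chernoff bound sizes
the full analysis at 1060 samples (accuracy 0.05, confidence 99%);
this example runs a scaled-down N for speed.
"""

from analogcrn import (chernoff_sample_size, nominal_system,
                       run_monte_carlo, UncertaintySpec)
from analogcrn.robustness import critical_delta

print(f"Chernoff sample size (accuracy 0.05, confidence 99%): "
      f"{chernoff_sample_size(0.05, 0.99)}")

N, SEED = 200, 0
pi = nominal_system("pi", "linear")
cmc = nominal_system("cmc", "linear")
for delta in (0.2, 1.0, 1.2):
    a = run_monte_carlo(pi, UncertaintySpec(delta, N, SEED))
    b = run_monte_carlo(cmc, UncertaintySpec(delta, N, SEED))
    print(f"Delta={delta}: PI worst overshoot "
          f"{a.worst.get('M_OV', float('nan')):6.1f}% "
          f"({a.n_unstable} unstable) | CMC "
          f"{b.worst.get('M_OV', float('nan')):6.1f}% "
          f"({b.n_unstable} unstable)   [N={N}]")

found, scan = critical_delta(cmc, [1.2, 1.4, 1.6, 1.8], n_per_point=N,
                             seed=SEED)
print(f"smallest Delta with an unstable CMC sample on the grid: {found} "
      f"(N={N}, seed={SEED})")
if found is None:
    print("  (instability is rare per draw: at this reduced N the scan can "
          "come up empty; N=500 per point locates the onset at "
          "Delta ~ 1.6-1.8)")
print("The PI loop loses stability around Delta=1.2 while the cycle's "
      "saturating map keeps the CMC loop stable well beyond -- the "
      "uncertainty pushes it from its linear regime into a hyperbolic one, "
      "which lowers, not raises, its effective gain.")
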