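"""How enhancement scales with stretch size but not stretch speed.

Sweeps the stretch magnitude (all trials ending at the same final length)
and the stretch velocity at fixed 8% magnitude, with small ensembles.
"""

import sarcsim as ss
from sarcsim.experiments import SweepSpec, magnitude_sweep, velocity_sweep

params = ss.HalfSarcomereParams()

mag = magnitude_sweep(
    SweepSpec("magnitude", (0.02, 0.08, 0.16), seeds_per_point=4,
              master_seed=7), params)
print("stretch magnitude -> RFE (%):")
for _, row in mag.iterrows():
    print(f"  {row.magnitude_percent:5.1f} %  ->  {row.rfe_percent:6.2f}")
print(f"fitted slope: {mag.attrs['slope']:.2f} %RFE per %stretch "
      f"(R^2 = {mag.attrs['r_squared']:.3f})")
print()

vel = velocity_sweep(
    SweepSpec("velocity", (0.05, 0.1, 0.5), seeds_per_point=4,
              master_seed=7), params)
print("stretch velocity -> RFE (%):")
for _, row in vel.iterrows():
    print(f"  {row.velocity:5.2f} lengths/s  ->  {row.rfe_percent:6.2f}")
print(f"max/min ratio: {vel.attrs['max_min_ratio']:.2f}")
print()
print("Enhancement grows roughly in proportion to how far the fiber was")
print("stretched, but a ten-fold change in stretch speed barely moves it —")
print("the two classic signatures of residual force enhancement.")
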