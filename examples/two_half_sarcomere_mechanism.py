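"""The enhancement mechanism in its smallest form: two dissimilar units.

A weak and a strong half-sarcomere in series are stretched together.
The weak unit absorbs most of the stretch, skewing its bound cross-bridge
strains upward; afterwards it creeps longer while the strong unit
shortens, and during that slow antagonistic motion the pair's common
tension stays above the isometric reference.
"""

import numpy as np

import sarcsim as ss

params = ss.HalfSarcomereParams()
demo = ss.two_hs_demo(params, zeta_weak=0.85, zeta_strong=1.15,
                      late_time=20.0,
                      lt_grid=np.linspace(1100.0, 1600.0, 15))

s1, late = demo["at_1s"], demo["late"]
print("one second after stretch:")
print(f"  weak unit   {s1['length_weak']:7.1f} nm")
print(f"  strong unit {s1['length_strong']:7.1f} nm")
print(f"  tension     {s1['tension']:9.0f} N/m^2")
print(f"  weak above its steady-state curve:  {demo['weak_above_curve']}")
print(f"  strong below its steady-state curve: {demo['strong_below_curve']}")
print("twenty seconds later:")
print(f"  weak unit   {late['length_weak']:7.1f} nm  (still lengthening)")
print(f"  strong unit {late['length_strong']:7.1f} nm  (still shortening)")
print(f"  tension     {late['tension']:9.0f} N/m^2")
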