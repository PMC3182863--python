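"""A fiber of six myofibrils with z-lines registered across them.

Desmin-like springs (stiffness k_im) couple corresponding z-disks of
parallel myofibrils.  Whole sarcomeres then vary less in length than the
half-sarcomeres inside them, which still diverge — and some residual
enhancement survives the stabilisation.
"""

import sarcsim as ss
from sarcsim.experiments import myofibril_lattice_experiment

params = ss.HalfSarcomereParams()
res = myofibril_lattice_experiment(params, seeds=2, master_seed=3)

print(f"lattice RFE at 6 s post-stretch : {res['rfe'].rfe_percent:6.2f} %")
print(f"half-sarcomere length rel. SD   : "
      f"{100 * res['rel_sd_half_sarcomere']:6.2f} %")
print(f"whole-sarcomere length rel. SD  : "
      f"{100 * res['rel_sd_sarcomere']:6.2f} %")
print()
print("Z-line registration reduces whole-sarcomere length variation below")
print("the half-sarcomere level, yet heterogeneity inside each sarcomere")
print("persists and some enhancement survives the stabilisation.")
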