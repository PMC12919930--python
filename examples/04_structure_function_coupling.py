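"""Measure how much synapse density improves structure-function coupling
and whether the gain depends on behavioural state.

Coupling per region = adjusted R^2 of regressing its FC profile on its
communicability profile; the delta is the gain from adding the target
region's density.  The generator plants the short-lifetime PSD95
contribution in the awake state only, so the paired Wilcoxon test
should reject for that map and not for the others.
"""

import pandas as pd

import synaptodyn as sd
from synaptodyn.coupling import augmented_coupling, communicability, compare_states
from synaptodyn.synthetic import _rank_unit

cfg = sd.SynthConfig(seed=1)
density, _ = sd.synthetic.gen_density(cfg)
sc, fc_awake, fc_anaesth = sd.synthetic.gen_connectomes(cfg, density)
G = communicability(sc)

sim = sd.synaptome.subtype_similarity(density)
labels = sd.synaptome.consensus_cluster(
    sim, sd.synaptome.ConsensusParams(seed=1),
    strata=density.subtype_meta["protein_class"],
)
maps, _ = sd.synaptome.cluster_mean_maps(density, labels)

print(f"{'map':<14}{'median dR2 awake':>18}{'median dR2 anaesth':>20}"
      f"{'Wilcoxon p':>14}")
for name in ("psd95_long", "psd95_short", "sap102"):
    u = pd.Series(_rank_unit(maps.loc[name].values), index=fc_awake.region_ids)
    da = augmented_coupling(G, fc_awake, u).table["delta"]
    dn = augmented_coupling(G, fc_anaesth, u).table["delta"]
    res = compare_states(da, dn)
    print(f"{name:<14}{da.median():>18.4f}{dn.median():>20.4f}{res['p']:>14.2e}")

print("\nOnly the short-lifetime map should show a state-dependent gain "
      "(small p); the other maps improve coupling equally in both states.")
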