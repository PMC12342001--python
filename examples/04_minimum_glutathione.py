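"""Minimum glutathione supplementation under oxidative stress.

For increasing hydrogen-peroxide insults at the start of perfusion, find
the smallest medium GSH amount that keeps mitochondrial [H2O2] inside
the normal band (1e-9..1e-8 M) at the end of perfusion.
"""

from nashflux import MCConfig, PerfusionModel, TemperaturePolicy

model = PerfusionModel()
scs = model.run_scs()
policy = TemperaturePolicy.constant(16.0, 8)

print("perturbation (nmol/cell) -> min GSH (nmol/cell), end [H2O2] (M), GSH/GSSG")
for P in (0.0, 5e-6, 1e-5, 1.5e-5, 2e-5, 3e-5):
    out = model.minimize_gsh(
        scs.final_state, policy, MCConfig(n_iter=15, seed=4, perturbation=P)
    )
    panel = out.result.final_panel
    print(f"  {P:8.2e} -> {out.supplement:.3e}  {panel.h2o2_conc:.2e}  "
          f"{panel.gsh_gssg_ratio:6.2f}")

print("\nSmall insults are absorbed by the glutathione retained from the")
print("cold flush, so the minimum stays at the lower bound (2.22e-5, the")
print("standard perfusate amount); past ~1.5e-5 nmol/cell the demand rises")
print("and the GSH/GSSG ratio falls -- the oxidative-stress signature.")
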