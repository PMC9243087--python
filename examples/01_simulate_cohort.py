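"""Generate a small synthetic tumor/normal panel cohort and inspect its truth.

The generator draws per-patient purity, a trunk-plus-subclones clone
structure, copy-number segments, and binomial read counts at panel-like
depth, then leaks tumor content into the matched normal to emulate
circulating tumor cells.
"""

from clonopanel import SimulationConfig, simulate_cohort

config = SimulationConfig(n_patients=5, panel_size=500_000, seed=42,
                          somatic_rate_per_mb=10.0)
bundle = simulate_cohort(config)

print(f"panel footprint: {bundle.resources.footprint_mb:.2f} Mb, "
      f"{len(bundle.resources.genes)} genes, "
      f"{len(bundle.resources.hotspots)} hotspot sites")
print(bundle.truth.variants["class"].value_counts().to_string())
print()
for pid, p in bundle.patients.items():
    print(f"{pid}: purity={p.purity:.2f} contamination={p.contamination:.2f} "
          f"tumor calls={len(p.tumor)} normal calls={len(p.normal)}")
print()
print("Variant classes above: 'somatic' are real tumor events; "
      "'germline_common' and 'artifact' must be removed by filtering; "
      "'contaminant_only' exist only in the blood via circulating tumor cells.")
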