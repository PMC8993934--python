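"""Build a synthetic flux-tower site: two years of daily forcing, a known
transpiration stress function, and noisy pseudo-observations of evaporation.

The generator evolves a real soil column under the forcing, so the plant
available water (PAW) that the stress function reads feeds back on the
evaporation it produces — exactly the loop the hybrid model closes.
"""

import hybridevap as he

forcing = he.generate_forcing(seed=1, n_days=730)
series = he.generate_observations(
    forcing, he.TruthStressSpec(noise_sd_mm=0.05), he.SoilParams.tall(), seed=2
)

print(series[["P", "Ta", "VPD", "PAW", "S_t_true", "E_pt_raw", "E_obs"]].describe().round(3))
print()
print(f"wet days: {(series['P'] > 0.5).sum()} of {len(series)}")
print(f"mean truth stress S_t: {series['S_t_true'].mean():.3f}")
print(f"mean observed E: {series['E_obs'].mean():.3f} mm/day "
      f"(potential {series['E_pt_raw'].mean():.3f} mm/day)")
# S_t is the fraction of potential transpiration the ecosystem realises;
# observed E = S_t * E_pt plus interception on rain days plus noise.
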