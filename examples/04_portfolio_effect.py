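"""Quantify synchrony and the portfolio effect from zone abundances.

phi near 1 means all zones boom and bust together; the portfolio effect
(PE) compares the total-abundance variance predicted from Taylor's
mean-variance scaling with the variance actually observed — PE above 1
means asynchrony stabilizes the whole population.
"""

from dunesync import (
    correlation_matrix,
    default_params,
    generate_climate,
    generate_population,
    portfolio_effect,
    zone_abundance,
)

climate = generate_climate(1985, 40, seed=1)
census, _ = generate_population(default_params(), climate, seed=2)
abundance = zone_abundance(census)
print("abundance (zones x years):")
print(abundance.to_string())

stats = portfolio_effect(abundance)
print(f"\nsynchrony phi           {stats.phi:.3f}")
print(f"Taylor slope z          {stats.z:.2f}")
print(f"observed total variance {stats.var_obs_total:,.0f}")
print(f"predicted (scaling law) {stats.var_pred_total:,.0f}")
print(f"portfolio effect PE     {stats.pe:.2f}")

corr = correlation_matrix(abundance)
print("\npairwise zone correlations (abundance):")
print(corr.round(3).to_string(index=False))
# Adjacent zones correlate strongly; distant zones weakly or negatively —
# the spatial signature that pushes phi down and PE up.
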