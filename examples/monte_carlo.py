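"""Propagate measurement uncertainty to a dose distribution.

Each specific activity is drawn from a mean-preserving lognormal with the
tabulated relative uncertainty (13–45% per nuclide); every draw re-runs
the full processing-plant scenario.
"""

import normdose as nd

scenario = nd.load_scenario("processing_plant")
deterministic = nd.run_scenario(scenario)
print(f"deterministic gamma+dust dose: {deterministic.subtotal_excl_radon_msv:.3f} mSv/a")

result = nd.monte_carlo_dose(nd.SamplingSpec(n_draws=2000, seed=7), scenario)
print()
print(result.summary().round(3).to_string())

print()
print("Reading: because every pathway is linear in the activities and the")
print("sampling preserves the mean, the Monte Carlo mean matches the")
print("deterministic dose; the 5–95% band shows the spread the measured")
print("nuclide uncertainties alone induce.")
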