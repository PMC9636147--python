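{
 "model": "transient_excess_exponential",
 "description": "Purifying-selection clock correction: the apparent substitution rate of a clade of age t is inflated by transient mildly deleterious variants not yet purged; instantaneous rate multiplier r(t) = 1 + a*exp(-t/tau), so E[rho](t) = mu*L*(t + a*tau*(1 - exp(-t/tau))). Replace a/tau with the published conversion-curve coefficients to match a specific published clock.",
 "a": 0.41,
 "tau_years": 2000.0
}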