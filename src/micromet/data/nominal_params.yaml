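# Nominal model configuration (normalized units, rates in 1/day).
# This file is the single versioned source of the default rate constants;
# ModelParameters() loads it at import time.
#
# k_ink is linked to k_iap (k_ink = 0.02 * k_iap) when not set explicitly,
# so it is deliberately absent here.
k_pmc: 1.0      # tumor proliferation rate, 1/day (lower edge of the screened range)
M_T: 1.0        # micrometastasis carrying capacity, n.u.
k_iap: 1.0      # T-cell cytotoxic efficiency, 1/(day * n.u.)
k_atg: 1.0      # antigen presentation level (HLA surrogate), normalized to 1
k_iev: 1.0      # immune-evasion efficiency, dimensionless
k_nkc: 1.0      # NK Hill half-constant, antigen-presentation units
g_nk: 6.0       # NK Hill exponent
k_apc: 0.04     # inherent APC-mediated activation rate, n.u./day
k_gir: 1.0      # vaccine amplification (global immune response), dimensionless
k_atc: 0.02     # T-cell self-expansion rate, 1/day (weak relative to vaccine-driven activation)
k_tapc: 0.02    # activation Hill half-constant (sensitive APC detection of presented antigen)
g_1: 2.0        # activation Hill exponent
k_tatc: 0.02    # expansion Hill half-constant
g_2: 2.0        # expansion Hill exponent
k_dtc: 0.005    # T-cell depletion rate, 1/(day * n.u.^2); slow decay of the activated pool
rho_mem: 0.01   # delayed (memory) depletion weight relative to k_dtc
t_dtc: 30.0     # depletion time delay, days
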