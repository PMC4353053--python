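# Reference parameter set for the coupled bulk-surface activator-depleted model.
# alpha1 = beta1 = 5/12; the coupling satisfies the steady-state compatibility
# condition (beta1 - alpha1)(kappa2 - alpha2) - kappa1*beta2 = 0.
# d_omega / d_gamma default to 1 (the no-pattern regime); raise either above its
# critical value (~8.57 for these kinetics) to trigger patterning.
a = 0.1
b = 0.9
gamma_omega = 500.0
gamma_gamma = 500.0
d_omega = 1.0
d_gamma = 1.0
alpha1 = 0.4166666666666667
beta1 = 0.4166666666666667
alpha2 = 5.0
kappa2 = 5.0
kappa1 = 0.0
beta2 = 0.0
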