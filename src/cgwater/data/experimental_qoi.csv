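qoi,value,unit,temperature_K
rho,0.999,g/cm3,283.0
epsilon,84.0,dimensionless,283.0
gamma,74.2,mN/m,283.0
kappa,47.89,1e-6/bar,283.0
eta,1.307,mPa s,283.0
rho,0.997,g/cm3,298.0
epsilon,78.4,dimensionless,298.0
gamma,72.0,mN/m,298.0
kappa,45.24,1e-6/bar,298.0
eta,0.891,mPa s,298.0
rho,0.988,g/cm3,323.0
epsilon,69.9,dimensionless,323.0
gamma,67.9,mN/m,323.0
kappa,44.17,1e-6/bar,323.0
eta,0.547,mPa s,323.0
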