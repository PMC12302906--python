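"""Fit the gene model to one simulated temperature-driven gene.

The model predicts log2 expression from a gated, clipped look-back average
of an environmental variable (temperature or irradiance) over a window up to
72 h before sampling, modulated by plant age and the time of day.  Seven
nonlinear parameters shape the environmental input — window length T and
delay D (h), gate phase phi (h), gate strength gamma, gate sharpness w, and
the clipping bounds — and eight linear coefficients are selected by adaptive
group lasso with BIC.  Fitting both candidate variables and comparing BIC
yields a per-gene predictor choice: temperature, radiation, or neither.
"""

import numpy as np

from fieldfit import (NonlinearParams, LinearCoefs, enumerate_conditions,
                      fit_gene)
from fieldfit.synthdata import TruthGene, simulate_gc_study

true_nl = NonlinearParams(T=6.0, D=0.0, phi=14.0, gamma=1.0, w=2.0,
                          theta_lo=-50.0, theta_hi=50.0)
true_lin = LinearCoefs(b0=8.0, b_age=0.0, b_cos=0.4, b_sin=-0.2,
                       b_e=0.15, b_e_age=0.0, b_e_cos=0.0, b_e_sin=0.0)
truth = [TruthGene("demo", "temperature", true_nl, true_lin, noise_sd=0.1)]

bundle = simulate_gc_study(enumerate_conditions(), truth, seed=7,
                           batch_effect_sd=0.0)
idx = np.sort(np.random.default_rng(1).choice(len(bundle.samples), 512,
                                              replace=False))
sub = bundle.samples.subset(idx)
y = bundle.expr.loc["demo"].to_numpy()[idx]

fit = fit_gene("demo", y, sub)
print(f"chosen predictor: {fit.predictor}  (truth: temperature)")
nl = fit.nl
print(f"window T = {nl.T:5.2f} h   (truth {true_nl.T:.1f})")
print(f"delay  D = {nl.D:5.2f} h   (truth {true_nl.D:.1f})")
print(f"phase phi = {nl.phi:5.2f} h  (truth {true_nl.phi:.1f})")
print(f"env coefficient = {fit.coefs.b_e:.3f} (truth {true_lin.b_e:.2f})")
print(f"BIC = {fit.criterion:.1f} on n = {fit.n_train} samples")
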