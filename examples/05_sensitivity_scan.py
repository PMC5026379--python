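"""Local sensitivity of the fit error to a handful of parameters.

Generates a synthetic reference (the model's own output with mild noise),
then perturbs each parameter by +25 % and reports the log-log sensitivity
coefficient of the summed fit error.  Strong drivers (body weight, the
active-transport pair) stand out against the passive transfer constants.
A short 2 h horizon keeps this a coffee-break run.
"""

import numpy as np

import hepasim as h
from hepasim.metrics import OUTPUT_NAMES
from hepasim.sensitivity import pairwise_interaction, sensitivity_matrix

subset = ("pbpk_bw", "cc3d_Vmax_AT_APAP", "cc3d_Km_AT_APAP",
          "pbpk_kGutabs", "cc3d_k_PD_H2S", "cc3d_k_PD_S2R",
          "cc3d_k_PD_R2R", "sc_Km_GLUC")

ref = h.generate_reference(h.REFSIM, duration_h=2.0, noise_cv=0.05, seed=11,
                           times=np.arange(0.25, 2.01, 0.25))
runner = h.multiscale_runner(20.0, 2.0, ref, dose_bw_kg=70.0)

mat = sensitivity_matrix(h.REFSIM, runner, subset)
row = mat.values[OUTPUT_NAMES.index("RMSEsum")]
print("J(RMSEsum) per +25% parameter variation:")
for name, j in sorted(zip(subset, row), key=lambda kv: -abs(kv[1])):
    print(f"  {name:20s} {j:+.3f}")
print("Coefficients near zero mean the fit barely notices the parameter; "
      "magnitudes near or above one mark parameters that must be known "
      "accurately.")

ppv = pairwise_interaction(h.REFSIM, runner, "cc3d_Vmax_AT_APAP",
                           "cc3d_Km_AT_APAP")
print(f"pairwise interaction Vmax_AT x Km_AT: {ppv:+.4f} "
      "(nonzero: the two saturable-uptake constants compensate each other)")
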