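"""Fully coupled three-scale simulation of a therapeutic oral dose.

Whole-body circulation, hepatic sinusoid transit and per-hepatocyte
metabolism run together for 8 simulated hours (quasi-steady coupling).
The printout shows the serum exposure of parent and conjugates, the
urinary composition and the zonation of the toxic-pathway marker.
"""

import numpy as np

import hepasim as h
from hepasim.metrics import model_outputs, zonal_summary
from hepasim.subcell import SPECIES

result = h.run_multiscale(h.REFSIM, dose_mg_per_kg=20.0, duration_h=8.0)
out = model_outputs(result)

print(f"serum APAP : Cmax {out.CmaxA * 151.16:5.1f} ug/mL at {out.TmaxA:.2f} h")
print(f"serum APAPG: Cmax {out.CmaxG * 327.29:5.1f} ug/mL at {out.TmaxG:.2f} h")
print(f"serum APAPS: Cmax {out.CmaxS * 231.23:5.1f} ug/mL at {out.TmaxS:.2f} h")

tub = result.tubule_amounts()
total = sum(tub.values())
print("urinary (tubule) composition at 8 h: "
      + ", ".join(f"{c} {100 * v / total:.1f}%" for c, v in tub.items()))
print(f"excreted metabolic ratio: {out.metabRatio:.3f} "
      "(fraction of recovered material that is conjugated)")

zs = zonal_summary(result.hep_traces, result.hep_side, result.hep_rank)
gi = SPECIES.index("NAPQI_GSH")
print("cumulative NAPQI-GSH (mmol/L) per zone: "
      + ", ".join(f"{z} {zs[z]['mean'][-1, gi]:.4f}"
                  for z in ("PP", "MZ", "PV")))
print(f"scaled liver-wide NAPQI-GSH: {out.NAPQIGSH_Sum:.4f} mmol; "
      f"mole ledger closes to {result.conservation_error():.1e} relative.")
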