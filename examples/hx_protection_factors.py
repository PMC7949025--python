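"""Amide hydrogen-exchange protection factors from serial-spectrum decays.

Generates a synthetic D2O-exchange dataset on the real acquisition schedule
(5-min spectra, then 20-min spectra out to 3 months) for a known per-residue
log PF profile, runs the full pipeline — intrinsic-rate prediction, decay
fitting, censoring — and compares the recovered protection against truth.
"""

import numpy as np

from pntkit import datasets, synth
from pntkit.hx import analyze_hx, protection_frame
from pntkit.intrinsic import IntrinsicRateModel

# truth: helices protected (log PF 5-8), loops and termini exchange fast
rng = np.random.default_rng(0)
profile = {}
for i, aa in enumerate(datasets.CONSTRUCT_SEQUENCE):
    resnum = datasets.CONSTRUCT_START + i
    if i == 0 or aa == "P":
        continue
    if datasets.ETV6_HELICES.contains(resnum):
        profile[resnum] = float(rng.uniform(5.0, 8.0))
    else:
        profile[resnum] = float(rng.uniform(0.0, 2.0))

series, truth = synth.gen_hx_dataset(profile, pH_star=7.0, temperature_K=294.15, seed=0)
model = IntrinsicRateModel(datasets.CONSTRUCT_SEQUENCE, datasets.CONSTRUCT_START,
                           pH_star=7.0, temperature_K=294.15)
records = analyze_hx(series, model)
frame = protection_frame(records)

counts = frame["status"].value_counts()
print(f"{len(frame)} amides analysed: "
      f"{counts.get('measured', 0)} measured, "
      f"{counts.get('fast_limit', 0)} exchanged before the first spectrum "
      f"(log PF upper bounds), {counts.get('slow_limit', 0)} still intact after "
      "3 months (lower bounds)")

measured = frame[frame["status"] == "measured"].merge(truth, on="residue")
err = (measured["log_PF"] - measured["log_pf_true"]).abs()
print(f"median |recovered - true| log PF = {err.median():.3f} over "
      f"{len(measured)} measured amides")

most = measured.loc[measured["log_PF"].idxmax()]
print(f"most protected measured amide: residue {int(most.residue)} with "
      f"log PF {most.log_PF:.1f} -> dG_HX {most.dG_kJmol:.1f} kJ/mol "
      "(free energy of the opening reaction that permits exchange)")
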