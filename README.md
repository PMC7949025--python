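# pntkit

Biophysical characterization of self-associating helical-bundle interfaces,
built around the ETV6 PNT (pointed) domain system.

The ETV6 transcriptional repressor polymerizes head-to-tail through two flat,
complementary surfaces of its PNT domain — the mid-loop (ML) and end-helix
(EH) surfaces. Monomerizing point mutations (A93D on the ML side, V112E/R on
the EH side) block one surface each, so a pair of complementary mutants forms
a defined heterodimer that models one unit of the polymer. `pntkit`
implements the four analyses used to characterize these interfaces, plus a
seeded synthetic-data generator that stands in for the spectrometer and
biosensor output:

* **CSP mapping** (`pntkit.csp`) — combined amide chemical-shift
  perturbations between free and bound states,
  Δδ = [(Δδ_H)² + (0.14·Δδ_N)²]^½, with interface classification at
  Δδ > 0.2 ppm.
* **Hydrogen-exchange protection** (`pntkit.hx`, `pntkit.intrinsic`) —
  single-exponential fits of serial-HSQC peak intensities
  I_t = I₀·e^(−k_obs·t), intrinsic (random-coil) rate prediction from the
  poly-DL-alanine reference scheme with neighbor, pH, temperature and
  isotope corrections, protection factors PF = k_pred/k_obs, and
  ΔG_HX = 2.303·R·T·log₁₀(PF). Amides that exchange before the first
  spectrum or not at all are censored with explicit upper/lower bounds on
  log PF.
* **SPR kinetics and alanine scanning** (`pntkit.spr`) — closed-form 1:1
  Langmuir sensorgrams, global (k_on, k_off, R_max) fits across a
  concentration series, K_D = k_off/k_on with propagated errors,
  ΔΔG = RT·ln(K_D,mut/K_D,ref), and strict ΔΔG > 6 kJ/mol hot-spot
  classification with fold-change binning.
* **MD trajectory statistics** (`pntkit.md`) — Kabsch superposition, RMSD
  series, per-residue all-atom RMSF, chain-vs-chain ΔRMSF with a ±0.3 Å
  interface-rigidification rule, PCA of coordinate covariance, and backbone
  H-bond persistence (trajectory-mean amide-N⋯carbonyl-O ≤ 3.5 Å) for
  comparison with HX protection.
* **Synthetic data** (`pntkit.synth`) — ideal-geometry helix bundles,
  Gaussian-fluctuation trajectories, HX decay series on the real
  acquisition schedule, noisy sensorgram sets, and perturbed shift tables —
  each with a machine-readable ground-truth table.

The published alanine-scan rate-constant tables for both surfaces ship in
`pntkit.datasets` and act as inputs to the ΔΔG/hot-spot pipeline.

## Worked example

```python
from pntkit import datasets
from pntkit.spr import classify_scan, kd_from_rates

kd, _ = kd_from_rates(datasets.EH_SCAN.loc["None", "kon"],
                      datasets.EH_SCAN.loc["None", "koff"])
print(f"{kd * 1e9:.1f} nM")                      # 7.5 nM reference K_D

annotated = classify_scan(datasets.ML_SCAN)
print(int(annotated.hotspot.sum()))              # 7 hot spots of 14 mutants
row = annotated.set_index("mutation").loc["R105A"]
print(f"{row.ddG_calc_kJmol:.1f} kJ/mol, {row.fold_category}")
```

prints

```
7.5 nM
7
15.2 kJ/mol, ~1000x
```

meaning: the unmutated heterodimer binds with nanomolar affinity; half of
the tested ML-surface residues are energetic hot spots; and R105A alone
weakens binding ~1000-fold (ΔΔG = RT·ln(2340/5.1) ≈ 15.2 kJ/mol), marking
the R105–D111 salt bridge as critical for self-association.

The `examples/` directory contains one short narrative script per stage
(`spr_alanine_scan.py`, `hx_protection_factors.py`,
`csp_interface_mapping.py`, `md_rigidity.py`, `synthetic_datasets.py`), and
the `pntkit` console command exposes the same stages for batch use
(`pntkit scan --surface ML --out scan.tsv`, `pntkit hx-fit …`,
`pntkit simulate …`; see `pntkit --help`).

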