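# Methods

This note documents the models implemented in `pntkit`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Chemical shift perturbation

Combined amide CSPs are Δδ = [(Δδ_H)² + (w·Δδ_N)²]^½ with nitrogen weight
w = 0.14 (the conventional scaling that makes 15N dispersion commensurate
with 1H). Differences are bound − free; the sign is irrelevant to Δδ but is
kept in the output for diagnostics. Interface classification uses a strict
Δδ > 0.2 ppm rule. Residues assigned in only one state are reported with a
`missing` flag, never dropped — free and bound spectra are typically
recorded under slightly different conditions and lose different
assignments. No pH-difference correction is applied to the shifts; small
CSPs can partly reflect condition differences, which is why the
classification threshold is an order of magnitude above the background
noise rather than a significance test.

## Intrinsic exchange rates

`pntkit.intrinsic` implements the poly-DL-alanine reference scheme for
protium→deuterium exchange:

    k_pred = k_A·[D⁺]·A_L·A_R + k_B·[OD⁻]·B_L·B_R + k_W·B_L·B_R

with log₁₀ reference rates 1.62 (acid, M⁻¹min⁻¹), 10.05 (base, M⁻¹min⁻¹)
and −1.5 (water, min⁻¹) at 293.15 K; activation energies 14, 17 and
19 kcal/mol for Arrhenius temperature scaling; and pK(D₂O) = 15.05 for the
deuteroxide concentration. The side-chain correction factors are the
published H→D table: the "left" column of a residue type modifies its own
amide, the "right" column the amide of the following residue; chain termini
contribute their own factors to the second and last amides. Titratable side
chains (Asp, Glu, His) interpolate between their protonated and
deprotonated factors with Henderson–Hasselbalch populations at pKa(D₂O)
4.48 / 4.93 / 7.42. Prolines and the N-terminal residue receive no
prediction.

pH\* — the meter reading of the D₂O sample uncorrected for the isotope
effect — is used directly as pD by default, matching how such readings are
reported; an optional +0.4 glass-electrode correction is available
(`apply_glass_correction`) but off by default. Only the H→D regime is
implemented.

## Exchange decay fitting and censoring

Per-amide intensities (scaled by the number of scans per spectrum,
assuming a linear detector) are fit to I_t = I₀·e^(−k_obs·t) by unweighted
nonlinear least squares (lmfit/Levenberg–Marquardt), with standard errors
from the fit covariance. Two starting rates (a log-linear slope and the
first I₀/e crossing) are tried and the better optimum kept, which removes
the local minimum that a near-vanished decay can otherwise fall into.

The noise floor defaults to 3σ with σ estimated from the scaled median
absolute deviation of successive sample differences (differencing removes
the exponential trend; the MAD resists the large steps across day-scale
gaps). Censoring:

* **fast_limit** — the mean of the first three spectra is at or below the
  floor: the amide exchanged before it could be characterized. Its log PF
  upper bound is log₁₀(k_pred·t_first / ln(I₀/I_noise)), the protection at
  which the peak would just have survived to the first observation. With
  the default schedule and rates this bound sits near log PF ≈ 3, i.e.
  amides below that protection are unmeasurable, which is why the
  H-bond/protection comparison uses log PF > 3 as its "measurable
  protection" floor.
* **slow_limit** — the fitted decay over the full window is less than
  `min_decay_frac` = 0.25 of the initial intensity: no significant
  exchange. The lower bound on log PF is the largest measured log PF in
  the same sample — the window cannot distinguish anything slower. The
  0.25 floor is the package's quantification of "no significant exchange";
  it makes a three-month window separate log PF 6.5 (fully measurable)
  from log PF ≳ 7.5 (censored) for typical intrinsic rates, consistent
  with the monomer/heterodimer lower limits of 7 and 8.5.
* **measured** — everything else; PF = k_pred/k_obs and
  ΔG_HX = 2.303·R·T·log₁₀(PF).

ΔG_HX is converted at 298.15 K by default even though exchange is measured
at 294.15 K, because standard-temperature free energies are what the
censoring limits are quoted in (log PF 8.5 ↦ 48.5 kJ/mol, log PF 7 ↦
40.0 kJ/mol); both temperatures are explicit arguments. R = 8.314 J/(mol·K).

## SPR kinetics

The 1:1 Langmuir model: during association at analyte concentration C,
R(t) = R_eq·(1 − e^(−(k_on·C + k_off)·t)) with R_eq = R_max·C/(C + K_D);
after t_a, R decays as e^(−k_off·(t−t_a)). One (k_on, k_off, R_max) set is
fit globally across the concentration series (R_max shared — one surface),
with rates parameterized on a log scale for conditioning. K_D = k_off/k_on
identically; its standard error combines the rate SEs in quadrature of
relative errors, the package's reconstruction of "propagated errors".
ΔΔG = RT·ln(K_D,mut/K_D,ref) at T = 298.15 K (the assay temperature);
this reproduces all 32 published ΔΔG values from the published K_D columns
within the 0.15 kJ/mol that rounding of the printed K_D values allows.
Hot spots are strict ΔΔG > 6 kJ/mol; fold categories bin K_D ratios to the
nearest decade on a log₁₀ scale (~1×, ~10×, ~100×, ~1000×).

Mass-transport limitation, bulk refractive-index jumps and surface
heterogeneity are not modelled — the model class matches the simple 1:1
analysis the data were originally fit with. A fit whose K_D falls more
than 100× outside the analyte concentration range warns, mirroring the
experimental protocol of re-running weak binders at a micromolar series
(0.2–60 nM standard, 20–6000 nM weak).

## Trajectory statistics

Superposition is least-squares rigid-body (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`); tests cross-check it
against a brute-force quaternion minimization. RMSD series superpose each
frame on frame 0 over the chosen selection (backbone 47–123 full, 57–120
core). RMSF aligns all frames on the core backbone to the time-average
structure, iterated twice so the average is self-consistent (the reference
choice is the package's own; it is stable under frame ordering), then
reports per-residue unweighted means over all atoms of sqrt(⟨|r − ⟨r⟩|²⟩).
ΔRMSF between the two chains of a heterodimer is classified three ways at
±0.3 Å. PCA diagonalizes the covariance of aligned selected coordinates
(backbone of core residues by default) and reports eigenvalues, variance
fractions and projections.

H-bond persistence follows the trajectory-mean convention: for every
non-proline amide nitrogen, the two backbone carbonyl oxygens with the
smallest trajectory-mean N⋯O distance are candidates, and the amide is
bonded if the smallest mean is ≤ 3.5 Å (inclusive). The residue itself and
its predecessor (whose carbonyl is covalently adjacent) are excluded as
candidates; this exclusion is a reconstruction of standard practice and
can be disabled (`exclude_adjacent=False`), and a per-frame-minimum mode
(`mode="per_frame"`) is provided because the published description is
ambiguous between the two. The comparison with HX counts a residue as
protected when its measured log PF exceeds 3 or it is a slow-limit
non-exchanger.

## Synthetic data: what it does and does not emulate

* `gen_helix_bundle` builds backbone (N, CA, C, O) geometry by internal
  coordinates: φ = −57°, ψ = −47° inside annotated helices (ideal α-helix;
  mid-helix N(i)⋯O(i−4) ≈ 3.1 Å), fully extended φ = ψ = 180° elsewhere.
  No side chains, no packing — loop behaviour beyond "no H-bonds" is not
  meaningful.
* `gen_trajectory` adds independent per-atom Gaussian displacements with a
  per-residue σ (chain-resolved keys supported), giving exact second
  moments (RMSF = √3·σ) but no correlated collective modes, so PCA on
  these trajectories shows flat spectra by design.
* `gen_hx_dataset` uses the same intrinsic-rate model as the analysis and
  the real acquisition pattern (twelve ~5-min spectra, ~20-min spectra
  back-to-back for ~3 h, hourly to ~24 h, intermittent to 3 months; first
  observation at ~5 min). Noise is additive with σ = noise_frac·I₀
  (default 2%), constant per spectrum, because peak-height noise in an NMR
  spectrum does not scale with the peak — and an absolute detection floor
  is what makes fast-exchanger censoring meaningful. The truth table
  carries each residue's expected censor status derived from k_pred and
  the schedule, plus a `marginal` flag for residues whose noise-free
  signal lies within the noise of a censoring boundary — for those the
  observed status is irreducibly a coin toss, so classification tests
  score only non-marginal residues.
* `gen_scan_dataset` simulates each mutant at the standard nanomolar
  series, switching to the micromolar series when the true K_D exceeds
  60 nM, with Gaussian noise (default 1 RU).
* `gen_shift_tables` perturbs interface residues by |Δδ_H| ~ U(0.1, 0.4)
  and |Δδ_N| ~ U(0.5, 2.0) ppm with random signs against N(0, 0.01 ppm)
  background. Under these magnitudes a single draw clears the 0.2 ppm rule
  with probability ≈ 0.91, so per-seed recovery of a 14-residue interface
  fluctuates; the sensitivity test aggregates 400 seeds.

All generators are deterministic given seed and parameters. Passing tests
on these data demonstrate correctness of the estimators and classification
rules under the stated noise models — not robustness to artifacts the
generators omit (peak overlap, baseline drift, mass transport, correlated
dynamics).

## Problem sizes and other choices

Recovery statistics use problem sizes that keep the full suite fast while
leaving estimator variance far below the tolerances: 100 replicate global
SPR fits, one 81-residue HX dataset per check, 300–500-frame trajectories.
The sequence used throughout is the 86-residue ETV6 construct (residues
40–125, author numbering, never re-indexed); all tables join on author
residue numbers. Heterodimer chain roles are supplied by the caller
(chain-resolved σ profiles, explicit chain pairs to ΔRMSF), not inferred
from sequence. Insertion codes are rejected by the PDB reader; only the
first altloc is kept. Multi-model PDB is the only trajectory format —
portable, text-only; binary-format adapters were deliberately left out.

Known limitations: no EX1/EX2 discrimination and no pD-dependence
experiments in the HX stage; no titration-based K_D extraction from CSPs
(binding in this system is slow-exchange); the MD stage analyses
trajectories but never generates physical ones; PDB output is the minimal
ATOM/MODEL subset.
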