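# Methods

## The measurement problem

Capillary electrophoresis (CE) separates protein species by their effective
electrophoretic mobility. A lysine *charge ladder* — a family of derivatives
of one protein differing by integer numbers of acetylations, each of which
removes one positive lysine charge — turns CE into a self-calibrating net
charge meter: because every rung differs from the next by the same charge
increment ΔZ_Ac, the rung mobilities lie on a line in acetylation number N,
and extrapolating that line to zero mobility locates the point where the
protein's total charge would vanish. No absolute mobility-to-charge theory
(Henry's law, Debye–Hückel) is needed; the ladder is the calibration.

Comparing Z between oxidation states of a redox metalloprotein then
measures the net charge change per transferred electron, ΔZ/e. A bare
electron makes the protein one unit more negative (ΔZ/e = −1, uncoupled
ET); if reduction is accompanied by uptake of one proton, the charges
cancel (ΔZ/e = 0, proton-coupled electron transfer, PCET); two protons give
ΔZ/e = +1 (2PCET). Intermediate values reflect partial charge regulation —
compensatory pKa shifts distributed over the protein's ionizable groups.

## Model and estimator

Effective mobility against a neutral electroosmotic-flow (EOF) marker:

    μ = (L_d · L_t / V) · (1/t − 1/t_eof)      [cm² kV⁻¹ min⁻¹]

with L_d the capillary length to the detector (cm), L_t the total length
(cm), V the voltage (kV) and t, t_eof migration times (min). An analyte
co-migrating with the marker has μ = 0; anions under normal polarity elute
after the marker and have μ < 0 internally (reported magnitudes are a
display convention).

Ladder model: μ_N = c·(Z + N·ΔZ_Ac), with c > 0 an unknown hydrodynamic
coefficient. Ordinary least squares of μ on N over the first `max_rungs`
rungs (default 6; later rungs are low-abundance and more affected by wall
adsorption) gives slope cΔZ_Ac and intercept cZ, hence

    Z = ΔZ_Ac · intercept / slope = −x_intercept · ΔZ_Ac.

c cancels exactly, and with it any run-to-run scaling of the mobilities —
the estimator's key robustness property, verified by test. Each replicate
is analyzed against its own EOF marker and fitted independently; replicate
Z values are aggregated as mean ± sample sd (n−1). A pooled single-
regression mode exists as an option; per-replicate-then-aggregate is the
default because the replicates are technical and their scatter is the
quantity of interest.

ΔZ_Ac is a required, logged analysis parameter (default −0.9). Its
magnitude is below 1 because the acetylated protein partially re-regulates;
all *difference* quantities (ΔZ, ΔZ/e, % regulation) are ratios of two Z
values estimated with the same ΔZ_Ac times that constant, so the redox
conclusions are insensitive to its exact value.

Redox statistics, for an event transferring n_e electrons:

    ΔZ      = Z_red − Z_ox              (sd: quadrature of the two Z sds)
    ΔZ/e    = ΔZ / n_e                  (sd: ΔZ_sd / n_e)
    %CR     = 100 · (1 − min(|ΔZ/e|, 1))   clamped to [0, 100]
    n_H/e   = ΔZ/e + 1;  label ET/PCET/2PCET if within tol (default 0.25)
                         of 0/1/2, else "fractional"

ΔZ is defined as Z_red − Z_ox so that a protein that becomes more negative
upon reduction has ΔZ < 0; this is the convention the measured values
themselves follow. The per-electron uncertainty uses the scaled (÷ n_e)
quadrature sd throughout, which is the only rule self-consistent with the
percent-regulation uncertainty. Values |ΔZ/e| > 1 fall outside the 0–2
proton framework and raise a warning. Reported tables round half away from
zero, two decimals for charges and integers for percents, at the reporting
layer only.

## Henderson–Hasselbalch charge model

Ground truth for simulations comes from a mean-field titration model: each
ionizable group class contributes `+count/(1+10^(pH−pKa))` (bases) or
`−count/(1+10^(pKa−pH))` (acids); metal sites contribute formal integer
charges per redox state (+2/+1 for Cu); acetylations add n·ΔZ_Ac. Group
counts are per subunit and scaled by the subunit count; metal sites are
enumerated per assembly. Default pKa values (Asp 3.7, Glu 4.2, His 6.4,
Cys 8.5, Tyr 10.1, Lys 10.5, Arg 12.5, N-term 8.0, C-term 3.2) are textbook
intrinsic values and overridable everywhere; the model ignores site–site
interactions and conformational pKa shifts, which is sufficient for its
role here (monotone pH trends and redox bookkeeping, not absolute pKa
prediction). Coordinated-solvent and ligand charge redistribution are not
modeled explicitly; they are absorbed into the scenario's proton count.

Proton-coupling arithmetic is exact integers: ΔZ = n_protons − n_electrons
per redox event. A four-site Cu dimer with one proton coupled per electron
gives ΔZ_4ET = 0 — complete charge regulation.

The structural utility counts residues of requested classes (default Asp,
Glu, His, Lys, Arg) with **any atom** within a **closed** radius of a given
center (typically a metal ion coordinate), via Bio.PDB. Published shell
counts of this kind depend on unstated selection conventions (e.g. whether
Ser/Thr near a metal count as ionizable), so exact reproduction of any
particular literature count is not guaranteed; the operation is validated
against an all-pairs brute-force oracle instead.

## Synthetic electropherograms

Each trace is a uniform grid (default 240 points/min over 12 min) carrying
Gaussian peaks (constant σ, default 0.04 min — no tailing physics), one for
the EOF marker (default t_eof = 1.6 min) and one per rung at the time
implied by inverting the mobility equation, plus linear baseline drift
(default 0.005 units/min) and i.i.d. Gaussian detector noise (default sd
0.01 of a unit-height peak). Rung abundances follow a binomial acetylation
model (22 sites, p = 0.10), so heights rise to a mode and decay. Defaults
emulate the studied 4Cu-SOD1 dimer conditions: Z_ox = −6.35, Z_red = −6.44
(ΔZ = −0.09 over 4 electrons), ΔZ_Ac = −0.9, c = 0.93 cm² kV⁻¹ min⁻¹ per
unit charge (placing rung mobilities at magnitudes ≈ 5.9–10), 6 rungs,
6 technical replicates per redox state, 30/20 cm capillary at 29 kV.

Replicate-to-replicate variation has two deliberately distinct components:

- `replicate_jitter` (lognormal, default 1 %) multiplies t_eof, the peak
  amplitudes and the overall mobility scale of a replicate. It reproduces
  the ~1 % run-to-run scatter observed in reported rung mobilities, but it
  cancels *exactly* in the Z estimate (own-marker normalisation and the
  x-intercept's scale invariance).
- `rung_mobility_jitter` (lognormal, default 0.3 %) perturbs each rung
  independently. Being uncorrelated across rungs it propagates into the
  fit and is what sets the replicate scatter of Z, at the few-hundredths
  level technical CE replicates show. An independent per-rung jitter as
  large as the observed mobility scatter (1 %) would imply Z sds of ~0.15,
  three times the scatter actually observed — evidence that real run-to-run
  mobility variation is dominated by a correlated, self-cancelling scale.

What the generator does *not* emulate: peak tailing and wall-adsorption
kinetics, Joule heating, pH-dependent EOF drift within a run, and rung-
dependent peak widths. Passing tests therefore demonstrate correctness of
the estimator under the stated statistical structure, not robustness to
strongly asymmetric peaks; with real traces the detection defaults (below)
may need adjustment, and centroids (not apexes) are already used to reduce
sensitivity to mild asymmetry.

## Peak detection and numerical choices

Detection: moving-average smoothing (5 points) → baseline by rolling
minimum over ≥ 5 median peak widths (the width itself estimated in a
baseline-corrected first pass restricted to prominent maxima, so drift and
noise cannot corrupt it) → local maxima above 5 % of the corrected maximum
separated by at least two median Gaussian σ → per-peak measurement on the
*raw* baseline-corrected signal.

Peak centers are computed by a weighted log-quadratic (Caruana/Guo)
Gaussian interpolation over the contiguous above-half-height region: the
logarithm of a Gaussian is an exact parabola, so for noiseless Gaussian
peaks the center is recovered to machine precision regardless of how the
grid samples the peak — an intensity-weighted moment would carry O(grid
step) discretisation error (~10⁻³ min) and could not support the exact
end-to-end identity the estimator satisfies. In noise the weighted fit is a
standard robust Gaussian estimator; if the fit region is degenerate (< 4
points, non-positive values, non-negative curvature) the intensity-weighted
mean is used as fallback. Rung assignment takes the earliest-eluting peak
as the EOF marker (anionic convention; a "tallest" rule is available),
numbers subsequent peaks N = 0, 1, …, and drops-and-records extras beyond
the expected rung count.

Degenerate inputs: ladders with < 3 rungs or zero slope, traces shorter
than the smoothing window, non-monotone time axes, analytes whose mobility
never reaches the detector, and pH-mismatched redox comparisons all raise
informative errors rather than propagating nonsense.

## Problem sizes and verification

The verification suite runs three tiers, chosen as the smallest sizes that
exercise each claim: exact arithmetic on published-style charge pairs
(instantaneous); noiseless paired experiments (2 replicates × 2 states ×
5–6 rungs) recovering Z to < 10⁻⁶ across different capillary geometries,
hydrodynamic coefficients and ΔZ_Ac; and 20 seeded stochastic experiments
(6 replicates × 2 states each, default noise) whose mean recovered ΔZ lies
within ±0.03 of the true −0.09 and whose per-condition replicate sd of Z
is ~0.05. Oracles are independent re-derivations: normal-equation OLS,
all-pairs distance counting, forward/inverse mobility round-trips, and the
binomial pmf.

## Known limitations

- Rungs must be temporally resolved: geometries where L_d·L_t/V is large
  compress the ladder into a few hundredths of a minute and no detector
  could separate the rungs; the pipeline reports a peak shortfall rather
  than guessing.
- Overlapping peaks (separations ≲ 5σ) bias centroids toward each other;
  the exact-recovery guarantee applies to resolved ladders.
- The Henderson–Hasselbalch ground truth is mean-field; it cannot predict
  which residue accepts the proton in PCET, only the bookkeeping of Z.
- `%CR` is clamped to [0, 100]; events moving more than one charge per
  electron are flagged as outside the framework rather than interpreted.
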