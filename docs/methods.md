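# Methods

## Scope and data model

A SIP experiment is organised as treatments (oxygen condition × labeled
substrate × isotope), each fractionated in up to three *technical*
ultracentrifugation replicates of the same DNA extract — the replication
unit for all uncertainty statements. Per fraction the package consumes a
buoyant density (g/mL) and a qPCR 16S copy total (SQ); sequenced fractions
contribute columns to an ASV × (treatment, replicate, fraction) read-count
matrix. Fractions are canonicalised to ascending density internally; all
downstream statistics are order-independent, but peak detection and reports
need one convention (ties at the copy peak break toward lower density).
Two-well qPCR layouts are averaged at read time; a fraction may lack a copy
total only if it was never sequenced.

Gradient QC mirrors how such gradients are fractionated in practice:
adjacent spacing within 0.005–0.007 g/mL (warn outside), 7–14 sequenced
fractions (warn outside), and the sequenced window must span the SQ-vs-
density peak with at least one sequenced fraction on each flank. These are
warnings, not errors, because real gradients routinely violate them at the
edges.

## Filter cascade

Three stages, in a fixed order, with an auditable ledger (ids and removed-
read fraction per stage, computed against that stage's input reads):

1. list-based contaminants (case-insensitive substring on any rank; default
   blocklist Ralstonia, Variovorax, Streptococcus, user-extensible) plus
   organelle reads (mitochondria, chloroplast);
2. global rarity: keep ASVs with ≥ `min_total` (default 10) reads over all
   samples;
3. per-replicate support: within each treatment keep ASVs with **strictly
   more than** `min_reads` (default 10) reads in *every* technical
   replicate. This stage produces per-treatment inclusion sets only — no
   counts are ever modified, and stage-2/stage-3 thresholds are
   deliberately asymmetric (≥ vs >) to match the conventions the thresholds
   came from.

The per-replicate rule is applied over all sequenced fractions of the
treatment; frequency-model contaminant inference (decontam-style) is out of
scope by design.

## EAF estimation

The chain (copies → weighted density → GC → molecular weights → EAF) is
given in the README. Numerical conventions that matter:

- The GC/density/molecular-weight coefficients are the standard qSIP
  calibration constants; they live in `IsotopeConstants` and are
  overridable, since lab-specific recalibrations exist.
- The unlabeled reference W_light is the per-ASV mean over the ¹²C
  multi-substrate bottle's technical replicates. ASVs absent from every
  unlabeled replicate are excluded (their GC baseline is undefined) with a
  logged reason.
- Negative EAFs are preserved unclamped; the theoretical ceiling
  1 − 0.01111233 is asserted in the simulator, not enforced by clamping.
  Clamping would bias the bootstrap interval criterion.
- The point estimate is the **median** over labeled replicates; the
  bootstrap resamples the labeled and unlabeled replicate sets
  independently with replacement (n_boot default 1000, percentile interval
  at 90%). Whether one resamples jointly or independently is a genuine
  design choice with three replicates either way; the independent scheme is
  declared here and fixed. All bootstraps are seeded; table-level estimation
  iterates ASVs in sorted order from one generator so results are
  independent of input row order.
- Incorporator call: `ci_low > 0`, strictly — an interval touching zero is
  not a call. With three replicates the percentile bootstrap is slightly
  anti-conservative; measured one-sided false-positive rates at default
  noise are ~8–10% against the nominal 5% (see the recovery properties
  below), which is the known cost of bootstrapping n = 3.
- Incorporator relative abundance is computed over the treatment's
  sequenced-fraction samples (mean per-sample proportion, summed over
  called ASVs); pre-fractionation communities are not reconstructed.

## Community statistics

Composite communities pool reads over each incubation's sequenced fractions
(fraction-level ordination would conflate density structure with
composition). Shannon diversity uses natural log. Bray–Curtis
dissimilarities feed classical PCoA (double-centred −½D²; negative
eigenvalues are reported as diagnostics, never corrected) and a one-way
PERMANOVA with seeded label permutations, `p = (1 + #{F* ≥ F}) / (1 + n_perm)`,
or exhaustive enumeration of distinct labelings for small n. NMDS is a
deliberate non-goal: PCoA is deterministic and testable. Cross-substrate
incorporator sets are partitioned into disjoint Venn regions; EAF–EAF
comparisons regress one substrate's median EAFs on another's by OLS
(default pairing: ASVs called incorporators under *both* substrates, with a
`shared` mode for sensitivity analysis), reporting R², adjusted R², the
slope F-test, and a central-subset (rainbow-type) linearity check: fit the
middle ⌈n/2⌉ x-ordered points and all n, and refer
((RSS_full − RSS_sub)/(n − n_sub)) / (RSS_sub/(n_sub − 2)) to an F
distribution.

## Bottle oxygen model

∂C/∂t = D ∂²C/∂z² − R on a vertical column: Dirichlet air-equilibrium top
boundary (the ~160 mL headspace is treated as an unlimited reservoir),
no-flux bottom, uniform zero-order respiration that switches off where
C = 0. Explicit finite differences with D·dt/dz² ≤ 0.5 enforced (default
0.4); snapshots are linearly interpolated in time. Defaults: 12 cm column
(1 L bottle minus headspace), initial 14 μM, boundary 350 μM
(air-equilibrium at ~4–5 °C, salinity ~19; a Garcia–Gordon solubility
helper is provided but the default is a fixed constant for
reproducibility), D = 1.3 × 10⁻⁵ cm²/s (molecular diffusion in cold
seawater; incubations are static, so no turbulent term), grid 0.1 cm
(halving it moves the 48 h volume fraction by < 0.003). The closed form
t = 1000·C₀/R gives the anoxia-onset time of an isolated parcel — 35 h at
C₀ = 14 μM, R = 400 nmol O₂ L⁻¹ h⁻¹.

**Known discrepancy.** With these defaults the volume fraction below the
63 μM hypoxia threshold at 48 h is 0.746 (R = 30) to 0.771 (R = 400), not
≥ 0.80. The often-quoted "80–90% stays hypoxic" figure for such bottles
follows from equating the oxygenated layer with the diffusion length
√(Dt) ≈ 1.5 cm; the full PDE with a 350 μM boundary pushes the 63 μM
isoline to ≈ 2√(Dt) ≈ 3 cm (erfc⁻¹ of 49/336 ≈ 1.03 diffusion lengths),
because the boundary concentration is ~5.6× the threshold. Reaching 80%
would need a taller column or a flux-limited interface; both are outside
this model's declared scope (no gas-exchange kinetics, no headspace
depletion, 1-D uniform cross-section). The package reports what the stated
model yields.

## Synthetic data generator

The generator emulates the analysed study design: 2 conditions ×
{3 ¹³C substrates, a ¹²C multi-substrate reference, a no-substrate
control} × 3 technical replicates, ~20 fractions per gradient. Mechanisms:

- Unlabeled density from GC via the inverse calibration; labeled density
  via the exact inverse of the EAF chain, so generator and estimator are
  exact inverses in the noise-free continuous limit.
- Within-gradient Gaussian band spread σ = 0.004 g/mL (band broadening /
  diffusion), chosen so a taxon occupies ~6–10 fractions as in published
  gradient profiles; expected copies per fraction are the Gaussian mass in
  the fraction's density interval (truncation outside the gradient range is
  warned about).
- Default density range 1.65–1.78 g/mL over 20 fractions (0.0065 g/mL
  spacing, inside the 0.005–0.007 QC band) so that W ± 3σ is covered for
  GC 0.3–0.7 and for strongly labeled taxa.
- Noise: lognormal qPCR error on fraction SQ (CV 0.10), multinomial
  sequencing counts (10⁴ reads/fraction, optional linear depth tilt, or
  deterministic rounded counts for noise-free checks), and a N(0, 0.001
  g/mL) per-replicate shift of the whole fraction grid — the dominant
  replicate-to-replicate variability in real gradients.
- Scenario shapes: `oxic-like` (no taurine labeling; 5 methionine / 13
  glucose utilizers, one shared) and `hypoxic-like` (8 triple-labeled, 3
  organosulfur-only, 5 taurine∩glucose, 7 taurine-only, 10 glucose-only;
  methionine EAFs ≈ 0.6× the taurine EAFs of the same ASVs, mimicking
  taurine preference), plus fully `custom` maps. Contaminant spike-ins are
  density-uniform (reagent background); organelle spike-ins band like real
  taxa.
- Determinism: all draws come from `numpy.random.default_rng` seeded
  through `SeedSequence(seed, spawn_key)` with separate streams for truth
  and dataset, so a fixed seed reproduces bit-identical tables across
  platforms.

What the generator does **not** emulate: read-level errors/chimeras, 16S
copy-number variation between taxa, compositional sequencing biases,
fraction-selection truncation (all fractions are marked sequenced), or
biological replication. Passing recovery tests therefore demonstrate
correctness of the inference chain under the stated noise model, not
robustness to those real-data pathologies.

## Measured recovery properties (defaults, seeded)

Computed by the test suite, not asserted from memory: noise-free round trip
exact to ≤ 0.02 (fraction-discretisation error); RMSE of median EAF ≤ 0.05
over a true-EAF grid {0, 0.05, 0.2, 0.5, 0.95} across 200 simulated
datasets; 90% CI coverage ≈ 0.83 (within the accepted 0.80–0.98 band);
unlabeled-vs-unlabeled false-positive rate ≈ 0.09 over 200 ASVs;
sensitivity ≥ 0.9 at true EAF 0.4.

## Problem sizes

Simulation studies in the tests use 5–200 ASVs, 20 fractions, 3 + 3
replicates and 200–1000 bootstrap iterations — sizes at which the full
suite runs in well under a minute while keeping the binomial error of
coverage/FPR estimates a few percent.
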