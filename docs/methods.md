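# Methods

## Model overview

The package predicts LogBB (log brain-to-plasma partitioning) from the 3D
distribution of a molecule's electrostatic potential (ESP) sampled on a
common grid. The pipeline is: molecular-weight subsetting → field-based
rigid alignment to a subset template → grid-ESP descriptors → PCA →
a small sigmoid network → statistical validation. Each stage is usable on
its own; `alphaq.pipeline.run_subset` wires them together.

## Charge model

The original protocol derives charge densities from ab initio (RHF/6-31G**)
wavefunctions. This package instead uses a classical, pluggable charge
model: each atom contributes a normalized isotropic Gaussian of width σ
(default 0.4 Å, configurable per element), weighted by

* its electron count (`promolecule` mode) — an everywhere-positive proxy
  for the electron density, used for alignment, or
* its signed partial charge (`partial_charge` mode) — used for the
  descriptor ESP; partial charges come from an SDF property or Gasteiger
  assignment.

Externally computed quantum-mechanical fields can be imported via Gaussian
cube files and used in place of either. The algorithmic structure
(alignment objective, descriptors, statistics) is independent of where ρ
comes from.

## Electrostatics

The Poisson equation is solved as ∇²φ = −4πρ in Gaussian-style units
(charge e, length Å), so a unit point charge gives φ = 1/r and E_ij carries
e²/Å. The printed form of the defining equation omits the −4π factor; any
fixed positive rescaling of φ multiplies every E_ij by the same constant
and cannot change an argmax, so alignments are convention-invariant (tested
explicitly).

The default solver is free-space: ρ is zero-padded to a doubled grid and
convolved with the 1/r Green function by FFT; the r = 0 kernel entry is the
quadrature average of 1/r over one voxel. A periodic spectral solver
(φ_k = 4πρ_k/k², zero-mean gauge) is retained for speed. Accuracy against
the closed-form Gaussian potential erf(r/σ√2)/r is ≈0.2% at 1σ–6σ probes
with σ = 4·spacing; the direct Gaussian-smeared Coulomb sum
(`coulomb_direct`) is kept as an independent oracle, never used in the
pipeline itself.

## Alignment

The target is re-centred to the box centre (the translation search absorbs
the centring choice), its density computed exactly once, and each of the
2000 rotamer densities obtained by trilinear re-interpolation of that
field. Rotations come from a deterministic near-uniform Hopf-coordinate
product grid on SO(3) (uniform fiber circle × spherical Fibonacci base,
first element the identity). The translation search is an exhaustive
zero-padded (linear, not circular) FFT cross-correlation over all integer
grid shifts; shifts that push the target's van der Waals envelope outside
the box are masked. Ties break to the lowest rotamer index, then the
lexicographically smallest shift. Reported translations are the total move
(centring plus grid shift), so a target pre-displaced by a grid vector d
reports −d.

Production spacing is 0.106 Å with a 2.7 Å box margin; the test suite runs
the same code at 0.4–0.8 Å on ≤12-atom molecules, which keeps the full
pipeline in seconds while exercising every code path.

## Template selection

For each ordered pair the best cross-correlation E_ij defines
d_ij = ½(E_ii + E_jj) − E_ij, which is half the Coulomb self-energy of the
difference density at the optimal alignment: non-negative, and zero for
identical aligned fields. (The sign is flipped relative to the printed
defining formula, which is ≤ 0 for a positive-definite kernel and could not
serve as a path length.) The two orderings are computed and averaged;
discretization noise below 10⁻⁹ of the self-correlation scale is clamped
to zero.

Betweenness centrality follows the convention: one deterministic weighted
shortest path per unordered vertex pair (Dijkstra predecessor chains), an
indicator f_i = 1 if vertex i is interior to that path, and
C_i = Σ f_i / N_pairs. This differs from the common library convention
(credit split among co-shortest paths, (n−1)(n−2)/2 normalization); the two
coincide when shortest paths are unique, which is the cross-check used in
the tests. The Monte Carlo estimator samples vertex pairs uniformly with
restart and averages the indicator; when the budget covers all pairs it
enumerates them and equals the exact result. Exact computation is the
default at the subset sizes involved (≤ 71 molecules).

## Descriptors

ESP values at every node of the common descriptor grid (0.212 Å default),
flattened x-fastest, form the raw K-vector. PCA is fitted on training-fold
rows only; the number of retained components defaults to the smallest p
explaining 95% of training variance (capped at n_train − 1) and is also
settable explicitly. Components follow a fixed sign convention (largest
absolute loading positive) so projections are reproducible. Out-of-sample
rows are projected with the training mean and components; the model is
never refitted on test rows.

## Regression model

The network is p × M × 1 with M = 3 hidden neurons, logistic activations
and no bias terms; inputs and labels are min-max scaled to [0, 1]
(label extremes map exactly to 0 and 1). The loss is the summed squared
error F with convergence criterion F ≤ 10⁻⁴.

**Optimizer.** Plain full-batch gradient descent with backtracking, even
with step adaptation, plateaus around F ≈ 10⁻² on this loss surface: the
extreme normalized targets (exactly 0 and 1) force partial sigmoid
saturation, and first-order steps crawl there. The loss is a small
nonlinear least-squares problem, so the default optimizer is
Levenberg–Marquardt on the residual vector with the analytic Jacobian,
restarted from seeded random initializations of escalating scale
(0.5 → 8) until the criterion is met; underdetermined cases fall back to a
trust-region reflective solver. Gradient descent is retained as
`optimizer="gd"`. All paths are deterministic given the seed; the recorded
trace of accepted losses is non-increasing.

**A realizability caveat** documented because it shapes the fixtures:
min-max normalization maps the extreme training labels to exactly 0 and 1,
which a sigmoid output can only approach. If labels are generated by an
arbitrary teacher network, rescaling warps the target function slightly out
of the model class and the attainable loss floor sits near 10⁻³. The
teacher-recovery fixtures therefore rescale the teacher's output layer so
its logits span at least ±7 on the sample; its outputs then nearly fill
(0, 1), the normalization is near-identity, and a ≤ 10⁻⁴ solution exists.
Training real labels to F ≤ 10⁻⁴ similarly requires (and the optimizer
delivers) partially saturated weights. Predictions are bounded to the open
training label range by construction — the model cannot extrapolate beyond
the label extremes it saw.

## Validation

* R² = 1 − SS_res/SS_tot about the set's own mean; r²_pred centres SS_tot
  on the training mean. The squared Pearson correlation is exposed as an
  auxiliary output (`pearson_r2_*` in fit reports) since both conventions
  circulate.
* Leverage uses the PCA-projected descriptors, columns centred on training
  means, h = xᵀ(XᵀX)⁻¹x, with h* = 3p/n and p the retained component
  count. Standardized residuals divide by the training residual SD for
  train and test points alike; a point is out of the applicability domain
  if |standardized residual| > 3 or h > h*.
* Y-scrambling permutes a random 10% of the labels among themselves
  (derangement not enforced) and refits the regression on the unchanged
  descriptors.
* Fivefold external cross-validation draws five independent random
  80–85% train splits (not a disjoint partition — the splits are
  "generated at random"), re-selecting the template and refitting PCA per
  training fold in the end-to-end variant; summaries name the best fold by
  R²_test, since per-subset results are conventionally reported as the best
  of the five resamples. Splits are not stratified by LogBB.

## Synthetic data

`alphaq.fixtures` generates neutral molecules (dumbbells, rings, random
clusters of 4–10 Gaussian atoms with zero-sum partial charges) and labels
from a known teacher model — a random 3-hidden network or a linear map —
acting on the molecules' own ESP descriptor projections, affinely mapped to
the LogBB span (−2.69, 1.64) plus optional Gaussian noise. Because the
teacher is known, recovery is measurable exactly.

What the synthetic data does *not* emulate: chemistry. There are no bonds,
no conformational strain, no real charge distributions, and the
label-generating process is by construction a function of the descriptors.
Passing tests therefore demonstrate the correctness and internal
consistency of the machinery (alignment optima, solver accuracy, estimator
convergence, train/test hygiene, the direction of the scrambling control) —
not predictive performance on real LogBB data, which depends on descriptor
fidelity and dataset quality.

Study sizes used by the checks: the scrambling and cross-validation studies
run on a fixed 60-molecule synthetic set (teacher on 3 descriptor
components, label noise 0.05 LogBB, model p = 5); teacher recovery uses
n = 40 samples and p = 10 inputs; generalization checks use n = 50 in 6
dimensions, where the input coverage supports out-of-sample evaluation.

## Numerical choices and degenerate inputs

* Grid: node-centred, 0-based, x-fastest flattening; box dimensions are
  ceil(extent/spacing) + 1 per axis with the margin added to each extent.
* MW bins are half-open (low, high], first bin closed below; bin edges are
  midpoints between flanking order statistics.
* Degenerate cases raise: constant labels (normalizer), all-equal MWs
  (quantiles), empty molecule lists, p ≥ n (leverage), negative distances
  (betweenness). Singular XᵀX falls back to a 10⁻⁸ ridge with a warning;
  a non-negligible density at the box boundary warns.
* All randomness flows through explicit integer seeds; identical seeds give
  bit-identical results end to end.

## Known limitations

* The classical charge model is a stand-in for quantum-mechanical
  densities; absolute descriptor fidelity is limited accordingly.
* Single-conformer, single-tautomer: flexibility and tautomeric equilibria
  are out of scope.
* Predictions cannot leave the training label range (sigmoid output).
* E_ij symmetry holds only to discretization accuracy (≈2% on coarse test
  grids); distances are symmetrized by averaging.
* The no-bias network inherits the representational quirk that the hidden
  pre-activations vanish at the scaled-input origin.
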