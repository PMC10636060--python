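# Methods

## Coarse-grained representation and geometries

A nucleotide is represented by four atoms: the backbone phosphate P, the
sugar atoms C4' and C1', and the glycosidic base nitrogen (N1 for
pyrimidines, N9 for purines).  This resolution carries the backbone trace
and the base direction — enough to define informative inter-nucleotide
distances and orientations — while keeping energy evaluations and test
runtimes small.  Sugar pucker, base-pair edge classification and full-atom
detail are out of scope.

Pairwise geometries between nucleotides i and j are five distances (P–P,
C4'–C4', C1'–C1', N–N, and the asymmetric C4'(i)–N(j)) and five
orientations built on the glycosidic vector: one symmetric dihedral
C1'(i)–N(i)–N(j)–C1'(j), two asymmetric dihedrals (C4'(i)–C1'(i)–N(i)–N(j)
and P(i)–C4'(i)–C1'(i)–N(j)), and two planar angles (C1'(i)–N(i)–N(j) and
C4'(i)–N(i)–N(j)).  Four backbone torsions describe each nucleotide: the
pseudotorsions eta (C4'₋₁–P–C4'–P₊₁) and theta (P–C4'–P₊₁–C4'₊₁), a
glycosidic-frame torsion chi (P–C4'–C1'–N) and a mixed backbone torsion
zeta (C1'–C4'–P₊₁–C4'₊₁).  The atom quadruples are this package's own
choice; all downstream code depends only on the channel counts
(5 distances + 5 orientations 2D, 4 torsions 1D) and class counts.

Distances are discretized into 38 bins of 1 Å on [2, 40) plus a catch-all
class for ≥ 40 Å; dihedrals into 24 bins of 15°, planar angles into 12
bins of 15°, each with one extra no-assignment class used beyond the 40 Å
P–P horizon (2D) or at chain termini (1D).  Two nucleotides are in
contact when their minimum coarse-atom distance is below 8 Å and their
sequence separation is at least 2; the 8 Å value is a configuration
constant, not a fitted quantity.

## Network

The geometry predictor maintains an MSA representation (n × L × c) and a
pair representation (L × L × c').  Each block updates them in four
directions: row-wise gated self-attention with a pair-derived bias on the
attention logits, column-wise gated self-attention and a feed-forward
transition (MSA → MSA); an outer-product mean over rows (MSA → pair);
multiplicative triangle updates, outgoing and incoming, whose input first
passes through a 4-scale 3×3 residual convolution stack to sharpen local
patterns, followed by a pair transition (pair → pair); and attention maps
projected from the pair representation and applied to the MSA rows
(pair → MSA).  Full inference recycles the final pair representation and
first MSA row back into the inputs (layer-normalized, gradients stopped
between cycles).  Heads map the (optionally symmetrized) pair
representation through one hidden layer to per-channel softmax
distributions; the 1D head pools MSA rows by learned softmax weights.
Residual output projections initialize at zero, so an untrained block is
the identity map; gates initialize open (bias +1).

The production-scale setting of this architecture family is 48 blocks
cycled 4 times; the default configuration here is 2 blocks, 1 cycle,
c = c' = 32, 4 heads — sized so a forward pass at L = 32, n = 8 takes well
under a second on one CPU and the tiny-overfit experiment finishes in
minutes.  The network and its training run on a minimal reverse-mode
autodiff engine written on numpy (`cgrna.autodiff`); gradients are
validated against finite differences in the test suite.

Input features: the MSA one-hot over {A, C, G, U, gap} through a learned
linear map; the pair features concatenate mutual information with
average-product correction, the 5×5 joint column frequencies, the pairing
probability matrix, and a relative-position one-hot clipped at ±32.
MI+APC was chosen over mean-field or pseudolikelihood direct-coupling
estimates because it is dependency-free and fast, and the channel feeds a
learned network that can recalibrate it.

## Losses and self-distillation

The loss is `L_2D + L_1D + 5·L_cont` with fixed normalizers 1/(10 L²),
1/(4 L) and 1/L²; masked elements contribute zero without renormalizing,
matching the fixed 1/128 convention of the per-nucleotide confidence
average.  Contact loss is binary cross-entropy on the symmetrized contact
probability.

For self-distillation, the reference distribution P^ref_s is the mean
predicted P–P distance distribution at sequence separation s ≤ 128,
accumulated over a sample of predictions and renormalized.  A pair's
confidence is c_ij = KL(P_ij ‖ P^ref_|i−j|) in nats; a nucleotide's
confidence averages c_ij over the fixed window j = i+1 … i+128 divided by
128 regardless of how many terms exist.  Elements with confidence below
0.5 (raw nats, as printed) are masked out of the distillation loss and
the surviving predicted distributions become soft labels.  Reference rows
with zero mass where a prediction has mass are epsilon-smoothed (1e-8).

Training runs in three phases — real labels; a 1:3 real:distilled mix
per epoch (distilled samples drawn without replacement, seeded); and a
fine-tune restricted to sequences above 100 nt — with Adam at 1e-4 for
the first two phases and 5e-5 for the third.  Sequences are cropped to
150 nt.  Gradients are clipped at global norm 5; without clipping,
small-batch training at desk scale occasionally suffers destructive loss
spikes (observed directly in the overfit experiment).  For toy runs the
schedule's epoch counts, batch size and learning rate are configurable;
the tiny-overfit test uses full-batch steps at lr 5e-3, appropriate for
an 8-sample memorization task.

## Restraints and folding

Selected predicted distributions become potentials
−ln((p + ε)/(p_ref + ε)), ε = 1e-4, tabulated at bin centers and cubically
interpolated.  Tangents are monotonicity-limited (Fritsch–Butland):
log-ratio tables have deep wells beside flat plateaus, and unlimited
cubic tangents overshoot there, carpeting the energy surface with
spurious local minima (this materially degraded recovery before the
limiter was added).  Dihedral potentials are periodic (value and slope
continuous at ±180°); distance potentials are anchored to zero at the
last bin, flat beyond 40 Å, and rise linearly below the 2 Å edge.
p_ref is the by-separation reference distribution when one is supplied,
otherwise uniform over the classes; orientation backgrounds are uniform.

Selection: distance pairs with P(d_P-P < 40) > 0.45; 2D orientations with
assigned (non-catch-all) mass > 0.65; contacts with probability > 0.6 and
separation ≥ 2; 1D torsions wherever defined.  The energy is
`E = 1.03 E_dist + 1.0 (E_ori,2D + L/2 E_ori,1D) + 1.05 E_cont +
0.05 E_int`.  The contact term is a sigmoidal well centred at 8 Å on a
softmin (temperature 0.5 Å) of the 16 coarse atom-pair distances — the
softmin keeps the gradient continuous when the closest atom pair changes.
E_int replaces a full physics force field with harmonic virtual bonds and
angles toward the generator's ideal A-form values plus quartic soft-sphere
repulsion below 3.2 Å between non-bonded atoms (separation ≥ 2); it is
approximately zero for an ideal, clash-free A-form duplex.

Folding builds 20 starting structures — stems extracted greedily from the
pairing matrix at probability 0.5 placed as ideal A-form helices (rise
2.81 Å, twist 32.7°/bp), the rest as seeded self-avoiding walks — then
minimizes each with L-BFGS (memory 10, ≤ 300 iterations per stage) under
a five-stage schedule of (repulsion scale, table smoothing in bins,
orientation scale): (0, 6, 0), (0, 3, 0), (0.2, 1.5, 0), (0.5, 0.75,
0.5), (1, 0, 1).  Two scheduling choices matter and were settled
empirically during development: potentials are Gaussian-smoothed along
the bin axis early (a coarse-to-fine funnel; sharp wells otherwise leave
most starts trapped far from the optimum), and orientation terms enter
only after the distance topology has formed (angular restraints applied
from the start steer minimization into twisted local minima and degraded
recovery even though the true structure is the global minimum).  The
decoy energy reported is always the full-weight energy; the minimizer
returns the best full-energy iterate seen, so a decoy is never worse than
its start.  A final clash-refinement stage re-minimizes with repulsion
×10, restraint terms frozen, and a positional tether (k = 0.05 Å⁻²) that
bounds the move; if the clash count would increase, the unrefined decoy
is kept.  The lowest-energy decoy is the prediction.

## Confidence

pRMSD is the mean pairwise all-coarse-atom RMSD of the ten lowest-energy
decoys.  mp assigns each of the top 15 L pairs (ranked by P(d_P-P < 40))
to the distance bin of its maximum probability — ties broken toward the
lower class, catch-all argmaxes excluded — and averages the per-bin mean
maxima over the 38 finite bins, empty bins contributing zero.  std is the
mean per-pair standard deviation of the 39-class P–P probability vectors;
prop is the fraction of pairs with P(d_P-P < 40) > 0.45.  The estimator
`eRMSD = 0.64 pRMSD − 189.43 std − 4.01 mp − 1.06 prop + 15.2` is
evaluated exactly and may go negative on synthetic oracle input (reported
raw, logged); `refit_estimator` provides ordinary least squares for
refitting inside the toy world.  MSA selection runs the predictor on each
candidate alignment and keeps the argmax of std: sharper, more peaked
distance maps have larger per-vector spread, so higher std reads as the
more informative alignment (direction fixed here as a design decision;
ties break to the lowest index).

## Synthetic data: what it emulates, what it does not

`make_toy_structure` realizes a nested secondary structure in 3D: stems
as ideal A-form helices (paired C1'–C1' ≈ 10.4 Å), loops as steered
self-avoiding walks with a fixed 5.8 Å P–P step, closed against the
stem exit, with a steric floor of 3.25 Å.  `oracle_prediction` converts
the true geometries into class distributions by exact Gaussian bin masses
(CDF differences, so the sharp limit is one-hot), with a per-pair
probability `noise` of replacement by the uniform distribution — drawn
independently for the distance, orientation and contact channel groups,
since each is a separate prediction head in the real model — and contact
probability sigmoid(8 − d_min).  `synthetic_msa` mutates rows at
a per-column rate with 90% compensatory (Watson–Crick/G·U preserving)
substitutions at paired columns and a small gap rate.

The generator reproduces the *structure* of the problem — A-form stems,
chain connectivity, covariation, calibratable prediction quality — not
its physics: loops are random walks, not thermodynamic ensembles; helix
geometry is sequence-independent; pseudoknots are unsupported by the
generator (folding itself has no such restriction).  Passing tests
therefore demonstrate that the machinery (features → network → losses →
restraints → minimization → confidence) is internally correct and that
the pipeline recovers structures when predictions carry the information —
they do not demonstrate predictive accuracy on real RNA, which requires
production-scale training on experimental structures.

Test-condition choices: the recovery experiments use sharp oracles
(σ_dist = 1.5 Å, σ_ang = 18°) on 20–30 nt hairpins with 20 decoys; the
ablation uses weak distances and sharp orientations (σ_dist = 8 Å,
σ_ang = 10°, noise 0.3) folded from unstructured starts, the regime in
which each restraint class contributes distinguishable information; the
distillation-filter experiment fixes σ_dist = 2 Å with the reference
built from an independent oracle ensemble at noise 0.5, emulating a
reference accumulated over a large, lower-quality distillation set.
These were chosen from the failure-mode analysis in development notes
(the KL threshold of 0.5 nats separates corrupted from clean pairs only
when the reference is broad enough at every separation) and then frozen.

## Numerical notes and degenerate inputs

* Frames: collinear C4'/C1'/N raises a degenerate-frame error naming the
  nucleotide; terminal torsions are masked, not errors.
* Distances exactly 40 Å discretize to the catch-all class; values below
  2 Å clip to class 0 (a valid structure cannot produce them).
* Argmax ties anywhere break toward the lower class index.
* The loss uses log-softmax (training) or log(p + 1e-12) (numpy
  predictions); binary cross-entropy uses the softplus form on logits.
* L-BFGS stage convergence uses scipy defaults with ftol 1e-8; a stage
  that stops on iteration count is not flagged as a failure.
* The structure generator retries with derived seeds (up to 80 whole-
  structure attempts) and raises a generation error if a spec cannot be
  embedded clash-free with chain closure.

## Known limitations

* The 2-block default network is a test vehicle; nothing here speaks to
  production accuracy.
* The coarse-grained internal energy is a stand-in for a molecular force
  field; its bonded ideals come from the generator's own helix template,
  so loops carry nonzero internal energy by construction.
* The eRMSD coefficients are meaningful only on realistically soft
  predictions; on synthetic oracles the estimator saturates.
* INF/F1 operate on caller-supplied pair sets; no base-pair annotation is
  derived from 3D coordinates.
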