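# Methods

## The model

`gmshift` estimates the ¹³C chemical shift of a benzenic carbon — a carbon
belonging to an isolated, all-carbon, six-membered aromatic ring — directly
from an atom-tagged SMILES string. The estimator is a *graph machine*: a
parameterized function whose computational graph is isomorphic to the
molecule's 2-D heavy-atom structure.

Construction proceeds in three steps:

1. **Molecular graph.** The SMILES is parsed (RDKit) into a heavy-atom
   graph; hydrogens stay implicit. Supported elements are C, O, N, S, P,
   Si, F, Cl, Br and I; anything else is rejected at parse time.
2. **Rooted DAG.** The graph is oriented toward the tagged carbon by
   breadth-first levels: each bond becomes an edge from the deeper atom to
   the shallower one, so the tagged carbon is the unique sink. A bond
   between two atoms of equal level (possible only in odd rings) is
   oriented from higher canonical symmetry rank to lower, with ties broken
   by atom index — deterministic and acyclic, since a node can have at
   most one same-level outgoing edge. An atom reachable by two paths (a
   ring closure) is a single shared node whose output fans out to both
   parents. Children of every node are ordered by canonical rank so the
   DAG, and therefore every prediction, is invariant under rewriting of
   the input SMILES.
3. **Node function.** One shared single-hidden-layer perceptron (tanh
   hidden units, linear output) is evaluated at every node in topological
   order. Its inputs are a one-hot atom-type encoding (10 elements), the
   atom's valence scaled by 1/4 (valence counts implicit hydrogens and
   rates aromatic bonds 1.5, so an aromatic ring carbon has valence 4),
   and the outputs of its children in canonical order, zero-padded to four
   slots (zero is the tanh-neutral value). The root's output, mapped back
   from the training scale, is the shift estimate in ppm.

### The state channel

The width of the value passed from a child to its parent is configurable
(`state_dim`). With `state_dim=1` the node function is the classical
single-output perceptron (15 inputs; `q = 16h + h + 1` parameters). We
found that this scalar channel is a severe information bottleneck for
atom-level prediction: every subtree must compress the identity and
position of all its substituents into one number, and training stalls far
above the noise floor regardless of optimizer, initialization or restart
budget (see *Known limitations*).

With `state_dim=4` each node emits a 4-vector, the parent reads four
4-wide child slots (27 inputs), and the first component of the root state
is the prediction. For h = 26 this architecture has
26·28 + 4·27 = 836 adjustable parameters — essentially the "834
parameters" regime in which this class of models is known to reach
sub-ppm accuracy on thousands of benzenic shifts — and on our synthetic
benchmarks it trains roughly an order of magnitude more accurately than
the scalar variant at equal h. The CLI and the shipped protocols default
to `state_dim=4`; the scalar form remains available and is the default of
the low-level types.

## Training

All graph machines of a training set share one parameter vector θ.
Training minimizes the sum of squared residuals between scaled
experimental shifts and graph-machine outputs. Targets are scaled to
[-1, 1] over the training range (tanh works in its responsive region;
the `ScalingSpec` is stored with every model).

Minimization is Levenberg-Marquardt on the explicit normal equations:
the batched reverse-mode Jacobian Z (N × q) is assembled in a few dense
matrix operations per composition depth, and the damped system
(ZᵀZ + λI) δ = Zᵀr is solved by Cholesky factorization. Accepted steps
never increase the cost; λ is multiplied by 10 on rejection and divided
by 10 on acceptance. A run terminates when the relative cost drop stays
below 1e-8 for 10 consecutive accepted steps (LM on tanh networks
plateaus and recovers, so a single tiny step is not treated as
convergence), when the gradient norm falls below 1e-10, at the iteration
cap, or — flagged as `failed` — when no acceptable step exists at maximum
damping. Identity damping outperformed Marquardt diagonal scaling on
these landscapes and is the default.

Because the cost surface is multimodal, the standard protocol trains many
restarts from uniform random initializations in [-0.3, 0.3]; per-restart
seeds derive deterministically from a master seed, so entire runs are
bit-reproducible. Restart fits typically plateau within a few hundred
iterations at basin-dependent error levels, so restart count — not
iteration count — dominates final quality; `explore_refine_train`
implements the budgeted variant (many short restarts to find a good
basin, then continued LM on the best).

## Model selection

Refitting N times for true leave-one-out is impractical, so restarts are
ranked by the virtual leave-one-out (VLOO) score

    h_ii = z_iᵀ (ZᵀZ)⁺ z_i        (leverages, clamped to [0, 1 - 1e-8])
    VLOO = sqrt( mean_i ( r_i / (1 - h_ii) )² )

with r_i the training residual in ppm and Z the output Jacobian at the
trained parameters. For linear-in-parameters models this is the exact
PRESS identity (our tests verify agreement with brute-force leave-one-out
to ten significant digits); for graph machines it is a first-order
approximation that is accurate when no single record dominates a
parameter direction (leverages well below 1). The k models with the
smallest VLOO scores form the prediction ensemble (presets k = 25 and
k = 10); the predicted shift is the mean of the member outputs, with
per-sequence means averaged first when several independent restart pools
are combined. A complexity scan repeats the protocol over a list of
hidden-layer sizes and reports best RMSTE, mean/sd of the k smallest
VLOO scores, and timing per row; the appropriate h is the one where the
mean VLOO score stops improving materially.

## Synthetic data

Two generators provide ground-truth benzenic datasets so the pipeline is
testable without any proprietary shift collection:

* **Additive oracle.** Random benzenes are built from a library of ~15
  common monovalent substituents (Me, OMe, OH, NH₂, NO₂, halogens, CN,
  CHO, COMe, CO₂Me, t-Bu, SMe); the shift of a ring carbon is 128.5 ppm
  plus one increment per substituent chosen by its ring position (ipso /
  ortho / meta / para). Increment values are engineering constants in the
  style of classical increment tables; tests depend only on internal
  consistency, never on particular ppm values.
* **Teacher graph machine.** A fixed random node function, calibrated
  once on an internal probe set so its outputs span 100–160 ppm,
  generates targets a student of the same architecture should recover.

Both add i.i.d. Gaussian noise (default experiments use 0.3 ppm, the
order of inter-laboratory reproducibility of assigned shifts) and are
bit-reproducible per seed. One record is emitted per *distinct carbon
environment*: symmetry-equivalent ring carbons share a canonical tagged
SMILES and a single shift, as in experimental tables.

What the generators do **not** emulate: steric twisting of substituents
out of the ring plane (which breaks increment additivity in real crowded
molecules), solvent and temperature effects, assignment errors, and the
long-tailed substituent diversity of curated databases. Passing the
synthetic benchmarks therefore demonstrates the correctness of the
machinery and the trainability of the architecture, not real-data
accuracy.

## Study conditions and problem sizes

The shipped verification protocols are desk-scale by design: 200-molecule
datasets (~1100 distinct carbons), h = 8, `state_dim=4`. Teacher-student
recovery uses 16 restarts × 600 Levenberg-Marquardt iterations followed
by a top-2 VLOO ensemble (held-out RMSE ≈ 0.46–0.49 ppm against a
0.3 ppm noise floor, stable across master seeds); additive learnability
uses a 3 × 800 exploration plus a 2500-iteration refinement of the best
basin (RMSTE ≈ 0.08–0.14 ppm on noiseless data). A production-scale
run — h = 26, 100 restarts on ~10⁴ carbons — is hours of single-core
time and is left to the user via the CLI.

## Numerical choices

* Leverage computation uses a pseudo-inverse with relative cutoff 1e-10
  (rank-deficient Jacobians from over-parameterized restarts) and clamps
  leverages at 1 - 1e-8 so VLOO stays finite.
* Degenerate single-value datasets get a unit half-range scaling.
* VLOO ties are broken by restart order.
* Rejected LM trials are evaluated cost-only; the Jacobian is recomputed
  only for accepted parameters.
* The gradient check compares analytic and central-difference Jacobians
  by max-norm relative error per DAG; the per-component quotient is
  dominated by finite-difference roundoff near zero components.

## Known limitations

* With the scalar state channel, training stalls orders of magnitude
  above the noise floor on both synthetic benchmarks (e.g. ~5 ppm RMSTE
  on noiseless additive data after 12,000 iterations); use
  `state_dim=4`.
* Restart basins vary widely (individual teacher-student restarts land
  anywhere between ~0.4 and ~1.6 ppm training RMSTE); results quoted for
  the multi-restart protocols do not hold for single-restart runs. Even
  the best desk-scale basins sit ~0.1 ppm above the teacher noise floor;
  closing that last gap is a restart-budget question, not a correctness
  one.
* Predictions for molecules outside the training domain — fused
  aromatics, heteroaromatic rings, unseen elements — are computed but
  flagged with applicability warnings; they should not be trusted.
* No per-prediction confidence intervals, solvent corrections,
  stereochemistry, charges or isotopes.
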