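# Methods

## Model class

`udekit` trains universal differential equations (UDEs): coupled ODE systems
whose right-hand side and/or observable mapping is the sum of a mechanistic
term and a feed-forward neural network,

    dx/dt = f_M(t, x, theta_M) + f_ANN(t, x, theta_ANN),    x(0) = x0
    ybar  = h_M(t, x, theta_M) + h_ANN(t, x, theta_ANN),

with known initial state `x0`, bounded mechanistic parameters `theta_M`,
flat network weights `theta_ANN`, and one additive-Gaussian noise standard
deviation per observable estimated jointly with everything else.  The
network enters through an explicit placement: a stoichiometric matrix `B`
maps the network outputs into selected state derivatives (`dx += B f_ANN`),
which is how structural constraints such as the nuclear-export mass balance
are imposed (opposite signs and compartment-volume factors inside `B`).

### Built-in problems

* **Glycolysis** — the seven-species yeast glycolysis oscillator
  (glucose influx, a Hill-inhibited first step with exponent 4, NADH and
  ATP cycling, extracellular exchange).  Free parameters: the eleven
  printed rate symbols plus the conserved adenine total `A` (twelve); the
  NAD(H) total is fixed at 1.  The reference parameterisation is the
  published one (J0=2.5, k1=100, k2=6, k3=16, k4=100, k5=1.28, k6=12,
  K1=0.52, kappa=13, phi=0.1, k_ex=1.8, A=4); it sits on a stable limit
  cycle with period ~1.17.  The shipped initial state is a point on that
  limit cycle, frozen from a converged long simulation.  The hybrid variant
  removes the ATP drain `-k5*A3` and adds a network (all seven states in,
  one output into dA3/dt), leaving eleven free mechanistic parameters.
  Published per-parameter bounds are not available in the main text; the
  package ships synthetic bounds `[ref/5, 5*ref]` per parameter, a
  moderately informative choice representative of kinetic prior knowledge.
  Observables are the directly measured species N2 and A3.

* **STAT5 dimerisation** — the eight-species Epo-stimulated STAT5A/B
  phosphorylation, dimerisation and nucleocytoplasmic shuttling model with
  fixed compartment volumes (V_cyt=1.4, V_nuc=0.45), a decaying stimulus
  `1.25e-7 exp(-Epo_degradation_BaF3 t)`, and three relative
  phospho-ratio observables with specificity constant specC17=0.107.
  Six kinetic parameters are estimated (bounds 1e-5..1e5) plus three noise
  levels.  Four hybrid scenarios: (1) network replaces nuclear pApA export
  under a monomer-conservation placement; (2) network is the entire pApB
  derivative, with the stimulus as an extra input; (3) three augmentation
  species with network dynamics and mass-action export into the monomers
  (adds three export rates, trained in two stages); (4) network replaces
  the third observable.  The published measurement table (16 time points,
  3 observables) and the published maximum-likelihood parameters ship as
  plain-text fixtures; the package reproduces the reference NLL of 138.22
  from them (asserted in the test suite), which validates both fixtures.

## Objective

The negative log-likelihood is `1/2 sum [log(2 pi sigma_s^2) +
(y - ybar)^2 / sigma_s^2]` over records, with `sigma_s` per observable.
(The inner sum is over observables; a per-state reading would be
inconsistent with an observable-level noise model.)  Training minimises
the NLL on the training partition plus a weight-decay penalty
`lambda ||theta_ANN||^2 / n_ANN` (mean-square normalisation, so lambda is
comparable across architectures).  The validation partition is scored with
the plain NLL, without the penalty: the penalty is a training-time device
and including it would make early stopping depend on the architecture
size.  Noise is optimised as `log sigma` (positivity by construction);
mechanistic parameters on the unconstrained tanh coordinate

    theta = b_l + (tanh(rho - a) + 1)/2 (b_u - b_l),

with the offset `a` chosen so `rho = 0` maps to `theta = 1` whenever the
bounds bracket 1 (the zero-to-one anchor of a log transform); otherwise
`a = 0`, placing the bound midpoint at `rho = 0`.

## Optimisation

One start runs ADAM (default 500 epochs, beta1=0.9, beta2=0.999, eps=1e-8)
followed by BFGS up to a total epoch budget (default 3000; one BFGS
iteration counts as one epoch; convergence at gradient norm 1e-8).  The
validation NLL is evaluated every epoch and the best-scoring parameter
vector is retained (early stopping); with no validation partition the rule
degenerates to best-so-far on the training NLL.  Initial noise levels are
set to their closed-form optimum given the initial predictions, which
keeps the starting likelihood finite and well scaled.  Network weights use
Glorot-uniform hidden layers with a zero output layer and zero biases, so
every hybrid model starts exactly at its mechanistic part ("the bias set
to zero" is read as all biases; this is the conservative reading that
still guarantees zero initial network output).

Multi-start runs jointly Latin-hypercube-sample the mechanistic start
values and the hyperparameters (depth 1-4, width 3/5/10, activation
tanh/relu/gaussian-rbf/swish, input normalisation on/off, learning rate
and regularisation strength log-uniform).  Mechanistic starts are
stratified on the tanh coordinate within `a +- 2` (log-like spacing
covering ~96% of the bound interval; the per-parameter sampling scales of
the original study are not published).  "No regularisation" is one extra
level of the lambda dimension with probability `1/(decades + 1)` where
`decades` spans the log-uniform range — the study states no mixture
weight, so "none" is weighted like one more decade; this is configurable.
Each start derives its own seed from `(master_seed, index)` via a seed
sequence, so batches are reproducible and order-independent.  The best
model of a batch minimises the plain NLL over all records used during
training (training plus validation).  Two-stage training (scenario 3)
first fits the mechanistic model alone, then starts the full hybrid model
from those estimates.

Failed simulations (state blow-up beyond 1e6, non-finite values, or an
adaptive-solver evaluation budget of 50k right-hand-side calls) map to an
infinite objective: the start is effectively discarded rather than
crashing the batch.

## Numerics and gradients

Two integration routes coexist.  Simulation and evaluation use adaptive
solvers (explicit Runge-Kutta for the non-stiff glycolysis system, BDF for
the stiff STAT5 scenarios; both selectable), default tolerances rtol=1e-6,
atol=1e-8.  Training uses a fixed-step classical RK4 pass over a grid that
contains every measurement time (default maximum step 0.01 for glycolysis;
the studies here use 0.0075, giving observable-trajectory errors below 1%
against tight-tolerance adaptive reference solutions) and a **discrete
adjoint**: the backward sweep re-walks the same grid accumulating exact
reverse-mode gradients of the discrete loss via hand-derived mechanistic
Jacobians (checked against symbolic differentiation in the tests) and
analytic network backpropagation; noise-parameter gradients are closed
form.  Because the adjoint differentiates the discretised trajectory
exactly, gradients agree with central finite differences of the loss to
solver precision (asserted at 1e-4 relative).  For the glycolysis family a
compiled (numba) kernel implements numerically identical forward/adjoint
sweeps; the plain numpy route is the reference and the two are
cross-checked to 1e-10 in the tests.  The adjoint route does not propagate
gradients through parameter-dependent extra network inputs (the scenario-2
stimulus input); such problems fall back to finite-difference gradients.

## Synthetic data

The generator emulates the glycolysis study grid: the reference model is
simulated once at tight tolerance (rtol=1e-10); observables are sampled on
a uniform inclusive grid of 8/16/31/46/61 points on t in [0, 1.5] (just
over one oscillation) and corrupted with additive Gaussian noise at
5/10/20/35%.  The noise level maps to a single per-observable sigma:
`sigma_s = (level/100) * mean |ybar_s|` over the training window — one
interpretation of "x% noise" consistent with an observable-specific
additive error model; it is configurable and not asserted to be the
original convention.  The noise-free truth is kept on both the training
window and the extrapolation window (1.5, 5] (100 uniform points), where
predictions are scored.  Splits are deterministic: the known t=0 record is
always training and excluded from the split; remaining time points
alternate train/validation (even temporal coverage without randomness),
with the alternation phase chosen to reproduce the fixed counts 8 -> 4:3,
16 -> 7:8, and 1:1 for 31/46/61 (the odd 45-point remainder of the
46-point setting gives the extra point to training).  The measured STAT5
table is split 4:1 by time point (every fifth point to validation; 16
points -> 13:3, the integer realisation of 4:1).

What the generator does **not** emulate: technical replicates, missing
values, non-Gaussian or multiplicative error, non-uniform sampling, and
inter-experiment variability.  Passing tests therefore demonstrate correct
behaviour under the stated noise model, not robustness to real assay
artefacts.

## Evaluation

Prediction quality is the normalised mean absolute error against the
noise-free truth on (1.5, 5]: `mean |y - ybar| / y`.  The printed formula
of the source convention is a double sum; the mean is implemented (the
reported magnitudes support averaging) and the raw-sum variant is exposed.
A fit is successful iff NMAE < 0.15, strictly.  AIC = 2 NLL + 2 n_theta
and BIC = n_theta log(n_d) + 2 NLL use the total free parameter count
(mechanistic + network + noise).  Without test data, models in the 95%
confidence region of the best fit satisfy NLL <= NLL_best + q/2 with q the
chi-squared 0.95-quantile at df=1 (a likelihood-ratio band around the best
model; df is configurable).  Oscillation recovery uses detected peaks on
the dense test grid: sustained means >= 3 peaks with the last
peak-to-trough amplitude at least half the first; amplitude is the mean
peak-to-trough excursion, frequency the reciprocal median inter-peak
interval, and "close to truth" means within 20% (the qualitative
"close" of the source has no printed tolerance; these defaults are
configurable).  Parameter recovery is the sum of squared natural-log
errors; noise recovery the relative sigma deviation.

## Problem sizes used in the checks

The original multi-start studies ran 10,000-30,000 starts at 3000-epoch
budgets on a cluster; the package's studies are scaled-down stand-ins
chosen as desk-scale defaults: 50-100 starts with 500 ADAM epochs and
1500 total epochs.  Under these conditions only a fraction of starts
fit well — the same qualitative picture as the full-scale study — and the
selected best model is not guaranteed to cross the success threshold at
very small budgets.

## Known limitations

* The discrete adjoint assumes the fixed-step grid resolves the dynamics;
  stiff systems (STAT5) are integrated adaptively instead, and training
  them relies on finite-difference gradients, which is practical only for
  small budgets.
* Joint sigma estimation on noise-free data drives sigma toward the
  discretisation-error floor; comparisons on noise-free settings are made
  between runs sharing the same integrator settings.
* Symbolic distillation of trained networks and profile-likelihood
  uncertainty analysis are out of scope.
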