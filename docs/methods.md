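# Methods

This note documents the model, the numerical choices, and what the bundled
synthetic fixtures do and do not establish.

## Membrane model and units

Neurons are passive, isopotential single compartments; all are identical
except for their connectivity and excitatory/inhibitory polarity. The unit
system is mV / pS / pF / s, so currents come out in pS·mV "arbitrary
units". Defaults: C = 1 pF, G_c = 10 pS, E_cell = −35 mV, g = 100 pS per
synapse or gap junction, E_exc = 0 mV, E_inh = −45 mV, β = 0.125 mV⁻¹,
a_r = 1 s⁻¹, a_d = 5 s⁻¹. Integration is forward Euler at dt = 10⁻⁴ s;
synaptic activations are clipped to [0, 1] after each step to guard
explicit-integration overshoot. A single-neuron check against the analytic
exponential confirms first-order convergence.

**Thresholds.** `V_th` is not part of the published parameter set. By
default each neuron's threshold is placed at its own zero-input equilibrium
voltage: with every sigmoid at 1/2, the rest activations are the uniform
`a_r/2 / (a_r/2 + a_d)` and the voltage balance is a single linear solve,
making rest exactly self-consistent (one Euler step leaves it unchanged to
10⁻⁹ mV). Supplied thresholds are honoured instead, with the fixed point
found by alternating the activation equilibrium and the linear voltage
solve. This construction is a documented package choice, not a published
prescription.

**Initial conditions** default to the resting state (configurable). The
synapse-count convention is `Ns[i, j]` = synapses from presynaptic `j` onto
postsynaptic `i`, matching the synaptic sum in which `s_j` and `E_j` belong
to the sender; the file formats document this orientation. Asymmetric
gap-junction tables are symmetrized by averaging reciprocal entries (with a
warning) since published tables vary in dialect.

## Injury model

Swelling multiplies a neuron's membrane area, hence its capacitance and
leak conductance, by `1 + μ m_i`; dividing the coupling currents by the
same factor is algebraically identical (verified numerically in the tests).
Injury vectors draw `m_i` i.i.d. from a swelling-magnitude histogram,
zero the protected set (default: the stimulated input pair), and normalize
to ‖m‖₂ = 1. Spatial structure is deliberately ignored; a per-neuron
weighting hook exists for spatially biased variants. The mean-swelling
identity `μ = (⟨a_i/a_H⟩ − 1)/⟨m_i⟩` averages over non-protected neurons.
The empirical mouse optic-nerve histogram is not available in numeric form,
so the package ships a clearly labeled synthetic log-normal stand-in
(median 0.3, σ_log = 0.5, 30 bins); any user histogram file is accepted,
and results should record which distribution was used.

## Response plane

The plane is the first two left singular vectors of the motorneuron voltage
snapshot matrix, computed on the healthy network after discarding a 5 s
transient and recording 20 s at 1 ms (snapshots are not mean-centered by
default; a centered-PCA switch exists). Mode signs are fixed so the
largest-magnitude component is positive, making stored planes reproducible.
The healthy plane is reused unchanged for every injured projection, so all
orbits share coordinates.

## Attractor classification and μ*

After a 5 s transient, criteria are checked at the end of each successive
5 s window:

* **fixed point** — the trailing window stays within radius 0.01 (plane
  units, roughly three orders below the healthy orbit radius) of the window
  mean; genuinely tiny orbits are deliberately read as rest;
* **periodic** — the post-transient path leaves the 0.01-disc around its
  own final point (a point on the orbit) and revisits it at least twice
  with re-entry-interval coefficient of variation < 0.2, *and* the orbit
  extent is steady (trailing-half RMS ≥ 75% of the leading half). The
  steadiness condition rejects slow decaying oscillatory transients, which
  revisit the disc at constant intervals while shrinking through its scale.
  Re-entries are detected on the sampled polyline (distance from the
  reference to each segment), so a fast orbit cannot step over the disc
  between samples.

Simulation is extended in chunks up to a 60 s cap; a still-undetermined
trajectory is conservatively treated as a fixed point by the pipeline (and
logged) — such cases occur just below collapse, where transients are
slowest, and bias μ* at most by the bisection tolerance scale.

μ* is bracketed by doubling from μ = 1 and bisected to a relative bracket
width of 10⁻³, balancing precision against simulation cost. Amplitudes below collapse are sampled
at 5 interior points of (0, 0.9 μ*) and 10 of (0.9 μ*, μ*).

**Period estimation** uses the autocorrelation of the centered plane
coordinates (FFT-based; peak picked on the tapered estimate, refined on the
unbiased one with parabolic interpolation). A Poincaré section through the
orbit centroid — the more familiar choice — fails on injured crescent
orbits that do not enclose their centroid, which arise routinely at
intermediate μ; the autocorrelation estimator is geometry-free, agrees with
the re-entry intervals of the classifier, and is accurate to ~0.5% on
analytic cycles (exact on circles).

## Shape analysis

One full period (sliced by estimated period from the trajectory tail) is
resampled to N = 200 points with a periodic cubic spline on the
chord-length parameter; PD is stable to <1% for N ≥ 100 on smooth cycles.
The Procrustes solution is closed-form (SVD of the centered
cross-covariance); reflections are excluded (det R = +1) but both traversal
directions are searched during phase alignment, since reversing traversal
is not a plane rotation. The reported PD is the standardized dissimilarity
`1 − tr(Σ)²/(‖A_c‖²‖B_c‖²)` — symmetric, zero iff the shapes are
similarity-equivalent, and identical to the statistics-toolbox convention;
the raw minimized residual is also returned. The scaling factor `b` is the
factor taking the healthy cycle onto the injured one (< 1 for shrunken
cycles). Translation is reported as the displacement of the injured-cycle
mean from the healthy-cycle mean, which makes the healthy-vs-healthy curve
identically zero (the plane origin is arbitrary under uncentered SVD).

Deficit curves are averaged per endpoint class after normalizing each
curve's μ axis by its own μ* and (PD only) its value axis by its maximum;
scaling and translation are averaged on their raw scale, where their
monotone trends are the object of interest.

## Endpoint classes and trees

Endpoints are mean-centered, the leading principal axis taken by SVD, and
projections ≥ −0.01 labeled *upper*. Whether the original procedure
centered the cloud is ambiguous; both variants are implemented
(`center=False` for raw projections) and the threshold is exposed.

The CART learner is written in-package so that its behavior is fully
deterministic: exhaustive search over per-feature midpoint thresholds,
Gini-impurity decrease, ties broken by lowest feature index then lowest
threshold, minimum leaf size enforced on every split, leaf labels the
lexicographically smallest majority class. Tests verify exact structural
agreement with an independently written exhaustive-search oracle and
accuracy parity with scikit-learn's tree on learnable data. Cross-validation
uses seeded uniform (unstratified) fold assignment; shuffled-label
baselines permute labels per trial with per-trial seeds. The study-scale
minimum leaf size is 40; small ensembles shrink it to K/10 so that a tree
can grow at all.

## Behavioral map

An affine map (2×2 matrix plus offset; a pure-linear variant exists) is
least-squares fitted from the healthy cycle to the unit circle at matched
uniform phase, then applied unchanged to every trajectory. The relative
rotation between the neural plane and the posture plane is unknowable from
the neural side; it defaults to identity and is exposed as a calibration
angle. PD is always computed in the neural plane: the map is affine, and
Procrustes distance is similarity- but not affine-invariant (tested). The
bundled two-mode posture basis is a synthetic quadrature sinusoid pair,
labeled non-biological; real eigenworm modes are user-supplied as a CSV.

## Synthetic fixtures: what they do and do not show

* **Oscillator motif** (frozen constants): two excitatory sensory neurons
  driving a 3-neuron inhibitory ring with deliberately unequal synapse
  counts (10/12/9 ring, 5/6/4 drive), β = 1 mV⁻¹ and input 5 arb. units.
  At five neurons the network gain available at the published β cannot
  sustain oscillation, so the fixture uses a steeper sigmoid; the ring's
  asymmetry removes the rotation-symmetric invariant subspace so the cycle
  self-starts from exact rest. It yields a ~1.47 Hz, ~10 mV limit cycle
  that collapses at μ* ~ 20–35 under random injuries — qualitatively the
  full network's phenomenology at desk scale. Passing fixture tests shows
  the *machinery* (plane, bisection, shape analysis, classification) is
  correct; it says nothing quantitative about the real connectome, whose
  reproduction requires the tables referenced in `configs/full_study.yaml`.
* **Planted ensembles**: injury-like feature matrices whose labels follow
  an axis-aligned two-driver rule plus optional label noise (Bayes error =
  the noise rate; expected upper fraction `(1−q²)(1−p) + q²p`). They
  calibrate the classification stage's power — CV error well below the
  shuffled baseline, driver recovery — under a known ground truth, which
  the real ensemble never provides.
* **Analytic trajectories** (circles, ellipses, spirals, fixed points) give
  the attractor and shape stages closed-form expected values.

## Reproducibility

Every stage is a pure function of (inputs, config, seed). Per-injury child
seeds derive from the master seed by counter (`SeedSequence((seed, k))`),
so growing an ensemble never perturbs earlier injuries. Ensemble runs
checkpoint each injury keyed by a config hash and resume bit-identically;
per-injury failures are flagged gaps, not aborts. The acceptance script
runs the oscillator ensemble at K = 8 and the planted analog at K = 50
(100 shuffle trials) — sizes chosen so the whole reproduction completes in
well under a minute while leaving the statistics stable.
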