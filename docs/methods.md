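# Methods

`nemagrn` implements a complete workflow for inferring a preliminary gene
regulatory network (GRN) for gut formation in an early sea-anemone embryo
from two-dimensional gene expression images: quantification of spatial
expression into standardized profiles, correlation clustering and gene
selection, ensemble fitting of a gene-circuit ODE model, and derivation of a
signed regulation network from the fitted parameter ensembles.  This note
documents the models, the defaults and the design decisions, and states
precisely what the synthetic data generator does and does not emulate.

## Morphologies and quantification

A *morphology* is the averaged outline of the embryonic cell layer at one
stage: closed outer (ectodermal) and inner (endodermal-facing) loops in
pixel coordinates, plus an index marking the oral pole.  Landmark
correspondence between samples (equal point counts, aligned oral anchors)
is a precondition of averaging and stage interpolation, not something the
package solves: in practice those landmarks come from manual annotation,
and automated segmentation of low-contrast embryo images is out of scope.
Averaging is the point-wise mean; interpolation between stages is linear in
the corresponding points.  Loops are stored counter-clockwise from the
aboral pole, with images assumed oriented oral-right (a `flip` option
mirrors profiles quantified from oppositely oriented images).

Quantification decomposes the band between the loops into quadrilateral
segments of approximately a user-chosen width by pairing equal-arc-length
resamplings of the two loops.  Per segment, the mean intensity of a chosen
color channel is taken over pixels whose centers fall inside the segment
polygon; a segment containing no pixel centers is flagged missing rather
than silently zeroed.  Which channel carries the stain varies between
image sources, so the channel is a required user choice.

The raw trace is edited by deterministic, logged rules replacing the manual
clean-up that image curators normally apply: background subtraction (default
the 5th percentile of the trace), masking of stated segment ranges (filled
by circular linear interpolation from neighbors), and an optional circular
moving average (off by default).  Reproducibility is preferred over fidelity
to any particular manual edit.

The edited trace is standardized: circularly rotated so the oral pole lands
at segment 50 of 100, linearly interpolated at 100 equidistant points, and
scaled to unit maximum (identically-zero profiles are passed through).
Anchoring fixed anatomical points to fixed profile positions compensates
for inhomogeneous tissue expansion during gastrulation; unit scaling removes
the arbitrary intensity scale of staining reactions.  Both conventions mean
absolute expression levels are not comparable between genes or stages, which
propagates into the fitting objective (below).

## Clustering and gene selection

Profiles are compared with the Pearson correlation distance `1 - r` and
clustered with unweighted average linkage (UPGMA, via
`scipy.cluster.hierarchy`); cutting the dendrogram at linkage distance 0.6
separates the characteristic spatial classes (central endodermal domain,
oral-pole peaks, narrow border peaks).  A constant profile has no defined
correlation and is rejected by name rather than mapped to a conventional
distance.  Genes are then partitioned into four groups: present at the
cleavage stage; absent at the gastrula stage; and, for the rest, by whether
their planula-stage cluster is endodermal or oral.  Stage names are derived
from hours post-fertilization at 16 °C when not given (cleavage < 10 h,
blastula 10–20 h, gastrula 20–48 h, planula ≥ 48 h).  One representative
gene per group — the one with the most profiles, ties broken
lexicographically — is selected for simulation.

## Gene-circuit model

The dynamic model is the connectionist gene-circuit formalism on a
one-dimensional chain of cell-layer points `a`:

    dP_i^a/dt = R_i s(sum_j T_ij P_j^a + m_i P_mat^a + h_i)
                + D_i (P_i^{a-1} - 2 P_i^a + P_i^{a+1})
                - lambda_i P_i^a,      s(f) = 1/2 + arctan(f)/pi

with interaction matrix `T`, maternal influence `m` of a constant maternal
gradient, constant influence `h`, production rate `R`, diffusion `D` and
decay `lambda` (per hour).  The fitted, simplified model fixes `R = 1` and
`D = 0`, leaving `n(n+3)` free parameters for `n` interacting genes (18 for
the 3-gene system) instead of the full `n(n+5)` (24): with unit-normalized
targets the production rate is confounded with decay, and a physically
meaningful diffusion term on a growing, curved cell layer would have to be
time dependent.  The full parameterization remains available, and a small
uniform diffusion shared by all genes can be enabled as a smoothing
alternative to omitting diffusion entirely.  With `D = 0` the spatial points
are mathematically independent ODE systems; diffusion, when on, uses a
no-flux discrete Laplacian.

Integration uses an adaptive explicit Runge–Kutta scheme (`solve_ivp`,
RK45) at `rtol 1e-6 / atol 1e-9`; the vector field is smooth, bounded
(`0 < s < 1`) and non-stiff over the fitted parameter ranges, so adaptive
control is cheap insurance rather than a necessity.  Trajectories from
non-negative states stay non-negative and below `R/lambda`; the solver's
round-off-scale undershoots are clipped at zero.

## Objective and normalization

The fit minimizes the root-mean-squared difference between simulated and
reference profiles over all (gene, target time, segment) triplets,
optionally weighted per gene.  Because reference profiles are unit-
normalized, both simulation and reference are re-normalized to unit maximum
per gene per time point before differencing — except when the reference is
identically zero ("no observed expression"), in which case the raw
simulated concentrations are compared against zero so that spurious
expression is penalized.  One consequence, inherited from the data's
normalization, is that only the signs of interactions are identifiable, not
their strengths.  A `raw` mode (no normalization) is kept for ablation.
Simulation failures inside the search return a large finite penalty (10×
the worst feasible objective seen, floor 1e3) so ranking stays meaningful.

## Scatter-search estimation

The global optimizer is a scatter-search metaheuristic modeled on enhanced
scatter search (eSS), re-implemented from its published description at
simplified fidelity and with local search deliberately absent: a Latin
hypercube of `10 × dim` points seeds a reference set of 10 solutions
balancing quality and diversity; all pairs are combined by sampling in
quality-biased hyper-rectangles; a go-beyond step keeps extending
improving directions with doubling steps; the reference set is refreshed by
quality with a minimum-separation guard, and rebuilt from a fresh Latin
hypercube around the retained incumbent (an in-run restart) after 10
consecutive non-improving iterations.  Every run is fully determined by its seed and
stops exactly at its evaluation budget (default 10,000).  The optimizer is
pluggable behind a plain `f(x) -> float` interface, so an independent
backend (e.g. differential evolution) can cross-check results.

Parameter bounds: `T, m, h` in `[-5, 5]` — the sigmoid saturates beyond
inputs of magnitude ≈ 3, so wider bounds add no expressiveness — and
`lambda` in `[0.01, 1]` per hour, which keeps steady states of order 1–100
and dynamics resolvable over the 50-hour window.  An ensemble repeats the
search from seeds `seed + 0 .. n-1` (default 100 runs); runs are
independent, order-stable, and individually fallible without aborting the
ensemble.

## Network inference

For each interaction parameter (`T_ij` and `m_i`), the fractions of
ensemble best fits in which it is strictly positive / strictly negative /
exactly zero are computed (zeros count toward neither sign).  An activation
edge enters the network when the positive fraction reaches the consistency
threshold (default 0.9), an inhibition edge when the negative fraction
does.  Maternal influences participate in edge inference, yielding edges
from the maternal gene.  Raising the threshold can only remove edges.
Per-parameter ensemble means and standard deviations (n−1 denominator) are
reported alongside.

## Sensitivity analysis

A parameter's sensitivity is the highest, over genes, of the cell-layer-
averaged absolute derivative of concentration with respect to the parameter
at an evaluation time (default: the last fitted time, 50 h; the absolute
value makes the quantity comparable across parameters of either sign).
Two methods are implemented and cross-validated against each other: central
finite differences with step `max(1e-4, 1e-4 |theta|)`, and forward
sensitivity ODEs integrating the variational equation jointly with the
model.  Sensitivity simulations run at tightened solver tolerances
(`rtol 1e-10`) so finite-difference quotients are not dominated by
integration error.  Sensitivities are not additionally averaged over time.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline needs, with known ground
truth:

* **Profile templates** are sums of Gaussian bumps on the 100-segment axis,
  chosen to match the observed cluster geometry: endodermal (bump at
  segment 50, sd 6), oral (bumps at 35 and 65, sd 3), border (bumps at 40
  and 60, sd 1.5) and a broad central maternal gradient (bump at 50,
  sd 20).  The real maternal gradient's exact shape is not published beyond
  being a broad gradient; the synthetic one is a stand-in, not a
  reconstruction.
* **Noisy profiles** add i.i.d. Gaussian noise (default sd 0.05), clip at
  zero and re-normalize — the simplest model consistent with
  stain-intensity noise.  The default gene panel mirrors the observed
  grouping (maternal-group genes present from cleavage; endodermal and
  oral genes from gastrulation; late border genes only in the planula) with
  profile counts chosen so each group's representative is unambiguous.
* **Rendered embryo images** paint a known staining profile into the
  cell-layer band of an idealized annular morphology, providing exact
  round-trip validation of quantification (peak positions recovered within
  ±3 segments at low noise).
* **Circuit-derived references** simulate a known parameter set from zero
  initial conditions and apply the same normalization as the objective, so
  the generating parameters score exactly zero.

What passing tests on these data do *not* show: robustness to real
micrograph artifacts (uneven illumination, annotation overlays, stain
dispersion in older images), to morphology adaptation error, to
between-laboratory staining differences, or to the strong imbalance of
profiles per gene in curated collections.  The synthetic noise is spatially
white; real staining noise is correlated along the layer.

## Problem sizes in tests and demonstrations

The test suite and the acceptance script use scaled-down study conditions
chosen to exercise every stage end to end: parameter-recovery experiments
use a 2-gene circuit with strong interactions (|T| = 4.5, near the bounds)
on 30 spatial points with 20 searches of 2,000 evaluations; the end-to-end
demonstration fits 3 genes on reduced spatial grids with small ensembles.
The full-scale protocol (100 runs × ≥10,000 evaluations on 100-point
profiles) is the package default (`FitConfig`, `run_ensemble`) and runs
unchanged, just longer.

## Known limitations

* Landmark correspondence and morphology adaptation are preconditions, not
  algorithms; no image segmentation is provided.
* Edge strengths are not calibrated — normalization erases them by
  construction; only signs and their ensemble consistency are reported.
* The clustering heuristic that labels a cluster endodermal / oral / border
  from its mean profile is tuned to the synthetic template geometry; real
  data may need an explicit label mapping.
* The eSS re-implementation follows the published algorithm sketch, not any
  specific software release; run-for-run traces will differ from other
  implementations even at equal budgets.
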