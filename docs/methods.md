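# Methods

## The model

The pipeline treats classifier performance as a growth process over
training data. For a taxon with performance points (t, F1) — t the number
of training observations per species — the Von Bertalanffy growth function

    L(t) = L_inf (1 − e^{−k (t − t0)})

is fitted by least squares to the mean F1 per task size. L_inf is the
asymptotic F1 the taxon would approach with unlimited data, k the
per-observation growth rate, and t0 the hypothetical size at which F1
would be zero (typically negative: even one observation per species beats
zero performance). The choice of this saturating form assumes diminishing
returns in training-set size, which both transfer-learned image
classifiers and the synthetic proxy classifier exhibit; it makes no claim
about the mechanism, only the shape.

The value of information (VoI) of one additional image-bearing observation
in taxon x is

    VoI(x) = L'(t_avg) / s_x,      L'(t) = b k e^{−k t},  b = L_inf e^{k t0}

with t_avg = n_x / s_x the taxon's current average image-bearing
observations per accepted species and s_x its checklist species count. The
division by s_x reflects that a single new observation documents one of
s_x species, so its expected benefit to the taxon-average F1 is diluted
accordingly. Two simplifications are accepted deliberately: t_avg (raw
availability per species) is substituted into a curve fitted over curated
training counts without correcting for the test-set holdout, and s_x is
the full checklist count including never-photographed species. Both follow
the definition of the statistic as an expected taxon-level average; a
holdout correction would rescale t_avg by roughly 200/220 and does not
change any qualitative ordering we examined.

Relative representation uses R_x = n_x − n·s_x/s with totals computed over
exactly the taxa supplied, so the analysis universe (all classes, or the
selected orders) is always an explicit caller decision. Records lacking
the analysis rank are excluded from both n_x and n, with a logged count.

## The experimental design

Defaults are the design constants: eligibility at ≥ 220 image-bearing
observations per species (so ≥ 20 remain as test data beside the
200-observation base task), 17-species windows, 9:1 train:validation, five
runs per taxon, reduction to a minimum of 10 observations per species.

Two points in the protocol admitted more than one reading and were fixed
as follows:

* **Reduction rounding.** Each step discards `floor(n/4)` — exactly 25%
  when divisible by four, slightly less otherwise. This is the unique
  simple rule that yields the task sequence
  200, 150, 113, 85, 64, 48, 36, 27, 21, 16, 12.
* **Validation size under reduction.** Shrinking training and validation
  sets independently by the floor rule cannot reproduce those combined
  totals (e.g. 135 + 15 = 150 but 102 + 12 ≠ 113). Instead the combined
  size follows the schedule and validation is `floor(size/10)`,
  train the remainder, both drawn as nested uniform subsets of the
  previous task. This keeps the validation fraction ≤ 10% at every size
  and makes consecutive tasks strictly nested.
* **Taxon-level choice.** Among ranks yielding ≥ 12 taxa with eligible
  species, the rank whose best 12 taxa have the largest minimum
  eligible-species count wins; ties go to the coarser rank (never
  exercised by the default data).
* **Species windows.** Species sort case-insensitively on the
  concatenated kingdom→species path, which makes congeners contiguous;
  the window start index is uniform with wraparound. Runs draw fresh
  seeds but window collisions between runs are not forbidden.
* **Test assignment** is uniform at observation granularity (no
  stratification); all images of an observation stay in one subset.

Seed policy: one master seed; per-run (window, split) seed pairs are
derived via a `SeedSequence` keyed on the master seed, a stable hash of
the taxon name and the run index, and stored in the manifest. Regeneration
from the stored pair alone is bit-for-bit identical, verified by byte
comparison of the serialized manifests.

## F1 aggregation

Per-class confusion counts are combined as macro-averaged F1 by default:
test sets are near-balanced by construction (≥ 20 observations per
species) and macro matches the robustness-to-imbalance rationale for
using F1 in the first place. Micro averaging is provided for sensitivity
analysis; no result in the test suite depends on the choice.

## Fitting details

Deterministic trust-region-reflective least squares (scipy), tolerances
1e-12 on cost, parameters and gradient. Initialization is data-driven:
L_inf⁰ is the maximum observed mean F1 (≤ 1), k⁰ comes from a linear
regression of log(L_inf⁰ − F1) on t, t0⁰ = 0. Bounds:
L_inf ∈ (0, 1.2] — deliberately above 1 so fits near a perfect classifier
are not biased by the boundary, with a logged warning when the estimate
exceeds 1 — k ∈ (1e-6, 10], t0 ∈ [−10·max t, min t]. On non-convergence a
fixed three-value grid of growth-rate starts (0.005, 0.02, 0.1) is tried
and the best kept; the convergence flag is reported honestly either way.
Constant-F1 input is flagged as degenerate (k unidentifiable) rather than
fitted silently. Noiseless curves generated at the 11 schedule sizes are
recovered to better than 1e-6 relative in all three parameters.

## What the synthetic data emulates — and what it does not

`SyntheticConfig` defaults plant 12 orders with 18 eligible species each
(plus below-threshold species, checklist-only species, and a few
background orders with no eligible species), so eligibility filtering and
the order-level choice are exercised in both directions. Per-species
image-bearing counts are threshold plus a discretized log-normal
(mu = 3, sigma = 0.8), reproducing the right skew of citizen-science
abundance data; images per image-bearing observation follow a geometric
distribution truncated to {1..17} (median 1, mean ≈ 1.4, long right
tail), and 20% of records carry no image. Planted per-order curve
parameters spread L_inf over 0.70–0.95 and k over 0.012–0.040, giving
visibly distinct learning curves.

Performance is emulated either by drawing F1 directly from the planted
curve plus Gaussian noise (sigma 0.02 by default, clipped to [0, 1] on the
raw scale — simpler than a logit-scale model, and the fitter must tolerate
boundary-clipped points anyway), optionally expanded into integer
confusion tables whose macro-F1 is within half a count of the drawn value;
or by actually training a nearest-centroid classifier on synthetic
Gaussian feature vectors, whose curves rise with task size and saturate at
a level set by the class separability.

Passing tests on this data demonstrate that the machinery is correct:
formulas match their oracles, protocols satisfy their invariants, planted
parameters are recovered at the stated noise. They do not demonstrate that
real recognition models follow a Von Bertalanffy curve, that real
abundance distributions match the log-normal defaults, or anything about
any particular real dataset — the published per-order curves depend on
large GPU-trained models and a full national data download, and are out
of scope here.

## Problem sizes

Default verification sizes: the full design (12 orders × 5 runs × 11
tasks) for combinatorics and protocol invariants; 100 simulations of
5 replicates × 11 sizes at sigma = 0.02 for parameter recovery (mean
absolute L_inf error comfortably below 0.05); a 108-point parameter box
for the analytic-vs-numerical slope check, using complex-step
differentiation because real-step finite differences lose all precision
where k·t is large. The full pipeline plus the acceptance script completes
in a few seconds on one CPU.

## Known limitations

* No confidence intervals on fitted parameters or VoI (a bootstrap over
  runs would be the natural extension).
* No alternative growth laws (logistic, power law) for model comparison.
* The proxy classifier is a caricature of a CNN; it shares only the
  qualitative size–performance relationship.
* Checklist-based s_x assumes the checklist and the observation taxonomy
  agree on names; no synonym resolution is attempted.
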