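# Methods

## Model

`chipabm` simulates the migration of peripheral-blood leukocytes toward
doxorubicin-treated MDA-MB-231 tumor cells in the filmed sub-region of a
microfluidic co-culture chip, and estimates the model's free parameters
from leukocyte-tracking data by sequential Monte Carlo approximate
Bayesian computation (ABC-SMC).

### Chip lattice

The filmed region is a rectangle of Lx × Ly = 1707 × 1452 µm discretized
into 12 µm squares.  Horizontally it splits into a left chamber (676 µm),
a microchannel section (500 µm) and a right chamber (531 µm); each width
is independently rounded **up** to whole columns (57 + 42 + 45 = 144), so
the modeled width slightly exceeds the physical one.  Vertically, 31
channels one row high alternate with 30 interspaces of ceil(33/12) = 3
rows, giving 121 rows.  Interspace rows within the channel-section columns
are obstacles (occupancy −1): no agent may sit there and no chemoattractant
flux crosses them (no-flux walls).  Grid squares are addressed 1-based,
row 1 at the top; cell centers carry physical coordinates with y
increasing upward.

Partitions for summary statistics: 10 vertical column bands ("bins", the
remainder columns when `n_col % 10 != 0` are assigned to the *rightmost*
bins so the heavily weighted bin 1 has a fixed width) and a 3 × 3
"quadrants" partition with row/column remainders pushed down/right,
numbered row-major from the top-left.

### Annexin A1 field

Tumor cells release annexin A1, which diffuses and is eliminated:

    dA/dt = k_A · N_C(x,y,t) + D ∇²A − k_XA · A,   A(·,0) = 0.

The explicit lattice step (default, "conservative-share") sends
`D·A(p)/d_n` from each square to each admissible Moore neighbor
(d_n = 1 orthogonal, √2 diagonal, measured in grid units) and removes the
total sent; production `k_A·N_C·dt` applies only on tumor-occupied
squares, elimination `k_XA·A·dt` everywhere.  With sources and sinks off
this scheme conserves total mass to floating precision.  A "literal"
scheme reproducing the printed neighbor update verbatim (neighbor receives
`A(p)/d_n` undamped) is selectable; it creates mass and exists only for
fidelity experiments.

Stability: the update coefficient of A(p) must stay nonnegative, so the
step requires `k_XA·dt + D·max_p Σ_n 1/d_n ≤ 1` (the max is 4 + 2√2 ≈ 6.83
on interior squares).  This combined bound is slightly stricter than
requiring each term separately but is what actually guarantees
nonnegativity of the explicit step.

### Leukocyte movement

A leukocyte at square p moves within its extended Moore neighborhood
N̄(p) = N(p) ∪ {p}, restricted to in-grid, non-obstacle squares (and, by
volume exclusion, channel squares not already holding another leukocyte —
a leukocyte radius of 4 µm in a 12 µm channel admits one cell per square;
chamber squares allow co-occupancy).  With

    TA = Σ_{q∈N̄(p)} A(q)^λ,    P_MT = exp(−γ·TA),

the landing distribution is `P(q) = P_MT/|N̄(p)| + (1−P_MT)·A(q)^λ/TA`,
which sums to one by construction.  γ is the annexin sensitivity
threshold; λ the chemotactic exponent amplifying relative concentration
differences.  Conventions: `0^0 = 1` so λ = 0 yields an exactly isotropic
walk on any field; if TA = 0 the distribution is uniform.

A consequence worth knowing when designing experiments: because A^λ
*shrinks* with λ wherever A < 1, a chemoattractant field that stays far
below one unit makes large-λ walkers effectively blind (γ·TA → 0 restores
the isotropic walk) and inverts the intended meaning of λ.  λ behaves as
"chemotactic strength" only where the field reaches order-one
concentrations — see *Synthetic world* below.

### Leukocyte–tumor interaction

A tumor cell reached by a leukocyte (same square after the move) has its
biological age advanced by `k_TL·(age_c/L_c + 1)`: older cells receive
larger increments, accelerating death (at age_c > L_c).  Every step of
co-occupancy counts as a contact, and several leukocytes can hit the same
cell in one step (applied once each, in seeded shuffled order — the update
does not commute exactly, so the order is randomized but reproducible).

### Simulation loop

Each step of `dt = 4` min executes spawn → field step → moves (seeded
shuffled order) → contacts → aging/death.  The full horizon is 2880 min
(720 steps); the video covers the second half, so frames are recorded at
every step from `video_start = 1440` min on.  Video frames are 2 min
apart; at dt = 4 min, odd video frames are carried forward from the
previous step (the evaluation frames, every 40 video frames = 80 min,
always align exactly).  Leukocytes accrue in the rightmost half of the
right chamber with per-step probability `min(k_leu1·dt, 1)` (at most one
per chamber per step; a full region silently skips) and, once
`t ≥ t_dly`, on the top row of the left chamber with probability
`min(k_leu2·dt, 1)`; ages are drawn Uniform(0, L_L) at birth.  `t_dly` is
a deterministic onset gate rather than a random delay.  Initial tumor
cells: `round(k_dis·n_tumor)` on distinct random free squares of the lower
half of the left chamber, the rest in the upper half.

## Free parameters and priors

| name   | meaning                                   | prior (uniform)    |
|--------|-------------------------------------------|--------------------|
| k_leu1 | right-chamber accrual rate, 1/min         | [0.001, 0.2]       |
| γ      | annexin sensitivity threshold             | [100, 1e7]         |
| λ      | chemotactic exponent                      | [0, 6]             |
| k_TL   | contact aging intensity, min              | [10, 1e4]          |
| k_dis  | lower-half tumor fraction                 | [0.5, 1]           |
| k_leu2 | left-chamber accrual rate, 1/min          | [0.0001, 0.1]      |
| t_dly  | left-chamber onset delay, min             | [60, 1440]         |

Spawn probabilities use rate × dt (the parameters carry 1/min units), not
the rate directly.

## Fixed parameters not available in the source material

The supplementary table holding the fixed rates was not available, so the
package documents its own defaults, chosen once for stability and for a
physically sensible field (values are config-overridable):

* `k_A = 10` conc/min per tumor cell, `D = 0.14`, `k_XA = 5e-4` /min —
  satisfy the stability bound (0.002 + 0.956 < 1) and flood the chip with
  an order-1-or-larger annexin gradient within the 24 h pre-video period,
  as required for λ to act as a chemotactic amplifier (see above).  The
  filmed experiment shows leukocytes chemotaxing from the right chamber,
  so a field the leukocytes can sense everywhere is the realistic regime.
* `L_L = 2880` min (leukocytes can survive the filmed window),
  `L_c = 5760` min (tumor cells die within the horizon only under
  leukocyte attack), `n_tumor = 20` on the full chip.

## Inference

ABC-SMC with uniform box priors, Latin hypercube sampling (LHS,
`scipy.stats.qmc`) for population 1, systematic resampling by importance
weight thereafter, and a component-wise Gaussian perturbation kernel with
scale `0.25·|θ*|` (a zero component — λ may be 0 — is a point mass:
kernel density factor 1 on equality, 0 otherwise).  Weights: `w = 1` in
population 1, else `π(θ) / Σ_g w_g·Ke(θ|θ_g)`, normalized per population.
Out-of-prior proposals are re-drawn (prior density 0).  One simulation
realization is run per candidate.  Losses:

    LossB = Σ_t Σ_j |f_j^sim − f_j^obs|·ω_j,  ω = (5,1,…,1)
    LossQ = Σ_t Σ_k |n_k^sim − n_k^obs|

over the evaluation frames (default video frames 0, 40, …, 720; T = 19).
The bin-1 up-weighting penalizes candidates whose leukocytes never cross
to the far (tumor) side — it is also what lets the tolerance schedule
escape the degenerate "simulate almost nothing" region, whose loss equals
the weighted observed total.

Tolerance schedules: the printed defaults (2303, 2015, 1727, 1439; plus
1200 for Quadrants) for real data, or an adaptive schedule for synthetic
experiments in which population 1 accepts the full LHS sample and each
later tolerance is a quantile (default 0.5) of the previous accepted
losses.  A population that consumes more than
`n_particles / acceptance_floor` simulations aborts with a diagnostic.
Candidate RNG streams are keyed by (population, candidate index) and
acceptance is processed in candidate order, so results are independent of
the joblib worker count.

## Posterior analysis

KDEs use `scipy.stats.gaussian_kde` with Silverman bandwidth and the SMC
importance weights (unweighted estimates available by flag).  1-D highest
density intervals are superlevel sets of the KDE on a 4096-point grid over
the sample range padded by 3 bandwidths; they may be unions of disjoint
intervals.  2-D HDRs use a 256 × 256 grid; the density threshold is found
by sorting grid masses.  Delta distributions pair samples by index and
report equal-tailed percentile credible intervals (90%/95%) with a
zero-inclusion flag.  Interval overlap is reported as a percentage of each
interval's own width (so the two percentages generally differ).

## Synthetic world and what green tests establish

Because the original tracking tables are not deposited and the published
fits took ~2 days on 48 cores, the recovery study runs on a scaled-down
stated world: a 29 × 38 lattice with the same three-section layout
(168/120/168 µm, 8 channels), horizon 960 min with the video in the second
half, 8 tumor cells, evaluation frames every 40 video frames (T = 7),
64 particles and 6 adaptive-quantile tolerance levels.  The true
parameters are the published final posterior means of the two genotypes
(chemotactically competent CC with λ = 2.65; insensitive CA with
λ = 0.304, whose doubled right-chamber accrual also lifts the observed
totals well above the degenerate-region loss).  Green recovery tests
establish that the estimation machinery concentrates on the truth and
separates the genotypes *in this world*; they do not reproduce the
published posterior tables, which would require the original videos.
Pseudo-observations are a single seeded realization, exactly as the
method treats real data (one realization per candidate θ).

Known limitations: no continuous-space positions, no flow, no
pharmacokinetics; tumor cells are immobile; the literal printed diffusion
update is non-conservative and therefore not the default; λ and γ are
only jointly identified where the field magnitude makes γ·TA cross its
threshold, and posteriors for k_TL, k_dis and t_dly stay prior-like
whenever leukocytes rarely reach the tumor (as the published CA fits also
show).
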