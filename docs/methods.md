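# Methods

`astroca` asks a single quantitative question: are the measured changes of
spontaneous astrocytic Ca²⁺ spiking with temperature consistent with
temperature acting through the SERCA pump rate alone? It answers it with
three model layers — a stochastic spatial cell, a well-stirred rate-equation
counter-model, and shared spike statistics — plus a closing inference step
that converts two exponential spike-width fits into a linear
pump-activity/temperature relation.

## 1. IP₃ receptor gating (`astroca.ip3r`)

Each IP₃R channel has four identical subunits; a subunit carries an IP₃
binding site, an activating Ca²⁺ site, and a dominant inhibiting Ca²⁺ site,
giving an eight-state Markov chain per subunit (the occupancy cube, twelve
reversible transitions). A subunit is *active* when IP₃ and activating Ca²⁺
are bound but inhibiting Ca²⁺ is not; a channel is open when at least three
of its four subunits are active. The activating site has the higher Ca²⁺
affinity, which together with slower inhibition produces the bell-shaped
stationary open probability that drives Ca²⁺-induced Ca²⁺ release (CICR):
rising local Ca²⁺ first recruits channels, then shuts them.

Rate constants are not a measured quantity of this analysis; they are loaded
from the packaged configuration. The defaults are the canonical
receptor-model values (binding rates a₁=400, a₂=0.2, a₃=400, a₄=0.2, a₅=20
(µM s)⁻¹ with dissociation constants d₁=0.13, d₂=1.049, d₃=0.9434,
d₄=0.1445, d₅=0.08234 µM; inhibition kinetics depend on IP₃ occupancy).
Stochastic gating uses an exact next-event SSA with propensities frozen
between concentration updates; the generator, its stationary law, and the
SSA are cross-checked against each other in the test suite (total-variation
distance < 0.02 over ≈10⁵ transitions).

One caveat worth stating plainly: at the configured resting Ca²⁺ of 55 nM
the stationary open probability of a channel is ≈0.16, so the resting state
of this receptor model is not silent — the simulated cell lives in a regime
of continual local release events, and "baseline" is a dynamical balance
between spontaneous openings and Ca²⁺-driven inhibition rather than a true
off state.

## 2. The spatial cell (`astroca.gca`)

### Fields and linearization

The cytosol/ER of a spherical cell (radius 10 µm) is described by four
deviation fields from rest: cytosolic Ca²⁺, ER (lumenal) Ca²⁺, and the
bound fractions of one mobile and one immobile buffer. Buffer kinetics are
linearized about the resting mass-action equilibrium; SERCA uptake is the
linear sink P_p·[Ca²⁺] (the Hill form's half-saturation constant therefore
plays no runtime role); the ER leak rate is not free but fixed by the
resting balance σ_l = P_p·Ca₀/(E₀−Ca₀) (≈0.0103 s⁻¹ at P_p = 150 s⁻¹), so
zero deviation is an exact fixed point for *every* pump strength scanned.
The ER is a second diffusing field whose equation is −γ times the cytosolic
exchange fluxes (γ = V_cyt/V_ER = 5) plus lumenal diffusion; the
γ-weighted total c + e/γ + b + b_i is conserved by every process except the
pump/leak pair, which the solvers exploit as an exactness check. Lumenal
buffering is outside the model's scope (one mobile + one immobile cytosolic
buffer only).

### Green's-function propagation

With Neumann (no-flux) boundaries, the linear system diagonalizes over the
Laplacian eigenmodes of the ball, spherical Bessel functions times
spherical harmonics with radial wavenumbers from j_l′(kR) = 0. Each mode
evolves under a 4×4 matrix A(k²) = M − k²D, which is eigendecomposed once;
between source switches the propagation is exact and elementwise in the
eigenbasis. Channel clusters enter as point-like sources (a uniform ball of
radius 0.05 µm, entering through its spherical form factor) carrying flux
P_c · n_open · (E−Ca) with the ER drive evaluated at switch-on. Because
sources sit at fixed positions and fields are only ever needed at those
same positions (plus the volume average, which lives entirely in the k = 0
mode), the azimuthal sums collapse via the Legendre addition theorem into
precomputed coupling tensors between cluster sites — the per-step cost is
independent of any spatial grid.

Truncation (default l ≤ 40, kR ≤ 60) acts as a spatial low-pass: the
"local concentration at a cluster" is the truncated field at the cluster
center, i.e. a local average on the ≈0.5 µm truncation scale. The
arbitrariness of both the regularization radius and the truncation scale is
absorbed by flux calibration (below), and far-field accuracy is enforced by
an independent oracle: a backward-Euler finite-difference solve of the same
linear system on a sphere-masked Cartesian grid. Spectral and
finite-difference solutions are compared as 0.45 µm ball averages — the
observable both discretizations represent faithfully — and agree within 5%
at cluster sites and at a probe 2 µm from an active source; pure-diffusion
mass conservation holds to 0.1%.

### Calibration of the channel flux

The single-channel flux coefficient P_c is not published; it is fixed by a
physical anchor instead: a reference cluster carrying 9 fully open channels
(the ensemble median of the 2–16 range) must raise its own local
concentration to ≈100 µM in quasi-steady state, the level reported for
local cluster concentrations independent of pump strength. Bisection to 2%
converges quickly because the linear system makes the peak essentially
proportional to P_c. Using the fixed reference count (rather than whichever
count a particular random geometry sampled) keeps P_c stable to <2% across
geometry seeds. The pump-independence of the local peak is itself a tested
property, not an input.

### Hybrid loop

Geometry: 31 clusters (2–16 channels each, uniform), pairwise separation
≥1.5 µm, inside 80% of the cell radius, by seeded rejection sampling. Every
macro-step (1 ms) the local Ca²⁺ at each cluster is evaluated and all
subunits advance by exact SSA with frozen propensities. Channel open/close
events inside a step are committed as source switches at the step boundary:
at most 1 ms of source latency against a ≈50 ms local field rise time, so a
newly opened channel sees its own elevated concentration from the next
millisecond on (per-subunit transition probability within the latency
< 1%). An earlier variant that re-evaluated the full field at every channel
transition showed the same regime behavior but was an order of magnitude
slower, with events arriving at several kHz. When the cell is
fully quiescent (no open channels, deviations below 0.1 nM) the step
lengthens to 50 ms and the SSA halts at the first opening instead, which is
exact because the propensities are constant on a flat field. The cell-wide
readout is the volume-averaged cytosolic concentration (the model analogue
of whole-cell fluorescence). Geometry and gating use separate seeds; runs
are bit-reproducible.

The IP₃ concentration is kept at the printed 80 µM even though it is far
above receptor saturation (it may well be a units typo for 80 nM); at
saturation the IP₃ sites are simply always occupied, and the parameter is
exposed in the configuration for anyone who wants the unsaturated variant.

### Emergent regimes and problem sizes

With the full 31-cluster geometry the model reproduces the qualitative
regime structure: at P_p = 22 s⁻¹ the cell enters a plateau (15–25 channels
persistently open, cytosolic mean ≈0.6 µM), while large pump rates give
isolated spikes on a quiet baseline; the fraction of time with ≥10 open
channels decreases sharply with P_p. Few-cluster cells (≤10) lose the
plateau — cell-wide coordination is carried by the summed far fields of
many clusters — which is why the scaled-down spot checks in the test suite
still use the full geometry with shortened durations (≈2 min of biological
time) rather than fewer clusters. Full production scans (hours of
biological time per pump strength) use the same code path.

## 3. The rate-equation counter-model (`astroca.ode`)

Three well-stirred pools (cytosol, ER, mitochondria) exchange Ca²⁺ through
IP₃R release (activation × inhibition Hill factors times the ER–cytosol
gradient), SERCA uptake, an ER leak, uniporter/Na⁺-Ca²⁺-exchanger
mitochondrial fluxes, plasma-membrane influx, and PMCA extrusion, with the
printed parameter set as defaults (µM, ms). The mitochondrial pool is
closed with dCa_m/dt = J_uni − J_NaCa, the minimal closure consistent with
the Δ·J_mito term in the cytosolic balance. Two printed ambiguities are
explicit configuration:

* **K_serca** — the SERCA half-saturation symbol collides with the
  Na⁺/Ca²⁺-exchanger prefactor (10 µM ms⁻¹) in the source tables; it is a
  separate mandatory parameter, reference value 0.2 µM (typical
  sub-micromolar SERCA affinity). A sensitivity scan over 0.1–1 µM is part
  of the test suite's findings (no qualitative change: see below).
* **inhibition** — the release-inhibition factor as printed,
  p₃⁴/(p₄⁴+Ca⁴), is ≫1 at rest; variants p₄⁴/(p₄⁴+Ca⁴) and
  p₃⁴/(p₃⁴+Ca⁴) are selectable. The printed form is the default.

**Finding (documented and tested, not patched):** with the printed values
the model is non-oscillatory for every pump strength, every inhibition
variant, and every K_serca in [0.1, 10] µM we scanned. The cause is
structural: the plasma-membrane balance J_ext,bas ≈ J_pmca pins the
cytosolic fixed point at ≈0.51 µM, outside the positive-feedback region of
the printed inhibition factor (which peaks below 0.2 µM), so the fixed
point is stable regardless of the ER fluxes. A genuine oscillatory window
exists in a corrected configuration — inhibition half-point at p₃ = 1.3 µM,
IP₃ = 2.0 µM, K_serca = 0.1 µM — shipped as `ode_oscillatory` in the
configuration: oscillations occupy a bounded interior window of P_p
(≈2.0–2.6 µM ms⁻¹ at P_r = 0.03 ms⁻¹) and the spike amplitude rises with
P_p there. The period *increases monotonically* across the window (no
interior minimum) and the width is flat-to-decreasing, so two of the three
qualitative claims made for this model family are not reproduced by our
implementation in any configuration we found; the corresponding acceptance
checks are left failing rather than adjusted. The model's scientific role —
a well-stirred cell does not reproduce the experimental width/amplitude
trends — is unaffected (indeed reinforced).

Integration uses LSODA with rtol 10⁻⁸, dense output on a 0.25 s grid, and
spike metrics measured after discarding the first 25% of each run; rows
with fewer than three surviving peaks are flagged non-oscillating.

## 4. Spike metrics (`astroca.spikes`)

Detection: baseline = running 10th percentile over a 60 s window, refined
per spike by the 10th percentile between the neighboring peaks (so an
isolated wide transient does not drag its own baseline up); candidates are
local maxima with height and prominence ≥ 20% of the global range *and*
≥ 6× the robust noise level (MAD of first differences) — the latter keeps
pure-noise traces detection-free; minimum separation 5 s. The FWHM is the
time above baseline + amplitude/2 between the bounding troughs, measured
by sample counting, which is unbiased under symmetric noise where
first-crossing walks are biased short by ≈15% at SNR 10. Spikes whose
half-height region touches the recording edge are discarded. ISI statistics
use the unbiased (n−1) standard deviation and require ≥3 spikes for σ. The
σ–T_av population line is ordinary least squares, with the deterministic
time T_det = −intercept/slope. Exponential fits y = a·e^(−bx) are
equal-weight nonlinear least squares initialized from the log-linear
regression, with heteroscedasticity-robust (HC3) standard errors since
width spreads scale with the width.

## 5. Synthetic traces (`astroca.synth`)

The generator realizes the statistical structure the analysis assumes of
spontaneous astrocyte spiking: a renewal process with ISI = T_det +
Exp(mean), which gives exactly the slope-1 σ–T_av line with intercept
T_det; stereotyped spike shapes (Gaussian or fast-rise/slow-decay double
exponential) of controlled FWHM and amplitude; baseline drift; additive
Gaussian noise. Defaults (T_det = 20 s, waiting mean 30 s, FWHM 30 s)
mirror the measured regime. It deliberately does *not* emulate imaging
physics — bleaching, indicator kinetics, cell-to-cell amplitude
heterogeneity — so passing recovery tests demonstrates correctness of the
statistics pipeline, not robustness to every artifact of real recordings.
The module also carries the nine measured (temperature, mean spike width)
conditions from cultured astrocytes and acute slices as a typed table (one
spike count was never reported and is stored as missing).

## 6. Inference (`astroca.inference`)

From g(T) = a·e^(−bT) (experiment) and f(P_p) = α·e^(−βP_p) (simulation),
setting g ∝ f gives P_p(T) = (b/β)·T + ln(α/a)/β. The unknown
proportionality constant shifts only the intercept, never the slope — the
slope b/β is the falsifiable part. With the published fit values
(a = 620 s, b = 0.109 °C⁻¹, α = 61 s, β = 0.012 s) the relation is
P_p(T) ≈ 9.08·T − 193 s⁻¹, and relative activity is reported as
100·P_p(T)/P_p(30 °C). Below ≈21 °C the linear relation predicts negative
pump rates, so relative values at the lowest temperatures are qualitative
only; the comparison dataset for absolute pump activity exists only as
plotted points elsewhere and is not digitized here.

## 7. Reproducibility and numerical choices

* Every stochastic component takes an explicit seed; simulations are
  bit-reproducible.
* Spectral truncation l ≤ 40, kR ≤ 60; macro-step 1 ms; quiescent step
  50 ms; ER-drive refresh 10 ms; all configurable.
* FD oracle: backward Euler, dt 2 ms, grid 0.4 µm on a radius-4 µm test
  cell (the oracle scales cubically with radius and is a validation tool,
  not a production path).
* Degenerate inputs: zero-duration gating returns the input state; empty
  source histories give identically zero fields; flat traces yield empty
  spike lists; fits require ≥3 points and positive widths.
* Test problem sizes (full geometry, 1.5–2.5 min of biological time per
  pump strength; 3 seeds for regime ordering) were chosen as the smallest
  sizes at which the regime structure is stable; production scans are the
  same code at longer durations.

## Known limitations

* The linearized buffers never saturate, so near-source concentrations and
  screening are those of the linear model; the 100 µM local-peak anchor
  absorbs part, not all, of this.
* The receptor rate constants are literature defaults, not fitted to these
  recordings; emergent quantities (spike widths, T_av) inherit that
  uncertainty.
* The rate-equation model as printed cannot oscillate (see §3); its
  qualitative claims are assessed in the corrected configuration.
* Quantitative agreement of the spatial model's absolute spike widths with
  the recordings is not asserted anywhere; the tested claims are the regime
  structure, trends with P_p, the σ–T_av law, and the calibration anchor.
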