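# Methods

`sideslip` studies how a hovering hawkmoth-sized flapper performs direct
lateral maneuvers ("sideslips") by rolling its body to reorient its net
aerodynamic force vector. The package couples a mechanistic flight
simulator to the observation process of a videographic study and to the
statistical models used to analyse such data, so that the whole chain --
physics, measurement, inference -- can be exercised and validated end to
end on data whose ground truth is known.

Units are cm / g / s throughout (forces in dyn), angles in degrees at every
interface and radians only inside trigonometric kernels. The global
reference frame (GRF) has +x forward, +y to the animal's right and +z down
(parallel with gravity, g = 980.665 cm/s^2), so a positive roll angle beta
means the right wing base is lower, and at force trim the lateral
acceleration is g sin(beta) with the vertical acceleration g(1 - cos beta).

## Blade-element flight model (`sideslip.simulate`)

The body has three free degrees of freedom: lateral position y, vertical
position z and roll beta. Fore-aft translation, yaw and pitch are frozen --
the lateral-maneuver models involve only {y, z, beta}, and yaw control is a
separate problem. Two wing pairs are commanded independently by sweep mean
and peak-to-peak amplitude (phi0, phi_p), elevation mean and amplitude
(theta0, theta_p), and midstroke wing-pitch angles per halfstroke
(alpha_down, alpha_up). Sweep and elevation follow sinusoids at the flap
frequency; the chord angle follows a smoothed square wave between the
downstroke and upstroke pitch with a cosine reversal occupying 10% of each
halfstroke by default (the analysis uses midstroke pitch only, so the
reversal shape is a free smoothness choice). All waveform derivatives are
analytic, including through command transitions, which are cosine-blended
over half a wingbeat.

Aerodynamic forces are summed over blade elements (default 10 per wing,
elliptic chord profile peaking at 3.0 cm on a 5 cm wing). Each element sees
a relative flow combining its flapping velocity, the body translational
velocity and the roll-rate-induced velocity at its span station; this last
coupling produces flapping counter-torque (FCT), the passive damping that
opposes body roll. Per element the model applies:

* translational lift and drag on the flow component perpendicular to the
  span, with `C_L = A_L sin(2a)` and `C_D = C_D0 + B_D (1 - cos 2a)`
  evaluated at the signed effective angle of attack;
* a rotational (Kramer) force `C_rot rho c^2 omega_pitch U` along the chord
  normal, with `C_rot = pi(0.75 - x0)` and the pitch axis at `x0 = 0.25`
  chord;
* added mass, `rho pi c^2 / 4` per unit span times the chord-normal
  component of the flapping acceleration (body-acceleration feedback is
  omitted to keep the state derivative explicit).

The aerodynamic constants (`A_L = 1.8`, `C_D0 = 0.1`, `B_D = 1.7`,
`x0 = 0.25`) and the morphology (2 g body, 5 cm wings, 26 Hz, roll inertia
1.5 g cm^2) are calibration choices, exposed in `SimConfig`, set so that
hover trim falls at a sweep amplitude near 115-120 deg -- the planform and
coefficient table of a real specimen are not part of this package. Wing
inertia torques are deliberately absent.

Integration is fixed-step RK4 at 100 steps per wingbeat (50 is the enforced
floor); runs are deterministic given the configuration. The integrator can
lock individual axes (acceleration forced to zero) so that damping probes
measure single-axis decay without exciting the slow roll/sideslip coupling
mode. `damping_probe` perturbs one axis velocity impulsively against a
matching unperturbed baseline and fits a log-linear decay to the
wingbeat-averaged velocity difference; with the default constants the roll
axis is heavily damped (half-life ~18 ms, under half a wingbeat) while the
lateral and vertical axes decay over ~0.2-0.4 s.

Sign conventions worth recording: a positive wing-pitch split (left pitch
up, right pitch down, `alpha_LR > 0`) rolls the moth rightward -- away from
the higher-pitch pair -- because below 45 deg more pitch means more lift;
an imposed positive roll rate generates negative wingbeat-averaged torque
(FCT); and with the default 10 deg mean elevation a rightward lateral
velocity produces a leftward roll torque (a dihedral-like restoring
coupling), which is what makes the fitted roll-velocity model's lateral
velocity coefficient negative.

## Synthetic observations (`sideslip.observe`)

The generator renders a trajectory into what hand digitization of
multi-camera video yields: 3D GRF positions of 8 landmarks -- scutum,
abdomen tip, both wing bases, both forewing tips, both hindwing tips --
sampled at four phases per wingbeat (end-upstroke, mid-downstroke,
end-downstroke, mid-upstroke). Phase times come from the commanded sweep
waveform (extrema = end-strokes, mean crossings = midstrokes), the
deterministic analogue of visual phase identification. The body landmarks
form a rigid template posed by (y, z, beta); wing tips are placed from the
commanded wing vectors, and the hindwing tip sits one chord-mark length
(1.5 cm) behind the forewing tip along the commanded chord direction, so
noiseless landmarks reproduce every commanded angle exactly.

Landmark noise is isotropic Gaussian in the GRF (default 0.05 cm, the
order of sub-pixel triangulation error for this working volume); hindwing
tips can be dropped at a configurable rate to emulate occluded points.
What the generator does *not* emulate: digitization bias, lens distortion,
marker-identification errors, wing flexion and abdominal articulation --
passing tests therefore validate the pipeline's mathematics and its noise
robustness, not those systematics.

`project_to_cameras` and `generate_wand` render pixel-level observations
through 11-parameter DLT cameras; the wand is two LEDs exactly 68.5 mm
apart moving along a smooth seeded Lissajous path with precessing
orientation.

## Videogrammetry (`sideslip.videogrammetry`)

Standard 11-coefficient DLT with the 12th projective parameter fixed to 1
(the coefficient-file convention of common digitization tools, 11 rows x
one column per camera). Calibration is linear least squares on >= 6
non-coplanar known control points, with an explicit coplanarity check;
wand-based self-calibration is out of scope, and the wand serves as a
reconstruction diagnostic (mean/sd/RMSE of the reconstructed LED
separation against the nominal 68.5 mm). Triangulation intersects DLT rays
by linear least squares; points seen by fewer than two cameras come back
as missing values rather than errors, matching sparse digitization.

## Kinematics extraction (`sideslip.kinematics`)

Body pose: the body x-axis runs from the abdomen tip to the centroid of
scutum + wing bases; the y-axis is the wing-base line orthonormalized
against x (Gram-Schmidt); z completes the right-handed triad. Euler angles
use the intrinsic z-y-x (yaw -> pitch -> roll) sequence, making roll
absolute to the GRF horizontal plane. The MGRF is the GRF yaw-rotated to
the trial's mean heading (circular mean of per-frame yaw) with z untouched;
body position and its derivatives are expressed there.

Wing angles follow the projected-vector definitions: sweep is the
base-to-forewing-tip vector projected into the body x/y plane, elevation
its angle above the body horizontal, and wing pitch the hindwing-to-forewing
chord projected into the body x/z plane -- measured from +x in downstroke
frames and from -x in upstroke frames, so midstroke pitch is positive in
both halfstrokes. When the hindwing tip is missing, wing pitch falls back
to the angle of the wing-vector normal in the x/z plane and the row is
flagged `fallback`; flagged rows stay in the table but the model design
matrices treat their pitch values as missing, because the fallback carries
no real chord information (it degenerates when the wing lies near the
lateral axis).

Derivatives are computed from like-phase samples one wingbeat apart
(central differences, one-sided at series ends), which exactly nulls any
signal with a one-wingbeat period; the four phase-specific estimates are
averaged per wingbeat, and second derivatives reuse the same stencil on the
first-derivative series. Maneuvers are maximal constant-sign runs of
lateral acceleration lasting at least 0.077 s (about two wingbeats).

The stroke table has one row per halfstroke: halfstroke amplitudes from
the bracketing end-strokes (3D angle, and x/y- and x/z-plane projections),
midstroke angles and left-minus-right asymmetries, pair means with
whole-dataset-centered versions (suffix `_c`; the means are written to a
JSON sidecar), the drag proxy |v| sin(theta_i) of the wing ipsilateral to
the lateral velocity, body state at midstroke, and stair-step summaries
(down/up ratios, lag autocorrelation of the pitch asymmetry) as table
annotations.

## Maneuver models (`sideslip.models`)

The statistical core is organised like statsmodels: `ManeuverModel(table,
ModelSpec)` with `fit()` returning a `ManeuverResults` carrying
coefficients, standard errors, p-values, log-likelihood, AICc, adjusted or
conditional r^2 and a `summary()` table. The three a priori equations are

    y_ddot    ~ g sin(beta) + y_dot + sgn(beta) phi_p_bar_c + sgn(beta) theta_p_bar_c
    z_ddot    ~ g(1 - cos beta) + z_dot + phi_p_bar_c + theta_p_bar_c
    beta_dot  ~ alpha_LR + phi_p_LR + theta_p_LR + y_dot        (no intercept)

with both roll coefficients expected near +1 (constant dorsal force of one
body weight, reoriented by roll), the velocity coefficients negative
(passive damping linearized over the observed speed range), and the
asymmetry coefficients positive (more pitch or amplitude on one side rolls
the animal the other way). Roll responses never carry an intercept: a
stably hovering animal has no asymmetry and no damping input. A centered
amplitude term is sign-multiplied by sgn(beta) in the lateral equation so
that amplitude increases push the animal toward its rolled side.

OLS fits go through statsmodels OLS; random-intercept models (grouping by
moth or trial) use statsmodels MixedLM with REML. The REML log-likelihood
was verified against the explicit restricted-likelihood formula. Mixed
p-values use a residual-degrees-of-freedom t approximation; conditional
r^2 is (fixed + random variance) / (fixed + random + residual). AICc is
`-2 llf + 2k + 2k(k+1)/(n-k-1)` with k counting every estimated parameter
including variance components (k = p+1 for OLS, p+2 for a random-intercept
model); results report NaN when n - k - 1 <= 0.

Cascade selection orders candidate terms by their p-value in the full
linear model containing every candidate (ties by larger |t|), grows the
model term by term accepting only AICc improvements, re-tests the lone
exclusion of the previously confirmed term after each acceptance, then
evaluates random-intercept variants and (for roll responses) single-term
up/down coefficient splits. The procedure intentionally admits an inactive
term at AICc's nominal acceptance rate (~16% per term); the tests check
the true term's selection and that false inclusions stay at that rate.

Derived reports: percent contributions `100 |K_i| mean|x_i| / sum_j ...`;
damping time constants `-1/K` (half-life `ln 2 / |K|`) from negative
velocity coefficients, with non-negative coefficients flagged non-finite;
quartile-binned t-tests comparing ipsi- and contralateral wing kinematics
during high roll velocity against bottom-quartile "normal flapping"
(one-sample t against the normal-bin baseline, unpaired t ipsi vs contra;
degenerate zero-variance comparisons return p = 1 with a warning); and the
first-order diagnostic fitting roll velocity and roll acceleration to the
same asymmetry terms side by side -- in a heavily damped roll system the
velocity model wins.

## The synthetic study (`sideslip.pipeline`)

The default `RunConfig` defines the study conditions: 4 moths x 3 trials x
20 wingbeats at 26 Hz (~480 halfstrokes, comparable to a few hundred in a
real data set), landmark noise 0.05 cm, 2% missing hindwing tips. Each
trial commands a rightward then a leftward pitch-split pulse (|alpha_LR|
drawn from 6-10 deg), yielding >= 2 sustained lateral maneuvers per trial
and roll excursions of roughly +-30 deg. On a 2.5-wingbeat keyframe grid
the bilateral sweep amplitude (3% sd) and elevation amplitude (6% sd)
wobble and small per-wing amplitude asymmetries (2 deg / 1.5 deg sd) are
redrawn, so the amplitude predictors carry variance that is uncorrelated
with the roll state; per-moth baselines (elevation mean 1 deg sd, sweep
amplitude 2 deg sd) create the between-individual variation that the
random-intercept models absorb. All randomness derives from the single run
seed; identical configs give byte-identical stroke tables.

Parameter recovery on this study is attenuated a few percent below the
physical values because the like-phase differencing filters the responses
while the roll predictor is sampled instantaneously, and because landmark
noise propagates into the roll angle (~4 deg per frame through the 1 cm
wing-base baseline) -- the classic errors-in-predictors bias. The recovered
roll coefficients stay within ~0.1 of one, which is the package's headline
check that the measurement-plus-inference chain preserves the physics.

## Known limitations

Quasi-steady aerodynamics only: no wake capture, no wing-wake interaction,
no wing flexibility or camber, no abdomen articulation. The 3-DOF body
cannot express yaw/pitch coupling of real maneuvers. The aerodynamic
constants are plausibility-calibrated, not fitted to any specimen, so
absolute damping magnitudes are indicative rather than predictive. The
observation model omits digitization systematics (bias, distortion,
misidentification). Autoregressive residual structures and nested random
effects are out of scope.
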