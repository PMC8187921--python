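# Methods

`ablate2d` simulates atrial fibrillation (AF) and catheter ablation (CA) on
2D "unfolded" left-atrium (LA) tissues and trains a CNN to predict, from the
tissue image alone, which ablation strategy will terminate the arrhythmia.
This note records the model, the calibration, the synthetic-data assumptions,
and the numerical choices, in enough detail to judge what a passing test does
and does not establish.

## 1. Tissue representation

The LA is represented by its standardised unfold map: a disk of diameter
150 mm rasterised at 0.3 mm/pixel (500x500), with the mitral valve at the
disk border and five circular openings inside it — the four pulmonary veins
(LSPV/LIPV/RSPV/RIPV) and the left atrial appendage (LAA). Pixels are
labelled void / healthy / fibrotic. The unfold-map literature fixes no
canonical coordinates for the openings, so the default template places the
PVs on a ring at 0.45 x disk radius (left pair left of centre, superior
veins up), PV radius 6 mm, LAA (radius 9 mm) below-left of centre. All
geometry is configurable; every template is validated (openings strictly
inside the disk, pairwise disjoint).

### Procedural LGE stand-ins

Real late-gadolinium-enhancement (LGE) images are not distributed with the
package. Stand-in intensity fields are Gaussian random fields with a 7.5 mm
correlation length — the centimetre scale of atrial fibrosis patches — mapped
linearly so that segmentation by the image intensity ratio (IIR — intensity
over mean blood-pool intensity; > 1.24 dense fibrosis, < 1.08 healthy)
yields a requested fibrosis burden (default range 5-35% of tissue area).
The 1.08-1.24 intermediate band maps to healthy because downstream images
are binary. What the stand-ins do **not** emulate: the intensity histogram
of real LGE, spatial correlation between fibrosis and anatomy (e.g.
peri-venous fibrosis), and inter-patient covariance. Green tests therefore
establish that the *pipeline* behaves correctly on realistic-looking
burdens and geometries, not that the classifier's accuracy would transfer
to patient images.

### Synthetic augmentation

Synthetic tissues follow a three-stage recipe: (1) weighted average of up to
65 base intensity images with independent uniform(0,1) weights, renormalised
by the maximum over tissue pixels; (2) fibrosis extraction at a
case-specific threshold followed by affine transforms of the fibrosis
pattern only (void geometry is anatomy and never moves); the ten cases pair
thresholds evenly spaced on [0.065, 0.095] with flips, rotations,
translations and their combinations. The case threshold is interpreted as
an absolute offset above the healthy IIR cut (fibrotic iff intensity >
1.08 x blood-pool + threshold), so the case range straddles the dense-
fibrosis cut and erodes or dilates the extracted pattern; (3) PV variation
on a seeded random half (floor(n/2)) of the synthetic set: diameters scaled
by 5-50% (one factor for all four PVs / one per left-right pair / four
independent ones, variants 1-3), variants 4-6 additionally shift each PV by
up to 10 mm per axis, resampling draws that collide or leave the disk.

## 2. Electrophysiology

Voltage follows the monodomain equation with the three-current Fenton-Karma
(FK) cell model (fast inward Na-like, slow inward Ca-like, slow outward
K-like currents; normalised voltage u in [0,1]; capacitance folded to 1).
Integration is forward Euler, dt = 0.01 ms, with a 5-point divergence-form
Laplacian at dx = 0.3 mm. Face diffusivities are arithmetic means of node
values and zero across faces touching non-conducting nodes; this enforces
zero-flux boundaries at the disk edge, the openings and ablation lesions,
and makes pure diffusion exactly conservative (tested to 1e-10).

Diffusion encodes tissue state: healthy D = 0.1 mm^2/ms (Scenario A,
early-stage AF) or 0.05 (Scenario B, persistent AF); fibrotic tissue 0.15 x
healthy D (slow conduction); void 0.

### Parameter choice and calibration

The FK constants are not prescribed by the problem statement beyond two
observables — planar conduction velocity (CV) of 0.7 m/s at D = 0.1 and a
rotor that survives at least 2000 ms on the 150 mm disk. The default
`ATRIAL_AF` set starts from a widely used FK parameterisation ("set 8" of
the spiral-breakup literature) and is calibrated in two steps:

* **APD.** tau_r 33.25 -> 18, tau_si 29 -> 16, tau_w+ 800 -> 350 shorten
  the action potential to ~87 ms, the AF-remodelled atrial range. This is
  a physical requirement, not a convenience: with CV 0.7 m/s the re-entry
  wavelength is CV x APD ~ 60 mm, and a rotor only fits the 150 mm disk if
  the wavelength is comfortably below the disk diameter. (The original
  ~160 ms APD gave a 110 mm wavelength: every initiation attempt ended
  with the wave sliding off the tissue. An intermediate ~100 ms APD
  initiated a rotor that drifted into the LSPV opening and annihilated
  after ~800 ms — the 6 mm veins are too small to pin a rotor at that
  wavelength, so the wavelength must be short enough for the functional
  rotor to be stable on its own. Both failures were observed directly in
  full-resolution screening runs.)
* **CV.** tau_d (the inverse fast-inward conductance) is tuned so the
  measured planar CV on the reference grid equals 0.70 m/s at D = 0.1:
  tau_d = 0.1062 ms. CV then measures 0.467 m/s at D = 0.05 — within the
  stated +-10% band of the 0.5 m/s target but biased low, because at
  dx = 0.3 mm the FK upstroke (front width ~ 0.1 mm) is under-resolved and
  the lattice slows slow waves preferentially. A lower excitation
  threshold u_c widens the front and removes most of this bias, but
  destabilised the rotor in disk simulations, so u_c stays at 0.13. The
  sqrt(D) scaling law is therefore verified on a refined grid
  (dx = 0.15 mm) where the discretisation has converged, while the
  headline CVs are reported at the production grid, like-for-like with the
  0.3 mm resolution they were defined at.

The kernel is a numba-compiled float32 loop; tanh in the slow-inward gate
uses a 4096-entry lookup table with linear interpolation (max error ~1e-7,
far below float32 state noise). A float64 path exists for the conservation
tests. Divergent states (|u| > 3 or non-finite) abort with a diagnostic.

### AF initiation (cross-field protocol)

S1 excites a 3 mm strip along the left disk edge at t = 0, launching a
planar wave (+x). S2 *cuts* that wave: at the scenario time (28 ms in A,
58 ms in B; anchored at the LSPV and the disk centre respectively) the
voltage is reset to 0 in the axis-aligned quadrant up-and-left of the
anchor, gates untouched. The surviving front ends abruptly at the cut line;
the free end curls into the resetting region as its gates recover, forming
a rotor near the anchor. The more common textbook variant — exciting a
perpendicular half-plane — was implemented first and never produced
sustained re-entry on the homogeneous disk (the S2 and S1 fronts merge and
exit); the cut variant is also the natural reading of "the wave is cut off
at the LSPV". A cut can only create a free end if the front has passed the
anchor, so when re-entry is not sustained S2 is retried 25 ms later, up
to five times. "Not sustained" covers both a dead probe (quiescent within
500 ms of S2, or no detectable tip) and a rotor that passes the probe but
extinguishes before the scenario duration (e.g. by drifting into an
opening): both retry. On the all-healthy disk Scenario A sustains at the
first retry (S2 = 53 ms). Probe runs stop early once the tissue has been
quiescent for 100 ms, and a successful probe is continued in place, so
retries cost little.

## 3. Rotor tracking

Tips are intersections of the u = 0.8 isoline in consecutive tracked frames
(10 ms cadence): away from the pivot the isoline sweeps forward between
frames, so only the pivot region is common to both. Isolines are extracted
sub-pixel by marching squares and intersected segment-by-segment (shapely);
segment-overlap results (identical frames) are discarded, and intersection
points within 10 mm (about one core diameter) merge into one tip — an
oblique front/back crossing yields a close pair for one pivot. Tips are
only accepted at least 3 mm inside the *disk*: wavefronts grazing the
outer (mitral) border bend their isolines there between frames, producing
crossings that are not pivots. The PV/LAA rims are deliberately not
masked: a rotor that drifts onto an opening continues as anatomical
re-entry whose tip rides within half a pixel of the rim (observed directly
in the Scenario A reference run, where the functional rotor pins to the
LAA after ~1 s), and masking rims would blind the tracker to exactly
those anchored rotors. Rim-grazing artifacts from passing waves do slip
through, but they are intermittent and fall apart into short tracks.
Linking is frame-to-frame minimum-total-distance assignment (Hungarian)
gated at 20 mm (meander and rim-orbit steps reach ~7 mm per 10 ms frame),
with up to two missed frames tolerated, followed by gap-closing: when a
tip is double-detected for a frame, frame-wise assignment can hand the
continuation to the fresh duplicate and close the original track even
though the rotor never disappeared, so — as in standard particle-tracking
pipelines — a track ending within 50 ms and 25 mm of another track's
start absorbs it. A rotor is *stable* if a single trajectory lasts
>= 2000 ms.

Note the temporal gap: the isoline-intersection definition nominally uses
consecutive solver steps, over which isolines move ~100 nm and every
isoline point is self-intersecting to machine precision; a finite
displacement is what isolates the pivot, so the tracking cadence (10 ms,
configurable) is used instead.

## 4. Ablation strategies

Lesions are 2 mm-radius discs (a catheter tip; configurable) in which u and
D are set to zero and the nodes leave the conduction mask; zero-flux
borders follow from the face-diffusivity rule. Plans:

* **Fibro** — lesions along the healthy/fibrotic border of every fibrotic
  component (sub-pixel contour, ordered per component, centre spacing
  1.5 x radius so discs overlap into continuous lines). Contour stretches
  facing void (disk edge, vein rims) are already non-conducting and are
  skipped.
* **PVI-1** — a closed lesion ring around each PV at ~2 mm clearance from
  the opening edge, grown outward if it would clip another opening.
* **PVI-2** — one large ring around the left PV pair and one around the
  right pair.
* **Rotor** — no precomputed plan; each interval ablates the most recent
  tracked tip position.

Execution starts from an established AF state (first tracked tip + 100 ms)
shared by all eight runs of a tissue ({Fibro, PVI-1, PVI-2, Rotor} x
{10, 30 ms} lesion intervals), making outcomes directly comparable. A run
ends at quiescence (max u < 0.1 over conducting nodes held for 100 ms), at
plan exhaustion (plus one hold window), at 2000 ms, or at the 40% ablated-
tissue cap — a lesion that would cross the cap is not applied and ends the
run (the cap exists to rule out "success" by critical-mass destruction).
Success = quiescent at the end; ablated percentage is ablated nodes over
initially conducting nodes. Class aggregation: a strategy class succeeds if
any of its runs did (the two PVI variants report one PVI class), and its
ablated% for labelling is the minimum over its successful runs.

## 5. Labelling and datasets

Two labelling rules turn per-class outcomes into a single ground-truth
class: *minimum percentage* (successful class with least ablated tissue;
ties broken toward the scarcer class, PVI > Fibro > Rotor) and *class
availability* (first successful class in scarcity order PVI > Fibro >
Rotor, which balances the class distribution). Tissues with no successful
strategy are discarded.

Scenario A and B labels for the same tissue would give one image two
labels, so the combined A+B dataset pairs the original image with the A
label and a binary-inverted copy (healthy <-> fibrotic; void unchanged —
void is anatomy, not signal, and the choice keeps inversion an involution)
with the B label. Splits: a holdout (default ~10% of tissue ids, stratified
by base/synthetic origin) is removed first, then seeded stratified 5-fold
cross-validation (80/20).

## 6. Classifier

The CNN is four 3x3 convolutions of 32 filters (ReLU, per-filter max-norm
3.0), one 2x2 max-pool, a 512-unit ReLU dense layer (max-norm), dropout
0.9, and a 3-way softmax; categorical cross-entropy with optional balanced
class weights w_c = N/(K n_c); Adam at 1e-4 with the plateau rule — when
the validation loss has not improved by 1e-3 within a 200-epoch patience
window the learning rate is multiplied by 0.8 ("monitored at every 200
epochs" is read as a patience window rather than checks at epochs 200/400
only); at most 500 epochs; the checkpoint is the epoch with the best
validation accuracy, and the best of the five CV folds (highest validation
accuracy, ties to the lowest fold index) is selected.

No deep-learning framework is assumed: layers, backprop and Adam are
implemented in numpy (im2col convolutions). This bounds practical input
sizes; tissue label images are downsampled nearest-neighbour to a
configurable input (128x128 nominal; the test suite uses 24-32 px). Pixel
encoding: healthy 0, fibrotic 1, void 0.5 — symmetric around void so image
inversion flips signal, not anatomy.

## 7. Numerical and degenerate-input choices

* Strict inequalities at both IIR cuts (a pixel at exactly ratio 1.24 is
  healthy).
* Quiescence threshold u < 0.1 held 100 ms; traces shorter than the hold
  window are not quiescent.
* CV measurement: thin homogeneous strip, stimulus at one end, activation
  = upward crossing of u = 0.5 at two probes >= 30 mm apart on the
  mid-row; 0.1 ms timing resolution.
* A translation that pushes all fibrosis off the tissue is retried at half
  amplitude, then dropped with a warning. PV-variant draws that collide
  resample (with shrinking shifts after repeated failures) and fall back
  to the original openings.
* Lesions entirely in void are no-ops; a tissue with no fibrosis has an
  empty Fibro plan (the run then succeeds only if AF was already absent).
* Tie-break in minimum-percentage labelling (equal ablated%): the scarcer
  class wins, mirroring the class-availability rationale.

## 8. Known limitations

* Procedural intensity fields stand in for patient LGE data; reported
  classifier metrics on synthetic cohorts say nothing about clinical
  accuracy.
* The solver is isotropic 2D monodomain; no fibre anisotropy, no 3D atrial
  geometry, no PV ectopy (triggers), no thermal lesion growth.
* At the production grid the FK front is under-resolved; absolute CVs at
  low D are biased a few percent low (section 2).
* The FK constants are a calibrated stand-in for the unavailable original
  parameterisation; rotor dynamics (core size, meander) match the stated
  observables, not any specific patient data.
* Tip tracking during rotor ablation uses the pre-ablation tracking
  mask, so isoline kinks at fresh scar edges can occasionally be
  reported as tips and draw a lesion; this wastes lesions but does not
  corrupt outcomes (success is judged on quiescence, not tip counts).
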