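# Methods

## The classification model

circFISH distinguishes RNA isoforms by colocalization rather than sequence.
The PC probe set binds the circularized exon(s), present in both isoforms;
the PL set binds linear-only exons. Each bound molecule appears as one
diffraction-limited spot per channel in which it has binding sites. The
model behind the classifier is therefore:

| molecule            | PL channel | PC channel | call                 |
|---------------------|-----------|-----------|----------------------|
| full-length linear  | spot      | spot      | paired within 250 nm |
| circular            | —         | spot      | unpaired PC          |
| linear fragment     | spot      | —         | unpaired PL          |

The 250 nm pairing radius is the assay's operating convention: it must
exceed the channel-to-channel registration error and the spot localization
error, and stay below the typical nearest-neighbour distance between
distinct molecules. Matching is one-to-one greedy by ascending 3D Euclidean
distance — a single RNA cannot explain two spots in the same channel, and
for sub-resolution registration errors the nearest-pair solution is the
physically correct one. Distances are computed in physical nanometres with
per-axis voxel scaling; the radius is inclusive (d ≤ 250 nm pairs). Ties
in distance break by lower PL index, then lower PC index, so results are
reproducible. A many-to-one mode (`one_to_one=False`) exists because the
original counterpart rule can also be read that way, but it is not the
default. A 2D in-plane distance mode is available behind a flag; 3D is the
default since spot coordinates are 3D.

Paired (linear) molecules are reported at the midpoint of their two spots —
a reporting convention, not an estimate of probe positions on the molecule.

## Probe tiling

Tiling is greedy left-to-right: the candidate window of `probe_len`
(default 20 nt, allowed 18–20) is emitted when its GC fraction lies in the
inclusive window [0.35, 0.55]; the cursor then advances by
`probe_len + min_gap` (gap default 2 nt, the spacing needed to prevent
fluorophore quenching between adjacent probes), otherwise by 1 nt. With the
GC filter off this yields exactly `floor((L + g)/(l + g))` probes, the
capacity used for feasibility checks; with 15 probes — the minimum for a
spot reliably brighter than background — the shortest usable target is
15·20 + 14·2 = 328 nt. Commercial designers solve the same placement
problem with proprietary thermodynamic scoring; this implementation trades
that for determinism, with the GC window as the only thermodynamic proxy
(no melting-temperature model). Probes may span exon–exon junctions inside
one target region (those junctions exist in both isoforms) but never the
gap between two non-adjacent blocks of the linear-only region, because no
molecule contains that joint sequence. Back-splice-junction-spanning probes
are deliberately not offered; avoiding BSJ dependence is the point of the
two-set design. U and T are treated as equivalent and probes are emitted in
the DNA alphabet.

## The synthetic-data generator

The simulator emulates the computational substrate of the experiment, not
its photochemistry. Defaults (all configurable on `SimulationConfig`):

* **Geometry** — 16 z-slices at 200 nm spacing; 130 nm lateral pixels
  (13 µm camera pixels through a 100× objective); fields 512×512 by
  default. PSF sigma 350 nm axially, 170 nm laterally — a widefield
  high-NA PSF sampled at ~1.3–1.75 voxels per sigma.
* **Cells** — non-overlapping ellipses (semi-axes 32–48 px ≈ 4–6 µm,
  aspect ≤ 1.3) as nuclei; cell territories are the nearest-nucleus
  partition clipped to a 30 px (~4 µm) dilation. Nuclei are placed far
  enough from the border that no territory is clipped by the field edge.
  Nuclei are 2D masks extruded through z, matching the 2D max-projection
  convention used for nuclear/cytoplasmic calls downstream.
* **Molecules** — per cell and class, counts are Poisson with means
  linear 30 / circular 10 / fragment 3 per cell, and nuclear probabilities
  0.25 / 0.50 / 0.25. The means are a scenario choice for a moderately
  expressed gene (the source experiments report bar charts, not numbers);
  the nuclear fractions reproduce the reported contrast of a predominantly
  cytoplasmic (75%) linear isoform against an evenly distributed circle.
  A fixed-count mode supports exact-recovery tests and a negative-binomial
  mode adds over-dispersion when wanted (off by default).
* **Rendering** — every molecule adds a peak-normalized anisotropic 3D
  Gaussian of amplitude 200 photons to its channel(s); the PC copy of each
  linear molecule is offset by per-molecule, per-axis N(0, 50 nm)
  registration jitter — well under the 250 nm radius, so classification at
  default settings is limited by crowding, not registration. Background is
  10 photons, with Poisson shot noise plus 2-photon Gaussian read noise,
  clipped at zero (SNR ≈ 50 at defaults; raise the background to emulate
  tissue autofluorescence).
* **Scenarios** — RNase R digestion is exponential in time: class *c*
  survives with probability 2^(−t/t½(c)), defaults t½ = 1 h for linear and
  fragment molecules and 48 h for circles (the wet protocol's observation
  that ~4 h removes most linear RNA while prolonged digestion slowly nicks
  circles). Survival is decided by a per-molecule uniform drawn once at
  sampling time, so digesting the same ground truth for longer always
  yields a subset of the shorter digestion — an in-silico time course on
  one sample, mirroring how the control experiment treats one specimen for
  increasing durations. Knockdown thins the target class by its efficiency
  using an independent per-molecule uniform.

Everything is a pure function of the config seed: named rng streams for
cell placement, molecule sampling, registration jitter and noise make each
stage independently reproducible.

**What the generator does not emulate** — optical aberrations,
photobleaching, hybridization efficiency below 100%, transcription-site
clusters, 3D nuclear shape, membrane stains, FFPE section artifacts and
spatially structured protein channels. Passing recovery tests on this
generator therefore demonstrates the correctness of the geometry,
statistics and bookkeeping of the pipeline, not robustness to every
real-microscope nuisance.

## Spot detection

The detector is a scale-normalized anisotropic Laplacian-of-Gaussian,
sign-flipped so bright blobs respond positively, with sigma matched to the
PSF (the original analysis used unpublished in-house code; the LoG is the
standard smFISH operator and is validated here against simulation). A
sigma below half a voxel on any axis is rejected as undersampled. Local
maxima in a 3×3×3 neighbourhood (configurable), with plateau ties broken
by lowest (z, y, x) index, become spots if their response clears the
threshold; positions are refined by the response-weighted centroid of the
3×3×3 window and reported in nm. Centroid refinement localizes to well
under half a voxel at the matching radius used; full 3D Gaussian fitting
would be the next refinement step but is unnecessary at 130 nm pixels for
a 250 nm rule.

The automatic threshold exploits the smFISH intensity gap: candidate
thresholds are log-spaced between the response's 90th percentile and its
maximum, and the detection count is evaluated at each. True spots produce a
long plateau where the count is stable (< 5% change per step); the
geometric midpoint of the longest such run is returned. Degenerate inputs
fail loudly rather than guess: a featureless volume detects nothing, and a
pure-noise volume (dynamic range max/p90 < 10, or no stable plateau)
raises with instructions to supply an absolute threshold.

## Quantification and statistics

Nuclei are segmented from the max-projected DAPI channel: Gaussian smooth
(σ = 1 px), Otsu threshold, hole filling, removal of objects under 200 px,
and a watershed on the distance transform (peak separation 20 px) to split
touching nuclei. Cell territories use the same nearest-nucleus construction
as the simulator. Cells touching the field border are excluded from
statistics by default. Spots are assigned by their rounded lateral pixel:
nuclear if on a nuclear pixel, cytoplasmic if elsewhere in a territory,
unassigned (and excluded) on background.

Per-cell summaries follow the field's reporting conventions: means over
cells (zero-count cells included), 95% confidence intervals as 1.96 × SEM
(normal approximation), and pooled-variance two-sided two-sample Student's
t-tests between conditions — Student's, not Welch's, matching the named
test — with stars `***` (p < 0.001), `*` (p < 0.05), `ns` otherwise and no
multiple-testing correction. Nuclear fractions average the per-cell
fraction over cells that contain the class, so low-expressing cells do not
produce 0/0; a class absent everywhere reports NaN. At least 100 cells per
condition are recommended (a warning below that), and conditions with
fewer than two cells skip testing.

## Problem sizes used in the test suite

Recovery properties are exercised at sizes chosen to give tight statistics
while keeping the suite quick to run: exact detection/classification on
single-cell 16×192–256² stacks, proportion recovery over 1000 noisy
single-cell scenes, scenario statistics on 20 independent 100-cell samples
(16×2048² fields), and matching optimality on 1000 random ≤ 20-spot
instances against an exhaustive maximum-cardinality oracle.

## Known limitations

* Greedy matching is not guaranteed maximum-cardinality; on random dense
  instances it attains ≥ 95% of the optimum and is exact whenever each
  spot has at most one in-radius candidate (the regime the assay is
  designed to operate in).
* Overlapping molecules closer than the optical resolution (~2.5 σ) merge
  into one spot; the pipeline does not attempt spot decomposition, so
  counts are biased low at high expression densities.
* Nuclear/cytoplasmic calls are 2D; a molecule above or below a nucleus is
  called nuclear.
* Intensity is ignored during matching (geometry only), and no chromatic
  aberration model beyond rigid per-molecule jitter is included.
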