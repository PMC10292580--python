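# Methods

## Problem and model

A SWATH-style DIA run cycles through a fixed scheme of wide precursor
isolation windows; every MS2 scan therefore superimposes fragments of all
peptides currently eluting inside one window. The package reconstructs
precursor–fragment relationships from a single run using one structural
assumption: **fragments of one peptide share their precursor's elution
profile** (same apex and width in retention time), while fragments of
different peptides generally do not. All stages operate on fixed-width
retention-time sliders so that a peptide's full chromatographic peak is
seen exactly once per slider, and XIC comparison needs no cross-run
alignment.

## Preprocessing

- **Sliders.** Width 20 duty cycles, stride 1. Width 20 is also the XIC
  length consumed by both neural networks. Per window there are
  `(n_cycles − 20) + 1` sliders; cycle indexing is half-open and 0-based.
  A slider's apex RT is the RT of its max-TIC MS1 cycle; an accepted
  group's RT is the RT at its precursor-XIC apex.
- **Binning.** Intensities accumulate at `floor(mz × 30)` into vectors of
  `ceil(1200 × 30) = 36000` bins. The binner also accumulates
  intensity-weighted m/z per bin, so every candidate ion carries a
  sub-bin centroid m/z. This matters: a bin center alone is up to
  ±0.017 Th off (≈33 ppm at 500 Th), far coarser than the 20 ppm
  precursor match tolerance. Peaks at m/z ≥ 1200 are dropped with a
  warning (window schemes vary; an error would be too strict).
- **MS1 peak finding.** Local maxima of the summed m/z profile with
  apex/baseline ≥ 3. The baseline is the median of nonzero profile values
  within ±15 bins sampled only at non-peak bins (raw local maxima and
  their ±1 neighbors are excluded): an isotope partner inside the window
  is signal, not background, and must not suppress its own monoisotopic
  peak. An apex with no measurable baseline passes.
- **Deisotoping.** For each peak, charges 1–5 are tested for companions
  at +k·1.00335/z Th. A companion counts if its XIC (±1-bin sums, robust
  to peaks jittering across a bin boundary) correlates with the apex XIC
  (Pearson ≥ 0.6, and at least 4 shared nonzero scans so sparse noise
  coincidences score 0) and the envelope stays plausible (each isotope at
  most 1.6× the previous, on ±1-bin-summed intensities). The charge with
  the most isotopes (ties: higher mean correlation, then lower charge)
  wins; at least 2 consecutive isotopes are required, otherwise the peak
  is dropped. Companion bins are consumed so isotopes are not re-reported
  as precursors. MS1 candidates get no MS2-style sparsity filter.
- **Fragment filters.** Candidate bins are local maxima of the summed MS2
  profile; their XICs must have strictly more than 5 nonzero points and a
  max/min-nonzero ratio strictly above 4.

## Embedding VAE

Encoder branches 20→384 | 20→192→384 | 20→48→128 | 20→128 (ReLU, dropout
0.2 per branch) concatenate to 1024, feeding two linear 16-dim heads: the
latent mean μ (the embedding) and the log-variance. The decoder mirrors
this from z ∈ ℝ¹⁶ (384 | 384→192 | 128→48 | 128, concat 752) into a
linear 20-dim reconstruction. Inputs are min-max scaled to [0, 1] per XIC
so the MSE term is comparable across fragment abundances and embeddings
are exactly scale-invariant.

Losses: L_KL = −½ Σ_d (log σ²_d − μ²_d − σ²_d + 1) ≥ 0;
L_recon = mean squared error over the 20 points; L_VAE = L_KL + L_recon.
A `literal_eq2` mode (−L_KL + L_recon) exists for comparison but is not
the default, because rewarding posterior divergence decreases without
bound as ‖μ‖ grows. Sampling uses z = μ + ε·σ with σ = exp(½ log σ²); a
`literal_sampling` mode z = μ + ε·σ² covers the variance-scaled reading
of the reparameterization, since "σ²" is used ambiguously for the second
encoder head in common descriptions. Triplet loss: batch mean of
[‖μₐ−μₚ‖² − ‖μₐ−μₙ‖² + α]₊ with α = 1. Total: mean VAE loss of the three
triplet members plus the triplet term.

Training: Adam (η = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e−8,
bias-corrected), batch size 256, 5 epochs on 20,000 synthetic triplets by
default. Everything — init (uniform fan-in scaling), shuffling, dropout
masks, latent ε — derives from one seed, so training is reproducible.
Both networks run on a small reverse-mode autodiff core (`_nn.py`) whose
gradients are verified against central finite differences in the tests.

## Clustering

Seeded k-means++ initialization followed by Lloyd iterations (tol 1e−6 on
the max centroid shift, cap 100). Ties go to the lowest-index centroid;
an emptied cluster re-seeds at the farthest point; per-iteration inertia
is asserted non-increasing. k is the number of candidate precursors
detected in the slider (clamped to [1, n_fragments]); the second pass
uses k₂ = number of still-unmatched precursors over the fragments not yet
absorbed into an accepted group. The choice of k is a design decision:
each cluster should ideally collect one precursor's fragments, and no
fixed global k fits sliders with different co-elution loads.

## Peptide index and scoring

Tryptic digestion (cleave after K/R except before P), ≤1 missed cleavage,
length 7–50, charges 1–5, fixed carbamidomethyl (C, +57.02146), variable
oxidation (M, +15.99491, ≤1 site by default) and protein N-terminal
acetylation (+42.01057). Monoisotopic residue masses; proton 1.007276 Th;
singly charged b/y fragments. Inverted tables register each entry under
its (precursor m/z bin, charge) and all fragment m/z bins, with ±1
neighbor bins so query-time lookups need only one bin while still
covering tolerance straddles; hits are verified at 20 ppm (precursor) and
0.03 Th (fragment). Correctness bar: exact equivalence with linear scans,
asserted on digests of 10⁴ entries. Cluster assignment intersects the
precursor hit set with the union of fragment hit sets and ranks by
hyperscore log₁₀(N_b!·N_y!·Σ matched apex intensities) — the X!Tandem
form, adopted because no alternative definition is fixed by the method
itself. Ranking ties break on peptide index for determinism.

## Co-elution CNN

Input: top-6 matched fragment XICs by apex intensity, each min-max
normalized, zero-padded to 6 rows. Branches (16 channels each): 1×1 |
1×1→3×3 | 1×1→5×5 | 3×3-maxpool→1×1, ReLU, channel concat (64×6×20),
flatten, FC 512, sigmoid unit — score in [0, 1] by construction. Binary
cross entropy on groups labeled same-peptide (1) vs mixed (0); scores at
exactly 0/1 are clamped at 1e−12 with a warning. Acceptance is strict:
score > θ, default θ = 0.5. Row-wise min-max normalization and the 16
channels per branch are design choices documented here because no
canonical values exist for them.

## Recalibration

Accepted groups supply (observed, theoretical) precursor m/z pairs;
duplicates per peptide keep the best hyperscore; an optional
engine-supplied expectation value is screened at < 0.001 when present
(the hyperscore-based screen stands in when it is not). The TOF model
m′ = A·m + B·√m + C is linear in (A, B, C) and fitted by ordinary least
squares; the orbitrap setting uses the two-parameter form m′ = A·m + B·√m
in the same basis. Calibration is global per run — the simplest reading
of recalibrating all precursors — and falls back to identity (with a
warning) below 5 calibrants or on a degenerate design.

## Pipeline

Sliders are independent, deterministic work units (per-slider k-means
seeds derive from the run seed, window and start index); results merge in
(window, slider) order, so execution order cannot change output. Because
stride-1 sliders see one elution ~20 times, groups with the same peptide
index and apex RT within width/2 cycles merge, keeping the highest
hyperscore; some consolidation rule is mandatory to avoid ~width-fold
duplicate spectra, and this one is the simplest that respects distinct
elutions of one peptide. Per slider, each fragment enters at most one
accepted group (stage-2 removal guarantees disjointness, asserted), and
accepted ≤ clusters ≤ 2×fragments is asserted per slider. MGF output uses
TITLE=<run>.<window>.<slider>.<rank>, PEPMASS, CHARGE with trailing sign,
RTINSECONDS — the dialect common search engines ingest.

## Synthetic data

The generator emulates SWATH acquisition: per duty cycle one MS1 scan
followed by one MS2 scan per isolation window (default scheme 400–600,
600–800, 800–1000 Th; 45 cycles; 3.3 s cycle time). Peptides are random
tryptic sequences (length 8–16, C-terminal K/R, no leading P so the
protein context remains cleavable); charges 2–3; apex intensity
log-uniform in [5e3, 5e4]; Gaussian elution with σ ∈ [1.5, 4] cycles so a
peak fits inside one width-20 slider; 3-peak isotope envelopes with
averagine-like Poisson ratios; ≥6 b/y fragments inside 100–1199 Th with
log-normal relative intensities sharing the precursor's profile;
background noise as Poisson-placed singleton peaks (mean 60/scan,
log-normal intensities, median ≈33) and 0.001 Th per-scan m/z jitter.
These defaults put precursor apexes ≳100× above the typical noise peak —
a clean-signal regime.

What the generator does **not** model: chimeric co-elution of analytes at
overlapping m/z, detectability/ionization biases, RT drift between runs,
profile-mode peak shapes in m/z, and ion mobility. Passing tests
therefore demonstrate the machinery is correct and self-consistent under
the stated assumptions, not that identification rates transfer to real
instrument data.

Training material is drawn from the same elution model directly
(`make_training_xics`, `make_group_examples`) rather than by extracting
every XIC from a full simulated run — orders of magnitude cheaper and
distributionally identical for the traces the networks see.

## Problem sizes and numerical choices

Default study sizes: 20,000 training triplets from 300 peptides (5
epochs), 2,000 labeled groups for the CNN (5 epochs), and a 20-peptide /
45-cycle / 3-window run for end-to-end evaluation — sizes chosen so a
scientist can iterate on a laptop CPU in minutes. k-means tolerance 1e−6;
Adam ε = 1e−8; BCE clamp 1e−12; constant XICs normalize to zeros; sigmoid
inputs are clipped at ±60 before exponentiation. All randomness flows
from explicit seeds; reruns are byte-identical.

## Known limitations

- Charge assignment needs ≥2 visible isotopes; very low-abundance or
  very high-charge precursors fall out at the deisotoping stage.
- Only b/y singly charged fragments are matched; modified fragments
  beyond the three supported modifications are not represented.
- The calibration is global per run; slow drift within a run is averaged.
- The CNN and VAE are trained on synthetic co-elution; applying them to
  real runs would call for retraining on instrument data.
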