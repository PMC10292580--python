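# deardia

Spectrum-centric deconvolution of data-independent acquisition (DIA /
SWATH) proteomics runs into pseudo-tandem mass spectra.

In DIA every peptide inside a wide isolation window is co-fragmented, so
each MS2 scan is a mixture of fragments from many precursors and cannot be
searched directly by a standard (DDA-style) engine. `deardia` untangles
those mixtures without a spectral library: it learns which extracted ion
chromatograms (XICs) co-elute, groups them, assigns each group to a
precursor via a peptide database, and writes the result as ordinary
pseudo-MS/MS spectra in MGF — ready for Comet, X!Tandem, MSFragger or any
other closed-search engine. It is aimed at proteomics method developers
and anyone who needs library-free DIA deconvolution on SWATH-style data.

## Method

Per isolation window, the run is cut into fixed-width retention-time
**sliders** (20 duty cycles — also the XIC length), binned on a truncated
m/z grid (30 bins per Th; max 1200 Th gives vectors of length 36,000).
Candidate precursors come from SNR peak finding plus isotope-envelope
deisotoping of the summed MS1 profile; candidate fragments are the MS2 bin
traces with more than 5 nonzero points and max/min-nonzero ratio above 4.
Then, per slider:

1. **Embed** — a 4-branch fully connected variational autoencoder maps
   each min-max-normalized fragment XIC *x* ∈ ℝ²⁰ to a latent mean
   μ ∈ ℝ¹⁶. Training minimizes, over triplets (anchor *a*, positive *p*,
   negative *n*),

   L_total = ⅓·(L_VAE(a) + L_VAE(p) + L_VAE(n)) + mean[‖μₐ−μₚ‖² − ‖μₐ−μₙ‖² + α]₊

   with L_VAE = KL(q(z|x) ‖ N(0, I)) + MSE(x, x̂) and margin α = 1, using
   an Adam optimizer (η = 0.001, β₁ = 0.9, β₂ = 0.999) implemented from
   scratch on a small numpy autodiff core.
2. **Cluster** — k-means (Lloyd, seeded k-means++) groups the embeddings
   into k classes, k = number of candidate precursors in the slider.
3. **Match** — an inverted index over the in-silico tryptic digest
   (Index1: (precursor m/z bin, charge) → peptides; Index2: fragment m/z
   bin → peptides) intersects precursor and fragment hits; candidates are
   ranked by the X!Tandem-style hyperscore log₁₀(N_b!·N_y!·ΣI).
4. **Gate** — an Inception-style 4-branch (1-2-2-1) CNN scores the
   co-elution of the top-6 matched XICs (a 6×20 matrix) in [0,1]; a group
   is kept when the score strictly exceeds θ (default 0.5).
5. **Second pass** — fragments of accepted groups are removed and the
   remainder re-clustered and matched once more.
6. **Recalibrate & emit** — accepted groups across the run serve as
   internal calibrants for a least-squares mass recalibration
   (m′ = A·m + B·√m + C for TOF), duplicated elutions from overlapping
   sliders are merged, and one MGF entry is written per precursor-fragment
   group.

A fully seeded synthetic SWATH generator (`deardia.synthdia`) provides
runs with known ground truth — interleaved MS1/MS2 duty cycles, Gaussian
co-elution shared between a precursor and its fragments, isotope
envelopes, charge states and background noise — plus the labeled triplets
and fragment-group matrices the two networks train on.

## Worked example

```python
import numpy as np
from deardia import synthdia, embed_vae, groupscore, pindex, pipeline

# 1. train the two models on synthetic material
xics = synthdia.make_training_xics(n_peptides=300, seed=0)
triplets = synthdia.make_triplets(xics, n=20000, seed=1)
vae_params, vae_hist = embed_vae.train_vae(triplets, epochs=5, seed=0)
cnn_params, cnn_hist = groupscore.train_classifier(
    synthdia.make_group_examples(2000, seed=0), epochs=5, seed=0)

# 2. simulate a 20-peptide SWATH run and build the search index
sim = synthdia.SimConfig(n_peptides=20, n_cycles=45, seed=42)
run, truths = synthdia.simulate_run(sim)
synthdia.write_truth_fasta(truths, "db.fasta", n_decoy_proteins=10, seed=5)
index = pindex.build_inverted_index(pindex.digest_fasta("db.fasta"))

# 3. deconvolve
cfg = pipeline.PipelineConfig(output_path="run.mgf", seed=0, run_name="synth")
report = pipeline.run_pipeline(cfg, vae_params, cnn_params, index, run=run)
```

Output of the example above:

```
VAE loss per epoch: [0.644, 0.513, 0.486, 0.473, 0.464]
CNN loss per epoch: [0.148, 0.007, 0.003, 0.001, 0.001]
digest: 2525 peptide entries
sliders: 78, candidate fragments: 4297
accepted precursor-fragment groups: 20
calibration residual: 0.68 ppm (20 calibrants)
pseudo-tandem spectra written: 20
```

The falling loss histories show both networks converging; the 78 sliders
(26 retention-time positions × 3 isolation windows) yield 4,297 candidate
fragment XICs, which condense into 20 accepted precursor-fragment groups —
one per simulated peptide — recalibrated to sub-ppm mass accuracy. The
resulting `run.mgf` holds one `BEGIN IONS` block per group:

```
BEGIN IONS
TITLE=synth.0.0.0
PEPMASS=428.189499
CHARGE=3+
RTINSECONDS=33.0000
161.03743 2827.6512
248.07066 892.5308
...
```

The same workflow is available from the shell:

```sh
deardia simulate --n-peptides 20 --seed 42 --out run.mzML --truth truth.tsv
deardia train-vae --out vae.npz
deardia train-cnn --out cnn.npz
deardia run --in run.mzML --fasta db.fasta --model vae.npz --cnn cnn.npz --out run.mgf
```

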