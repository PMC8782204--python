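# seegquake

Presurgical SEEG analysis in Python: automatic depth-electrode contact
localization from a post-implant CT volume, and two seizure-onset-zone (SOZ)
indices computed from intracranial EEG — the ictal Epileptogenicity Index
(EI) and the interictal High-Frequency Events Index (HI).

**Who it is for.** Epilepsy researchers and engineers who need the
computational core of a presurgical evaluation workflow without GUIs or
site-specific infrastructure: given a skull-stripped, co-registered CT-like
volume they get ordered per-electrode contact coordinates in mm; given
seizure or interictal SEEG they get per-channel SOZ scores; and a built-in
synthetic-data generator makes the whole pipeline testable end to end with
known ground truth.

## Methods at a glance

**Electrode localization.** Depth electrodes appear in CT as straight rows
of bright blobs (here 8–16 contacts per shaft, 2 mm contact diameter,
3.5 mm center-to-center pitch). The pipeline is:

1. *Thresholding* — voxels above an adaptive brightness threshold form a
   point cloud.
2. *3D line Hough transform* — votes over ~321 sign-deduplicated icosphere
   directions × a 1-voxel anchor grid in each direction's orthogonal plane;
   iterative peak extraction yields one line per electrode shaft without a
   user-supplied electrode count.
3. *Gaussian-mixture clustering* — one full-covariance component per Hough
   line, initialized from each line's inliers, assigns every cloud voxel to
   an electrode; a k-lines refinement pass cleans up crossings.
4. *Contact segmentation* — per shaft: total-least-squares axis, head voxel
   (the end nearer the brain's center of mass), then repeated
   center-of-mass convergence in a 2×2×2 mm cube (cluster voxels doubly
   weighted) with fixed 3.5 mm steps along the axis, head-first.
5. *Geometric QC* — per-contact distance to the line re-regressed through
   the final contacts ("axis–contact distance") and adjacent-spacing error
   relative to the pitch.

**Epileptogenicity Index.** After a 50 Hz notch (Q = 30) and a 5th-order
Butterworth band-pass to high gamma (60–140 Hz), the squared signal is
smoothed (500 ms window) and normalized by its mean over a pre-ictal
baseline, giving the normalized high-frequency energy NHFE. Per channel i,

    thre_i = max(NHFE_BL,i) + 10 · σ(NHFE_BL,i)

defines the onset threshold; the first target sample above it is the
channel's onset. With channels ranked by onset time, TC_i = 1/rank_i
(1, 1/2, 1/3, …), EC_i is the mean NHFE over the 250 ms right after the
earliest onset, and

    EI_i = TC_i × EC_i.

**High-Frequency Events Index.** The ripple-band (80–250 Hz) Hilbert
envelope is thresholded at

    thre_i = 2 · max(median(S_i), median(S_global)),

supra-threshold intervals closer than 20 ms are merged, intervals shorter
than 50 ms are discarded, and HI_i is the per-channel event count.

Both indices are validated against SOZ labels by ROC/AUC, with AUC computed
as all-pairs concordance (ties count 1/2).

## Worked example

Generate a synthetic subject, localize its electrodes, and score both
indices (all CLI subcommands also exist as library calls):

```bash
seegquake synth  --out demo --seed 3
seegquake locate --volume demo/volume.nii.gz --out demo/loc
# -> localized 8 electrode(s), 99 contact(s) -> demo/loc
seegquake eval   --found demo/loc/contacts.tsv --truth demo/truth_contacts.tsv --out demo/eval
# -> n_true 99  n_found 99  n_matched 99  mean_error_mm 0.071  max_error_mm 0.249
seegquake ei     --recording demo/ictal.edf --baseline 0:60 --target 62:85 --out demo/ei
# -> channel     thre  onset_s  rank       TC       EC       EI
#       CH00 3.077487   65.350   1.0 1.000000 4.061198 4.061198
#       CH01 3.399483   65.849   2.0 0.500000 1.535665 0.767833
#       CH02 2.934946   66.194   3.0 0.333333 0.846561 0.282187
seegquake hi     --recording demo/interictal.tsv --fs 1000 --out demo/hi
seegquake eval   --scores demo/ei/ei.tsv --labels demo/truth_soz.tsv --out demo/eval2
# -> EI AUC = 1.000
```

Reading the output: all 99 rendered contacts are recovered with a mean
localization error of 0.07 mm against the generator's ground truth. The
three channels with planted seizure onsets (staggered by 0.5 s) are ranked
in their true order — the earliest gets TC = 1, the next 1/2, the third
1/3 — and EI separates them perfectly from the silent channels (AUC 1.0).

The same from Python:

```python
from seegquake import ElectrodeLocator, make_volume, ElectrodeSpec

vol, truth = make_volume(ElectrodeSpec(n_electrodes=8), seed=3)
loc = ElectrodeLocator().fit(vol)
loc.contact_sets_      # per-electrode mm coordinates, head first
loc.qc_                # axis-contact distances, adjacent-spacing errors
```

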