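"""Extract feature tables from BCG segments with all five extractors.

Per-segment decompositions (K-means frame clustering, undecimated wavelet
transform, empirical wavelet transform) need no fitting; the learned maps
(kernel PCA, random feature mapping) compress a raw descriptor table.
"""
from bcghyper import SynthCohortConfig, generate_bcg_cohort, segment_cohort, standardize
from bcghyper.extract import (
    ewt_features,
    kmeans_features,
    modwt_features,
    pca_or_kpca_features,
    rfm_features,
    segment_descriptors,
)

records = generate_bcg_cohort(SynthCohortConfig(n_normal=5, n_hyper=5,
                                                duration=60.0, seed=1))
segs = segment_cohort(records, window_seconds=60.0)

km = kmeans_features(segs, K=4, frame_seconds=2.0, seed=0)
mw = modwt_features(segs, wavelet="db4", levels=5)
ew = ewt_features(segs, n_modes=5)
print(f"K-means frame clustering : {km.values.shape[1]} features/segment")
print(f"undecimated wavelet      : {mw.values.shape[1]} features/segment")
print(f"empirical wavelet        : {ew.values.shape[1]} features/segment")

desc, _ = standardize(segment_descriptors(segs))
kp, kp_model = pca_or_kpca_features(desc, kernel="linear", n_components=4)
rf, _ = rfm_features(desc, q=10, n_per_group=8, gamma=0.01, seed=0)
print(f"kernel PCA (linear, 4 pc): {kp.values.shape[1]} features/segment; "
      f"leading eigenvalue {kp_model.eigenvalues[0]:.2f}")
print(f"random feature mapping   : {rf.values.shape[1]} features/segment")
# Each extractor returns a samples x features table with labels attached —
# the common currency for the selection and classification stages.
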