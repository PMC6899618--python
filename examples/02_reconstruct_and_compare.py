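"""Reconstruct one noisy realization with MLEM and two guided methods.

MLEM uses the data alone; the Bowsher MAP method penalizes differences
between each voxel and its k most MR-similar neighbors; the
anato-functional MAP method weights the quadratic penalty by the product
of MR similarity and current-PET similarity, refreshed every iteration, so
PET-unique lesions are not smoothed away.  Metrics: whole-brain NRMSE vs
the ground truth, the eroded-white-matter standard deviation (noise
proxy), and the mean of tumor B (a PET-unique lesion).
"""

from guidedpet import (
    AcquisitionSpec,
    PhantomSpec,
    ReconConfig,
    RealizationStack,
    SimilarityParams,
    reconstruct,
    roi_mean_std_single,
    roi_nrmse,
)
from guidedpet.bench import BenchmarkConfig, simulate_data

config = BenchmarkConfig(
    phantom=PhantomSpec(shape=(64, 64), spacing=2.0, seed=1),
    acquisition=AcquisitionSpec(total_prompts=2e5, n_realizations=1, base_seed=1234),
    n_angles=96,
    n_iterations=120,
)
data = simulate_data(config)
m = data.realizations[0]
gt = data.bundle.pet_ground_truth.values
brain = data.bundle.roi_masks["whole_brain"].values
wm = data.bundle.roi_masks["wm_eroded"].values
tumor_b = data.bundle.roi_masks["tumor_B"].values

runs = {
    "MLEM": ReconConfig("MLEM", n_iterations=120),
    "BOWSHER": ReconConfig(
        "BOWSHER", SimilarityParams("BOWSHER", k=4), beta=1e3, n_iterations=120
    ),
    "ANATO_FUNCTIONAL": ReconConfig(
        "ANATO_FUNCTIONAL",
        SimilarityParams("ANATO_FUNCTIONAL", sigma_mr=0.1, sigma_pet=0.01),
        beta=1e3,
        n_iterations=120,
    ),
}

print(f"{'method':>18}  {'NRMSE%':>7}  {'WM std':>7}  {'tumor B':>8}")
for name, cfg in runs.items():
    res = reconstruct(name, m, data.model, data.bundle.mr_image, cfg,
                      background=data.background)
    img = res.image.values / data.count_scale
    nrmse = roi_nrmse(RealizationStack([img], gt), brain)
    wm_std = roi_mean_std_single(img, wm)[1]
    tb = roi_mean_std_single(img, tumor_b)[0]
    print(f"{name:>18}  {nrmse:7.2f}  {wm_std:7.4f}  {tb:8.4f}")

print("\nBoth guided methods cut the white-matter noise far below MLEM; the "
      "Bowsher prior also pulls the MR-invisible tumor toward white matter, "
      "while the anato-functional weights keep its mean close to MLEM's.")
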