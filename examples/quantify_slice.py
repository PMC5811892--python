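"""End-to-end MRSI slice quantification: fit, QA, map, GM regression.

Simulates a 16x16 FID-MRSI slice (brain-like tissue pattern, lipid rim,
SNR 40), quantifies every in-mask voxel, applies the conjunctive QA rule
(CRLB_NAA > 30% AND FWHM_NAA > 20 Hz), builds the MM1 amplitude map, and
regresses it on the gray-matter fraction.  The recovered slope should
match the phantom's configured GM dependence within ~10%.
"""

import numpy as np

import mrsmm as M
from mrsmm.lcfit import LCFitOptions

acq = M.default_acquisition()
truth = M.MMTruth.default(acq, seed=1)
nulled = M.generate_metabolite_nulled_spectrum(truth, 0.0, acq)
mm_model = M.parameterize_mm_amares(nulled)
noise_sd = M.mm_noise_sd_for_snr(truth, acq, 50.0)
priors = M.derive_ratio_priors([
    M.generate_metabolite_nulled_spectrum(truth, 0.0, acq, seed=300 + i, noise_sd=noise_sd)
    for i in range(6)
])
basis = M.build_basis(M.default_metabolite_groups(),
                      mm_model.with_ratio_priors(priors), acq, with_lipids=True)

sd40 = M.phantom_noise_sd_for_snr(40.0, acq, truth)
grid, ptruth = M.generate_mrsi_phantom(matrix=16, acq=acq, noise_sd=sd40,
                                       seed=4, lipid_ring=True, mm_truth=truth)
fits = M.quantify_grid(grid, basis, LCFitOptions(per_component_shift_ppm=0.0, tol=1e-7))
qa = M.qa_filter(fits)
print(f"fitted {len(fits.fitted_indices())} voxels; "
      f"auto-excluded {int(qa.excluded.sum())}, "
      f"flagged {int((qa.reason == 'flagged_single_criterion').sum())}")

cmap = M.make_map(fits, qa, "MM1")
err = np.abs(cmap.values - ptruth.amplitudes["MM1"]) / np.where(
    ptruth.amplitudes["MM1"] > 0, ptruth.amplitudes["MM1"], 1.0)
print(f"MM1 map: {int(cmap.defined.sum())} defined voxels, "
      f"median |error| {100 * np.nanmedian(err[cmap.defined]):.1f}%")

slope, intercept, r = M.gm_fraction_regression(cmap, grid)
print(f"MM1 vs GM fraction: slope {slope:.3f} (configured {ptruth.contrast_rules['MM1'][1]:.3f}), "
      f"intercept {intercept:.3f}, r {r:.3f}")
print("\nA positive slope reproduces the higher-in-gray-matter behavior of")
print("most MM components; the map hides voxels with CRLB above 30%.")
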