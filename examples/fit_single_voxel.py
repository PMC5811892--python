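"""Quantify one phantom voxel with the prior-constrained basis.

Simulates a small FID-MRSI phantom at SNR 40, fits the central voxel
with the con_MM_AM basis (17 metabolites + 9 MM components with soft
MM(XX)/MM1 ratio priors), and prints fitted amplitudes with CRLBs next
to the ground truth.  CRLBs below ~30% mark reliable estimates.
"""

import mrsmm as M
from mrsmm.core import fid_to_spectrum
from mrsmm.lcfit import LCFitOptions

acq = M.default_acquisition()
truth = M.MMTruth.default(acq, seed=1)
nulled = M.generate_metabolite_nulled_spectrum(truth, 0.0, acq)
mm_model = M.parameterize_mm_amares(nulled)
noise_sd = M.mm_noise_sd_for_snr(truth, acq, 50.0)
priors = M.derive_ratio_priors([
    M.generate_metabolite_nulled_spectrum(truth, 0.0, acq, seed=100 + i, noise_sd=noise_sd)
    for i in range(6)
])
basis = M.build_basis(M.default_metabolite_groups(),
                      mm_model.with_ratio_priors(priors), acq)

sd40 = M.phantom_noise_sd_for_snr(40.0, acq, truth)
grid, ptruth = M.generate_mrsi_phantom(matrix=16, acq=acq, noise_sd=sd40,
                                       seed=2, mm_truth=truth)
i = j = 8
spec = fid_to_spectrum(grid.voxel_fid(i, j))
res = M.lc_fit(spec, basis, LCFitOptions(per_component_shift_ppm=0.0))

print(f"voxel ({i},{j}): converged={res.converged}, "
      f"FWHM_NAA={res.fwhm_naa_hz:.1f} Hz, SNR_NAA={res.snr_naa:.0f}")
print("component   fitted    truth    CRLB%")
for name in ("NAA", "Cr", "PCr", "GPC", "Glu", "Ins", "MM1", "MM2", "MM5", "MM9"):
    print(f"{name:9s} {res.amplitudes[name]:8.3f} {ptruth.amplitudes[name][i, j]:8.3f}"
          f" {res.crlb_percent[name]:8.1f}")
print("\nAmplitudes are in generator units; the fit should track the truth")
print("column to within a few percent at this noise level.")
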