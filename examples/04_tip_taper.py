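"""Plus-end taper: fit Gaussian-survival decays and bin tip SD by rate.

A blunt plus end shows a steep fluorescence fall-off at the tip; a tapered
(incomplete-lattice) end decays gradually.  Fitting the decay with
background + amplitude * S((x - mu)/sigma) gives the tip SD.  Here tips are
rendered with a taper that grows with polymerization rate, and the binned
means recover that trend.
"""

import numpy as np

from mtdynamics import ImagingParams, LengthTrace, render_kymograph
from mtdynamics.tip import extract_profile, fit_tip_profile, mean_tipsd_by_rate

rng = np.random.default_rng(3)
fits, rates = [], []
for rate in np.linspace(0.5, 3.0, 40):
    sigma_true = 100.0 + 100.0 * rate  # taper grows with polymerization rate
    imaging = ImagingParams(psf_sigma_nm=130.0, tip_sd_nm=sigma_true,
                            noise_model="gaussian", read_noise_sd=1.5,
                            background_level=20.0)
    trace = LengthTrace(np.arange(3) * 3.0, np.full(3, 5.0), 3.0)
    kymo, _ = render_kymograph(trace, imaging, rng_seed=int(rng.integers(2**31)),
                               width_px=150)
    x, profile = extract_profile(kymo.intensity[0], 0, 0, 65.0)
    fit = fit_tip_profile(x, profile, psf_sigma_nm=130.0)
    if fit.converged:
        fits.append(fit)
        rates.append(rate)

table = mean_tipsd_by_rate(fits, rates, bin_edges=[0.0, 1.0, 2.0, 3.5])
print("rate bin (um/min)   n   mean tip SD (nm)   95% CI")
for row in table.itertuples():
    print(f"  {row.rate_lo:.1f}-{row.rate_hi:.1f}         {row.n:3d}   "
          f"{row.mean_sigma_nm:7.0f}        ({row.ci_lo:.0f}, {row.ci_hi:.0f})")
print("tip SD increases with polymerization rate, as built into the render; "
      "the fitted SD includes the 130-nm PSF in quadrature")
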