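"""Actin-bundle orientation from the angular power spectrum of a patch.

High-pass-filtered 2-D FFT power, binned by angle and rotated so that the
reported angle is the real-space fiber orientation (0 deg = AP,
90 deg = DV).  The DV-peak statistic - the power fraction within
90 +- 8 deg - quantifies circumferential bundling; an isotropic texture
gives the uniform share 16/180 ~ 0.089.
"""

import numpy as np

from embryomech import angular_spectrum, compare_peaks, dv_peak_value, gen_texture_patch

groups = {}
for kappa in (1.0, 6.0):
    peaks, dirs = [], []
    for seed in range(6):
        patch, _ = gen_texture_patch(mean_angle_deg=90.0, kappa=kappa,
                                     seed=seed, snr=10.0)
        spec = angular_spectrum(patch)
        peaks.append(dv_peak_value(spec))
        dirs.append(spec.mean_direction_deg())
    groups[f"kappa={kappa:g}"] = peaks
    print(f"kappa = {kappa:g}: DV peak = {np.mean(peaks):.3f} "
          f"(uniform share 0.089), mean orientation = {np.mean(dirs):.1f} deg")

table = compare_peaks(groups)
row = table.iloc[0]
print(f"\nWelch t-test {row.group_a} vs {row.group_b}: t = {row.t:.2f}, p = {row.p:.2g}")
print("(stronger angular concentration -> larger circumferential peak)")
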