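"""Generate a synthetic cohort and look at what makes a fall a fall.

Builds one noiseless fall trial and one walking trial, prints the phase
structure of the acceleration magnitude, then generates a small cohort and
summarizes it.
"""

import numpy as np

from fallstream import AdlProfile, FallProfile, generate_adl, generate_cohort, generate_fall

rng = np.random.default_rng(0)

fall = generate_fall(FallProfile(impact_peak=4.0, noise_sd=0.0), fs=200.0, duration=12.0, rng=rng)
mag = fall.acc_magnitude()
t = np.arange(len(mag)) / 200.0
print("fall trial: %d samples at 200 Hz" % len(mag))
print("  prefall mean |a| = %.2f g (gravity + gait)" % mag[t < 4.0].mean())
print("  falling  min |a| = %.2f g (approaching free fall)" % mag[(t >= 4.0) & (t < 4.4)].min())
print("  impact   max |a| = %.2f g (the global peak)" % mag.max())
print("  postfall mean |a| = %.2f g (lying still, rotated axis)" % mag[t > 5.0].mean())
print("  gyro peak = %.0f deg/s during the rotation burst" % fall.gyro_magnitude().max())

walk = generate_adl(AdlProfile(activity_kind="walking", gait_frequency=2.0), 200.0, 12.0, rng)
print("\nwalking trial: max |a| = %.2f g (never leaves the gait band)" % walk.acc_magnitude().max())

cohort = generate_cohort(n_subjects=5, falls_per_subject=4, adls_per_subject=4, fs=50.0, seed=7)
print("\ncohort: %d subjects, %d trials (%d falls)" % (
    len(cohort.subjects), len(cohort.trials), cohort.n_falls))
print("subjects differ: per-subject impact peaks =",
      [round(float(max(r.acc_magnitude().max() for r, lab, s in cohort.trials
                       if s == sid and lab == "fall")), 2) for sid in cohort.subjects])
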