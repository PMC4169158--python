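"""How much unexplained per-site rate variance could the data hide?

Simulates DNM datasets under the fitted MI model plus an extra mean-one
lognormal rate variance upsilon per site.  Because each MI bin averages
~10 million sites, a bin feels only upsilon/n of that variance, so
enormous per-site variance barely dents the observed correlation — the
sweep reports the proportion of simulated datasets whose correlation
beats the observed one, for increasing upsilon.
"""

import mutvar as mv

track = mv.make_mi_track(120_000_000, [(1.0, 60.0, 1e6)], (0, 119), seed=101)
model = mv.TrueRateModel(intercept=-8.0, slope=0.01)
dnms = mv.sample_dnms(track, model, 650, seed=102)
bins = mv.bin_by_mi(dnms, track)
fit = mv.fit_loglinear(bins)
print(f"observed r = {mv.run_table1(bins, fit, mv.SimulationConfig(n_reps=1, seed=0)).r_observed:.3f} "
      f"over {len(bins)} bins of ~1e7 sites\n")

config = mv.SimulationConfig(n_reps=1000, seed=103)
table = mv.upsilon_sweep(bins, fit, [0, 1e3, 1e4, 1e5, 1e6, 5e6], config)
print(table.to_string(index=False))

print(
    "\nproportion_greater is the share of simulated datasets correlating\n"
    "better than the observed one; it stays flat until upsilon/n becomes\n"
    "non-negligible, i.e. per-site variance up to ~1e4 (a coefficient of\n"
    f"variation of {mv.cv_of_lognormal(1e4):.0f}) would be invisible here."
)
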