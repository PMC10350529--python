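"""Rotarod running responses and a two-group reactivity comparison.

Part 1 runs the rotarod protocol (rest 0-60 s, forced running 60-240 s,
rest to 360 s) and summarizes the running response vs the first-10-second
reference. Part 2 compares hypercapnic CBVF responses between a normal
group and a group with elevated reactivity using the unpaired two-tailed
t-test, as in a transgenic-vs-wildtype comparison.
"""

import hemospec as hs

chrom = hs.load_chromophore_table()
scat = hs.load_scattering_table()
tissue = hs.TissueConfig()
instrument = hs.InstrumentModel()


def fitted(scenario, seed, params=None):
    truth = hs.make_trajectory(scenario, params, seed=seed)
    spectra, cal, _ = hs.simulate_session(truth, instrument, tissue, chrom, scat,
                                          seed=seed)
    return hs.fit_timeseries([hs.calibrate(s, cal) for s in spectra],
                             hs.FitOptions(), tissue, chrom, scat)


summary = hs.summarize_rotarod(fitted("rotarod", seed=3))
print(f"rotarod running response: CBVF {summary.max_cbvf_change_pct:+.1f}%, "
      f"SO2 {summary.max_so2_change_pct:+.1f}% vs first-10-s reference")
print(f"baseline-rest change (control): CBVF {summary.baseline_cbvf_change_pct:+.2f}%")

normal, elevated = [], []
high = hs.TrajectoryParams(cbvf_peak_pct=28.0)  # impaired autoregulation: larger rise
for i in range(4):
    normal.append(hs.summarize_hypercapnia(fitted("hypercapnia", 10 + i)).max_cbvf_change_pct)
    elevated.append(hs.summarize_hypercapnia(fitted("hypercapnia", 20 + i, high)).max_cbvf_change_pct)

cmp = hs.compare_groups(normal, elevated)
print(f"group A (normal):   {cmp.mean_a:.1f} +/- {cmp.sem_a:.1f}% (n={cmp.n_a})")
print(f"group B (elevated): {cmp.mean_b:.1f} +/- {cmp.sem_b:.1f}% (n={cmp.n_b})")
print(f"two-tailed unpaired t-test: t = {cmp.t:.2f}, p = {cmp.p:.4f}")
print("A significant negative t means group B over-responds to CO2.")
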