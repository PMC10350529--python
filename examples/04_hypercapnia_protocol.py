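"""Hypercapnia protocol: CO2 challenge, vasodilation readout, recovery time.

Simulates the full 360 s protocol (baseline 0-60 s, 10% CO2 from 60 s to
300 s, recovery to 360 s) with an injected vasodilatory response, runs the
pipeline, and prints the session summary used for group comparisons.
"""

import hemospec as hs

chrom = hs.load_chromophore_table()
scat = hs.load_scattering_table()
tissue = hs.TissueConfig()
instrument = hs.InstrumentModel()

truth = hs.make_trajectory("hypercapnia", seed=7)  # +16.9% CBVF, -31.8% SO2 injected
spectra, cal, _ = hs.simulate_session(truth, instrument, tissue, chrom, scat, seed=7)
series = hs.fit_timeseries([hs.calibrate(s, cal) for s in spectra],
                           hs.FitOptions(), tissue, chrom, scat)
summary = hs.summarize_hypercapnia(series)

print(f"baseline: CBVF {summary.baseline_mean_cbvf_pct:.2f}%, "
      f"SO2 {100 * summary.baseline_mean_so2:.1f}%")
print(f"max CBVF change over CO2 window: {summary.max_cbvf_change_pct:+.1f}% "
      "(vasodilation raises blood volume)")
print(f"min SO2 change over CO2 window:  {summary.min_so2_change_pct:+.1f}% "
      "(saturation falls slowly under CO2)")
if summary.time_to_baseline_censored:
    print("CBVF did not re-enter its baseline band before session end")
else:
    print(f"CBVF time to baseline after CO2 release: {summary.time_to_baseline_s:.0f} s")
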