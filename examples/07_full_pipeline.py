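"""Run the complete analysis end to end on a synthetic world.

Chains every stage - absolute abundance, seasonality, correlation network,
dust events, immigration indices, SEM - and prints the report's headline
numbers.  Re-running with the same seed reproduces them exactly.
"""

from aerodyn import AnalysisConfig, run_full_analysis

report = run_full_analysis(AnalysisConfig(seed=1, output_dir="scratch_run"))

print(f"abundance: {report['abundance']['mean_log10']:.2f} +/- "
      f"{report['abundance']['sd_log10']:.2f} log10 copies/m^3")
print(f"transport lag (cross-correlation): "
      f"{report['transport_lag']['abundance_lag_weeks']} weeks")
print("harmonic R2: " + ", ".join(
    f"{k} {v['r2']:.2f}" for k, v in report["harmonic_fits"].items()))
print(f"network: {report['network']['n_edges']} edges; focal trio in one "
      f"module: {report['network']['focal_comodule']}")
print(f"events: {report['events']['n_official']} official, "
      f"{report['events']['n_spikes']} spikes")
paths = report["sem"]["standardized"]["paths"]
print(f"SEM: LA<-LG {paths['LA<-LG']:.2f}, LA<-RD {paths['LA<-RD']:.2f}; "
      f"indices {report['sem']['fit_indices']}")
print("full report: scratch_run/report.json")
# The positive LG > RD ordering and the ~4-week lag recover the structure
# the generator was configured with.
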