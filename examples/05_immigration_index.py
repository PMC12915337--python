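"""Build the desert dust-immigration index.

Desert-station AQI values invert to PM10 through a piecewise-linear
breakpoint table; multiplying desert PM10 by the daily frequency of
desert-origin (pathway A) back-trajectories and smoothing with a 4-day
moving average gives one regional-dispersal indicator per desert region.
"""

from aerodyn import (WorldConfig, aqi_to_pm10, generate_world,
                     immigration_index, pathway_frequency, pm10_to_aqi)

for aqi in (50, 120, 250):
    conc = aqi_to_pm10(aqi)
    print(f"AQI {aqi:3d} -> PM10 {conc:6.1f} ug/m^3 "
          f"(round trip AQI {pm10_to_aqi(conc):.0f})")

world = generate_world(WorldConfig(seed=1))
freq_a = pathway_frequency(world.pathway_labels, pathway="A")
monthly = freq_a.to_pandas().groupby(freq_a.dates.month).mean()
print(f"\npathway-A frequency: Jan {monthly[1]:.2f}, Jul {monthly[7]:.2f}"
      "  (U-shaped, summer minimum)")

for region, pm in world.desert_pm10.items():
    index = immigration_index(pm, freq_a, smooth_days=4)
    print(f"immigration index, {region:11s}: mean "
          f"{index.to_pandas().mean():6.1f} ug/m^3 (frequency-weighted)")
# High index values mean heavy desert dust loads on air masses that
# actually travel toward the sampling site.
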