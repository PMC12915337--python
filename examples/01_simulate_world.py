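"""Generate a synthetic 3-year air-monitoring world and write its tables.

The world mimics a coastal monitoring campaign: ~315 air samples at 3-5
day intervals with qPCR totals and read compositions, daily meteorology
and PM10 (local plus three desert source regions), hourly PM10 for event
detection, and 2-hourly back-trajectory pathway labels.
"""

from aerodyn import WorldConfig, generate_world
from aerodyn.synthetic import write_world_csv

config = WorldConfig(seed=1)
world = generate_world(config)
write_world_csv(world, "scratch_world")

print(f"samples:            {len(world.samples)}")
print(f"dust events (truth): {len(world.truth.events)}")
for ev in world.truth.events[:3]:
    print(f"  desert emission {ev.desert_day.date()} -> local arrival "
          f"{ev.local_start.date()} (x{ev.magnitude:g})")
print(f"hourly PM10 points: {len(world.hourly_pm10)}")
print(f"trajectory labels:  {len(world.pathway_labels)} (12/day at 2-h steps)")
print("tables written to scratch_world/ (samples, daily, hourly, truth)")
# Each truth event is a ground-truth dust episode: the desert PM10 series
# is boosted on the emission day and the local series four weeks later.
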