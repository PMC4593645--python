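"""Segment a simulated deployment into foraging trips and summarize them.

Simulates a central-place forager making three excursions to a prey
patch 60 km from its colony, classifies each fix as flight or rest from
its ground speed (< 3 km/h = resting on the water), cuts the track into
trips at a 2 km colony buffer, and prints the per-trip metrics: trip
duration, total distance, maximum range, flight hours per day and the
short/long class (> 3 days = long).
"""

from foragescape import classify_behaviour, segment_trips, trips_table
from foragescape.simulate import simulate_trajectory, single_patch_config

traj, truth = simulate_trajectory(single_patch_config(seed=7))
traj = classify_behaviour(traj)
trips = segment_trips(traj)

print(f"simulated {truth['n_excursions']} excursions -> "
      f"recovered {len(trips)} trips\n")
table = trips_table(trips)
cols = ["trip_id", "duration_days", "total_distance_km",
        "max_distance_colony_km", "flight_hours_per_day", "duration_class"]
print(table[cols].round(2).to_string(index=False))
print("\nEach row is one colony-to-colony excursion; total distance sums "
      "the great-circle legs, and flight hours exclude drift/rest fixes.")
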