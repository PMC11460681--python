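"""Activity-season masks: when are mosquitoes actually flying?

Temperature covariates are averaged only over the activity season —
year-round for tropical container breeders, photoperiod-limited (>= 9 h
daylight) for diapausing temperate species, precipitation-limited
(>= 50 mm over the trailing 30 days) for aestivating Sahelian species.
"""

import numpy as np

from thermoniche import (
    day_length,
    photoperiod_season_mask,
    precipitation_season_mask,
    season_temperature_stats,
)

lats = np.array([0.0, 30.0, 45.0, 60.0])
mask = photoperiod_season_mask(lats)
print("photoperiod season length (days with >= 9 h daylight):")
for lat, length in zip(lats, mask.season_length):
    print(f"  lat {lat:5.1f}: {length} days "
          f"(solstice day lengths {day_length(lat, 172):.1f} h / {day_length(lat, 355):.1f} h)")

# a monsoon-like climate: 5 wet months, dry the rest of the year
precip = np.zeros((1, 365))
precip[0, 150:300] = 8.0  # mm/day
wet = precipitation_season_mask(precip)
print(f"\nmonsoon cell: precipitation season {wet.season_length[0]} days "
      "(wet spell + the 30-day trailing window)")

# in-season temperature statistics differ from annual ones
doy = np.arange(365)
temps = 18 + 10 * np.sin(2 * np.pi * (doy - 80) / 365)[None, :]
stats_year = season_temperature_stats(temps, precipitation_season_mask(np.full((1, 365), 2.0)))
stats_wet = season_temperature_stats(temps, wet)
print(f"annual mean {stats_year.mean[0]:.1f} C vs wet-season mean {stats_wet.mean[0]:.1f} C")
# The wet-season mean is what a rainfall-limited mosquito actually experiences.
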