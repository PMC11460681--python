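# 12-record cleaning fixture (synthetic)

Synthetic hand-built records over a 4x4 grid (origin (0, 0), cell size 1 deg),
land everywhere except cell (row 1, col 1), covariate missing at cell
(row 0, col 3), activity-season length 0 at cell (row 3, col 0), study
period 2000-2019.

Manual application of the cleaning cascade, in rule order:

| # | record                              | outcome                      |
|---|-------------------------------------|------------------------------|
| 1 | clean, unc 500 m                    | survives (cell r0,c0)        |
| 2 | clean, unc missing, 3 decimals      | survives (cell r0,c0)        |
| 3 | date 1999                           | rejected: out_of_period      |
| 4 | FOSSIL_SPECIMEN                     | rejected: basis_of_record    |
| 5 | UNKNOWN basis                       | rejected: basis_of_record    |
| 6 | unc 1500 m                          | rejected: coordinate_uncertainty |
| 7 | unc missing, 1 decimal              | rejected: coordinate_uncertainty |
| 8 | point in ocean cell (1.5, 1.5)      | rejected: not_on_land        |
| 9 | covariate-missing cell (3.5, 0.5)   | rejected: missing_covariate  |
|10 | zero-season cell (0.5, 3.5)         | rejected: no_activity_season |
|11 | unparseable latitude                | rejected: malformed          |
|12 | clean, unc 900 m                    | survives (cell r2,c2)        |

Expected: 3 survivors; tally {malformed: 1, out_of_period: 1,
basis_of_record: 2, coordinate_uncertainty: 2, not_on_land: 1,
missing_covariate: 1, no_activity_season: 1}; thinning the survivors gives
2 unique cell centroids (records 1 and 2 share cell r0,c0).
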