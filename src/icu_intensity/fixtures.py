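"""Reference stratum counts from the source study's printed tables.

The study this package reimplements (a 2006–2008 multicentre French
medical-ICU administrative cohort, n = 23,578) did not deposit its data;
its printed stratum counts — stays and hospital deaths per SAPS II age
band and treatment-intensity group — are inputs the table-builder
operations can be run on directly, reproducing every printed percentage.

Known internal inconsistency of the printed tables (reported, not fixed):
the <80-year group-0 count is printed as 6624 in one table while the age
band rows of the other sum to 7297 − 1073 = 6224; only 6224 is consistent
with both printed percentages (30.5 % of 20,375 and mortality 8.2 %), so
6224 is carried here.
"""

from __future__ import annotations

import pandas as pd

from .filters import AGE_BANDS

__all__ = [
    "reference_stratum_table",
    "REFERENCE_TOTAL_STAYS",
]

#: stays per (intensity group, age band) — intensity-by-age contingency table
_STAYS = {
    0: (1381, 2298, 1170, 643, 732, 1073),
    1: (776, 1012, 445, 232, 230, 266),
    2: (520, 1066, 546, 315, 308, 457),
    3: (1200, 3351, 1951, 1040, 1159, 1407),
}

#: hospital deaths per (intensity group, age band)
_DEATHS = {
    0: (35, 180, 105, 81, 108, 229),
    1: (30, 102, 83, 55, 70, 121),
    2: (41, 146, 100, 65, 83, 184),
    3: (362, 1496, 1056, 574, 709, 931),
}

REFERENCE_TOTAL_STAYS = 23_578


def reference_stratum_table() -> pd.DataFrame:
    """Long-format reference table: one row per (intensity group, age band).

    Columns: ``intensity_group``, ``age_band``, ``n``, ``deaths``.
    Marginal sums reproduce the study's printed group and age-band totals.
    """
    rows = [
        {
            "intensity_group": group,
            "age_band": band,
            "n": _STAYS[group][i],
            "deaths": _DEATHS[group][i],
        }
        for group in sorted(_STAYS)
        for i, band in enumerate(AGE_BANDS)
    ]
    table = pd.DataFrame(rows)
    assert int(table["n"].sum()) == REFERENCE_TOTAL_STAYS
    return table
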