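"""Printed summary tables of a published UAV survey, kept as fixtures.

These are the raw published numbers from an 80 ha dry-forest survey in the
Lambayeque region of Northern Peru (the landscape whose rule set this package
implements): plot-level detection counts, the whole-map raw tree counts, the
4-class error matrix of 441 validation trees, and — for cross-checking — the
derived statistics as printed. The package's accuracy machinery recomputes
every derived quantity from the raw counts at run time; the printed derived
values serve only for side-by-side comparison.

One printed cell is not reproducible from the stated adjustment rule: the
alive-Algarrobo adjusted count (1122, versus raw/rate = 1150). Reports flag
it rather than silently matching it.
"""

from __future__ import annotations

import pandas as pd

from .classify import CLASSES

SURVEY_AREA_HA = 80.0

#: plot-level detection assessment: crowns classified on the map vs trees
#: recorded in the four 1 ha field plots (crowns > 4 m2; Overo excluded)
DETECTION_CLASSIFIED = {"sapote": 72, "algarrobo_alive": 59, "algarrobo_dead": 73}
DETECTION_REFERENCE = {"sapote": 76, "algarrobo_alive": 51, "algarrobo_dead": 87}

#: whole-map raw (unadjusted) tree counts
RAW_MAP_COUNTS = {"sapote": 743, "algarrobo_alive": 1331, "algarrobo_dead": 504}

#: published adjusted counts; alive Algarrobo does not follow the stated rule
PUBLISHED_ADJUSTED = {"sapote": 784, "algarrobo_alive": 1122, "algarrobo_dead": 601}
UNRECONCILED_ADJUSTED_CLASSES = ("algarrobo_alive",)

#: 441 validation trees: rows = classified, columns = reference
#: class order: sapote, overo, algarrobo_alive, algarrobo_dead
ERROR_MATRIX_COUNTS = [
    [67, 0, 0, 0],
    [1, 225, 1, 9],
    [8, 1, 49, 4],
    [0, 1, 1, 74],
]

#: derived statistics as printed, for side-by-side comparison only
PUBLISHED_DETECTION_RATES_PCT = {
    "sapote": 94.73684,
    "algarrobo_alive": 115.6863,
    "algarrobo_dead": 83.90805,
    "total": 95.3271,
}
PUBLISHED_OVERALL_ACCURACY_PCT = 94.10
PUBLISHED_PRODUCERS_PCT = {
    "sapote": 88.16, "overo": 99.12, "algarrobo_alive": 96.08, "algarrobo_dead": 85.06,
}
PUBLISHED_USERS_PCT = {
    "sapote": 100.00, "overo": 95.34, "algarrobo_alive": 79.03, "algarrobo_dead": 97.37,
}
PUBLISHED_DENSITY_PER_HA = {
    "sapote": 9.8, "algarrobo_alive": 14.0, "algarrobo_dead": 7.5, "total": 31.3,
}
PUBLISHED_PCT_TREES = {"sapote": 31, "algarrobo": 69}
PUBLISHED_PCT_DEAD_ALGARROBO = 35
PUBLISHED_ALGARROBO_PER_HA = 21.5


def error_matrix_frame() -> pd.DataFrame:
    return pd.DataFrame(ERROR_MATRIX_COUNTS, index=list(CLASSES), columns=list(CLASSES))


def error_matrix_samples() -> list[tuple[str, str]]:
    """The 441 (reference, classified) pairs implied by the error matrix."""
    samples = []
    for clf in CLASSES:
        for ref in CLASSES:
            n = error_matrix_frame().at[clf, ref]
            samples.extend([(ref, clf)] * int(n))
    return samples
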