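"""Published placebo-cohort onset summaries for SOD1-G93A wheel-running studies.

Summary statistics (mean age at 20% reduction, SD, printed CV) for seven
placebo/control cohorts run over 18 months with the same home-cage
running-wheel protocol, plus the pooled row over all animals. These are the
standard reference inputs for the reproducibility (within/between-study CV)
and group-size calculations in :mod:`runwheel.cohort` and
:mod:`runwheel.power`.

The printed CV column is carried verbatim; note that for study 1 distance
the printed value (7.4) differs from the rounded recomputation from the
printed mean and SD (7.5), presumably because it was computed from the
unrounded raw data.
"""

from __future__ import annotations

import pandas as pd

METRICS = ("distance", "time", "avg_speed")

# study_id, n, metric -> (mean onset age d, SD d, printed CV %)
_ROWS = [
    ("1", 15, "distance", 44.27, 3.31, 7.4),
    ("1", 15, "time", 45.57, 4.54, 10.0),
    ("1", 15, "avg_speed", 47.13, 3.76, 8.0),
    ("2", 8, "distance", 41.75, 3.28, 7.9),
    ("2", 8, "time", 43.13, 3.98, 9.2),
    ("2", 8, "avg_speed", 43.38, 4.34, 10.0),
    ("3", 9, "distance", 43.22, 4.44, 10.3),
    ("3", 9, "time", 44.56, 3.40, 7.6),
    ("3", 9, "avg_speed", 48.25, 5.80, 12.0),
    ("4", 7, "distance", 44.71, 5.44, 12.2),
    ("4", 7, "time", 44.29, 9.62, 21.7),
    ("4", 7, "avg_speed", 45.80, 1.92, 4.2),
    ("5", 6, "distance", 44.67, 4.23, 9.5),
    ("5", 6, "time", 45.00, 3.69, 8.2),
    ("5", 6, "avg_speed", 46.00, 5.10, 11.1),
    ("6", 12, "distance", 45.21, 3.40, 7.5),
    ("6", 12, "time", 46.07, 3.79, 8.2),
    ("6", 12, "avg_speed", 46.42, 2.31, 5.0),
    ("7", 14, "distance", 42.86, 4.09, 9.5),
    ("7", 14, "time", 43.93, 5.02, 11.4),
    ("7", 14, "avg_speed", 48.67, 4.52, 9.3),
    ("all", 71, "distance", 43.85, 3.93, 9.0),
    ("all", 71, "time", 44.77, 4.84, 10.8),
    ("all", 71, "avg_speed", 46.77, 4.21, 9.0),
]

#: Tidy reference table: one row per study and metric.
REFERENCE_SUMMARIES = pd.DataFrame(
    _ROWS, columns=["study_id", "n", "metric", "mean_onset", "sd_onset", "cv_printed"]
)

#: Pooled (all-animal) SDs in days, the conventional inputs to group-size
#: calculations on these endpoints.
POOLED_SD = {"distance": 3.93, "time": 4.84, "avg_speed": 4.21}
POOLED_MEAN = {"distance": 43.85, "time": 44.77, "avg_speed": 46.77}


def study_means(metric: str) -> list[float]:
    """Per-study mean onset ages for one metric (excluding the pooled row)."""
    df = REFERENCE_SUMMARIES
    sel = df[(df["metric"] == metric) & (df["study_id"] != "all")]
    if sel.empty:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return sel["mean_onset"].tolist()
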