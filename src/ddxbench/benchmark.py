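"""Published reference results of the 400-vignette symptom-checker benchmark.

These constants are the reported aggregate results of the benchmark study
this framework implements: the per-physician accuracy table (three primary
care physicians who each diagnosed all 400 gold-standard vignettes), the
best-performing symptom checker's aggregate row, and the session-failure
counts of the six tested symptom checkers.  They serve as reference inputs
for reproducing the study's group statistics and failure accounting; the
underlying per-session data are published separately and are not required
by this package.

All values are percentages as printed (one decimal), except failure counts.
"""

from __future__ import annotations

#: Reported accuracy (%) of the three physicians over the 400-vignette suite.
#: Keys follow :class:`ddxbench.metrics.RaterSummary` metric names.
PHYSICIAN_RESULTS: dict[str, dict[str, float]] = {
    "MD_1": {
        "m1_pct": 49.7,
        "m3_pct": 62.0,
        "m5_pct": 62.7,
        "avg_recall_pct": 41.2,
        "avg_precision_pct": 58.6,
        "f1_pct": 48.4,
        "avg_ndcg_pct": 52.2,
    },
    "MD_2": {
        "m1_pct": 61.3,
        "m3_pct": 67.2,
        "m5_pct": 67.5,
        "avg_recall_pct": 41.2,
        "avg_precision_pct": 78.1,
        "f1_pct": 53.9,
        "avg_ndcg_pct": 58.0,
    },
    "MD_3": {
        "m1_pct": 72.5,
        "m3_pct": 88.2,
        "m5_pct": 88.5,
        "avg_recall_pct": 57.3,
        "avg_precision_pct": 71.7,
        "f1_pct": 63.7,
        "avg_ndcg_pct": 73.5,
    },
}

#: Reported aggregate accuracy (%) of the best-performing symptom checker.
AVEY_RESULTS: dict[str, float] = {
    "m1_pct": 67.5,
    "m3_pct": 87.3,
    "m5_pct": 90.0,
    "avg_recall_pct": 72.9,
    "avg_precision_pct": 43.7,
    "f1_pct": 54.6,
    "avg_ndcg_pct": 76.6,
}

#: Suite size of the benchmark.
SUITE_SIZE = 400

#: Reported session-failure counts per symptom checker over the 400 vignettes
#: (order: search limitations, age limitations, crashes, sessions concluded
#: without a differential).  Success counts are the remainder to 400.
CHECKER_FAILURES: dict[str, dict[str, int]] = {
    "Avey": {"search_limit": 0, "age_limit": 0, "crash": 0, "no_ddx": 2},
    "Ada": {"search_limit": 0, "age_limit": 0, "crash": 0, "no_ddx": 0},
    "WebMD": {"search_limit": 2, "age_limit": 1, "crash": 0, "no_ddx": 3},
    "K Health": {"search_limit": 18, "age_limit": 35, "crash": 0, "no_ddx": 2},
    "Buoy": {"search_limit": 2, "age_limit": 3, "crash": 5, "no_ddx": 74},
    "Babylon": {"search_limit": 15, "age_limit": 0, "crash": 0, "no_ddx": 351},
}
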