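"""Published prostate-cancer cohort characteristics.

Descriptive tables for the two cohorts the method was developed on: the
MSKCC cohort (expression-profiled primary/metastatic prostate tumors,
long follow-up) and the TCGA prostate adenocarcinoma cohort (larger,
shorter follow-up). Counts are per the published characteristics tables;
Gleason-score percentages are computed over patients with a recorded
Gleason score (per-cohort missingness noted below).
"""

from __future__ import annotations

from typing import Mapping

__all__ = ["TAYLOR_COHORT", "TCGA_COHORT", "gleason_percentages", "bcr_event_counts"]

TAYLOR_COHORT: dict = {
    "name": "Taylor",
    "n_samples": 150,
    # patients per Gleason stratum (recorded scores only)
    "gleason_counts": {"<=6": 80, "7": 50, "8": 10, ">=9": 9},
    "n_gleason_missing": 1,
    "n_bcr_missing": 10,
    "pct_bcr": 25.7,
    "median_followup_months": 45.5,
    "expression_platform": "exon array",
    "cna_platform": "aCGH",
}

TCGA_COHORT: dict = {
    "name": "TCGA",
    "n_samples": 498,
    "gleason_counts": {"<=6": 37, "7": 224, "8": 58, ">=9": 118},
    "n_gleason_missing": 61,
    "n_bcr_missing": 114,
    "pct_bcr": 15.4,
    "median_followup_months": 16.2,
    "expression_platform": "RNA-seq",
    "cna_platform": "SNP array",
}


def gleason_percentages(cohort: Mapping) -> dict[str, float]:
    """Percentage of patients per Gleason stratum among recorded scores.

    The denominator is ``n_samples - n_gleason_missing``; results are
    rounded to one decimal, matching the convention of published
    characteristics tables.
    """
    denom = cohort["n_samples"] - cohort["n_gleason_missing"]
    if denom <= 0:
        raise ValueError("no patients with recorded Gleason score")
    counts = cohort["gleason_counts"]
    if sum(counts.values()) != denom:
        raise ValueError(
            f"stratum counts sum to {sum(counts.values())}, expected {denom}"
        )
    return {k: round(100.0 * v / denom, 1) for k, v in counts.items()}


def bcr_event_counts(cohort: Mapping) -> dict[str, float]:
    """Recurrence follow-up summary: patients with outcome data and the
    implied number of recurrence events at the reported rate."""
    n_followed = cohort["n_samples"] - cohort["n_bcr_missing"]
    return {
        "n_followed": n_followed,
        "n_events_implied": round(cohort["pct_bcr"] / 100.0 * n_followed),
    }
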