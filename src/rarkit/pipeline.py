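"""End-to-end per-subject metric extraction and cohort assembly.

`subject_metrics` runs every estimator on one day-aligned recording and
returns a flat row; `cohort_metrics` maps it over a manifest or an in-memory
cohort into the tidy per-subject table the cohort analyses consume.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .config import Config
from .cohort import FEATURE_NAMES, SubjectFeatures
from .cosinor import fit_cosinor
from .extended_cosine import fit_extended_cosine
from .io import CohortManifest, DayMatrix, EpochSeries, hourly_totals, read_epoch_csv, trim_to_full_days
from .nonparam import interdaily_stability, intradaily_variability
from .sleep import detect_sleep_bouts, summarize_sleep


def subject_metrics(
    dm: DayMatrix, group: str = "", config: Config | None = None
) -> dict:
    """All per-subject RAR metrics for one day-aligned recording."""
    cos = fit_cosinor(dm)
    ext = fit_extended_cosine(dm, config=config)
    hourly = hourly_totals(dm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        iv = intradaily_variability(hourly)
        is_ = interdaily_stability(hourly, dm.days)
    sleep = summarize_sleep(detect_sleep_bouts(dm, config=config), dm.days)
    return {
        "subject_id": dm.subject_id,
        "group": group,
        "n_days": dm.days,
        "mesor": cos.mesor,
        "amplitude": cos.amplitude,
        "acrophase_h": cos.acrophase_h,
        "pseudo_F": ext.pseudo_F,
        "F_per_day": ext.F_per_day,
        "ext_alpha": ext.alpha,
        "ext_beta": ext.beta,
        "IV": iv,
        "IS": is_,
        "total_daily_sleep_min": sleep.total_daily_sleep_min,
        "bouts_per_day": sleep.bouts_per_day,
    }


def cohort_metrics(
    cohort: CohortManifest | list[tuple[EpochSeries, str]],
    config: Config | None = None,
) -> pd.DataFrame:
    """Per-subject metric table for a manifest or in-memory (series, group) list."""
    rows = []
    if isinstance(cohort, CohortManifest):
        items = [
            (read_epoch_csv(path, subject_id=sid, config=config), grp)
            for sid, path, grp in cohort.entries
        ]
    else:
        items = cohort
    for series, group in items:
        dm = trim_to_full_days(series)
        rows.append(subject_metrics(dm, group=group, config=config))
    return pd.DataFrame(rows)


def features_from_metrics(metrics: pd.DataFrame) -> list[SubjectFeatures]:
    """Extract the 4-D phenotype vectors (un-z-scored) from a metric table."""
    return [
        SubjectFeatures(
            subject_id=row["subject_id"],
            group=row["group"],
            raw=row[list(FEATURE_NAMES)].to_numpy(dtype=float),
        )
        for _, row in metrics.iterrows()
    ]
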