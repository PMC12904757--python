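"""Long-format multivariate longitudinal cohorts.

A cohort couples two tables: a *visits* table with one row per
subject-visit (subject id, time in years since disease onset, and K
biomarker readings) and a *baseline* table with one row per subject
(binary or continuous covariates).  Both the mixture model and the
sequential-updating machinery assume complete data: any row with a
missing biomarker or covariate is rejected at load time rather than
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LongCohort",
    "InclusionReport",
    "SchemaError",
    "ValidationError",
    "ReferentialError",
    "read_cohort",
    "apply_inclusion_criteria",
]

SUBJECT_COL = "subject_id"
TIME_COL = "time_years"


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ValidationError(ValueError):
    """A row violates the complete-data / ordering contract."""


class ReferentialError(ValueError):
    """A visit references a subject with no baseline row."""


@dataclass(frozen=True)
class LongCohort:
    """Validated long-format cohort.

    Attributes
    ----------
    visits : pandas.DataFrame
        Columns ``subject_id``, ``time_years`` and one column per
        biomarker, sorted by (subject, time) with strictly increasing
        times within subject.
    baselines : pandas.DataFrame
        One row per subject; columns ``subject_id`` plus covariates.
    k_names : tuple of str
        Biomarker column labels, in model order.
    """

    visits: pd.DataFrame
    baselines: pd.DataFrame
    k_names: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return len(self.baselines)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def subject_ids(self) -> list:
        return list(self.baselines[SUBJECT_COL])

    def covariate_names(self) -> list[str]:
        return [c for c in self.baselines.columns if c != SUBJECT_COL]

    def subject_visits(self, subject_id) -> pd.DataFrame:
        return self.visits[self.visits[SUBJECT_COL] == subject_id]

    def visit_counts(self) -> pd.Series:
        return self.visits.groupby(SUBJECT_COL, sort=False).size()


@dataclass(frozen=True)
class InclusionReport:
    """Per-rule exclusion bookkeeping for :func:`apply_inclusion_criteria`."""

    visits_outside_window: int = 0
    subjects_too_few_visits: int = 0
    subjects_late_first_visit: int = 0
    excluded_subject_ids: tuple = field(default_factory=tuple)


def _validate(visits: pd.DataFrame, baselines: pd.DataFrame,
              k_names: tuple[str, ...]) -> LongCohort:
    for col in (SUBJECT_COL, TIME_COL, *k_names):
        if col not in visits.columns:
            raise SchemaError(f"visits table lacks required column {col!r}")
    if SUBJECT_COL not in baselines.columns:
        raise SchemaError(f"baseline table lacks required column {SUBJECT_COL!r}")

    value_cols = [TIME_COL, *k_names]
    bad = visits.index[visits[value_cols].isna().any(axis=1)]
    if len(bad):
        raise ValidationError(
            "visits rows with missing time or biomarker values "
            f"(complete-data contract): rows {list(bad[:20])}"
        )
    cov_cols = [c for c in baselines.columns if c != SUBJECT_COL]
    bad = baselines.index[baselines[cov_cols].isna().any(axis=1)]
    if len(bad):
        raise ValidationError(
            f"baseline rows with missing covariates: rows {list(bad[:20])}"
        )
    if not np.isfinite(visits[value_cols].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite time or biomarker values in visits")
    if (visits[TIME_COL] < 0).any():
        raise ValidationError("negative time_years in visits")

    if baselines[SUBJECT_COL].duplicated().any():
        dup = baselines.loc[baselines[SUBJECT_COL].duplicated(), SUBJECT_COL]
        raise ValidationError(f"duplicate baseline rows for subjects {list(dup)}")
    known = set(baselines[SUBJECT_COL])
    orphan = set(visits[SUBJECT_COL]) - known
    if orphan:
        raise ReferentialError(
            f"visits reference subjects absent from baseline table: {sorted(map(str, orphan))}"
        )

    visits = visits.sort_values([SUBJECT_COL, TIME_COL], kind="mergesort").reset_index(drop=True)
    # same-day repeat measurements would break the strictly-increasing-time
    # invariant that prefix-based sequential updating relies on
    dup = visits.duplicated([SUBJECT_COL, TIME_COL])
    if dup.any():
        rows = visits.loc[dup, [SUBJECT_COL, TIME_COL]]
        raise ValidationError(
            f"duplicate (subject, time) visit rows: {rows.to_dict('records')[:10]}"
        )
    baselines = baselines.sort_values(SUBJECT_COL, kind="mergesort").reset_index(drop=True)
    return LongCohort(visits=visits, baselines=baselines, k_names=tuple(k_names))


def make_cohort(visits: pd.DataFrame, baselines: pd.DataFrame,
                k_names) -> LongCohort:
    """Validate in-memory tables into a :class:`LongCohort`."""
    return _validate(visits.copy(), baselines.copy(), tuple(k_names))


def read_cohort(visits_path, baseline_path, k_names,
                covariate_names=None) -> LongCohort:
    """Read and validate a cohort from two CSV files.

    Parameters
    ----------
    visits_path, baseline_path : path-like
        CSVs with a header row; see the column contracts on
        :class:`LongCohort`.
    k_names : sequence of str
        Biomarker columns expected in the visits file.
    covariate_names : sequence of str, optional
        If given, the baseline file must contain exactly these
        covariates; extra columns are dropped.
    """
    visits = pd.read_csv(visits_path)
    baselines = pd.read_csv(baseline_path)
    if covariate_names is not None:
        missing = [c for c in covariate_names if c not in baselines.columns]
        if missing:
            raise SchemaError(f"baseline table lacks covariate columns {missing}")
        baselines = baselines[[SUBJECT_COL, *covariate_names]]
    return _validate(visits, baselines, tuple(k_names))


def apply_inclusion_criteria(cohort: LongCohort, window_years: float = 10.0,
                             min_visits: int = 3, first_visit_by: float = 5.0,
                             ) -> tuple[LongCohort, InclusionReport]:
    """Apply the study's inclusion rules and report what was dropped.

    Visits after ``window_years`` are discarded; subjects then need at
    least ``min_visits`` remaining visits, the first of which must fall
    at or before ``first_visit_by`` years after onset.
    """
    v = cohort.visits
    in_window = v[TIME_COL] <= window_years
    n_outside = int((~in_window).sum())
    v = v[in_window]

    grp = v.groupby(SUBJECT_COL, sort=False)
    counts = grp.size()
    first_time = grp[TIME_COL].min()

    enough = counts >= min_visits
    early = first_time <= first_visit_by
    keep = counts.index[enough & early]
    # attribute each exclusion to the first rule it fails
    too_few = counts.index[~enough]
    late_first = counts.index[enough & ~early]

    kept_visits = v[v[SUBJECT_COL].isin(set(keep))].reset_index(drop=True)
    kept_base = cohort.baselines[
        cohort.baselines[SUBJECT_COL].isin(set(keep))
    ].reset_index(drop=True)

    excluded = set(cohort.baselines[SUBJECT_COL]) - set(keep)
    report = InclusionReport(
        visits_outside_window=n_outside,
        subjects_too_few_visits=len(too_few) + int(
            (~cohort.baselines[SUBJECT_COL].isin(set(counts.index))).sum()),
        subjects_late_first_visit=len(late_first),
        excluded_subject_ids=tuple(sorted(map(str, excluded))),
    )
    out = replace(cohort, visits=kept_visits, baselines=kept_base)
    return out, report
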