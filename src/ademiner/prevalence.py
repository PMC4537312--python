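"""Patient-level ADE flags, stratified prevalence tables and chi-square.

The downstream epidemiological question is not "how many mentions" but "how
many patients": a patient is flagged positive for an ADE if any document of
theirs contains at least one positive mention. Flags are crossed with a
patient attribute table (age band, gender, ethnicity, diagnosis) to produce
per-stratum prevalence, and heterogeneity across strata is tested with the
Pearson chi-square statistic on the strata × {positive, negative} table,
without continuity correction.

``reconstruct_counts`` recovers integer per-stratum counts from prevalences
printed as rounded percentages, which is how published tables that omit raw
counts can be re-analysed; the shipped reference table (see
:func:`load_reference_prevalence`) round-trips exactly under half-up
rounding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .corpus import ValidationError
from .gazetteer import Mention

__all__ = [
    "PatientFlag",
    "StratifiedTable",
    "ChiSquareResult",
    "patient_level_flags",
    "build_stratified_table",
    "pearson_chi_square",
    "reconstruct_counts",
    "load_reference_prevalence",
    "reference_stratum_counts",
]


@dataclass(frozen=True)
class PatientFlag:
    patient_id: str
    ade_id: str
    positive: bool


@dataclass(frozen=True)
class StratifiedTable:
    """Per-stratum cohort sizes, positive counts and percent prevalences."""

    stratum_labels: tuple[str, ...]
    cohort_sizes: tuple[int, ...]
    positive_counts: tuple[int, ...]

    @property
    def prevalences_percent(self) -> tuple[float, ...]:
        return tuple(
            100.0 * p / n if n else 0.0 for p, n in zip(self.positive_counts, self.cohort_sizes)
        )

    @property
    def total_cohort(self) -> int:
        return sum(self.cohort_sizes)

    @property
    def total_positive(self) -> int:
        return sum(self.positive_counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum_labels,
                "cohort_size": self.cohort_sizes,
                "positive": self.positive_counts,
                "prevalence_percent": self.prevalences_percent,
            }
        )

    def counts_matrix(self) -> list[list[int]]:
        """Strata × {positive, negative} contingency counts."""
        return [[p, n - p] for p, n in zip(self.positive_counts, self.cohort_sizes)]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def patient_level_flags(
    mentions: Sequence[Mention],
    ade_id: str,
    patient_ids: Iterable[str] | None = None,
) -> list[PatientFlag]:
    """Collapse mention-level output to one flag per patient.

    A patient is positive iff they have >= 1 positive-status mention of
    ``ade_id``. ``patient_ids`` supplies the full cohort roster so that
    patients without any mention appear as negatives; if omitted, the roster
    is the set of patients seen in ``mentions``.
    """
    relevant = [m for m in mentions if m.ade_id == ade_id]
    for m in relevant:
        if m.patient_id is None:
            raise ValidationError(
                f"mention in doc {m.doc_id!r} has no patient_id; cannot aggregate"
            )
    positives = {m.patient_id for m in relevant if m.is_positive}
    roster = set(patient_ids) if patient_ids is not None else {m.patient_id for m in relevant}
    roster |= positives
    return [PatientFlag(pid, ade_id, pid in positives) for pid in sorted(roster)]


def build_stratified_table(
    flags: Sequence[PatientFlag],
    patient_attributes: pd.DataFrame,
    stratifier: str,
    stratum_order: Sequence[str] | None = None,
) -> StratifiedTable:
    """Cross patient flags with an attribute column to get per-stratum counts.

    ``patient_attributes`` must have a ``patient_id`` column plus the
    ``stratifier`` column; patients missing the attribute fall into an
    explicit "unknown" stratum.
    """
    attr = patient_attributes.set_index("patient_id")[stratifier]
    flag_map = {f.patient_id: f.positive for f in flags}
    rows: dict[str, list[int]] = {}
    for pid in attr.index:
        stratum = attr.loc[pid]
        stratum = "unknown" if pd.isna(stratum) else str(stratum)
        cohort = rows.setdefault(stratum, [0, 0])
        cohort[0] += 1
        cohort[1] += int(flag_map.get(pid, False))
    labels = list(stratum_order) if stratum_order is not None else sorted(rows)
    for lab in rows:
        if lab not in labels:
            labels.append(lab)
    return StratifiedTable(
        stratum_labels=tuple(labels),
        cohort_sizes=tuple(rows.get(l, [0, 0])[0] for l in labels),
        positive_counts=tuple(rows.get(l, [0, 0])[1] for l in labels),
    )


def pearson_chi_square(table: Sequence[Sequence[int]] | StratifiedTable) -> ChiSquareResult:
    """Pearson X² on an r × c contingency table, no continuity correction.

    X² = Σ (obs − exp)² / exp with expectations from the row/column margins;
    df = (r−1)(c−1). The p-value comes from the chi-square survival function.
    """
    if isinstance(table, StratifiedTable):
        cells = table.counts_matrix()
    else:
        cells = [list(map(float, row)) for row in table]
    r, c = len(cells), len(cells[0]) if cells else 0
    if r < 2 or c < 2:
        raise ValidationError("contingency table must be at least 2x2")
    row_sums = [sum(row) for row in cells]
    col_sums = [sum(col) for col in zip(*cells)]
    total = sum(row_sums)
    if any(s <= 0 for s in row_sums + col_sums):
        raise ValidationError("zero row or column margin; expected counts undefined")
    x2 = 0.0
    for i in range(r):
        for j in range(c):
            exp = row_sums[i] * col_sums[j] / total
            x2 += (cells[i][j] - exp) ** 2 / exp
    df = (r - 1) * (c - 1)
    return ChiSquareResult(statistic=x2, df=df, p_value=float(stats.chi2.sf(x2, df)))


def reconstruct_counts(prevalence_percent: float, cohort_size: int) -> int:
    """Integer count behind a percent prevalence, rounding half up.

    round-half-up(prevalence/100 × cohort): (5.00, 1260) → 63.
    """
    if not (0.0 <= prevalence_percent <= 100.0):
        raise ValidationError("prevalence must be within [0, 100] percent")
    if cohort_size < 0:
        raise ValidationError("cohort size must be non-negative")
    return math.floor(prevalence_percent / 100.0 * cohort_size + 0.5)


def load_reference_prevalence() -> dict:
    """Published stratified EPSE prevalence reference values.

    Cohort sizes and percent prevalences of four extrapyramidal side effects
    (dystonia, akathisia, parkinsonism, tardive dyskinesia) in 12,879
    patients with serious mental illness from a de-identified psychiatric
    case register, stratified by age band, gender, ethnicity and diagnosis,
    together with the published chi-square statistics. Shipped so the
    reported statistics can be recomputed from the printed values.
    """
    with resources.files("ademiner").joinpath("data/epse_prevalence_reference.json").open(
        encoding="utf-8"
    ) as fh:
        return json.load(fh)


def reference_stratum_counts(partition: Mapping, ade_id: str) -> StratifiedTable:
    """Reconstruct integer counts for one partition × ADE of the reference."""
    labels, cohorts, counts = [], [], []
    for stratum in partition["strata"]:
        labels.append(stratum["label"])
        cohorts.append(int(stratum["cohort_size"]))
        counts.append(reconstruct_counts(stratum["prevalence_percent"][ade_id], cohorts[-1]))
    return StratifiedTable(tuple(labels), tuple(cohorts), tuple(counts))
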