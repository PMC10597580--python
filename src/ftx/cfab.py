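"""Composite functional assessment battery (CFAB) scoring.

Each of five physical-function determinants (rotarod latency, grip force,
inverted-cling time, treadmill max speed, voluntary wheel running) is
standardized against the mean/SD of a young reference group; the five
z-scores sum to the CFAB composite. Inverted-cling times are log10
transformed before standardization because the raw times are heavily
skewed. Larger raw values mean better performance for every determinant,
so no sign flips are applied.

Group comparisons use classical one-way ANOVA with unadjusted pairwise
least-significant-difference (LSD) t-tests on the pooled error term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

#: Determinant column names, in canonical order.
DETERMINANTS = ("rotarod_s", "grip_force", "inverted_cling_s", "treadmill_speed", "vwr")

#: Short phenotype aliases used by the CLI / association screen.
DETERMINANT_ALIASES = {
    "rotarod": "rotarod_s",
    "grip": "grip_force",
    "cling": "inverted_cling_s",
    "treadmill": "treadmill_speed",
    "vwr": "vwr",
}


@dataclass(frozen=True)
class FunctionalRecord:
    """Raw functional-test measurements for one animal."""

    animal_id: str
    age_group: str
    rotarod_s: float
    grip_force: float
    inverted_cling_s: float
    treadmill_speed: float
    vwr: float

    def __post_init__(self) -> None:
        for name in DETERMINANTS:
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise DomainError(f"{self.animal_id}: determinant {name!r} is missing or non-finite")
        if self.inverted_cling_s <= 0:
            raise DomainError(
                f"{self.animal_id}: inverted_cling_s must be > 0 (log10 is applied); got {self.inverted_cling_s}"
            )

    def determinant_values(self) -> dict[str, float]:
        """Determinant values on the scoring scale (cling log10-transformed)."""
        vals = {name: float(getattr(self, name)) for name in DETERMINANTS}
        vals["inverted_cling_s"] = transform_inverted_cling(vals["inverted_cling_s"])
        return vals


@dataclass(frozen=True)
class ReferenceStats:
    """Per-determinant mean/SD of the reference group (transformed scale)."""

    means: Mapping[str, float]
    sds: Mapping[str, float]
    n: int

    def __post_init__(self) -> None:
        for name in DETERMINANTS:
            if name not in self.means or name not in self.sds:
                raise DomainError(f"reference stats missing determinant {name!r}")
            if self.sds[name] <= 0:
                raise DomainError(f"reference SD for {name!r} must be > 0; got {self.sds[name]}")


@dataclass(frozen=True)
class CfabScore:
    animal_id: str
    age_group: str
    z: Mapping[str, float]
    cfab: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        object.__setattr__(self, "cfab", float(sum(self.z[name] for name in DETERMINANTS)))


def transform_inverted_cling(seconds: float) -> float:
    """log10 of an inverted-cling time; refuses non-positive times."""
    if seconds <= 0:
        raise DomainError(f"inverted cling time must be > 0 s, got {seconds}")
    return math.log10(seconds)


def determinant_score(value: float, ref_mean: float, ref_sd: float) -> float:
    """Standardized score: number of reference SDs away from the reference mean."""
    if ref_sd <= 0:
        raise DomainError(f"reference SD must be > 0, got {ref_sd}")
    return (value - ref_mean) / ref_sd


def reference_stats(records: Sequence[FunctionalRecord]) -> ReferenceStats:
    """Mean and sample SD (n-1) per determinant over the reference group.

    Inverted cling enters on the log10 scale. Raises on < 2 animals or a
    zero-variance determinant.
    """
    if len(records) < 2:
        raise DomainError(f"need >= 2 reference animals, got {len(records)}")
    table = pd.DataFrame([r.determinant_values() for r in records])
    means = table.mean()
    sds = table.std(ddof=1)
    for name in DETERMINANTS:
        if sds[name] <= 0 or not math.isfinite(sds[name]):
            raise DomainError(f"reference group has zero variance in {name!r}")
    return ReferenceStats(means=means.to_dict(), sds=sds.to_dict(), n=len(records))


def cfab_score(record: FunctionalRecord, ref: ReferenceStats) -> CfabScore:
    """Five determinant z-scores plus their sum for one animal."""
    vals = record.determinant_values()
    z = {
        name: determinant_score(vals[name], ref.means[name], ref.sds[name])
        for name in DETERMINANTS
    }
    return CfabScore(animal_id=record.animal_id, age_group=record.age_group, z=z)


def score_cohort(
    records: Sequence[FunctionalRecord], reference_group: str = "6m"
) -> pd.DataFrame:
    """Score every animal against the reference group's stats.

    Returns a frame indexed by animal_id with columns ``age_group``, one
    z-score per determinant (``z_<determinant>``) and ``cfab``.
    """
    ref_records = [r for r in records if r.age_group == reference_group]
    if not ref_records:
        raise DomainError(f"no animals in reference group {reference_group!r}")
    ref = reference_stats(ref_records)
    rows = []
    for rec in records:
        score = cfab_score(rec, ref)
        row = {"animal_id": rec.animal_id, "age_group": rec.age_group}
        row.update({f"z_{name}": score.z[name] for name in DETERMINANTS})
        row["cfab"] = score.cfab
        rows.append(row)
    return pd.DataFrame(rows).set_index("animal_id")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    pval: float
    df_between: int
    df_within: int
    mse: float
    lsd: pd.DataFrame  # columns: group_a, group_b, diff, t, pval


def group_anova_lsd(values: Sequence[float], groups: Sequence[str]) -> AnovaResult:
    """One-way ANOVA plus pairwise LSD post hoc tests.

    LSD = unadjusted pairwise t-tests using the pooled within-group mean
    square, on the within-group degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise DomainError("values and groups must have equal length")
    labels = list(dict.fromkeys(g))  # preserve first-appearance order
    if len(labels) < 2:
        raise DomainError("need >= 2 groups")
    parts = {lab: y[g == lab] for lab in labels}
    for lab, part in parts.items():
        if part.size < 2:
            raise DomainError(f"group {lab!r} has < 2 observations")

    grand = y.mean()
    ss_between = sum(p.size * (p.mean() - grand) ** 2 for p in parts.values())
    ss_within = sum(((p - p.mean()) ** 2).sum() for p in parts.values())
    df_b = len(labels) - 1
    df_w = y.size - len(labels)
    if ss_within == 0 and ss_between == 0:
        f_stat, pval = 0.0, 1.0
        mse = 0.0
    else:
        mse = ss_within / df_w
        if mse == 0:
            raise DomainError("zero within-group variance; F undefined")
        f_stat = (ss_between / df_b) / mse
        pval = float(stats.f.sf(f_stat, df_b, df_w))

    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            diff = parts[a].mean() - parts[b].mean()
            if mse == 0:
                t_stat, p_pair = 0.0, 1.0
            else:
                se = math.sqrt(mse * (1 / parts[a].size + 1 / parts[b].size))
                t_stat = diff / se
                p_pair = float(2 * stats.t.sf(abs(t_stat), df_w))
            rows.append({"group_a": a, "group_b": b, "diff": diff, "t": t_stat, "pval": p_pair})
    lsd = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "t", "pval"])
    return AnovaResult(f=float(f_stat), pval=float(pval), df_between=df_b, df_within=df_w, mse=float(mse), lsd=lsd)


def records_from_frame(meta: pd.DataFrame) -> list[FunctionalRecord]:
    """Build one FunctionalRecord per unique animal from a metadata table.

    The table must carry ``animal_id``, ``age_group`` and the five
    determinant columns; duplicated animal rows (technical replicate
    libraries) are collapsed to the first occurrence after checking the
    measurements agree.
    """
    needed = {"animal_id", "age_group", *DETERMINANTS}
    missing = needed - set(meta.columns)
    if missing:
        raise DomainError(f"metadata missing columns: {sorted(missing)}")
    records = []
    for animal_id, sub in meta.groupby("animal_id", sort=False):
        first = sub.iloc[0]
        for name in DETERMINANTS:
            if not np.allclose(sub[name], first[name]):
                raise DomainError(f"animal {animal_id!r} has inconsistent {name!r} across rows")
        records.append(
            FunctionalRecord(
                animal_id=str(animal_id),
                age_group=str(first["age_group"]),
                **{name: float(first[name]) for name in DETERMINANTS},
            )
        )
    return records
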