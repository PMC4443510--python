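"""Germination assays and the weighted germination index (GI).

The GI summarises a multi-day germination test into a single dormancy
phenotype: grains germinating early receive higher weight, so

    GI = sum_{d=1..n} (n - d + 1) * N_d / (n * total_grains)

where ``N_d`` is the number of grains newly germinated on day ``d`` of an
``n``-day test. GI is 1 when every grain germinates on day 1 (complete loss
of dormancy) and 0 when none germinate within the test window (full
dormancy). The classic screen runs for seven days, but any ``n >= 1`` is
accepted with weight ``n - d + 1`` on day ``d``.

Counts are *newly germinated grains per day*, not cumulative totals; callers
holding cumulative curves must difference them first (the CLI offers a
``--cumulative`` flag that does so).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

GENOTYPE_CLASSES = ("donor_hom", "other_hom", "het", "unknown")
TREATMENTS = ("light", "dark")

DEFAULT_N_DAYS = 7


@dataclass(frozen=True)
class GerminationRecord:
    """Daily germination counts for one plate of grains.

    ``daily_new_germinations[d-1]`` is the number of grains that newly
    germinated on day ``d``; grains never germinating simply contribute
    weight zero (there is no explicit "day n+1" term).
    """

    sample_id: str
    genotype_class: str
    treatment: str
    total_grains: int
    daily_new_germinations: tuple[int, ...]
    n_days: int = 0  # 0 means "use len(daily_new_germinations)"

    def __post_init__(self) -> None:
        daily = tuple(int(x) for x in self.daily_new_germinations)
        object.__setattr__(self, "daily_new_germinations", daily)
        n_days = self.n_days if self.n_days else len(daily)
        object.__setattr__(self, "n_days", n_days)
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValidationError(
                f"genotype_class: {self.genotype_class!r} not in {GENOTYPE_CLASSES}"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"treatment: {self.treatment!r} not in {TREATMENTS}")
        if n_days < 1:
            raise ValidationError(f"n_days: must be >= 1, got {n_days}")
        if len(daily) != n_days:
            raise ValidationError(
                f"daily_new_germinations: length {len(daily)} != n_days {n_days}"
            )
        if self.total_grains < 1:
            raise ValidationError(f"total_grains: must be >= 1, got {self.total_grains}")
        if any(x < 0 for x in daily):
            raise ValidationError("daily_new_germinations: counts must be >= 0")
        if sum(daily) > self.total_grains:
            raise ValidationError(
                f"daily_new_germinations: sum {sum(daily)} exceeds "
                f"total_grains {self.total_grains}"
            )


def compute_gi(record: GerminationRecord) -> float:
    """Weighted germination index in [0, 1] for one plate."""
    n = record.n_days
    weighted = sum(
        (n - d + 1) * nd for d, nd in enumerate(record.daily_new_germinations, start=1)
    )
    return weighted / (n * record.total_grains)


def summarize_by_class(records: Iterable[GerminationRecord]) -> pd.DataFrame:
    """Mean GI, standard error and count per (genotype_class, treatment).

    SE is the sample standard deviation over sqrt(count); groups of size one
    report SE as NaN.
    """
    records = list(records)
    if not records:
        raise ValidationError("records: empty collection")
    rows = [
        {
            "genotype_class": r.genotype_class,
            "treatment": r.treatment,
            "gi": compute_gi(r),
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    grouped = df.groupby(["genotype_class", "treatment"], sort=True)["gi"]
    out = grouped.agg(mean_gi="mean", n="count")
    sd = grouped.std(ddof=1)  # NaN for singleton groups
    out["se"] = sd / out["n"].pow(0.5)
    out["n"] = out["n"].astype(int)
    return out.reset_index()[["genotype_class", "treatment", "mean_gi", "se", "n"]]


def records_from_frame(
    df: pd.DataFrame, cumulative: bool = False
) -> list[GerminationRecord]:
    """Build records from a germination table.

    Expects columns sample_id, genotype_class, treatment, total_grains and
    day1..dayN. With ``cumulative=True`` the day columns hold running totals
    and are differenced into per-day counts.
    """
    day_cols = sorted(
        (c for c in df.columns if c.startswith("day") and c[3:].isdigit()),
        key=lambda c: int(c[3:]),
    )
    if not day_cols:
        raise ValidationError("germination table: no day1..dayN columns found")
    records = []
    for _, row in df.iterrows():
        counts = [int(row[c]) for c in day_cols]
        if cumulative:
            counts = [counts[0]] + [b - a for a, b in zip(counts, counts[1:])]
        records.append(
            GerminationRecord(
                sample_id=str(row["sample_id"]),
                genotype_class=str(row["genotype_class"]),
                treatment=str(row["treatment"]),
                total_grains=int(row["total_grains"]),
                daily_new_germinations=tuple(counts),
            )
        )
    return records
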