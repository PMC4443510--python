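"""Trait-linked SNP filtering from per-sample nucleotide depths.

Expressed SNPs that track the targeted QTL are nominated from RNA-seq
allele depths using four criteria applied to the four founder cultivars and
the per-family pool-A (QTL-positive) / pool-B (QTL-negative) samples:

1. the allele carried by the dormancy-donor founder is distinct from every
   other founder's allele;
2. the donor founder's call is either homozygous (>= 95 % of reads in
   agreement) or absent (no reads, e.g. an expression-silenced allele);
3. in at least four of the five families the pool-A sample is homozygous
   for the donor allele while the pool-B sample is homozygous for a
   different allele;
4. the candidate (donor) allele is supported by at least two reads summed
   over the samples called homozygous for it.

Depths are aggregated across timepoints per biological entity before
calling; a per-timepoint mode unions decisions over timepoints instead.
Founder rows are identified by ``pool == '.'``; family rows carry pool A/B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
DEPTH_COLUMNS = ["site_id", "contig", "pos", "entity", "pool", "timepoint", *NUCLEOTIDES]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the four trait-linked SNP criteria."""

    min_frac: float = 0.95
    min_family_concordance: int = 4
    n_families: int = 5
    min_allele_depth: int = 2
    donor_founder: str = "Yitpi"
    absent_max_depth: int = 0
    concordance_mode: str = "joint"  # or "per_pool"
    per_timepoint: bool = False

    def __post_init__(self) -> None:
        if not 0.5 < self.min_frac <= 1.0:
            raise ValidationError(f"min_frac: must be in (0.5, 1], got {self.min_frac}")
        if not 1 <= self.min_family_concordance <= self.n_families:
            raise ValidationError(
                "min_family_concordance: must be between 1 and n_families "
                f"({self.n_families}), got {self.min_family_concordance}"
            )
        if self.min_allele_depth < 1:
            raise ValidationError(
                f"min_allele_depth: must be >= 1, got {self.min_allele_depth}"
            )
        if self.concordance_mode not in ("joint", "per_pool"):
            raise ValidationError(
                f"concordance_mode: unknown mode {self.concordance_mode!r}"
            )


@dataclass(frozen=True)
class AlleleCall:
    """Per-sample allele state at one site."""

    state: str  # homozygous | absent | ambiguous
    allele: str | None
    depth: int
    agreement: float | None


@dataclass
class FilterDecision:
    """Per-site outcome of the four criteria."""

    site_id: str
    contig: str = ""
    pos: int = -1
    c1_donor_distinct: bool = False
    c2_donor_state: bool = False
    c3_family_concordance: bool = False
    c4_min_coverage: bool = False
    n_concordant_families: int = 0
    donor_allele: str | None = None
    other_allele: str | None = None
    passed: bool = False

    def finalize(self) -> "FilterDecision":
        self.passed = (
            self.c1_donor_distinct
            and self.c2_donor_state
            and self.c3_family_concordance
            and self.c4_min_coverage
        )
        return self


def call_allele_state(depths: Mapping[str, int] | Iterable[int], params: FilterParams) -> AlleleCall:
    """Call one sample at one site: homozygous, absent or ambiguous.

    Zero total coverage (up to ``absent_max_depth`` stray reads) is absent;
    a maximum-nucleotide fraction >= ``min_frac`` (inclusive) is homozygous
    for that nucleotide; anything else is ambiguous.
    """
    if isinstance(depths, Mapping):
        vec = np.array([int(depths.get(n, 0)) for n in NUCLEOTIDES])
    else:
        vec = np.asarray(list(depths), dtype=int)
        if vec.size != 4:
            raise ValidationError(f"depths: expected 4 nucleotide counts, got {vec.size}")
    if (vec < 0).any():
        raise ValidationError(f"depths: negative count in {dict(zip(NUCLEOTIDES, vec))}")
    total = int(vec.sum())
    if total <= params.absent_max_depth:
        return AlleleCall(state="absent", allele=None, depth=total, agreement=None)
    top = int(vec.argmax())
    agreement = float(vec[top]) / total
    if agreement >= params.min_frac:
        return AlleleCall(
            state="homozygous", allele=NUCLEOTIDES[top], depth=total, agreement=agreement
        )
    return AlleleCall(state="ambiguous", allele=None, depth=total, agreement=agreement)


def _aggregate(site_df: pd.DataFrame) -> pd.DataFrame:
    """Sum depths across timepoints per (entity, pool)."""
    return (
        site_df.groupby(["entity", "pool"], sort=True)[list(NUCLEOTIDES)]
        .sum()
        .reset_index()
    )


def _majority_allele(calls: list[AlleleCall]) -> str | None:
    """Most common homozygous-call allele; ties broken alphabetically."""
    votes: dict[str, int] = {}
    for c in calls:
        if c.state == "homozygous" and c.allele is not None:
            votes[c.allele] = votes.get(c.allele, 0) + 1
    if not votes:
        return None
    return sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def _evaluate_aggregated(agg: pd.DataFrame, site_id: str, contig: str, pos: int,
                         params: FilterParams) -> FilterDecision:
    founders = agg[agg["pool"] == "."]
    fam_rows = agg[agg["pool"].isin(["A", "B"])]
    families = sorted(fam_rows["entity"].unique())

    missing = []
    if params.donor_founder not in set(founders["entity"]):
        missing.append(f"founder {params.donor_founder}")
    for fam in families:
        for pool in ("A", "B"):
            if not ((fam_rows["entity"] == fam) & (fam_rows["pool"] == pool)).any():
                missing.append(f"family {fam} pool {pool}")
    if not families:
        missing.append("family pool samples")
    if missing:
        raise ValidationError(f"site {site_id}: missing required samples: {missing}")

    calls = {
        (row["entity"], row["pool"]): call_allele_state(
            {n: row[n] for n in NUCLEOTIDES}, params
        )
        for _, row in agg.iterrows()
    }
    donor_call = calls[(params.donor_founder, ".")]
    other_founders = [e for e in founders["entity"] if e != params.donor_founder]

    pool_a_calls = [calls[(f, "A")] for f in families]
    pool_b_calls = [calls[(f, "B")] for f in families]

    # candidate donor allele: donor founder's homozygous allele, else the
    # pool-A family consensus (donor may be expression-silenced => absent)
    if donor_call.state == "homozygous":
        donor_allele = donor_call.allele
    else:
        donor_allele = _majority_allele(pool_a_calls)

    # c1: donor allele distinct from every other founder. Absent or
    # ambiguous non-donor founders cannot exhibit the donor allele and are
    # non-conflicting (an ambiguous founder conflicts only if its majority
    # allele reaches min_frac, i.e. it would be called homozygous donor).
    c1 = donor_allele is not None and all(
        not (
            calls[(f, ".")].state == "homozygous"
            and calls[(f, ".")].allele == donor_allele
        )
        for f in other_founders
    )

    # c2: donor founder homozygous or absent
    c2 = donor_call.state in ("homozygous", "absent")

    # c3: family concordance with the pool assignment
    def a_matches(i: int) -> bool:
        c = pool_a_calls[i]
        return (
            donor_allele is not None
            and c.state == "homozygous"
            and c.allele == donor_allele
        )

    def b_differs(i: int) -> bool:
        c = pool_b_calls[i]
        return (
            donor_allele is not None
            and c.state == "homozygous"
            and c.allele != donor_allele
        )

    idx = range(len(families))
    if params.concordance_mode == "joint":
        n_conc = sum(1 for i in idx if a_matches(i) and b_differs(i))
        c3 = n_conc >= params.min_family_concordance
    else:  # per_pool: each pool independently reaches the threshold
        n_a = sum(1 for i in idx if a_matches(i))
        n_b = sum(1 for i in idx if b_differs(i))
        n_conc = min(n_a, n_b)
        c3 = (
            n_a >= params.min_family_concordance
            and n_b >= params.min_family_concordance
        )

    # c4: reads supporting the candidate allele, summed over entities
    # called homozygous for it
    support = 0
    if donor_allele is not None:
        col = donor_allele
        for _, row in agg.iterrows():
            call = calls[(row["entity"], row["pool"])]
            if call.state == "homozygous" and call.allele == donor_allele:
                support += int(row[col])
    c4 = donor_allele is not None and support >= params.min_allele_depth

    # REF for reporting: majority non-donor allele among pool-B families,
    # falling back to the non-donor founders
    other_allele = _majority_allele(pool_b_calls)
    if other_allele is None or other_allele == donor_allele:
        other_allele = _majority_allele(
            [calls[(f, ".")] for f in other_founders]
        )

    return FilterDecision(
        site_id=site_id,
        contig=contig,
        pos=pos,
        c1_donor_distinct=bool(c1),
        c2_donor_state=bool(c2),
        c3_family_concordance=bool(c3),
        c4_min_coverage=bool(c4),
        n_concordant_families=int(n_conc),
        donor_allele=donor_allele,
        other_allele=other_allele,
    ).finalize()


def evaluate_site(site_df: pd.DataFrame, params: FilterParams) -> FilterDecision:
    """Apply the four criteria to one site's depth rows.

    ``site_df`` holds the depth-table rows of a single site (columns
    entity, pool, timepoint, A, C, G, T plus site_id/contig/pos). Depths
    are summed across timepoints per entity unless ``params.per_timepoint``
    is set, in which case timepoints are evaluated separately and a site
    passes if any timepoint passes.
    """
    site_id = str(site_df["site_id"].iloc[0])
    contig = str(site_df["contig"].iloc[0]) if "contig" in site_df else ""
    pos = int(site_df["pos"].iloc[0]) if "pos" in site_df else -1
    if (site_df[list(NUCLEOTIDES)].to_numpy() < 0).any():
        raise ValidationError(f"site {site_id}: negative depth")
    if not params.per_timepoint:
        return _evaluate_aggregated(_aggregate(site_df), site_id, contig, pos, params)
    decisions = []
    for _, tp_df in site_df.groupby("timepoint", sort=True):
        decisions.append(
            _evaluate_aggregated(_aggregate(tp_df), site_id, contig, pos, params)
        )
    best = max(
        decisions,
        key=lambda d: (d.passed, d.n_concordant_families,
                       d.c1_donor_distinct + d.c2_donor_state
                       + d.c3_family_concordance + d.c4_min_coverage),
    )
    return best


def filter_sites(
    table, params: FilterParams | None = None
) -> tuple[list[str], list[FilterDecision]]:
    """Evaluate every site in a depth table, preserving input order.

    ``table`` is a depth DataFrame (or any object with a ``frame``
    attribute holding one). Returns (passing site ids, all decisions).
    """
    params = params or FilterParams()
    df = getattr(table, "frame", table)
    if df.empty:
        return [], []
    missing_cols = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"depth table: missing columns {missing_cols}")
    decisions = []
    for _, site_df in df.groupby("site_id", sort=False):
        decisions.append(evaluate_site(site_df, params))
    passing = [d.site_id for d in decisions if d.passed]
    logger.info("SNP filter: %d of %d sites pass", len(passing), len(decisions))
    return passing, decisions


def decisions_to_frame(decisions: Iterable[FilterDecision]) -> pd.DataFrame:
    """Machine-readable report: one row per site, per-criterion columns."""
    rows = [
        {
            "site_id": d.site_id,
            "contig": d.contig,
            "pos": d.pos,
            "c1_donor_distinct": d.c1_donor_distinct,
            "c2_donor_state": d.c2_donor_state,
            "c3_family_concordance": d.c3_family_concordance,
            "c4_min_coverage": d.c4_min_coverage,
            "n_concordant_families": d.n_concordant_families,
            "donor_allele": d.donor_allele or ".",
            "other_allele": d.other_allele or ".",
            "passed": d.passed,
        }
        for d in decisions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "contig", "pos", "c1_donor_distinct", "c2_donor_state",
            "c3_family_concordance", "c4_min_coverage", "n_concordant_families",
            "donor_allele", "other_allele", "passed",
        ],
    )
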