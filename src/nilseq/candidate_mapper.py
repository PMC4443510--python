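"""Candidate gene ranking inside a targeted QTL interval.

Joins three evidence streams on a shared contig namespace: differential
expression between the QTL pools, trait-linked SNPs surviving the
four-criterion filter (with coding-consequence annotation), and contig
placements relative to the QTL interval. In-region contigs carrying either
kind of evidence are ranked by DE significance first, coding severity as a
tie-break; out-of-region evidence is reported separately (such genes may be
downstream of the QTL rather than causal). Also provides exact-match
in-silico PCR for INDEL-spanning genetic markers.

All coordinates are 0-based half-open internally; VCF output is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import PrimerAmbiguityError, ValidationError

EFFECT_SEVERITY = {"nonsense": 3, "nonsynonymous": 2, "synonymous": 1, "noncoding": 0}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval: need 0 <= start < end, got [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class ContigPlacement:
    """Where a contig sits on the reference (0-based half-open), if placed."""

    contig_id: str
    chrom: str = ""
    start: int = 0
    end: int = 0
    placed: bool = True

    def __post_init__(self) -> None:
        if self.placed and not (0 <= self.start < self.end):
            raise ValidationError(
                f"placement {self.contig_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class GeneModel:
    """Single-ORF gene model on a contig (0-based half-open ORF)."""

    contig_id: str
    orf_start: int
    orf_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene model {self.contig_id}: strand must be + or -")
        if not 0 <= self.orf_start < self.orf_end:
            raise ValidationError(
                f"gene model {self.contig_id}: invalid ORF "
                f"[{self.orf_start}, {self.orf_end})"
            )
        if (self.orf_end - self.orf_start) % 3 != 0:
            raise ValidationError(
                f"gene model {self.contig_id}: ORF length not divisible by 3"
            )


@dataclass
class CandidateReport:
    """Ranked in-region candidates plus out-of-region evidence."""

    candidates: pd.DataFrame
    elsewhere: pd.DataFrame


def in_qtl_region(
    placement: ContigPlacement, interval: GenomicInterval, containment: bool = False
) -> bool:
    """Does the placement overlap the interval by >= 1 base (half-open)?

    Unplaced contigs are simply not in the region. ``containment`` requires
    the whole contig to lie inside the interval instead.
    """
    if not placement.placed or placement.chrom != interval.chrom:
        return False
    if containment:
        return placement.start >= interval.start and placement.end <= interval.end
    return placement.start < interval.end and placement.end > interval.start


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_snp_effect(
    model: GeneModel, sequence: str, pos: int, ref: str, alt: str
) -> str:
    """Coding consequence of a SNP: synonymous/nonsynonymous/nonsense/noncoding.

    ``pos`` is 0-based on the contig; ``ref``/``alt`` are plus-strand
    alleles. The affected codon is translated with the standard nuclear
    code on the coding strand.
    """
    ref, alt = ref.upper(), alt.upper()
    if not (0 <= pos < len(sequence)):
        raise ValidationError(f"site: position {pos} outside contig of length {len(sequence)}")
    if model.orf_end > len(sequence):
        raise ValidationError(
            f"gene model {model.contig_id}: ORF end {model.orf_end} exceeds "
            f"contig length {len(sequence)}"
        )
    if sequence[pos].upper() != ref:
        raise ValidationError(
            f"site: reference allele {ref} does not match contig base "
            f"{sequence[pos].upper()} at position {pos} (coordinate or strand bug?)"
        )
    if not (model.orf_start <= pos < model.orf_end):
        return "noncoding"
    if model.strand == "+":
        cds = sequence[model.orf_start : model.orf_end].upper()
        idx = pos - model.orf_start
        ref_c, alt_c = ref, alt
    else:
        cds = revcomp(sequence[model.orf_start : model.orf_end].upper())
        idx = model.orf_end - 1 - pos
        ref_c, alt_c = revcomp(ref), revcomp(alt)
    codon_i = idx // 3
    within = idx % 3
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_codon = codon[:within] + alt_c + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "nonsynonymous"


def _worst_effect(effects: Iterable[str]) -> str | None:
    effects = [e for e in effects if e is not None]
    if not effects:
        return None
    return max(effects, key=lambda e: EFFECT_SEVERITY.get(e, -1))


def rank_candidates(
    de_results: pd.DataFrame,
    snp_sites: pd.DataFrame,
    placements: Mapping[str, ContigPlacement] | Iterable[ContigPlacement],
    interval: GenomicInterval,
    containment: bool = False,
) -> CandidateReport:
    """Rank contigs combining DE, SNP and placement evidence.

    ``de_results`` is gene-indexed with columns padj and is_de;
    ``snp_sites`` has columns site_id, contig, passed and optionally
    effect. The candidate set is in-region contigs with is_de true or at
    least one passing SNP; ordering is padj ascending (untested contigs
    after all tested ones), then coding severity, then contig id. Evidence
    on out-of-region contigs lands in the ``elsewhere`` table.
    """
    if not isinstance(placements, Mapping):
        placements = {p.contig_id: p for p in placements}
    snp_pass = (
        snp_sites[snp_sites["passed"]]
        if len(snp_sites)
        else pd.DataFrame(columns=["site_id", "contig", "passed"])
    )
    contigs = set(de_results.index[de_results["is_de"]]) | set(snp_pass["contig"])

    rows = []
    for contig in contigs:
        placement = placements.get(contig, ContigPlacement(contig, placed=False))
        sites = snp_pass[snp_pass["contig"] == contig]
        effects = (
            list(sites["effect"]) if "effect" in sites.columns else []
        )
        padj = (
            float(de_results.loc[contig, "padj"]) if contig in de_results.index else np.nan
        )
        rows.append(
            {
                "contig": contig,
                "in_region": in_qtl_region(placement, interval, containment),
                "padj": padj,
                "is_de": bool(de_results.loc[contig, "is_de"])
                if contig in de_results.index
                else False,
                "snp_ids": ",".join(sorted(sites["site_id"])) or ".",
                "worst_effect": _worst_effect(effects) or ".",
            }
        )
    columns = ["contig", "in_region", "padj", "is_de", "snp_ids", "worst_effect"]
    frame = pd.DataFrame(rows, columns=columns)

    def sort_frame(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return df.reset_index(drop=True)
        key = df.assign(
            _padj=df["padj"].fillna(np.inf),
            _sev=-df["worst_effect"].map(lambda e: EFFECT_SEVERITY.get(e, -1)),
        )
        ordered = key.sort_values(
            ["_padj", "_sev", "contig"], kind="mergesort"
        ).index
        return df.loc[ordered].reset_index(drop=True)

    candidates = sort_frame(frame[frame["in_region"]])
    candidates["rank"] = np.arange(1, len(candidates) + 1)
    elsewhere = sort_frame(frame[~frame["in_region"]])
    return CandidateReport(candidates=candidates, elsewhere=elsewhere)


def _find_all(template: str, probe: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = template.find(probe, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def insilico_pcr(template: str, forward: str, reverse: str) -> int | None:
    """Exact-match PCR product length on a template, or None.

    The forward primer must match the plus strand exactly and the reverse
    primer must match as its reverse complement downstream; the product
    includes both primers. Multiple binding sites for either primer raise
    an ambiguity error; degenerate bases are not supported.
    """
    template = template.upper()
    forward, reverse = forward.upper(), reverse.upper()
    for name, primer in (("forward", forward), ("reverse", reverse)):
        if len(primer) < 10:
            raise ValidationError(f"{name} primer: length must be >= 10")
        if set(primer) - set("ACGT"):
            raise ValidationError(f"{name} primer: degenerate bases not supported")
    fwd_hits = _find_all(template, forward)
    rev_hits = _find_all(template, revcomp(reverse))
    if len(fwd_hits) > 1:
        raise PrimerAmbiguityError(f"forward primer binds at {len(fwd_hits)} sites")
    if len(rev_hits) > 1:
        raise PrimerAmbiguityError(f"reverse primer binds at {len(rev_hits)} sites")
    if not fwd_hits or not rev_hits:
        return None
    f0 = fwd_hits[0]
    r_end = rev_hits[0] + len(reverse)
    if rev_hits[0] < f0 + len(forward):  # wrong orientation / overlap
        return None
    return r_end - f0
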