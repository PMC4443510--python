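"""Synthetic MAGIC -> HIF -> NIL experiment generator.

Emulates the statistical structure the pipeline assumes, end to end:

* four founder cultivars, founder 0 being the dormancy donor whose allele
  at every trait-linked site differs from the other three;
* recombinant inbred lines (RILs) from a (A x B) x (C x D) funnel followed
  by selfing, with Poisson crossovers and no interference (Haldane);
* heterogeneous inbred family (HIF) founders: RILs heterozygous
  donor-vs-other across the QTL interval with near-complete background
  homozygosity, each yielding a near-isogenic pair fixed for opposite QTL
  alleles;
* negative binomial expression counts for pooled samples at 15/25/35 days
  post-anthesis, with one planted cis-regulated causal gene whose
  donor-allele effect grows with grain maturation;
* per-site nucleotide read depths at linked and decoy SNP sites, with
  coverage tied to the carrying gene's expression (a silenced allele
  yields no reads);
* semi-dominant germination phenotypes via a per-day logistic hazard
  decreasing with donor-allele dosage.

Everything is a pure function of (inputs, seed); per-operation substreams
are derived from the config seed so each stage is independently
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .candidate_mapper import ContigPlacement, GeneModel, GenomicInterval, revcomp
from .errors import ValidationError
from .phenotype import GerminationRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
TIMEPOINTS = (15, 25, 35)
BP_PER_MARKER = 10_000
CONTIG_LENGTH = 2_000

_SALTS = {
    "founders": 11,
    "ril": 12,
    "hif": 13,
    "expression": 14,
    "depths": 15,
    "germination": 16,
}


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulated experiment.

    Defaults mirror the study design: 4 founders, 5 HIF families chosen
    from a 1579-RIL F7 population, F1 -> F7 by six selfing generations,
    pooled samples at 15/25/35 DPA, and a causal-gene donor effect rising
    from log2FC 1 at 15 DPA to 3 at 35 DPA.
    """

    seed: int = 0
    n_chromosomes: int = 3
    markers_per_chromosome: int = 200
    map_length_cM: float = 150.0
    qtl_interval: tuple[int, int, int] = (0, 96, 104)  # chrom, start, end (half-open)
    n_selfing_generations: int = 6
    n_families: int = 5
    n_ril: int = 1579
    max_ril_batches: int = 8
    background_homozygosity_min: float = 0.95
    n_genes: int = 2000
    causal_gene_index: int | None = None  # None: centre gene, placed in-interval
    qtl_log2fc_by_timepoint: tuple[float, float, float] = (1.0, 2.0, 3.0)
    nb_dispersion: float = 0.2
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    unit_effect_sd: float = 0.1
    timepoint_effect_sd: float = 0.2
    mean_depth: float = 30.0
    seq_error_rate: float = 0.005
    depth_tracks_expression: bool = True
    dormancy_effect: float = 2.0
    hazard_intercept: float = -1.0
    hazard_slope: float = 0.5
    germination_days: int = 7
    grains_per_plate: int = 20
    n_plates_per_class: int = 10
    n_linked_sites: int = 3
    n_decoy_sites: int = 50
    n_nil_progeny: int = 400

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "markers_per_chromosome",
            "n_families", "n_ril", "n_genes", "grains_per_plate",
            "n_plates_per_class", "germination_days", "n_linked_sites",
            "n_nil_progeny",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name}: must be >= 1")
        if self.n_selfing_generations < 0:  # 0 = stop at the funnel F1
            raise ValidationError("n_selfing_generations: must be >= 0")
        if self.n_decoy_sites < 0:
            raise ValidationError("n_decoy_sites: must be >= 0")
        if not 0 < self.background_homozygosity_min < 1:
            raise ValidationError("background_homozygosity_min: must be in (0, 1)")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion: must be >= 0")
        if not 0 <= self.seq_error_rate < 0.25:
            raise ValidationError("seq_error_rate: must be in [0, 0.25)")
        c, s, e = self.qtl_interval
        if not (0 <= c < self.n_chromosomes and 0 <= s < e <= self.markers_per_chromosome):
            raise ValidationError(f"qtl_interval: {self.qtl_interval} outside its chromosome")
        if self.map_length_cM < 0:
            raise ValidationError("map_length_cM: must be >= 0")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    @property
    def interval_marker_ids(self) -> np.ndarray:
        c, s, e = self.qtl_interval
        return np.arange(c * self.markers_per_chromosome + s,
                         c * self.markers_per_chromosome + e)

    def chrom_name(self, index: int) -> str:
        return f"chr{index + 1}"

    @property
    def qtl_region(self) -> GenomicInterval:
        c, s, e = self.qtl_interval
        return GenomicInterval(self.chrom_name(c), s * BP_PER_MARKER, e * BP_PER_MARKER)


@dataclass(frozen=True)
class SiteDef:
    """Truth annotation of one simulated SNP site."""

    site_id: str
    gene_index: int
    contig_id: str
    pos: int  # 0-based within contig
    founder_alleles: tuple[int, int, int, int]  # indices into NUCLEOTIDES
    kind: str  # linked | decoy
    pattern: str  # nonsynonymous | synonymous | noncoding | shared | random | monomorphic
    coding: bool

    @property
    def donor_allele(self) -> str:
        return NUCLEOTIDES[self.founder_alleles[0]]

    @property
    def alt_alleles(self) -> tuple[str, ...]:
        return tuple(NUCLEOTIDES[a] for a in self.founder_alleles[1:])


@dataclass
class MarkerAssay:
    """INDEL-spanning PCR marker distinguishing the donor haplotype."""

    forward: str
    reverse: str
    donor_template: str
    other_template: str
    donor_product: int
    other_product: int


@dataclass
class FounderPanel:
    """Founder alleles plus the simulated genome/gene geometry."""

    founder_names: tuple[str, str, str, str]
    marker_alleles: np.ndarray  # (4, n_markers) nucleotide indices
    sites: list[SiteDef]
    gene_chrom: np.ndarray  # (n_genes,) chromosome index per gene/contig
    gene_start: np.ndarray  # (n_genes,) 0-based bp start of the contig
    causal_gene_index: int
    sequences: dict[str, str] = field(default_factory=dict)  # site-carrying contigs
    gene_models: dict[str, GeneModel] = field(default_factory=dict)
    marker_assay: MarkerAssay | None = None

    def __post_init__(self) -> None:
        if len(self.founder_names) != 4:
            raise ValidationError("founder_names: exactly 4 founders required")
        for s in self.sites:
            if s.kind == "linked" and any(
                s.founder_alleles[0] == a for a in s.founder_alleles[1:]
            ):
                raise ValidationError(
                    f"site {s.site_id}: donor allele must differ from every other founder"
                )

    @property
    def donor(self) -> str:
        return self.founder_names[0]

    @property
    def causal_sites(self) -> list[SiteDef]:
        return [s for s in self.sites if s.kind == "linked"]

    def contig_id(self, gene_index: int) -> str:
        return f"contig{gene_index:05d}"

    def gene_marker(self, gene_index: int, config: SimConfig) -> int:
        """Global index of the marker nearest the gene's contig."""
        local = int(
            np.clip(
                round(self.gene_start[gene_index] / BP_PER_MARKER),
                0,
                config.markers_per_chromosome - 1,
            )
        )
        return int(self.gene_chrom[gene_index]) * config.markers_per_chromosome + local

    def placements(self, config: SimConfig) -> list[ContigPlacement]:
        return [
            ContigPlacement(
                contig_id=self.contig_id(g),
                chrom=config.chrom_name(int(self.gene_chrom[g])),
                start=int(self.gene_start[g]),
                end=int(self.gene_start[g]) + CONTIG_LENGTH,
            )
            for g in range(len(self.gene_chrom))
        ]


@dataclass
class GenomeMosaic:
    """Founder-of-origin labels for both homologs of one line."""

    line_id: str
    origin: np.ndarray  # (2, n_markers) int8 in 0..3

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.int8)
        if self.origin.ndim != 2 or self.origin.shape[0] != 2:
            raise ValidationError("origin: expected shape (2, n_markers)")
        if ((self.origin < 0) | (self.origin > 3)).any():
            raise ValidationError("origin: founder labels must be in 0..3")

    @property
    def het_mask(self) -> np.ndarray:
        return self.origin[0] != self.origin[1]

    def heterozygosity(self) -> float:
        return float(self.het_mask.mean())

    def background_homozygosity(self, interval_markers: np.ndarray) -> float:
        mask = np.ones(self.origin.shape[1], dtype=bool)
        mask[interval_markers] = False
        return float((self.origin[0, mask] == self.origin[1, mask]).mean())


@dataclass
class HIFFamily:
    """One HIF founder with its derived NIL pair."""

    family_id: str
    founder_mosaic: GenomeMosaic
    nil_plus: GenomeMosaic
    nil_minus: GenomeMosaic
    progeny_qtl_counts: dict[str, int] = field(default_factory=dict)  # '++'/'+-'/'--'


# ---------------------------------------------------------------------------
# founders

_CODON_SETUPS = {
    # pattern -> (ref codon, offset within codon, ref base, donor base)
    "nonsynonymous": ("GCT", 1, "C", "A"),  # GCT (Ala) -> GAT (Asp)
    "synonymous": ("GCT", 2, "T", "C"),     # GCT (Ala) -> GCC (Ala)
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, length))


def _build_marker_assay(rng: np.random.Generator) -> MarkerAssay:
    """Primer pair whose product spans an 18-bp promoter INDEL.

    The donor haplotype amplifies at 117 bp, the deletion haplotype at
    99 bp, mirroring a donor-specific insertion between the primer sites.
    """
    for _ in range(100):
        forward = _random_seq(rng, 20)
        reverse = _random_seq(rng, 20)
        core = _random_seq(rng, 77)
        donor_amp = forward + core + revcomp(reverse)
        other_amp = forward + core[:30] + core[48:] + revcomp(reverse)
        left, right = _random_seq(rng, 40), _random_seq(rng, 40)
        donor_template = left + donor_amp + right
        other_template = left + other_amp + right
        ok = all(
            t.count(forward) == 1
            and t.count(revcomp(forward)) == 0
            and t.count(revcomp(reverse)) == 1
            and t.count(reverse) == 0
            for t in (donor_template, other_template)
        )
        if ok:
            return MarkerAssay(
                forward=forward,
                reverse=reverse,
                donor_template=donor_template,
                other_template=other_template,
                donor_product=len(donor_amp),
                other_product=len(other_amp),
            )
    raise RuntimeError("could not construct an unambiguous marker assay")


def _plant_site_sequence(seq: list[str], site: SiteDef, model: GeneModel) -> None:
    """Write the reference (non-donor) context for a site into a sequence."""
    pattern = site.pattern
    if pattern in _CODON_SETUPS:
        codon, offset, _, _ = _CODON_SETUPS[pattern]
        start = site.pos - offset
        seq[start : start + 3] = list(codon)
    else:
        # reference base is the first non-donor founder's allele
        seq[site.pos] = NUCLEOTIDES[site.founder_alleles[1]]


def simulate_founders(config: SimConfig) -> FounderPanel:
    """Construct the founder panel, gene geometry, sites and marker assay.

    Deterministic given the config seed. Linked sites sit in the causal
    gene (one nonsynonymous, one synonymous, the rest noncoding); decoy
    sites sit on contigs outside the QTL interval and, by construction,
    violate at least one filter criterion or segregate with the random
    genomic background.
    """
    rng = _rng(config.seed, _SALTS["founders"])
    founder_names = ("Yitpi", "Baxter", "Chara", "Westonia")
    marker_alleles = rng.integers(0, 4, (4, config.n_markers), dtype=np.int8)

    # gene/contig geometry: uniform placement, causal gene forced in-region
    chrom_len = config.markers_per_chromosome * BP_PER_MARKER
    gene_chrom = rng.integers(0, config.n_chromosomes, config.n_genes)
    gene_start = rng.integers(0, chrom_len - CONTIG_LENGTH, config.n_genes)
    causal = (
        config.causal_gene_index
        if config.causal_gene_index is not None
        else config.n_genes // 2
    )
    if not 0 <= causal < config.n_genes:
        raise ValidationError("causal_gene_index: outside gene range")
    qc, qs, qe = config.qtl_interval
    centre = (qs + qe) // 2 * BP_PER_MARKER
    gene_chrom[causal] = qc
    gene_start[causal] = centre

    region = config.qtl_region
    in_region = (gene_chrom == qc) & (
        (gene_start < region.end) & (gene_start + CONTIG_LENGTH > region.start)
    )
    out_genes = np.flatnonzero(~in_region)

    sites: list[SiteDef] = []
    gene_models: dict[str, GeneModel] = {}
    orf_start, orf_end = 300, 1500

    def contig_id(g: int) -> str:
        return f"contig{g:05d}"

    # linked sites in the causal gene
    linked_patterns = ["nonsynonymous", "synonymous"] + ["noncoding"] * max(
        0, config.n_linked_sites - 2
    )
    linked_patterns = linked_patterns[: config.n_linked_sites]
    for k, pattern in enumerate(linked_patterns):
        if pattern in _CODON_SETUPS:
            codon, offset, ref_base, donor_base = _CODON_SETUPS[pattern]
            pos = orf_start + 3 * (10 + 7 * k) + offset
            donor = NUCLEOTIDES.index(donor_base)
            ref = NUCLEOTIDES.index(ref_base)
            coding = True
        else:
            pos = orf_end + 60 + 11 * k
            donor = int(rng.integers(0, 4))
            ref = int((donor + 1 + rng.integers(0, 3)) % 4)
            coding = False
        sites.append(
            SiteDef(
                site_id=f"L{k + 1}",
                gene_index=causal,
                contig_id=contig_id(causal),
                pos=pos,
                founder_alleles=(donor, ref, ref, ref),
                kind="linked",
                pattern=pattern,
                coding=coding,
            )
        )

    # decoy sites on distinct out-of-region contigs
    decoy_patterns = ("shared", "random", "monomorphic")
    n_decoys = min(config.n_decoy_sites, len(out_genes))
    decoy_genes = rng.choice(out_genes, size=n_decoys, replace=False)
    for k, g in enumerate(decoy_genes):
        pattern = decoy_patterns[k % len(decoy_patterns)]
        pos = int(rng.integers(0, CONTIG_LENGTH))
        if pattern == "shared":
            a, b = rng.choice(4, size=2, replace=False)
            alleles = (int(a), int(a), int(b), int(b))
        elif pattern == "random":
            perm = rng.permutation(4)
            alleles = tuple(int(x) for x in perm)
        else:  # monomorphic
            a = int(rng.integers(0, 4))
            alleles = (a, a, a, a)
        sites.append(
            SiteDef(
                site_id=f"D{k + 1}",
                gene_index=int(g),
                contig_id=contig_id(int(g)),
                pos=pos,
                founder_alleles=alleles,
                kind="decoy",
                pattern=pattern,
                coding=orf_start <= pos < orf_end,
            )
        )

    # sequences and gene models for every site-carrying contig
    sequences: dict[str, str] = {}
    for g in {s.gene_index for s in sites}:
        cid = contig_id(g)
        gene_models[cid] = GeneModel(cid, orf_start, orf_end, "+")
        seq = list(_random_seq(rng, CONTIG_LENGTH))
        for s in sites:
            if s.gene_index == g:
                _plant_site_sequence(seq, s, gene_models[cid])
        sequences[cid] = "".join(seq)

    return FounderPanel(
        founder_names=founder_names,
        marker_alleles=marker_alleles,
        sites=sites,
        gene_chrom=gene_chrom,
        gene_start=gene_start,
        causal_gene_index=causal,
        sequences=sequences,
        gene_models=gene_models,
        marker_assay=_build_marker_assay(rng),
    )


# ---------------------------------------------------------------------------
# meiosis and RILs

def _marker_cm(config: SimConfig) -> np.ndarray:
    m = config.markers_per_chromosome
    return (np.arange(m) + 0.5) * config.map_length_cM / m


def meiosis_batch(
    origins: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per individual; crossovers Poisson(L/100), no interference."""
    origins = np.asarray(origins)
    n = origins.shape[0]
    gametes = np.empty((n, config.n_markers), dtype=np.int8)
    cm = _marker_cm(config)
    lam = config.map_length_cM / 100.0
    for c in range(config.n_chromosomes):
        sl = slice(
            c * config.markers_per_chromosome, (c + 1) * config.markers_per_chromosome
        )
        k = rng.poisson(lam, n)
        start = rng.integers(0, 2, n)
        kmax = int(k.max()) if n else 0
        if kmax == 0:
            counts = np.zeros((n, config.markers_per_chromosome), dtype=int)
        else:
            pos = rng.uniform(0.0, config.map_length_cM, (n, kmax))
            pos[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
            counts = (pos[:, :, None] <= cm[None, None, :]).sum(axis=1)
        hom = (start[:, None] + counts) % 2
        chrom = origins[:, :, sl]
        gametes[:, sl] = np.where(hom == 0, chrom[:, 0, :], chrom[:, 1, :])
    return gametes


def simulate_ril_batch(
    panel: FounderPanel, config: SimConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2, n_markers) founder-of-origin arrays for n independent RILs."""
    m = config.n_markers
    ab = np.broadcast_to(
        np.stack([np.zeros(m, np.int8), np.ones(m, np.int8)]), (n, 2, m)
    )
    cd = np.broadcast_to(
        np.stack([np.full(m, 2, np.int8), np.full(m, 3, np.int8)]), (n, 2, m)
    )
    g1 = meiosis_batch(ab, config, rng)
    g2 = meiosis_batch(cd, config, rng)
    individuals = np.stack([g1, g2], axis=1)
    for _ in range(config.n_selfing_generations):
        g1 = meiosis_batch(individuals, config, rng)
        g2 = meiosis_batch(individuals, config, rng)
        individuals = np.stack([g1, g2], axis=1)
    return individuals


def simulate_magic_ril(
    panel: FounderPanel, config: SimConfig, rng: np.random.Generator | None = None
) -> GenomeMosaic:
    """One RIL from the (A x B) x (C x D) funnel plus selfing."""
    rng = rng or _rng(config.seed, _SALTS["ril"])
    origin = simulate_ril_batch(panel, config, 1, rng)[0]
    return GenomeMosaic(line_id="RIL1", origin=origin)


def select_hif_founders(
    rils: Iterable[GenomeMosaic], panel: FounderPanel, config: SimConfig
) -> list[GenomeMosaic]:
    """HIF founders: donor-vs-other heterozygous across the whole QTL
    interval, background homozygosity above threshold, best backgrounds
    first, at most n_families returned."""
    interval = config.interval_marker_ids
    chosen = []
    for mosaic in rils:
        o = mosaic.origin[:, interval]
        # donor haplotype intact on one homolog, non-donor on the other
        het_donor = bool(
            ((o[0] == 0).all() and (o[1] != 0).all())
            or ((o[1] == 0).all() and (o[0] != 0).all())
        )
        if not het_donor:
            continue
        bg = mosaic.background_homozygosity(interval)
        if bg >= config.background_homozygosity_min:
            chosen.append((bg, mosaic))
    chosen.sort(key=lambda t: (-t[0], t[1].line_id))
    if not chosen:
        logger.warning(
            "select_hif_founders: no line is QTL-heterozygous with background "
            "homozygosity >= %.2f", config.background_homozygosity_min,
        )
    return [m for _, m in chosen[: config.n_families]]


def _fix_heterozygosity(
    origin: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Resolve residual heterozygous blocks to one homolog per block."""
    fixed = origin.copy()
    for c in range(config.n_chromosomes):
        sl = slice(
            c * config.markers_per_chromosome, (c + 1) * config.markers_per_chromosome
        )
        het = fixed[0, sl] != fixed[1, sl]
        if not het.any():
            continue
        idx = np.flatnonzero(het)
        # contiguous runs of heterozygous markers
        breaks = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, breaks + 1)
        base = c * config.markers_per_chromosome
        for run in runs:
            h = int(rng.integers(0, 2))
            fixed[1 - h, base + run] = fixed[h, base + run]
    return fixed


def derive_nil_pair(
    founder: GenomeMosaic,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    family_id: str | None = None,
) -> HIFFamily:
    """Self the HIF founder, genotype the progeny at the QTL, fix a NIL pair.

    Progeny segregate 1:2:1 at the interval markers; one donor-homozygote
    and one other-homozygote (homozygous across the whole interval) are
    fixed into nil_plus/nil_minus, with any residual background
    heterozygosity resolved by a further round of fixation.
    """
    rng = rng or _rng(config.seed, _SALTS["hif"])
    interval = config.interval_marker_ids
    o = founder.origin[:, interval]
    if not np.all((o[0] != o[1]) & ((o[0] == 0) | (o[1] == 0))):
        raise ValidationError(
            f"founder {founder.line_id}: not donor-vs-other heterozygous "
            "across the QTL interval"
        )
    mid = interval[len(interval) // 2]

    plus = minus = None
    counts = {"++": 0, "+-": 0, "--": 0}
    for _ in range(5):  # draw more progeny only if a class is missing
        n = config.n_nil_progeny
        tiled = np.broadcast_to(founder.origin, (n, 2, founder.origin.shape[1]))
        g1 = meiosis_batch(tiled, config, rng)
        g2 = meiosis_batch(tiled, config, rng)
        progeny = np.stack([g1, g2], axis=1)
        dosage = (progeny[:, :, mid] == 0).sum(axis=1)
        counts = {
            "++": counts["++"] + int((dosage == 2).sum()),
            "+-": counts["+-"] + int((dosage == 1).sum()),
            "--": counts["--"] + int((dosage == 0).sum()),
        }
        if plus is None:
            hit = np.flatnonzero((progeny[:, :, interval] == 0).all(axis=(1, 2)))
            if hit.size:
                plus = progeny[hit[0]]
        if minus is None:
            iv = progeny[:, :, interval]
            hom_other = ((iv[:, 0, :] == iv[:, 1, :]) & (iv[:, 0, :] != 0)).all(axis=1)
            hit = np.flatnonzero(hom_other)
            if hit.size:
                minus = progeny[hit[0]]
        if plus is not None and minus is not None:
            break
    if plus is None or minus is None:
        raise RuntimeError(
            f"derive_nil_pair: no interval-homozygous progeny for {founder.line_id}"
        )
    fid = family_id or f"{founder.line_id}F"
    nil_plus = GenomeMosaic(f"{fid}_NILplus", _fix_heterozygosity(plus, config, rng))
    nil_minus = GenomeMosaic(f"{fid}_NILminus", _fix_heterozygosity(minus, config, rng))
    return HIFFamily(
        family_id=fid,
        founder_mosaic=founder,
        nil_plus=nil_plus,
        nil_minus=nil_minus,
        progeny_qtl_counts=counts,
    )


def simulate_hif_families(panel: FounderPanel, config: SimConfig) -> list[HIFFamily]:
    """Simulate RIL batches and derive n_families NIL pairs.

    Each batch has the size of the source mapping population; further
    seeded batches are drawn (up to max_ril_batches) when a batch yields
    fewer qualifying HIF founders than requested.
    """
    rng = _rng(config.seed, _SALTS["hif"])
    qualifying: list[GenomeMosaic] = []
    for batch in range(config.max_ril_batches):
        origins = simulate_ril_batch(panel, config, config.n_ril, rng)
        rils = [
            GenomeMosaic(f"RIL{batch * config.n_ril + i + 1}", origins[i])
            for i in range(config.n_ril)
        ]
        qualifying.extend(_select_uncapped(rils, panel, config))
        if len(qualifying) >= config.n_families:
            break
    if len(qualifying) < config.n_families:
        logger.warning(
            "simulate_hif_families: only %d of %d requested families found",
            len(qualifying), config.n_families,
        )
    qualifying.sort(
        key=lambda m: (-m.background_homozygosity(config.interval_marker_ids), m.line_id)
    )
    founders = qualifying[: config.n_families]
    return [
        derive_nil_pair(f, config, rng, family_id=f"HIF{i + 1}")
        for i, f in enumerate(founders)
    ]


def _select_uncapped(rils, panel, config):
    """select_hif_founders without the n_families cap (batch accumulation)."""
    uncapped = replace(config, n_families=max(config.n_families, len(rils)))
    return select_hif_founders(rils, panel, uncapped)


# ---------------------------------------------------------------------------
# expression

@dataclass
class ExpressionTruth:
    """Planted expression parameters, for tests and the run report."""

    mu: pd.DataFrame  # gene x sample NB means
    baseline_log_mean: np.ndarray


def _sample_sheet(families: Sequence[HIFFamily], panel: FounderPanel) -> pd.DataFrame:
    rows = []
    for fam in families:
        for t in TIMEPOINTS:
            rows.append((f"{fam.family_id}_t{t}_A", fam.family_id, t, 1))
            rows.append((f"{fam.family_id}_t{t}_B", fam.family_id, t, 0))
    for i, name in enumerate(panel.founder_names):
        for t in TIMEPOINTS:
            rows.append((f"{name}_t{t}", name, t, 1 if i == 0 else 0))
    return pd.DataFrame(rows, columns=["sample_id", "unit", "timepoint", "qtl_status"])


def simulate_expression(
    families: Sequence[HIFFamily],
    panel: FounderPanel,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """NB counts for one pooled sample per (unit, timepoint, QTL status).

    log-mean = gene baseline + unit effect + timepoint effect +
    ln2 * log2FC[timepoint] * status for the causal gene. Parents appear
    once per timepoint with status set by their QTL allele.
    """
    if not families:
        raise ValidationError("families: need at least one HIF family")
    rng = _rng(config.seed, _SALTS["expression"])
    samples = _sample_sheet(families, panel)
    G = config.n_genes
    units = sorted(samples["unit"].unique())
    unit_idx = {u: i for i, u in enumerate(units)}
    tp_idx = {t: i for i, t in enumerate(TIMEPOINTS)}

    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, G)
    unit_eff = rng.normal(0.0, config.unit_effect_sd, (G, len(units)))
    tp_eff = rng.normal(0.0, config.timepoint_effect_sd, (G, len(TIMEPOINTS)))
    lfc = dict(zip(TIMEPOINTS, config.qtl_log2fc_by_timepoint))

    log_mu = np.empty((G, len(samples)))
    for j, row in samples.iterrows():
        log_mu[:, j] = (
            base
            + unit_eff[:, unit_idx[row["unit"]]]
            + tp_eff[:, tp_idx[row["timepoint"]]]
        )
        if row["qtl_status"] == 1:
            log_mu[panel.causal_gene_index, j] += np.log(2.0) * lfc[row["timepoint"]]
    mu = np.exp(log_mu)

    counts = draw_nb_counts(mu, config.nb_dispersion, rng)
    gene_ids = [panel.contig_id(g) for g in range(G)]
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"),
                             columns=samples["sample_id"])
    mu_df = pd.DataFrame(mu, index=counts_df.index, columns=counts_df.columns)
    return counts_df, samples, ExpressionTruth(mu=mu_df, baseline_log_mean=base)


def draw_nb_counts(
    mu: np.ndarray, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson NB draws: mean mu, variance mu + phi * mu^2."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    shape = 1.0 / phi
    return rng.poisson(rng.gamma(shape, phi * mu))


# ---------------------------------------------------------------------------
# allele depths

def _entity_samples(
    families: Sequence[HIFFamily], panel: FounderPanel
) -> list[tuple[str, str, int, str]]:
    """(entity, pool, timepoint, expression sample id) for every depth row."""
    rows = []
    for i, name in enumerate(panel.founder_names):
        for t in TIMEPOINTS:
            rows.append((name, ".", t, f"{name}_t{t}"))
    for fam in families:
        for pool in ("A", "B"):
            for t in TIMEPOINTS:
                rows.append((fam.family_id, pool, t, f"{fam.family_id}_t{t}_{pool}"))
    return rows


def _entity_genotype(
    entity: str, pool: str, site: SiteDef, families: dict[str, HIFFamily],
    panel: FounderPanel, config: SimConfig,
) -> tuple[int, int]:
    if pool == ".":
        a = site.founder_alleles[panel.founder_names.index(entity)]
        return a, a
    fam = families[entity]
    mosaic = fam.nil_plus if pool == "A" else fam.nil_minus
    m = panel.gene_marker(site.gene_index, config)
    o = mosaic.origin[:, m]
    return site.founder_alleles[int(o[0])], site.founder_alleles[int(o[1])]


def emit_read_depths(
    genotype: tuple[int, int],
    coverage_mean: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson coverage; each read reports a uniformly chosen homolog's
    allele, miscalled to a uniform other nucleotide with the error rate."""
    reads = int(rng.poisson(coverage_mean))
    if reads == 0:
        return np.zeros(4, dtype=int)
    probs = np.full(4, 0.0)
    for allele in genotype:
        p_correct = (1.0 - error_rate) / 2.0
        probs[allele] += p_correct
        for other in range(4):
            if other != allele:
                probs[other] += error_rate / 6.0  # (1/2) * e / 3
    return rng.multinomial(reads, probs)


def simulate_allele_depths(
    families: Sequence[HIFFamily],
    panel: FounderPanel,
    config: SimConfig,
    expression: ExpressionTruth | None = None,
) -> pd.DataFrame:
    """Depth table (site x entity x timepoint x nucleotide counts).

    Coverage is Poisson(mean_depth x relative expression of the carrying
    gene in the matching expression sample); with
    ``depth_tracks_expression`` off, relative expression is 1 everywhere.
    A genotype whose gene is silenced in a sample therefore yields zero
    depth, reproducing absent calls for unexpressed alleles.
    """
    rng = _rng(config.seed, _SALTS["depths"])
    fam_map = {f.family_id: f for f in families}
    rows = []
    baseline = (
        np.exp(expression.baseline_log_mean) if expression is not None else None
    )
    for site in panel.sites:
        for entity, pool, t, sample_id in _entity_samples(families, panel):
            genotype = _entity_genotype(entity, pool, site, fam_map, panel, config)
            rel = 1.0
            if config.depth_tracks_expression and expression is not None:
                mu = float(expression.mu.loc[site.contig_id, sample_id])
                rel = min(mu / float(baseline[site.gene_index]), 50.0)
            depths = emit_read_depths(
                genotype, config.mean_depth * rel, config.seq_error_rate, rng
            )
            rows.append(
                {
                    "site_id": site.site_id,
                    "contig": site.contig_id,
                    "pos": site.pos,
                    "entity": entity,
                    "pool": pool,
                    "timepoint": t,
                    "A": int(depths[0]),
                    "C": int(depths[1]),
                    "G": int(depths[2]),
                    "T": int(depths[3]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# germination

def simulate_germination(
    families: Sequence[HIFFamily], config: SimConfig
) -> list[GerminationRecord]:
    """Semi-dominant germination phenotypes for the three QTL dosage classes.

    Each grain germinates on day d with hazard
    logistic(intercept + slope * d - dormancy_effect * dosage); survivors
    of the test window stay ungerminated.
    """
    rng = _rng(config.seed, _SALTS["germination"])
    classes = (("donor_hom", 2), ("het", 1), ("other_hom", 0))
    records = []
    for fam in families:
        for cls, dosage in classes:
            for p in range(config.n_plates_per_class):
                alive = config.grains_per_plate
                daily = []
                for d in range(1, config.germination_days + 1):
                    h = float(
                        expit(
                            config.hazard_intercept
                            + config.hazard_slope * d
                            - config.dormancy_effect * dosage
                        )
                    )
                    g = int(rng.binomial(alive, h)) if alive else 0
                    daily.append(g)
                    alive -= g
                records.append(
                    GerminationRecord(
                        sample_id=f"{fam.family_id}_{cls}_p{p + 1}",
                        genotype_class=cls,
                        treatment="light",
                        total_grains=config.grains_per_plate,
                        daily_new_germinations=tuple(daily),
                    )
                )
    return records


# ---------------------------------------------------------------------------
# whole dataset

@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimConfig
    panel: FounderPanel
    families: list[HIFFamily]
    counts: pd.DataFrame
    samples: pd.DataFrame
    depths: pd.DataFrame
    germination: list[GerminationRecord]
    interval: GenomicInterval
    expression_truth: ExpressionTruth

    @property
    def truth(self) -> dict:
        assay = self.panel.marker_assay
        return {
            "seed": self.config.seed,
            "causal_contig": self.panel.contig_id(self.panel.causal_gene_index),
            "causal_gene_index": self.panel.causal_gene_index,
            "linked_site_ids": [s.site_id for s in self.panel.causal_sites],
            "qtl_interval": {
                "chrom": self.interval.chrom,
                "start": int(self.interval.start),
                "end": int(self.interval.end),
            },
            "qtl_log2fc_by_timepoint": {
                int(t): float(f)
                for t, f in zip(TIMEPOINTS, self.config.qtl_log2fc_by_timepoint)
            },
            "nb_dispersion": self.config.nb_dispersion,
            "dormancy_effect": self.config.dormancy_effect,
            "n_families": len(self.families),
            "marker": {
                "forward": assay.forward,
                "reverse": assay.reverse,
                "donor_product_bp": assay.donor_product,
                "other_product_bp": assay.other_product,
            },
        }

    @property
    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": s.site_id,
                    "contig": s.contig_id,
                    "pos": s.pos,
                    "kind": s.kind,
                    "pattern": s.pattern,
                    "donor_allele": s.donor_allele,
                    "coding": s.coding,
                }
                for s in self.panel.sites
            ]
        )


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run every generator stage with substreams of the config seed."""
    panel = simulate_founders(config)
    families = simulate_hif_families(panel, config)
    if not families:
        raise RuntimeError("simulate_dataset: no HIF families could be derived")
    counts, samples, truth = simulate_expression(families, panel, config)
    depths = simulate_allele_depths(families, panel, config, truth)
    germination = simulate_germination(families, config)
    return SimulatedDataset(
        config=config,
        panel=panel,
        families=families,
        counts=counts,
        samples=samples,
        depths=depths,
        germination=germination,
        interval=config.qtl_region,
        expression_truth=truth,
    )
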