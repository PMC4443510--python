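"""End-to-end orchestration: simulate (or load), filter SNPs, test DE,
rank candidates, and write every artifact of the run."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import candidate_mapper as cm
from . import io as nio
from . import magic_sim, phenotype, pooled_de, snp_filter
from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)

DEMO_SEED = 1234


@dataclass
class PipelineConfig:
    """One run of the pipeline, simulated or from real input files."""

    out_dir: str
    mode: str = "simulate"  # simulate | real
    seed: int = DEMO_SEED
    sim: magic_sim.SimConfig | None = None
    # real-mode inputs
    counts_path: str | None = None
    samples_path: str | None = None
    depths_path: str | None = None
    placements_path: str | None = None
    fasta_path: str | None = None
    models_path: str | None = None
    germination_path: str | None = None
    interval: cm.GenomicInterval | None = None
    # analysis options
    filter_params: snp_filter.FilterParams = field(default_factory=snp_filter.FilterParams)
    alpha: float = 0.01
    norm: str = "tmm"
    fdr: str = "bh"
    dispersion: str | float = "common"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise ValidationError(f"mode: unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha: must be in (0, 1), got {self.alpha}")
        if self.mode == "simulate" and self.sim is None:
            self.sim = magic_sim.SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = nio.load_yaml(path)
        sim = raw.pop("sim", None)
        interval = raw.pop("interval", None)
        fparams = raw.pop("filter_params", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = magic_sim.SimConfig(**{
                **sim,
                "qtl_interval": tuple(sim.get("qtl_interval", (0, 96, 104))),
                "qtl_log2fc_by_timepoint": tuple(
                    sim.get("qtl_log2fc_by_timepoint", (1.0, 2.0, 3.0))
                ),
            })
        if interval is not None:
            cfg.interval = cm.GenomicInterval(**interval)
        if fparams is not None:
            cfg.filter_params = snp_filter.FilterParams(**fparams)
        return cfg


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except ValidationError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run summary.

    Simulate mode first writes every simulated input file, then runs the
    analysis exactly as it would on real inputs. All intermediate and final
    tables land in ``config.out_dir`` along with a JSON run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    sequences: dict[str, str] = {}
    models: dict[str, cm.GeneModel] = {}
    germination: list[phenotype.GerminationRecord] = []
    truth = None

    if config.mode == "simulate":
        sim = config.sim or magic_sim.SimConfig(seed=config.seed)
        ds = _stage("simulate", magic_sim.simulate_dataset, sim)
        counts, samples, depths = ds.counts, ds.samples, ds.depths
        placements = {p.contig_id: p for p in ds.panel.placements(sim)}
        interval = ds.interval
        sequences = dict(ds.panel.sequences)
        assay = ds.panel.marker_assay
        if assay is not None:
            sequences["marker_donor_haplotype"] = assay.donor_template
            sequences["marker_other_haplotype"] = assay.other_template
        models = ds.panel.gene_models
        germination = ds.germination
        truth = ds.truth
        nio.write_counts(counts, out / "counts.tsv")
        nio.write_samples(samples, out / "samples.tsv")
        nio.write_depths(depths, out / "depths.tsv")
        ds.sites_frame.to_csv(out / "sites.tsv", sep="\t", index=False)
        nio.write_fasta(sequences, out / "contigs.fasta")
        nio.write_bed(
            placements.values(), out / "placements.bed", regions={"qtl": interval}
        )
        nio.write_gene_models(models, out / "models.tsv")
        nio.write_germination(germination, out / "germination.tsv")
        nio.dump_yaml(truth, out / "truth.yaml")
    else:
        for name, path in (("counts", config.counts_path),
                           ("samples", config.samples_path),
                           ("depths", config.depths_path),
                           ("placements", config.placements_path)):
            if path is None:
                raise ValidationError(f"real mode: missing required input {name!r}")
        counts = _stage("read-counts", nio.read_counts, config.counts_path)
        samples = _stage("read-samples", nio.read_samples, config.samples_path)
        depths = _stage("read-depths", nio.read_depths, config.depths_path)
        placement_list, regions = _stage("read-bed", nio.read_bed, config.placements_path)
        placements = {p.contig_id: p for p in placement_list}
        interval = config.interval or regions.get("qtl")
        if interval is None:
            raise ValidationError(
                "real mode: no QTL interval (flag or 'region:qtl' BED record)"
            )
        if config.fasta_path:
            sequences = _stage("read-fasta", nio.read_fasta, config.fasta_path)
        if config.models_path:
            models = _stage("read-models", nio.read_gene_models, config.models_path)
        if config.germination_path:
            germination = _stage(
                "read-germination", nio.read_germination, config.germination_path
            )

    # germination index summary
    if germination:
        gi_rows = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in germination],
                "genotype_class": [r.genotype_class for r in germination],
                "treatment": [r.treatment for r in germination],
                "gi": [phenotype.compute_gi(r) for r in germination],
            }
        )
        gi_rows.to_csv(out / "gi.tsv", sep="\t", index=False)
        gi_summary = phenotype.summarize_by_class(germination)
        gi_summary.to_csv(out / "gi_summary.tsv", sep="\t", index=False)
    else:
        gi_summary = pd.DataFrame()

    # SNP filter
    fparams = config.filter_params
    if config.mode == "simulate" or fparams.n_families != samples["unit"].nunique():
        n_fam = len({u for u in samples["unit"]
                     if (samples.loc[samples["unit"] == u, "qtl_status"].nunique() == 2)})
        if n_fam and n_fam != fparams.n_families:
            fparams = dataclasses.replace(
                fparams,
                n_families=n_fam,
                min_family_concordance=min(fparams.min_family_concordance, n_fam),
            )
    passing, decisions = _stage("filter-snps", snp_filter.filter_sites, depths, fparams)
    snp_report = snp_filter.decisions_to_frame(decisions)
    snp_report.to_csv(out / "snp_report.tsv", sep="\t", index=False)
    nio.write_vcf(decisions, out / "snps.vcf",
                  contig_lengths={c: len(s) for c, s in sequences.items()})

    # coding consequences for passing sites
    effects = {}
    for d in decisions:
        if not d.passed:
            continue
        model, seq = models.get(d.contig), sequences.get(d.contig)
        if model is None or seq is None or d.donor_allele is None:
            continue
        ref = seq[d.pos].upper()
        alt = d.donor_allele if d.donor_allele != ref else (d.other_allele or ref)
        if alt == ref:
            continue
        effects[d.site_id] = _stage(
            "classify-snps", cm.classify_snp_effect, model, seq, d.pos, ref, alt
        )
    snp_sites = snp_report[["site_id", "contig", "passed"]].copy()
    snp_sites["effect"] = snp_sites["site_id"].map(effects)

    # differential expression
    de = _stage(
        "de", pooled_de.run_de, counts, samples,
        alpha=config.alpha, norm=config.norm, fdr=config.fdr,
        dispersion=config.dispersion,
    )
    de_out = de.results.reset_index()
    de_out.to_csv(out / "de_results.tsv", sep="\t", index=False)

    # candidate ranking
    report = _stage(
        "map-candidates", cm.rank_candidates, de.results, snp_sites, placements, interval
    )
    report.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    report.elsewhere.to_csv(out / "elsewhere.tsv", sep="\t", index=False)

    # marker products (simulate mode plants an INDEL-spanning assay)
    marker = {}
    if config.mode == "simulate" and truth is not None:
        assay_truth = truth["marker"]
        marker = {
            "donor_product_bp": cm.insilico_pcr(
                sequences["marker_donor_haplotype"],
                assay_truth["forward"], assay_truth["reverse"],
            ),
            "other_product_bp": cm.insilico_pcr(
                sequences["marker_other_haplotype"],
                assay_truth["forward"], assay_truth["reverse"],
            ),
        }

    top = (
        report.candidates["contig"].iloc[0] if len(report.candidates) else None
    )
    summary = {
        "mode": config.mode,
        "seed": config.seed,
        "n_genes_tested": int(len(de.results)),
        "n_de_contigs": int(de.results["is_de"].sum()),
        "dispersion": float(de.dispersion) if isinstance(de.dispersion, float)
        else "tagwise",
        "n_sites": int(len(snp_report)),
        "n_passing_snps": len(passing),
        "passing_snp_ids": list(passing),
        "n_in_region_candidates": int(len(report.candidates)),
        "top_candidate": top,
        "marker": marker,
    }
    if truth is not None:
        summary["causal_contig"] = truth["causal_contig"]
        summary["causal_recovered"] = bool(top == truth["causal_contig"])
    run_log = {
        "config": {
            "mode": config.mode, "seed": config.seed, "alpha": config.alpha,
            "norm": config.norm, "fdr": config.fdr,
            "dispersion": str(config.dispersion),
            "filter_params": dataclasses.asdict(fparams),
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
        },
        "summary": summary,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    nio.dump_yaml(summary, out / "summary.yaml")
    logger.info("pipeline complete: top candidate %s", top)
    return summary
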