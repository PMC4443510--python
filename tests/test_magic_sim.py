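"""Simulator: genetic structure, expression model, depths, germination."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from nilseq.errors import ValidationError
from nilseq.magic_sim import (
    GenomeMosaic,
    SimConfig,
    _rng,
    derive_nil_pair,
    draw_nb_counts,
    emit_read_depths,
    meiosis_batch,
    select_hif_founders,
    simulate_dataset,
    simulate_expression,
    simulate_founders,
    simulate_germination,
    simulate_ril_batch,
)
from nilseq.phenotype import compute_gi

CFG = SimConfig(seed=11, n_genes=200, n_decoy_sites=10)


def test_founders_deterministic_and_donor_distinct():
    p1 = simulate_founders(CFG)
    p2 = simulate_founders(CFG)
    assert np.array_equal(p1.marker_alleles, p2.marker_alleles)
    assert [s.site_id for s in p1.sites] == [s.site_id for s in p2.sites]
    for site in p1.causal_sites:
        assert all(site.founder_alleles[0] != a for a in site.founder_alleles[1:])
    # decoys live outside the QTL interval
    region = CFG.qtl_region
    for site in p1.sites:
        if site.kind == "decoy":
            g = site.gene_index
            on_chrom = CFG.chrom_name(int(p1.gene_chrom[g])) == region.chrom
            overlaps = (
                p1.gene_start[g] < region.end
                and p1.gene_start[g] + 2000 > region.start
            )
            assert not (on_chrom and overlaps)


def test_no_decoys_when_disabled():
    panel = simulate_founders(dataclasses.replace(CFG, n_decoy_sites=0))
    assert all(s.kind == "linked" for s in panel.sites)


def test_zero_map_length_gives_single_founder_blocks():
    cfg = dataclasses.replace(CFG, map_length_cM=0.0)
    panel = simulate_founders(cfg)
    origins = simulate_ril_batch(panel, cfg, 20, _rng(cfg.seed, 12))
    m = cfg.markers_per_chromosome
    for line in origins:
        for hom in line:
            for c in range(cfg.n_chromosomes):
                chrom = hom[c * m : (c + 1) * m]
                assert len(np.unique(chrom)) == 1


def test_residual_heterozygosity_halves_per_selfing_generation():
    """F7 heterozygosity ~ h0 * 2^-6, where h0 is the measured F1 value."""
    cfg = dataclasses.replace(CFG, n_selfing_generations=0)
    panel = simulate_founders(cfg)
    n = 1000
    f1 = simulate_ril_batch(panel, cfg, n, _rng(4, 1))
    h0 = (f1[:, 0, :] != f1[:, 1, :]).mean()
    cfg6 = dataclasses.replace(CFG, n_selfing_generations=6)
    f7 = simulate_ril_batch(panel, cfg6, n, _rng(4, 2))
    per_line = (f7[:, 0, :] != f7[:, 1, :]).mean(axis=1)
    expected = h0 * 2.0 ** -6
    half_width = 2.576 * per_line.std(ddof=1) / np.sqrt(n)
    assert abs(per_line.mean() - expected) < half_width


def test_founder_genome_shares_are_equal():
    panel = simulate_founders(CFG)
    n = 500
    origins = simulate_ril_batch(panel, CFG, n, _rng(5, 1))
    for f in range(4):
        shares = (origins == f).mean(axis=(1, 2))
        half_width = 2.576 * shares.std(ddof=1) / np.sqrt(n)
        assert abs(shares.mean() - 0.25) < half_width


def test_select_hif_founders_postconditions(small_dataset):
    cfg = small_dataset.config
    interval = cfg.interval_marker_ids
    for fam in small_dataset.families:
        o = fam.founder_mosaic.origin[:, interval]
        assert np.all(o[0] != o[1])
        assert np.all((o[0] == 0) | (o[1] == 0))
        bg = fam.founder_mosaic.background_homozygosity(interval)
        assert bg >= cfg.background_homozygosity_min


def test_select_hif_founders_empty_for_homozygous_lines(caplog):
    panel = simulate_founders(CFG)
    hom = GenomeMosaic("hom1", np.zeros((2, CFG.n_markers), dtype=np.int8))
    with caplog.at_level("WARNING"):
        assert select_hif_founders([hom], panel, CFG) == []
    assert "no line" in caplog.text


def test_derive_nil_pair_structure(small_dataset):
    cfg = small_dataset.config
    interval = cfg.interval_marker_ids
    for fam in small_dataset.families:
        plus, minus = fam.nil_plus.origin, fam.nil_minus.origin
        assert np.all(plus[:, interval] == 0)
        assert np.all(minus[:, interval] != 0)
        assert np.all(minus[0, interval] == minus[1, interval])
        # identical wherever the founder was homozygous in the background
        founder = fam.founder_mosaic.origin
        bg_hom = founder[0] == founder[1]
        bg_hom[interval] = False
        assert np.array_equal(plus[:, bg_hom], minus[:, bg_hom])
        # fully fixed lines
        assert fam.nil_plus.heterozygosity() == 0.0


def test_derive_nil_pair_rejects_homozygous_founder():
    panel = simulate_founders(CFG)
    hom = GenomeMosaic("hom1", np.zeros((2, CFG.n_markers), dtype=np.int8))
    with pytest.raises(ValidationError, match="heterozygous"):
        derive_nil_pair(hom, CFG)


def test_f8_progeny_segregate_1_2_1(small_dataset):
    for fam in small_dataset.families:
        counts = fam.progeny_qtl_counts
        n = sum(counts.values())
        observed = [counts["++"], counts["+-"], counts["--"]]
        expected = [n / 4, n / 2, n / 4]
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.001


def test_nb_counts_match_moment_formulas(rng):
    mu, phi, n = 50.0, 0.3, 10_000
    draws = draw_nb_counts(np.full(n, mu), phi, rng).astype(float)
    se_mean = draws.std(ddof=1) / np.sqrt(n)
    assert abs(draws.mean() - mu) < 3 * se_mean
    target_var = mu + phi * mu**2
    m4 = ((draws - draws.mean()) ** 4).mean()
    se_var = np.sqrt((m4 - draws.var(ddof=1) ** 2) / n)
    assert abs(draws.var(ddof=1) - target_var) < 3 * se_var


def test_null_effect_leaves_pools_equal(small_dataset):
    cfg = dataclasses.replace(
        SMALL := small_dataset.config, qtl_log2fc_by_timepoint=(0.0, 0.0, 0.0)
    )
    counts, samples, truth = simulate_expression(
        small_dataset.families, small_dataset.panel, cfg
    )
    causal = small_dataset.panel.contig_id(small_dataset.panel.causal_gene_index)
    mu = truth.mu.loc[causal]
    a = mu[samples.set_index("sample_id")["qtl_status"] == 1]
    b = mu[samples.set_index("sample_id")["qtl_status"] == 0]
    # planted means differ only through unit/timepoint effects, not pool
    assert abs(np.log(a).mean() - np.log(b).mean()) < 0.2


def test_planted_log2fc_reached_at_35dpa(small_dataset, rng):
    """Configured log2FC of 3 at 35 DPA gives a pool mean ratio near 8."""
    panel, families = small_dataset.panel, small_dataset.families
    cfg = small_dataset.config
    causal = panel.contig_id(panel.causal_gene_index)
    _, samples, truth = simulate_expression(families, panel, cfg)
    sel = samples[samples["timepoint"] == 35].set_index("sample_id")
    mu_row = truth.mu.loc[causal]
    reps_a, reps_b = [], []
    for sid, row in sel.iterrows():
        draws = draw_nb_counts(
            np.full(100, mu_row[sid]), cfg.nb_dispersion, rng
        ).mean()
        (reps_a if row["qtl_status"] == 1 else reps_b).append(draws)
    ratio = np.mean(reps_a) / np.mean(reps_b)
    assert abs(np.log2(ratio) - 3.0) < 0.5


def test_depth_emission_cases(rng):
    hom = emit_read_depths((0, 0), 100.0, 0.0, rng)
    assert hom[0] > 0 and hom[1:].sum() == 0
    het = emit_read_depths((0, 1), 10_000.0, 0.0, rng)
    total = het.sum()
    frac = het[0] / total
    half_width = 2.576 * np.sqrt(0.25 / total)
    assert abs(frac - 0.5) < half_width
    assert emit_read_depths((2, 2), 0.0, 0.0, rng).sum() == 0


def test_silenced_gene_yields_zero_depth(small_dataset):
    """Coverage tracks expression: relative expression 0 => no reads."""
    from nilseq.magic_sim import simulate_allele_depths

    truth = small_dataset.expression_truth
    silenced = truth.mu.copy()
    silenced.iloc[:, :] = 0.0
    zeroed = dataclasses.replace(small_dataset.config)
    depths = simulate_allele_depths(
        small_dataset.families,
        small_dataset.panel,
        zeroed,
        dataclasses.replace(truth, mu=silenced),
    )
    assert depths[["A", "C", "G", "T"]].to_numpy().sum() == 0


def test_germination_dosage_ordering(small_dataset):
    """Semi-dominance: donor homozygotes most dormant, hets intermediate."""
    records = small_dataset.germination
    ok = 0
    families = {r.sample_id.split("_")[0] for r in records}
    for fam in families:
        means = {}
        for cls in ("donor_hom", "het", "other_hom"):
            gis = [
                compute_gi(r)
                for r in records
                if r.genotype_class == cls and r.sample_id.startswith(fam + "_")
            ]
            means[cls] = np.mean(gis)
        if means["donor_hom"] < means["het"] < means["other_hom"]:
            ok += 1
    assert ok >= len(families) - 1


def test_germination_null_and_degenerate_cases(small_dataset):
    fams = small_dataset.families
    null_cfg = dataclasses.replace(small_dataset.config, dormancy_effect=0.0,
                                   n_plates_per_class=40)
    recs = simulate_germination(fams, null_cfg)
    by_class = {
        cls: np.mean([compute_gi(r) for r in recs if r.genotype_class == cls])
        for cls in ("donor_hom", "het", "other_hom")
    }
    assert max(by_class.values()) - min(by_class.values()) < 0.03

    sure = dataclasses.replace(small_dataset.config, hazard_intercept=50.0,
                               dormancy_effect=0.0)
    recs = simulate_germination(fams, sure)
    assert all(compute_gi(r) == 1.0 for r in recs)


def test_dataset_is_deterministic():
    cfg = SimConfig(seed=23, n_genes=80, n_decoy_sites=5, n_ril=400,
                    max_ril_batches=15, n_plates_per_class=2)
    d1 = simulate_dataset(cfg)
    d2 = simulate_dataset(cfg)
    assert d1.counts.equals(d2.counts)
    assert d1.depths.equals(d2.depths)
    assert d1.truth == d2.truth
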