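"""Readers and writers for the pipeline's plain-text formats.

TSV throughout, '.' for missing values. Coordinates: BED records and all
internal intervals are 0-based half-open; VCF POS is 1-based. FASTA is read
via Biopython (wrapped or unwrapped); the minimal VCF 4.2 the SNP filter
emits is read back with cyvcf2.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .candidate_mapper import ContigPlacement, GeneModel, GenomicInterval
from .errors import ValidationError
from .phenotype import GerminationRecord, records_from_frame
from .snp_filter import DEPTH_COLUMNS, FilterDecision


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise ValidationError(f"{path}: malformed TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample count matrix; first column is the gene id."""
    df = _read_tsv(path, [])
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        dup = df.loc[df[gene_col].duplicated(), gene_col].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    df = df.set_index(gene_col)
    df.index.name = "gene"
    mat = df.apply(pd.to_numeric, errors="coerce")
    if mat.isna().any().any():
        raise ValidationError(f"{path}: non-numeric count values")
    if (mat < 0).any().any() or not (mat.round() == mat).all().all():
        raise ValidationError(f"{path}: counts must be non-negative integers")
    return mat.astype(int)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample_id", "unit", "timepoint", "qtl_status"])
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_depths(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, DEPTH_COLUMNS)
    return df[DEPTH_COLUMNS + [c for c in df.columns if c not in DEPTH_COLUMNS]]


def write_depths(depths: pd.DataFrame, path: str | Path) -> None:
    depths.to_csv(path, sep="\t", index=False)


def read_germination(
    path: str | Path, cumulative: bool = False
) -> list[GerminationRecord]:
    df = _read_tsv(path, ["sample_id", "genotype_class", "treatment", "total_grains"])
    return records_from_frame(df, cumulative=cumulative)


def write_germination(records: Iterable[GerminationRecord], path: str | Path) -> None:
    records = list(records)
    n_days = max(r.n_days for r in records) if records else 0
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "genotype_class": r.genotype_class,
            "treatment": r.treatment,
            "total_grains": r.total_grains,
        }
        for d in range(1, n_days + 1):
            row[f"day{d}"] = (
                r.daily_new_germinations[d - 1] if d <= r.n_days else 0
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(
    path: str | Path,
) -> tuple[list[ContigPlacement], dict[str, GenomicInterval]]:
    """BED records: unnamed/contig rows become placements; rows whose name
    starts with 'region:' become named intervals (e.g. the QTL region)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    placements, regions = [], {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 BED columns")
            chrom, start, end, name = fields[:4]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if name.startswith("region:"):
                regions[name[len("region:"):]] = GenomicInterval(chrom, start, end)
            else:
                placements.append(ContigPlacement(name, chrom, start, end))
    return placements, regions


def write_bed(
    placements: Iterable[ContigPlacement],
    path: str | Path,
    regions: dict[str, GenomicInterval] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, iv in (regions or {}).items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion:{name}\n")
        for p in placements:
            if p.placed:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.contig_id}\n")


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    df = _read_tsv(path, ["contig", "orf_start", "orf_end", "strand"])
    models = {}
    for _, row in df.iterrows():
        cid = str(row["contig"])
        if cid in models:
            raise ValidationError(f"{path}: duplicate gene model for {cid!r}")
        models[cid] = GeneModel(cid, int(row["orf_start"]), int(row["orf_end"]),
                                str(row["strand"]))
    return models


def write_gene_models(models: dict[str, GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"contig": m.contig_id, "orf_start": m.orf_start, "orf_end": m.orf_end,
             "strand": m.strand}
            for m in models.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def write_vcf(
    decisions: Iterable[FilterDecision],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Minimal VCF 4.2 of passing sites; POS is 1-based, REF the non-donor
    allele, ALT the donor allele, with C1-C4 and NFAM in INFO."""
    passing = [d for d in decisions if d.passed]
    contigs = sorted({d.contig for d in passing})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=nilseq\n")
        for c in contigs:
            length = (contig_lengths or {}).get(c)
            if length:
                fh.write(f"##contig=<ID={c},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        for i in range(1, 5):
            fh.write(
                f'##INFO=<ID=C{i},Number=1,Type=Integer,'
                f'Description="Trait-linked SNP criterion {i} satisfied">\n'
            )
        fh.write(
            '##INFO=<ID=NFAM,Number=1,Type=Integer,'
            'Description="Number of concordant families">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for d in passing:
            info = (
                f"C1={int(d.c1_donor_distinct)};C2={int(d.c2_donor_state)};"
                f"C3={int(d.c3_family_concordance)};C4={int(d.c4_min_coverage)};"
                f"NFAM={d.n_concordant_families}"
            )
            fh.write(
                f"{d.contig}\t{d.pos + 1}\t{d.site_id}\t{d.other_allele or 'N'}\t"
                f"{d.donor_allele or 'N'}\t.\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a (nilseq-style) VCF into a site table with 0-based positions."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    rows = []
    for var in VCF(str(path)):
        rows.append(
            {
                "site_id": var.ID or ".",
                "contig": var.CHROM,
                "pos": var.POS - 1,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "n_concordant_families": var.INFO.get("NFAM"),
                "passed": True,
            }
        )
    return pd.DataFrame(
        rows, columns=["site_id", "contig", "pos", "ref", "alt",
                       "n_concordant_families", "passed"]
    )


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
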