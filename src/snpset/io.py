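"""Readers and writers for the text formats the pipeline touches.

Formats: VCF v4.2 (via pysam; GT field, diploid, ``./.`` missing), a simple
tab-separated dosage dialect, covariate/battery TSVs, annotation TSV
(1-based inclusive), and GMT gene-set files.

Dosage dialect: first row is ``snp_id  chrom  pos  ref  alt`` followed by the
individual ids; each subsequent row is one SNP with dosages 0/1/2 or NA.
The dialect carries no allele-frequency metadata, so a ``SnpSpec`` read back
from disk reports the empirical minor-allele frequency; VCF output preserves
the generating MAF and gene label through INFO fields.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .sim import AnnotationTable, Cohort, GenotypeMatrix, SnpSpec

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "read_gmt",
    "write_gmt",
    "write_cohort",
    "read_cohort",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _empirical_maf(col: np.ndarray) -> float:
    ok = ~np.isnan(col)
    if not ok.any():
        return 0.25
    f = float(col[ok].mean() / 2.0)
    f = min(f, 1.0 - f)
    return min(max(f, 1e-6), 0.5)


def write_dosage_tsv(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tref\talt\t" + "\t".join(g.individual_ids) + "\n")
        for j, s in enumerate(g.snps):
            vals = [
                "NA" if np.isnan(v) else str(int(v)) for v in g.dosages[:, j]
            ]
            fh.write(
                f"{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.allele_ref}\t{s.allele_alt}\t"
                + "\t".join(vals)
                + "\n"
            )


def read_dosage_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if fields[:5] != ["snp_id", "chrom", "pos", "ref", "alt"]:
            raise ParseError(f"{path}: line 1: unexpected header {fields[:5]}")
        ids = fields[5:]
        if not ids:
            raise ParseError(f"{path}: line 1: no individual ids in header")
        snps: list[SnpSpec] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 + len(ids):
                raise ParseError(
                    f"{path}: line {lineno}: expected {5 + len(ids)} fields, "
                    f"got {len(parts)}"
                )
            try:
                pos = int(parts[2])
                vals = np.array(
                    [np.nan if v == "NA" else float(v) for v in parts[5:]]
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            snps.append(
                SnpSpec(parts[0], parts[1], pos, parts[3], parts[4], maf=0.25)
            )
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no SNP rows")
    dosages = np.vstack(rows).T
    snps = [
        SnpSpec(s.snp_id, s.chrom, s.pos, s.allele_ref, s.allele_alt,
                maf=_empirical_maf(dosages[:, j]))
        for j, s in enumerate(snps)
    ]
    return GenotypeMatrix(ids, snps, dosages)


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Plain-text VCF v4.2 with GT genotypes; MAF and gene label in INFO."""
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.add_line(
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Simulated minor allele frequency">'
    )
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene block label">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(s.chrom for s in g.snps):
        header.contigs.add(chrom, length=2**30)
    for ind in g.individual_ids:
        header.add_sample(ind)
    gt_of = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, s in enumerate(g.snps):
            rec = vf.new_record(
                contig=s.chrom, start=s.pos - 1, stop=s.pos,
                alleles=(s.allele_ref, s.allele_alt), id=s.snp_id,
            )
            rec.info["MAF"] = s.maf
            if s.gene is not None:
                rec.info["GENE"] = s.gene
            for i, ind in enumerate(g.individual_ids):
                v = g.dosages[i, j]
                rec.samples[ind]["GT"] = (None, None) if np.isnan(v) else gt_of[v]
            vf.write(rec)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    with pysam.VariantFile(str(path)) as vf:
        ids = list(vf.header.samples)
        snps: list[SnpSpec] = []
        rows: list[np.ndarray] = []
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "N"
            maf = float(rec.info.get("MAF", 0.25))
            gene = rec.info.get("GENE")
            snps.append(
                SnpSpec(rec.id or f"{rec.contig}:{rec.pos}", rec.contig, rec.pos,
                        rec.ref, alt, maf=min(max(maf, 1e-6), 0.5), gene=gene)
            )
            vals = np.empty(len(ids))
            for i, sample in enumerate(rec.samples.values()):
                gt = sample["GT"]
                vals[i] = (
                    np.nan if gt is None or gt[0] is None
                    else float(sum(a for a in gt if a is not None))
                )
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no variant records")
    return GenotypeMatrix(ids, snps, np.vstack(rows).T)


def write_annotation_tsv(annotation: AnnotationTable, path: str | os.PathLike) -> None:
    annotation.records.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(
    path: str | os.PathLike, zero_based_half_open: bool = False
) -> AnnotationTable:
    """Read gene annotation; set the flag to convert BED-style coordinates."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if zero_based_half_open:
        df = df.assign(start=df["start"] + 1)
    return AnnotationTable(df)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    "and at least one gene"
                )
            sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_cohort(cohort: Cohort, outdir: str | os.PathLike,
                 genotype_format: str = "dosage-tsv") -> None:
    """Write one cohort to a directory (genotypes + covariates + battery)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if genotype_format == "dosage-tsv":
        write_dosage_tsv(cohort.genotypes, out / "genotypes.dosage.tsv")
    elif genotype_format == "vcf":
        write_vcf(cohort.genotypes, out / "genotypes.vcf")
    else:
        raise ValueError(f"unknown genotype format {genotype_format!r}")
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    cohort.battery.to_csv(out / "battery.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"individual_id": cohort.genotypes.individual_ids, "latent_g": cohort.latent_g}
    ).to_csv(out / "latent_g.tsv", sep="\t", index=False)
    (out / "name.txt").write_text(cohort.name + "\n")


def read_cohort(outdir: str | os.PathLike) -> Cohort:
    out = Path(outdir)
    if (out / "genotypes.dosage.tsv").exists():
        genotypes = read_dosage_tsv(out / "genotypes.dosage.tsv")
    elif (out / "genotypes.vcf").exists():
        genotypes = read_vcf(out / "genotypes.vcf")
    else:
        raise FileNotFoundError(f"no genotype file under {out}")
    covariates = pd.read_csv(out / "covariates.tsv", sep="\t",
                             dtype={"individual_id": str})
    battery = pd.read_csv(out / "battery.tsv", sep="\t", dtype={"individual_id": str})
    latent = pd.read_csv(out / "latent_g.tsv", sep="\t")["latent_g"].to_numpy()
    name = (out / "name.txt").read_text().strip()
    return Cohort(name, genotypes, covariates, battery, latent)
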