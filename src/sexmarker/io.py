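"""Readers and writers for every external representation the pipeline touches.

Formats: VCF (v4.x, read via cyvcf2) plus a tab-separated sex map; the
compact genotype-table dialect (header of marker names, one row per sample,
heterozygotes ``X/Y``, homozygotes a single base, missing ``.``); FASTA
haplotypes (Biopython); tab-separated marker reports; BED candidate export
(0-based half-open).  A minimal VCF writer exists solely to support
write-then-read round-trip testing.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO

from .errors import GenotypeParseError, ValidationError
from .genotypes import (
    Genotype,
    GenotypeMatrix,
    LocusRecord,
    MISSING,
    SampleInfo,
    Sex,
    normalize_genotype,
)
from .scan import (
    AssociationStat,
    LocusSexPattern,
    MarkerReport,
    SexCountSummary,
)

REPORT_COLUMNS = [
    "marker",
    "contig",
    "position",
    "ref",
    "alt",
    "pattern",
    "n_f_het",
    "n_f_hom",
    "n_f_missing",
    "n_m_het",
    "n_m_hom",
    "n_m_missing",
    "p_value",
    "q_value",
]


# ---------------------------------------------------------------------------
# Sex map
# ---------------------------------------------------------------------------


def read_sex_map(path: str | os.PathLike) -> list[SampleInfo]:
    """Read a 2-3 column tab-separated sample/sex(/species) table."""
    samples: list[SampleInfo] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns"
                )
            sample_id = parts[0].strip()
            if sample_id in seen:
                raise GenotypeParseError(
                    f"{path}:{lineno}: duplicate sample id {sample_id!r}"
                )
            seen.add(sample_id)
            species = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
            samples.append(SampleInfo(sample_id, Sex.from_token(parts[1]), species))
    return samples


def write_sex_map(samples: list[SampleInfo], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in samples:
            sp = s.species or ""
            fh.write(f"{s.sample_id}\t{s.sex.value}\t{sp}\n".rstrip() + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_genotypes(
    vcf_path: str | os.PathLike,
    sex_map: list[SampleInfo],
    biallelic_only: bool = True,
) -> GenotypeMatrix:
    """Load SNP records from a VCF into a sexed genotype matrix.

    GT indices are resolved to bases; half-calls and ``./.`` become
    missing.  Multiallelic records are excluded when ``biallelic_only``
    (the default).  Loci are ordered by (contig, position); every VCF
    sample must appear in ``sex_map``.
    """
    from cyvcf2 import VCF

    by_id = {s.sample_id: s for s in sex_map}
    vcf = VCF(str(vcf_path))
    missing_ids = [s for s in vcf.samples if s not in by_id]
    if missing_ids:
        raise ValidationError(
            "VCF samples absent from sex map: " + ", ".join(missing_ids)
        )
    samples = [by_id[s] for s in vcf.samples]

    loci: list[LocusRecord] = []
    rows: list[list[Genotype]] = []
    for var in vcf:
        alts = [a for a in var.ALT if a]
        if biallelic_only and len(alts) != 1:
            continue
        if len(var.REF) != 1 or any(len(a) != 1 for a in alts):
            continue  # SNPs only
        alleles = [var.REF] + alts
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        row: list[Genotype] = []
        for g in var.genotypes:
            idx = g[:-1]  # last entry is phasedness
            if len(idx) != 2:
                raise ValidationError(
                    f"{var.CHROM}:{var.POS}: non-diploid GT for a sample "
                    f"(ploidy {len(idx)})"
                )
            if idx[0] < 0 or idx[1] < 0:
                row.append(MISSING)
            else:
                row.append(Genotype((alleles[idx[0]], alleles[idx[1]])))
        loci.append(
            LocusRecord(name, var.CHROM, var.POS, var.REF, alts[0] if alts else "N")
        )
        rows.append(row)
    vcf.close()
    return GenotypeMatrix(loci, samples, rows).sorted_by_position()


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Minimal VCF v4.2 emitter (round-trip test helper only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in dict.fromkeys(loc.contig_id for loc in matrix.loci):
            fh.write(f"##contig=<ID={contig}>\n")
        header = [
            "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
        ]
        fh.write("\t".join(header + matrix.sample_ids()) + "\n")
        for locus, row in matrix:
            ref, alt = locus.reference_base, locus.alternative_base
            calls = []
            for g in row:
                if g.is_missing:
                    calls.append("./.")
                    continue
                try:
                    calls.append(
                        "/".join(str((ref, alt).index(a)) for a in g.alleles)
                    )
                except ValueError:
                    raise ValidationError(
                        f"{locus.marker_name}: genotype {g.to_token()} uses an "
                        f"allele outside REF={ref}/ALT={alt}"
                    ) from None
            fh.write(
                "\t".join(
                    [
                        locus.contig_id,
                        str(locus.position),
                        locus.marker_name,
                        ref,
                        alt,
                        ".",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + calls
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genotype table (compact dialect)
# ---------------------------------------------------------------------------


def read_genotype_table(
    path: str | os.PathLike,
    sex_map: list[SampleInfo],
    loci: list[LocusRecord] | None = None,
) -> GenotypeMatrix:
    """Read the compact marker-table dialect into a genotype matrix.

    Layout: a tab-separated header of marker names, then one row per
    sample (sample id followed by genotype tokens).  When no
    ``loci`` metadata is supplied, positions are synthesised as 1..k on
    the pseudo-contig ``TABLE``.
    """
    by_id = {s.sample_id: s for s in sex_map}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    marker_names = [c.strip() for c in lines[0].split("\t") if c.strip()]
    if not marker_names:
        raise GenotypeParseError(f"{path}: header contains no marker names")
    if loci is None:
        loci = [
            LocusRecord(name, "TABLE", k + 1) for k, name in enumerate(marker_names)
        ]
    elif [l.marker_name for l in loci] != marker_names:
        raise ValidationError("supplied loci do not match the table header")

    samples: list[SampleInfo] = []
    columns: list[list[Genotype]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(marker_names) + 1:
            raise GenotypeParseError(
                f"{path}:{lineno}: row has {len(parts) - 1} genotypes for "
                f"{len(marker_names)} markers"
            )
        sample_id = parts[0].strip()
        if sample_id not in by_id:
            raise ValidationError(
                f"{path}:{lineno}: sample {sample_id!r} absent from sex map"
            )
        samples.append(by_id[sample_id])
        columns.append(
            [
                normalize_genotype(tok, where=f"{path}:{lineno} ({name})")
                for tok, name in zip(parts[1:], marker_names)
            ]
        )
    if not samples:
        raise GenotypeParseError(f"{path}: no samples")
    rows = [[col[i] for col in columns] for i in range(len(marker_names))]
    return GenotypeMatrix(loci, samples, rows)


def write_genotype_table(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(loc.marker_name for loc in matrix.loci) + "\n")
        for j, s in enumerate(matrix.samples):
            tokens = [matrix.genotypes[i][j].to_token() for i in range(matrix.n_loci)]
            fh.write("\t".join([s.sample_id] + tokens) + "\n")


# ---------------------------------------------------------------------------
# Marker reports / BED
# ---------------------------------------------------------------------------


def write_marker_report(
    reports: Iterable[MarkerReport], path: str | os.PathLike
) -> None:
    """Write one tab-separated row per scanned locus (deterministic columns)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in reports:
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        r.locus.marker_name,
                        r.locus.contig_id,
                        r.locus.position,
                        r.locus.reference_base,
                        r.locus.alternative_base,
                        r.pattern.value,
                        r.counts.n_f_het,
                        r.counts.n_f_hom,
                        r.counts.n_f_missing,
                        r.counts.n_m_het,
                        r.counts.n_m_hom,
                        r.counts.n_m_missing,
                        repr(r.stat.p_value),
                        repr(r.stat.q_value),
                    ]
                )
                + "\n"
            )


def read_marker_report(path: str | os.PathLike) -> list[MarkerReport]:
    """Parse a marker-report file back into report objects (round-trip)."""
    reports: list[MarkerReport] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != REPORT_COLUMNS:
            raise GenotypeParseError(f"{path}: unexpected report header")
        for line in fh:
            if not line.strip():
                continue
            v = dict(zip(REPORT_COLUMNS, line.rstrip("\n").split("\t")))
            reports.append(
                MarkerReport(
                    LocusRecord(
                        v["marker"], v["contig"], int(v["position"]), v["ref"], v["alt"]
                    ),
                    SexCountSummary(
                        n_f_het=int(v["n_f_het"]),
                        n_f_hom=int(v["n_f_hom"]),
                        n_f_missing=int(v["n_f_missing"]),
                        n_m_het=int(v["n_m_het"]),
                        n_m_hom=int(v["n_m_hom"]),
                        n_m_missing=int(v["n_m_missing"]),
                    ),
                    LocusSexPattern(v["pattern"]),
                    AssociationStat(float(v["p_value"]), float(v["q_value"])),
                )
            )
    return reports


def write_candidate_bed(
    reports: Iterable[MarkerReport], path: str | os.PathLike
) -> None:
    """BED export (0-based half-open) of candidate sex-linked loci."""
    with open(path, "w") as fh:
        for r in reports:
            if r.is_candidate:
                fh.write(
                    f"{r.locus.contig_id}\t{r.locus.position - 1}\t"
                    f"{r.locus.position}\t{r.locus.marker_name}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta_sequences(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA records into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
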