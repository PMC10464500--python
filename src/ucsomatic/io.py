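"""Readers and writers for the file formats the pipeline consumes.

Variant tables use either VCF (with per-sample AD/DP fields, read through
cyvcf2 when available) or a documented TSV dialect with the columns::

    chrom pos ref alt variant_class sample_id tumor_depth tumor_alt
    normal_depth normal_alt [population_af] [consequence] [gene]

Intervals are BED (0-based half-open), transcripts BED6 with strand in
column 6, copy-number segments a Sequenza-style TSV (``chromosome``,
``start.pos``, ``end.pos``, ``CNt``, ``Bf``), and population allele
frequencies a TSV of ``chrom pos ref alt af``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ucsomatic.copynumber import CnSegment
from ucsomatic.filtering import SomaticVariant
from ucsomatic.strandbias import TranscriptAnnotation

__all__ = [
    "open_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_transcripts_bed",
    "write_transcripts_bed",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_vcf",
    "read_popdb_tsv",
    "read_sequenza",
    "write_sequenza",
]

_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "sample_id",
    "tumor_depth",
    "tumor_alt",
    "normal_depth",
    "normal_alt",
    "population_af",
    "consequence",
    "gene",
]


def open_fasta(path):
    """Open an indexed FASTA as a reference accessor (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return intervals


def write_bed(intervals: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_transcripts_bed(path) -> list[TranscriptAnnotation]:
    """BED6 with the transcript id in column 4 and strand in column 6."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"transcript BED needs 6 columns, got: {line!r}")
            out.append(
                TranscriptAnnotation(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    transcript_id=parts[3],
                    strand=parts[5],
                )
            )
    return out


def write_transcripts_bed(transcripts: Iterable[TranscriptAnnotation], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.transcript_id}\t0\t{t.strand}\n")


def _variant_from_row(row: Mapping) -> SomaticVariant:
    def opt(key):
        val = row.get(key)
        if val is None or (isinstance(val, float) and pd.isna(val)) or val in ("", "."):
            return None
        return val

    af = opt("population_af")
    return SomaticVariant(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        variant_class=str(row["variant_class"]),
        tumor_depth=int(row["tumor_depth"]),
        tumor_alt=int(row["tumor_alt"]),
        normal_depth=int(row["normal_depth"]),
        normal_alt=int(row["normal_alt"]),
        sample_id=str(row["sample_id"]),
        population_af=float(af) if af is not None else None,
        consequence=opt("consequence"),
        gene=opt("gene"),
    )


def read_variants_tsv(path) -> list[SomaticVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _VARIANT_COLUMNS[:10] if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV missing required columns: {missing}")
    return [_variant_from_row(row) for row in df.to_dict("records")]


def write_variants_tsv(variants: Sequence[SomaticVariant], path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "variant_class": v.variant_class,
                "sample_id": v.sample_id,
                "tumor_depth": v.tumor_depth,
                "tumor_alt": v.tumor_alt,
                "normal_depth": v.normal_depth,
                "normal_alt": v.normal_alt,
                "population_af": v.population_af if v.population_af is not None else "",
                "consequence": v.consequence or "",
                "gene": v.gene or "",
            }
        )
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) == len(alt):
        return "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


def read_vcf(path, tumor_sample: str, normal_sample: str) -> list[SomaticVariant]:
    """Read tumor/normal calls from a VCF with AD (or AD-like) FORMAT fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        ti, ni = samples.index(tumor_sample), samples.index(normal_sample)
    except ValueError:
        raise ValueError(
            f"samples {tumor_sample!r}/{normal_sample!r} not in VCF samples {samples}"
        )
    out = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks an AD FORMAT field")
        for alt_idx, alt in enumerate(rec.ALT):
            t_ref, t_alt = int(ad[ti][0]), int(ad[ti][alt_idx + 1])
            n_ref, n_alt = int(ad[ni][0]), int(ad[ni][alt_idx + 1])
            out.append(
                SomaticVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    variant_class=_variant_class(rec.REF, alt),
                    tumor_depth=t_ref + t_alt,
                    tumor_alt=t_alt,
                    normal_depth=n_ref + n_alt,
                    normal_alt=n_alt,
                    sample_id=tumor_sample,
                )
            )
    return out


def read_popdb_tsv(path) -> dict[tuple, float]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "af"}
    if not required.issubset(df.columns):
        raise ValueError(f"population DB TSV needs columns {sorted(required)}")
    return {
        (str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"])): float(r["af"])
        for r in df.to_dict("records")
    }


def read_sequenza(path, sample_id: str | None = None) -> list[CnSegment]:
    """Read a Sequenza-style segments TSV (chromosome, start.pos, end.pos, CNt, Bf)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"chromosome", "start.pos", "end.pos", "CNt", "Bf"}
    if not required.issubset(df.columns):
        raise ValueError(f"Sequenza TSV needs columns {sorted(required)}")
    sid = sample_id
    if sid is None:
        sid = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else Path(path).stem
    out = []
    for r in df.to_dict("records"):
        out.append(
            CnSegment(
                chrom=str(r["chromosome"]),
                start=int(r["start.pos"]),
                end=int(r["end.pos"]),
                total_cn=int(r["CNt"]),
                baf=0.0 if pd.isna(r["Bf"]) else float(r["Bf"]),
                sample_id=str(r.get("sample_id", sid)),
            )
        )
    return out


def write_sequenza(segments: Sequence[CnSegment], path) -> None:
    rows = [
        {
            "chromosome": s.chrom,
            "start.pos": s.start,
            "end.pos": s.end,
            "CNt": s.total_cn,
            "Bf": s.baf,
            "sample_id": s.sample_id,
        }
        for s in segments
    ]
    pd.DataFrame(
        rows, columns=["chromosome", "start.pos", "end.pos", "CNt", "Bf", "sample_id"]
    ).to_csv(path, sep="\t", index=False)
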