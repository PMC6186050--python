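"""Readers and writers for every on-disk artifact the pipeline touches.

Conventions, fixed here once: internal coordinates are 0-based half-open;
VCF and the consequence TSV are 1-based in the file and converted at this
boundary. Variant class labels travel in the VCF INFO field ``CLS``
(``derived`` or ``simulated``); allele frequencies in INFO ``AF``. All
writers are deterministic given input ordering.
"""

from __future__ import annotations

import json
import logging
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ANC_ALPHABET,
    BASES,
    EXTERNAL,
    LABELS,
    REF_ALPHABET,
    AncestorAlignment,
    GenomeSequence,
    ParseError,
    SpeciesCaddError,
    Track,
    Variant,
)

logger = logging.getLogger(__name__)

ALL_5MERS = ["".join(p) for p in product(BASES, repeat=5)]

CONSEQUENCE_COLUMNS = ["contig", "pos", "ref", "alt", "consequence", "transcribed", "translated"]


# ---------------------------------------------------------------------------
# FASTA

def _read_fasta_strings(path: str | Path, alphabet: frozenset) -> dict[str, str]:
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in contigs:
            raise ParseError(f"{path}: duplicate contig name {name!r}")
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise ParseError(f"{path}: contig {name!r} is empty")
        bad = set(seq) - alphabet
        if bad:
            raise ParseError(
                f"{path}: contig {name!r} contains disallowed characters "
                f"{sorted(bad)} (IUPAC ambiguity codes other than N are rejected)"
            )
        contigs[name] = seq
    if not contigs:
        raise ParseError(f"{path}: no FASTA records found")
    return contigs


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a reference genome FASTA (alphabet ACGTN after normalization)."""
    return GenomeSequence(_read_fasta_strings(path, REF_ALPHABET))


def read_ancestor_fasta(path: str | Path) -> AncestorAlignment:
    """Read a reference-projected ancestral FASTA ('-' allowed for unaligned)."""
    return AncestorAlignment(_read_fasta_strings(path, ANC_ALPHABET))


def _write_fasta_strings(contigs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    _write_fasta_strings(genome.contigs, path)


def write_ancestor_fasta(anc: AncestorAlignment, path: str | Path) -> None:
    _write_fasta_strings(anc.contigs, path)


# ---------------------------------------------------------------------------
# VCF

def _vcf_header(contigs: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(
        '##INFO=<ID=CLS,Number=1,Type=String,'
        'Description="Training class: derived (reference carries the derived '
        'allele, ALT is the ancestral state) or simulated">'
    )
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    for name in contigs:
        header.contigs.add(name)
    return header


def write_vcf(variants: list[Variant], path: str | Path) -> None:
    """Write SNVs as VCF 4.2 with class labels in INFO CLS and AF in INFO AF."""
    contigs = list(dict.fromkeys(v.contig for v in variants))
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig, start=v.pos, alleles=(v.ref_allele, v.alt_allele)
            )
            if v.label != EXTERNAL:
                rec.info["CLS"] = v.label
            if v.af is not None:
                rec.info["AF"] = (v.af,)
            out.write(rec)


def read_vcf_with_stats(path: str | Path) -> tuple[list[Variant], int]:
    """Read SNVs from a VCF; returns (variants, count of skipped non-SNV alleles).

    Multi-allelic records are split; records whose REF is not a single ACGT
    base, and ALT alleles that are not, are skipped and counted.
    """
    variants: list[Variant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            alts = rec.alts or ()
            if len(ref) != 1 or ref not in "ACGT":
                n_skipped += max(len(alts), 1)
                continue
            # pysam raises on INFO keys absent from the header
            try:
                label = rec.info.get("CLS", EXTERNAL)
            except (KeyError, ValueError):
                label = EXTERNAL
            if label not in LABELS:
                raise ParseError(f"{path}: unknown CLS value {label!r} at {rec.contig}:{rec.pos}")
            try:
                afs = rec.info.get("AF")
            except (KeyError, ValueError):
                afs = None
            for i, alt in enumerate(alts):
                alt = alt.upper()
                if len(alt) != 1 or alt not in "ACGT":
                    n_skipped += 1
                    continue
                af = None
                if afs is not None and i < len(afs) and afs[i] is not None:
                    af = float(afs[i])
                variants.append(
                    Variant(
                        contig=rec.contig,
                        pos=rec.start,
                        ref_allele=ref,
                        alt_allele=alt,
                        label=label,
                        af=af,
                    )
                )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-SNV allele(s) in %s", n_skipped, path)
    return variants, n_skipped


def read_vcf(path: str | Path) -> list[Variant]:
    return read_vcf_with_stats(path)[0]


# ---------------------------------------------------------------------------
# bedGraph / BED

def read_bedgraph(path: str | Path, name: str | None = None) -> Track:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                records.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    track_name = name if name is not None else Path(path).stem
    try:
        return Track.per_base(track_name, records)
    except SpeciesCaddError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: Track, path: str | Path) -> None:
    if track.kind != "per_base_score":
        raise SpeciesCaddError("write_bedgraph requires a per-base score track")
    with open(path, "w") as fh:
        for contig, start, end, value in track.iter_records():
            fh.write(f"{contig}\t{start}\t{end}\t{value:.6g}\n")


def read_bed(path: str | Path, name: str | None = None) -> Track:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                records.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    track_name = name if name is not None else Path(path).stem
    try:
        return Track.intervals(track_name, records)
    except SpeciesCaddError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bed(track: Track, path: str | Path) -> None:
    if track.kind != "interval":
        raise SpeciesCaddError("write_bed requires an interval track")
    with open(path, "w") as fh:
        for contig, start, end in track.iter_records():
            fh.write(f"{contig}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Shape table (all 1024 5-mers x shape descriptors)

def read_shape_table(path: str | Path) -> pd.DataFrame:
    """Read the 5-mer shape lookup table; must cover all 1024 5-mers."""
    df = pd.read_csv(path, sep="\t")
    if "kmer" not in df.columns:
        raise ParseError(f"{path}: shape table needs a 'kmer' column")
    if len(df.columns) < 2:
        raise ParseError(f"{path}: shape table has no descriptor columns")
    df["kmer"] = df["kmer"].str.upper()
    if df["kmer"].duplicated().any():
        dups = df.loc[df["kmer"].duplicated(), "kmer"].tolist()[:5]
        raise ParseError(f"{path}: duplicate 5-mers {dups}")
    missing = set(ALL_5MERS) - set(df["kmer"])
    if missing:
        raise ParseError(
            f"{path}: shape table incomplete, {len(missing)} of 1024 5-mers missing "
            f"(e.g. {sorted(missing)[:3]})"
        )
    return df.set_index("kmer").astype(float)


def write_shape_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="kmer", float_format="%.6g")


# ---------------------------------------------------------------------------
# Consequence table (VEP-like summaries; 1-based positions in the file)

def read_consequences(path: str | Path) -> pd.DataFrame:
    """Read the consequence TSV; positions are converted to 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    missing = [c for c in CONSEQUENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: consequence table missing columns {missing}")
    df = df[CONSEQUENCE_COLUMNS].copy()
    df["pos"] = df["pos"].astype(int) - 1
    for col in ("transcribed", "translated"):
        df[col] = _parse_bool_series(df[col], path, col)
    return df


def write_consequences(df: pd.DataFrame, path: str | Path) -> None:
    out = df[CONSEQUENCE_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1
    out["transcribed"] = out["transcribed"].astype(int)
    out["translated"] = out["translated"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def _parse_bool_series(s: pd.Series, path, col) -> pd.Series:
    mapping = {"0": False, "1": True, "true": True, "false": False}
    out = s.astype(str).str.lower().map(mapping)
    if out.isna().any():
        bad = s[out.isna()].iloc[0]
        raise ParseError(f"{path}: column {col} has non-boolean value {bad!r}")
    return out.astype(bool)


# ---------------------------------------------------------------------------
# Feature matrix TSV (row key contig:pos:ref:alt, NA for missing)

MATRIX_MAGIC = "##speciescadd-feature-matrix\tv1"
_META_COLS = ["key", "label", "fold", "consequence", "transcribed", "translated"]


def write_matrix(matrix, path: str | Path) -> None:
    """Write a FeatureMatrix as TSV with a tag preamble; missing values as NA."""
    with open(path, "w") as fh:
        fh.write(MATRIX_MAGIC + "\n")
        for col in matrix.columns:
            fh.write(f"##column\t{col.name}\ttags={';'.join(sorted(col.tags))}\n")
        names = [c.name for c in matrix.columns]
        fh.write("\t".join(_META_COLS + names) + "\n")
        labels = matrix.labels
        for i, v in enumerate(matrix.variants):
            meta = [
                v.key,
                "NA" if labels is None else str(int(labels[i])),
                "NA" if v.fold is None else str(v.fold),
                v.consequence if v.consequence is not None else "NA",
                str(int(v.transcribed)),
                str(int(v.translated)),
            ]
            row = []
            for col in matrix.columns:
                if col.missing_mask[i]:
                    row.append("NA")
                else:
                    row.append(f"{col.values[i]:.10g}")
            fh.write("\t".join(meta + row) + "\n")


def read_matrix(path: str | Path):
    """Read a feature-matrix TSV written by :func:`write_matrix`."""
    from .features import FeatureColumn, FeatureMatrix

    tags: dict[str, frozenset] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != MATRIX_MAGIC:
            raise ParseError(f"{path}: not a speciescadd feature matrix")
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("##column\t"):
            _, name, tagpart = line.rstrip("\n").split("\t")
            tags[name] = frozenset(t for t in tagpart[len("tags="):].split(";") if t)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"], keep_default_na=False,
                         dtype={"key": str, "consequence": str})
    variants = []
    labels = []
    have_labels = df["label"].notna().all()
    for _, row in df.iterrows():
        contig, p, ref, alt = row["key"].rsplit(":", 3)
        label = EXTERNAL
        if pd.notna(row["label"]):
            label = "simulated" if int(row["label"]) == 1 else "derived"
            labels.append(int(row["label"]))
        variants.append(
            Variant(
                contig=contig,
                pos=int(p),
                ref_allele=ref,
                alt_allele=alt,
                label=label,
                consequence=None if pd.isna(row["consequence"]) else row["consequence"],
                transcribed=bool(int(row["transcribed"])),
                translated=bool(int(row["translated"])),
                fold=None if pd.isna(row["fold"]) else int(row["fold"]),
            )
        )
    columns = []
    for name in df.columns:
        if name in _META_COLS:
            continue
        values = df[name].to_numpy(dtype=float)
        missing = np.isnan(values)
        columns.append(
            FeatureColumn(
                name=name,
                tags=tags.get(name, frozenset()),
                values=np.where(missing, 0.0, values),
                missing_mask=missing,
            )
        )
    return FeatureMatrix(
        variants=variants,
        columns=columns,
        labels=np.array(labels, dtype=int) if have_labels else None,
    )


# ---------------------------------------------------------------------------
# Model JSON (trained classifier and mutation model)

def write_model(model, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path: str | Path):
    from .training import TrainedModel

    with open(path) as fh:
        return TrainedModel.from_dict(json.load(fh))


def write_mutation_model(model, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_mutation_model(path: str | Path):
    from .mutmodel import MutationModel

    with open(path) as fh:
        return MutationModel.from_dict(json.load(fh))
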