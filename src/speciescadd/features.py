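"""Per-variant annotation matrix assembly.

Features are grouped into tagged classes (conservation, sequence, vep,
composite, coding, epigenetic, species_specific) so that nested
annotation subsets — all, no_epi (drop epigenetic and species-specific),
cons_vep (conservation + sequence + VEP, keeping coding-specific VEP
one-hots only), seq_only (derivable from sequence alone) — can be carved
out for training models of decreasing annotation availability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GenomeSequence, SpeciesCaddError, Track, Variant

VALID_TAGS = frozenset(
    {"conservation", "sequence", "vep", "composite", "coding", "epigenetic", "species_specific"}
)

DEFAULT_CONSEQUENCES = (
    "intergenic",
    "intron",
    "non_coding_exon",
    "synonymous",
    "missense",
    "stop_gained",
    "UTR",
)
CODING_CONSEQUENCES = frozenset({"synonymous", "missense", "stop_gained"})

TIERS = ("all", "no_epi", "cons_vep", "seq_only")


@dataclass
class FeatureConfig:
    gc_halfwidth: int = 75
    shape_k: int = 5
    composite_spec: list[tuple[str, str]] = field(default_factory=list)
    tier: str = "all"

    def __post_init__(self) -> None:
        if self.gc_halfwidth < 1:
            raise SpeciesCaddError("gc_halfwidth must be >= 1")
        if self.shape_k != 5:
            raise SpeciesCaddError("shape_k is fixed at 5")
        if self.tier not in TIERS:
            raise SpeciesCaddError(f"unknown tier {self.tier!r}, expected one of {TIERS}")


@dataclass
class FeatureColumn:
    """One named annotation over all variants, with explicit missingness."""

    name: str
    tags: frozenset
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.tags:
            raise SpeciesCaddError(f"column {self.name!r} has no tags")
        bad = set(self.tags) - VALID_TAGS
        if bad:
            raise SpeciesCaddError(f"column {self.name!r} has unknown tags {sorted(bad)}")
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise SpeciesCaddError(f"column {self.name!r}: values/missing shape mismatch")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise SpeciesCaddError(f"column {self.name!r} has non-finite present values")


@dataclass
class FeatureMatrix:
    """Ordered variants x tagged feature columns, with optional class labels."""

    variants: list[Variant]
    columns: list[FeatureColumn]
    labels: np.ndarray | None = None  # 1 = simulated, 0 = derived

    def __post_init__(self) -> None:
        n = len(self.variants)
        seen = set()
        for col in self.columns:
            if col.name in seen:
                raise SpeciesCaddError(f"duplicate column name {col.name!r}")
            seen.add(col.name)
            if len(col.values) != n:
                raise SpeciesCaddError(
                    f"column {col.name!r} has {len(col.values)} values for {n} variants"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != n:
                raise SpeciesCaddError("labels length mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def column(self, name: str) -> FeatureColumn:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def has_missing(self) -> bool:
        return any(c.missing_mask.any() for c in self.columns)

    def values_array(self) -> np.ndarray:
        """Dense (n_variants, n_columns) array; requires no missing values."""
        if self.has_missing():
            raise SpeciesCaddError("matrix still has missing values; run impute_missing first")
        if not self.columns:
            raise SpeciesCaddError("matrix has no columns")
        return np.column_stack([c.values for c in self.columns])

    def folds(self) -> np.ndarray:
        out = np.array([-1 if v.fold is None else v.fold for v in self.variants])
        return out

    def to_dataframe(self) -> pd.DataFrame:
        data = {}
        for c in self.columns:
            vals = c.values.copy()
            vals[c.missing_mask] = np.nan
            data[c.name] = vals
        return pd.DataFrame(data, index=[v.key for v in self.variants])


# ---------------------------------------------------------------------------
# individual feature extractors

def gc_content(ref: GenomeSequence, variant: Variant, halfwidth: int = 75) -> float | None:
    """GC fraction of the reference window [pos-halfwidth, pos+halfwidth].

    The window is clipped to contig bounds; N bases are excluded from the
    denominator; an all-N window yields None (missing).
    """
    seq = ref[variant.contig]
    if not 0 <= variant.pos < len(seq):
        raise SpeciesCaddError(f"variant position {variant.pos} outside contig")
    lo = max(0, variant.pos - halfwidth)
    hi = min(len(seq), variant.pos + halfwidth + 1)
    window = seq[lo:hi]
    n_gc = window.count("G") + window.count("C")
    n_known = len(window) - window.count("N")
    if n_known == 0:
        return None
    return n_gc / n_known


def shape_delta(
    ref: GenomeSequence, variant: Variant, table: pd.DataFrame
) -> dict[str, float | None]:
    """Predicted-shape differences alt-5-mer minus ref-5-mer, per descriptor.

    The 5-mer is centered on the variant; positions closer than 2 bases to
    a contig end, or 5-mers containing N, yield missing for every
    descriptor.
    """
    seq = ref[variant.contig]
    missing = {d: None for d in table.columns}
    if variant.pos < 2 or variant.pos > len(seq) - 3:
        return missing
    ref5 = seq[variant.pos - 2 : variant.pos + 3]
    if "N" in ref5:
        return missing
    if ref5[2] != variant.ref_allele:
        raise SpeciesCaddError(
            f"reference allele mismatch at {variant.contig}:{variant.pos}: "
            f"genome has {ref5[2]!r}, variant says {variant.ref_allele!r}"
        )
    alt5 = ref5[:2] + variant.alt_allele + ref5[3:]
    diff = table.loc[alt5] - table.loc[ref5]
    return {d: float(diff[d]) for d in table.columns}


def track_lookup(track: Track, variant: Variant) -> float | None:
    """Value covering the position (score tracks; None if uncovered) or 0/1."""
    return track.lookup(variant.contig, variant.pos)


def encode_consequences(
    csq: pd.DataFrame,
    variants: list[Variant],
    vocabulary: tuple[str, ...] = DEFAULT_CONSEQUENCES,
) -> list[FeatureColumn]:
    """One-hot consequence columns; carries flags onto the variants in place.

    Variants absent from the table get an all-zero encoding with
    transcribed = translated = False. Duplicate variant keys or terms
    outside the vocabulary are errors.
    """
    unknown = set(csq["consequence"]) - set(vocabulary)
    if unknown:
        raise SpeciesCaddError(f"unknown consequence term(s): {sorted(unknown)}")
    keyed: dict[tuple, tuple] = {}
    for row in csq.itertuples(index=False):
        key = (row.contig, int(row.pos), row.ref, row.alt)
        if key in keyed:
            raise SpeciesCaddError(
                f"duplicate consequence rows for {row.contig}:{row.pos}:{row.ref}:{row.alt}"
            )
        keyed[key] = (row.consequence, bool(row.transcribed), bool(row.translated))
    n = len(variants)
    onehots = {term: np.zeros(n) for term in vocabulary}
    for i, v in enumerate(variants):
        entry = keyed.get((v.contig, v.pos, v.ref_allele, v.alt_allele))
        if entry is None:
            v.consequence = None
            v.transcribed = False
            v.translated = False
            continue
        term, transcribed, translated = entry
        v.consequence = term
        v.transcribed = transcribed
        v.translated = translated
        onehots[term][i] = 1.0
    none_missing = np.zeros(n, dtype=bool)
    columns = []
    for term in vocabulary:
        tags = {"vep"}
        if term in CODING_CONSEQUENCES:
            tags.add("coding")
        columns.append(
            FeatureColumn(
                name=f"csq_{term}",
                tags=frozenset(tags),
                values=onehots[term],
                missing_mask=none_missing.copy(),
            )
        )
    return columns


def composite_features(
    matrix: FeatureMatrix, composite_spec: list[tuple[str, str]]
) -> list[FeatureColumn]:
    """Consequence x annotation interaction columns.

    For each (term, annot) pair the new column carries the annotation value
    where the term's one-hot is 1 and 0 elsewhere; missing annotation
    values propagate. Tags are {composite} plus the annotation's tags.
    """
    existing = set(matrix.names())
    out = []
    for term, annot in composite_spec:
        term_col = matrix.column(f"csq_{term}")
        annot_col = matrix.column(annot)
        name = f"{annot}_x_{term}"
        if name in existing:
            raise SpeciesCaddError(f"composite column name collision: {name!r}")
        existing.add(name)
        active = term_col.values == 1.0
        values = np.where(active, annot_col.values, 0.0)
        missing = annot_col.missing_mask & active
        values = np.where(missing, 0.0, values)
        out.append(
            FeatureColumn(
                name=name,
                tags=frozenset({"composite"} | set(annot_col.tags)),
                values=values,
                missing_mask=missing,
            )
        )
    return out


def apply_tier(matrix: FeatureMatrix, tier: str) -> FeatureMatrix:
    """Restrict columns to an annotation-availability tier.

    all: identity. no_epi: drop epigenetic and species-specific columns.
    cons_vep: keep conservation/sequence/vep/composite, then drop
    coding-tagged columns unless they are VEP one-hots. seq_only: keep only
    conservation and sequence columns.
    """
    if tier not in TIERS:
        raise SpeciesCaddError(f"unknown tier {tier!r}")
    if tier == "all":
        kept = list(matrix.columns)
    elif tier == "no_epi":
        kept = [
            c
            for c in matrix.columns
            if not ({"epigenetic", "species_specific"} & c.tags)
        ]
    elif tier == "cons_vep":
        kept = [
            c
            for c in matrix.columns
            if ({"conservation", "sequence", "vep", "composite"} & c.tags)
            and not ({"epigenetic", "species_specific"} & c.tags)
            and ("coding" not in c.tags or "vep" in c.tags)
        ]
    else:  # seq_only
        kept = [
            c
            for c in matrix.columns
            if ({"conservation", "sequence"} & c.tags)
            and not (
                {"epigenetic", "species_specific", "vep", "composite", "coding"} & c.tags
            )
        ]
    return FeatureMatrix(variants=matrix.variants, columns=kept, labels=matrix.labels)


def impute_missing(matrix: FeatureMatrix) -> FeatureMatrix:
    """Zero-fill missing values, adding a <name>__missing indicator per column.

    Indicator columns inherit the parent's tags; columns without
    missingness are passed through unchanged. The result has no missing
    values, which keeps zero-filled sparsity compatible with the
    divide-by-sd, no-centering standardization used downstream.
    """
    columns: list[FeatureColumn] = []
    for col in matrix.columns:
        if not col.missing_mask.any():
            columns.append(col)
            continue
        filled = np.where(col.missing_mask, 0.0, col.values)
        columns.append(replace(col, values=filled, missing_mask=np.zeros_like(col.missing_mask)))
        columns.append(
            FeatureColumn(
                name=f"{col.name}__missing",
                tags=col.tags,
                values=col.missing_mask.astype(float),
                missing_mask=np.zeros_like(col.missing_mask),
            )
        )
    return FeatureMatrix(variants=matrix.variants, columns=columns, labels=matrix.labels)


# ---------------------------------------------------------------------------
# assembler

def build_feature_matrix(
    ref: GenomeSequence,
    variants: list[Variant],
    tracks: list[tuple[Track, frozenset | set]] | None = None,
    csq: pd.DataFrame | None = None,
    shape_table: pd.DataFrame | None = None,
    config: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Assemble the annotation matrix for a variant set.

    Produces GC content, shape deltas, track lookups, consequence one-hots
    and configured composites; applies the configured tier and imputes
    missingness (zero-fill + indicator).
    """
    config = config or FeatureConfig()
    n = len(variants)
    labels = None
    label_set = {v.label for v in variants}
    if label_set <= {"derived", "simulated"} and variants:
        labels = np.array([1 if v.label == "simulated" else 0 for v in variants])

    columns: list[FeatureColumn] = []
    gc_vals = np.zeros(n)
    gc_missing = np.zeros(n, dtype=bool)
    for i, v in enumerate(variants):
        g = gc_content(ref, v, config.gc_halfwidth)
        if g is None:
            gc_missing[i] = True
        else:
            gc_vals[i] = g
    columns.append(
        FeatureColumn(
            name="GC",
            tags=frozenset({"sequence"}),
            values=gc_vals,
            missing_mask=gc_missing,
        )
    )

    if shape_table is not None:
        descriptors = list(shape_table.columns)
        vals = {d: np.zeros(n) for d in descriptors}
        miss = {d: np.zeros(n, dtype=bool) for d in descriptors}
        for i, v in enumerate(variants):
            deltas = shape_delta(ref, v, shape_table)
            for d in descriptors:
                if deltas[d] is None:
                    miss[d][i] = True
                else:
                    vals[d][i] = deltas[d]
        for d in descriptors:
            columns.append(
                FeatureColumn(
                    name=f"shape_{d}",
                    tags=frozenset({"sequence"}),
                    values=vals[d],
                    missing_mask=miss[d],
                )
            )

    for track, tags in tracks or []:
        vals = np.zeros(n)
        miss = np.zeros(n, dtype=bool)
        for i, v in enumerate(variants):
            value = track_lookup(track, v)
            if value is None:
                miss[i] = True
            else:
                vals[i] = value
        columns.append(
            FeatureColumn(
                name=track.name, tags=frozenset(tags), values=vals, missing_mask=miss
            )
        )

    if csq is not None:
        columns.extend(encode_consequences(csq, variants))

    matrix = FeatureMatrix(variants=variants, columns=columns, labels=labels)
    if config.composite_spec and csq is not None:
        matrix = FeatureMatrix(
            variants=matrix.variants,
            columns=matrix.columns + composite_features(matrix, config.composite_spec),
            labels=matrix.labels,
        )
    matrix = apply_tier(matrix, config.tier)
    return impute_missing(matrix)
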