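"""Synthetic species bundles with known ground truth.

Generates everything the pipeline consumes — a reference genome, an
ancestor evolved under known window-local CpG-stratified rates, numeric
and interval annotation tracks with planted class signal, a consequence
table with known region proportions, and a complete 5-mer shape table —
so every stage is testable without external data.

Evolution runs forward in time: the generated template sequence is the
ancestor, and substitutions drawn from the window-local CpG-stratified
rate table produce the derived reference. Because rates are later
estimated in exactly this direction (ancestral base and context ->
current base), the spec's rate table is the generating distribution and
re-estimation is unbiased up to sampling noise and the small loss from
the minimum-spacing rule. Coordinates are shared trivially: only
substitutions are applied, so ancestor and reference have equal lengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BASES,
    DERIVED,
    UNKNOWN_CODE,
    AncestorAlignment,
    GenomeSequence,
    SpeciesCaddError,
    Track,
    Variant,
    decode,
)
from .io_formats import ALL_5MERS
from .mutmodel import cpg_context_mask

_TRANSITION = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T

SHAPE_DESCRIPTORS = ("MGW", "Roll", "ProT")


@dataclass
class FixtureSpec:
    """Study conditions for a synthetic species.

    Substitution rates emulate a mouse-like ancestor/reference divergence:
    about 1% of sites differ, transitions ~4x transversions, CpG sites
    ~10x hypermutable. GC fraction defaults to the mouse-like 0.42.
    """

    genome_length: int = 200_000
    n_contigs: int = 2
    gc_fraction: float = 0.42
    transition_rate: float = 0.006
    transversion_rate: float = 0.0015
    cpg_multiplier: float = 10.0
    window_size: int = 100_000
    window_factors: tuple[float, ...] = (1.0,)
    unknown_fraction: float = 0.02
    unknown_run_length: int = 50
    n_informative_features: int = 3
    n_noise_features: int = 17
    effect_size: float = 2.0
    noise_sd: float = 1.0
    frac_transcribed: float = 0.5
    frac_translated: float = 0.3
    frac_missense: float = 0.5
    missense_enrichment: float = 1.5
    coding_effect_multiplier: float = 1.5
    noncoding_effect_multiplier: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_fraction < 1.0:
            raise SpeciesCaddError("gc_fraction must be in (0, 1)")
        for frac in (self.frac_transcribed, self.frac_translated, self.frac_missense,
                     self.unknown_fraction):
            if not 0.0 <= frac <= 1.0:
                raise SpeciesCaddError("fractions must lie in [0, 1]")
        if self.frac_translated > self.frac_transcribed:
            raise SpeciesCaddError("frac_translated cannot exceed frac_transcribed")
        max_factor = max(self.window_factors) if self.window_factors else 1.0
        worst = max(self.transition_rate, self.transversion_rate) * self.cpg_multiplier * max_factor
        if worst > 0.1:
            raise SpeciesCaddError(
                f"per-substitution rate {worst:.3g} exceeds 0.1; dense substitution "
                "would violate the minimum-spacing assumption"
            )

    def base_probs(self) -> np.ndarray:
        gc = self.gc_fraction
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def rate_tables(self) -> np.ndarray:
        """(2, 4, 4) generating rates, axis 0 = (CpG, nonCpG)."""
        non = np.zeros((4, 4))
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                non[a, b] = (
                    self.transition_rate if (a, b) in _TRANSITION else self.transversion_rate
                )
        return np.stack([non * self.cpg_multiplier, non])


def generate_genome(spec: FixtureSpec) -> GenomeSequence:
    """IID reference genome with P(G or C) = gc_fraction, split over contigs."""
    rng = np.random.default_rng(spec.seed)
    probs = spec.base_probs()
    per_contig = spec.genome_length // spec.n_contigs
    lengths = [per_contig] * spec.n_contigs
    lengths[-1] += spec.genome_length - per_contig * spec.n_contigs
    contigs = {}
    for i, n in enumerate(lengths):
        codes = rng.choice(4, size=n, p=probs).astype(np.int8)
        contigs[f"chr{i + 1}"] = decode(codes)
    return GenomeSequence(contigs)


def _thin_adjacent(mutated: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Enforce minimum spacing 2 by keeping alternate members of adjacent runs.

    Within each run of consecutive substituted positions every second
    member is kept, starting at a random offset so neither member of a
    pair is preferred (the common adjacent pair is the C and G of a CpG
    dinucleotide, and a deterministic choice would bias their realized
    rates asymmetrically).
    """
    keep = mutated.copy()
    idx = np.flatnonzero(mutated)
    if idx.size == 0:
        return keep
    run_start = np.flatnonzero(np.diff(idx, prepend=idx[0] - 2) > 1)
    boundaries = np.append(run_start, idx.size)
    for k in range(len(run_start)):
        run = idx[boundaries[k] : boundaries[k + 1]]
        if len(run) == 1:
            continue
        off = int(rng.integers(0, 2))
        keep[run] = False
        keep[run[off::2]] = True
    return keep


def evolve_ancestor(
    genome: GenomeSequence, spec: FixtureSpec
) -> tuple[GenomeSequence, AncestorAlignment, list[Variant]]:
    """Evolve a reference from the ancestral template; return the planted truth.

    The input genome is the ancestral template; each site substitutes to
    base b with probability rate[context][a -> b] from the spec's
    window-local, CpG-multiplied table (context from the ancestor, where
    CpG status is well defined). Adjacent substitutions are thinned to
    minimum spacing 2, and unknown-ancestor runs of 'N' are overlaid.
    Returns (reference, ancestor, planted derived variants); the planted
    set is exactly what derived-variant calling should recover.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rates = spec.rate_tables()  # (2, 4, 4)
    total_away = rates.sum(axis=2)  # (2, 4)
    ref_contigs: dict[str, str] = {}
    anc_contigs: dict[str, str] = {}
    planted: list[Variant] = []
    for contig in genome.names():
        s = genome.codes(contig).copy()  # ancestral states
        n = len(s)
        w = (np.arange(n) // spec.window_size) % max(len(spec.window_factors), 1)
        factor = np.asarray(spec.window_factors)[w] if spec.window_factors else np.ones(n)
        ctx = np.where(cpg_context_mask(s), 0, 1)
        p_mut = total_away[ctx, s] * factor
        if float(p_mut.max(initial=0.0)) > 1.0 / 3.0:
            raise SpeciesCaddError(
                "requested substitution density is incompatible with minimum spacing 2"
            )
        mutated = rng.random(n) < p_mut
        mutated = _thin_adjacent(mutated, rng)
        sites = np.flatnonzero(mutated)

        rows = rates[ctx[sites], s[sites], :] * factor[sites, None]
        cum = np.cumsum(rows / rows.sum(axis=1, keepdims=True), axis=1)
        u = rng.random(len(sites))
        alt = np.minimum((u[:, None] > cum).sum(axis=1), 3).astype(np.int8)

        ref = s.copy()
        ref[sites] = alt
        anc = s.copy()
        if spec.unknown_fraction > 0:
            run = max(1, spec.unknown_run_length)
            n_runs = int(round(spec.unknown_fraction * n / run))
            starts = rng.integers(0, max(1, n - run), size=n_runs)
            for st in starts.tolist():
                anc[st : st + run] = UNKNOWN_CODE

        for pos in np.flatnonzero((anc != ref) & (anc != UNKNOWN_CODE)).tolist():
            planted.append(
                Variant(
                    contig=contig,
                    pos=pos,
                    ref_allele=BASES[ref[pos]],
                    alt_allele=BASES[anc[pos]],
                    label=DERIVED,
                )
            )
        ref_contigs[contig] = decode(ref)
        anc_contigs[contig] = decode(anc)
    return GenomeSequence(ref_contigs), AncestorAlignment(anc_contigs), planted


@dataclass
class FeatureBundle:
    """Synthetic annotation inputs plus the generating truth."""

    tracks: list[tuple[Track, frozenset]]
    csq: pd.DataFrame
    shape_table: pd.DataFrame
    truth: dict


def _region_multiplier(spec: FixtureSpec, transcribed: bool, translated: bool) -> float:
    if translated:
        return spec.coding_effect_multiplier
    if not transcribed:
        return spec.noncoding_effect_multiplier
    return 1.0


def generate_feature_bundle(
    variants: list[Variant], labels: np.ndarray, spec: FixtureSpec
) -> FeatureBundle:
    """Tracks, consequences and shape table with planted class signal.

    Informative tracks are class-conditional Gaussians (simulated shifted
    by the effect size); the shift is scaled up in translated regions and
    down in untranscribed ones, and simulated variants are enriched for
    missense among translated sites, so coding subsets are the more
    separable — the gradient real deleteriousness models show. Noise
    tracks are class-independent. Consequence draws match the region
    layout fractions in expectation.
    """
    rng = np.random.default_rng(spec.seed + 2)
    labels = np.asarray(labels)
    n = len(variants)
    if len(labels) != n:
        raise SpeciesCaddError("labels length mismatch")

    # --- consequence assignment -------------------------------------
    ft, fv = spec.frac_transcribed, spec.frac_translated
    m = spec.frac_missense
    e = spec.missense_enrichment
    m_derived = min(1.0, 2.0 * m / (1.0 + e))
    m_by_label = {0: m_derived, 1: min(1.0, e * m_derived)}
    rows = []
    multipliers = np.ones(n)
    u_region = rng.random(n)
    u_kind = rng.random(n)
    u_sub = rng.random(n)
    for i, v in enumerate(variants):
        if u_region[i] < 1.0 - ft:
            consequence, transcribed, translated = "intergenic", False, False
        elif u_region[i] < 1.0 - fv:
            transcribed, translated = True, False
            if u_kind[i] < 0.7:
                consequence = "intron"
            elif u_kind[i] < 0.85:
                consequence = "non_coding_exon"
            else:
                consequence = "UTR"
        else:
            transcribed = translated = True
            m_lab = m_by_label[int(labels[i])]
            if u_kind[i] < m_lab:
                consequence = "missense"
            elif u_sub[i] < 0.9:
                consequence = "synonymous"
            else:
                consequence = "stop_gained"
        multipliers[i] = _region_multiplier(spec, transcribed, translated)
        rows.append(
            {
                "contig": v.contig,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "consequence": consequence,
                "transcribed": transcribed,
                "translated": translated,
            }
        )
    csq = pd.DataFrame(rows)

    # --- numeric tracks ----------------------------------------------
    tracks: list[tuple[Track, frozenset]] = []
    informative_names = []
    shift = labels * spec.effect_size * multipliers
    for j in range(spec.n_informative_features):
        name = f"cons_signal_{j}"
        informative_names.append(name)
        values = rng.normal(0.0, spec.noise_sd, size=n) + shift
        records = [
            (v.contig, v.pos, v.pos + 1, float(values[i])) for i, v in enumerate(variants)
        ]
        tracks.append((Track.per_base(name, records), frozenset({"conservation"})))
    noise_tags = [
        frozenset({"epigenetic"}),
        frozenset({"species_specific"}),
        frozenset({"conservation"}),
    ]
    for j in range(spec.n_noise_features):
        name = f"noise_{j}"
        values = rng.normal(0.0, 1.0, size=n)
        records = [
            (v.contig, v.pos, v.pos + 1, float(values[i])) for i, v in enumerate(variants)
        ]
        tracks.append((Track.per_base(name, records), noise_tags[j % len(noise_tags)]))

    # one interval track: random peaks, class-independent
    by_contig: dict[str, int] = {}
    for v in variants:
        by_contig[v.contig] = max(by_contig.get(v.contig, 0), v.pos + 1)
    peak_records = []
    for contig, length in sorted(by_contig.items()):
        n_peaks = max(1, length // 5000)
        starts = np.sort(rng.integers(0, max(1, length), size=n_peaks))
        for s in starts.tolist():
            peak_records.append((contig, s, s + rng.integers(200, 1000)))
    tracks.append((Track.intervals("peaks", peak_records), frozenset({"epigenetic"})))

    # --- shape table ---------------------------------------------------
    shape = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(ALL_5MERS), len(SHAPE_DESCRIPTORS))),
        index=pd.Index(ALL_5MERS, name="kmer"),
        columns=list(SHAPE_DESCRIPTORS),
    )

    truth = {
        "informative_features": informative_names,
        "effect_size": spec.effect_size,
        "noise_sd": spec.noise_sd,
        "region_multipliers": {
            "translated": spec.coding_effect_multiplier,
            "transcribed_untranslated": 1.0,
            "untranscribed": spec.noncoding_effect_multiplier,
        },
        "missense_prob_by_label": {str(k): v for k, v in m_by_label.items()},
        "region_fractions": {
            "untranscribed": 1.0 - ft,
            "transcribed": ft,
            "translated": fv,
        },
    }
    return FeatureBundle(tracks=tracks, csq=csq, shape_table=shape, truth=truth)


def write_bundle(
    outdir: str | Path,
    genome: GenomeSequence,
    ancestor: AncestorAlignment,
    bundle: FeatureBundle | None = None,
) -> None:
    """Write a fixture bundle to disk in the pipeline's input formats."""
    from . import io_formats as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(genome, outdir / "ref.fa")
    io.write_ancestor_fasta(ancestor, outdir / "anc.fa")
    if bundle is None:
        return
    track_dir = outdir / "tracks"
    peak_dir = outdir / "peaks"
    track_dir.mkdir(exist_ok=True)
    peak_dir.mkdir(exist_ok=True)
    manifest = []
    for track, tags in bundle.tracks:
        if track.kind == "per_base_score":
            path = track_dir / f"{track.name}.bedgraph"
            io.write_bedgraph(track, path)
        else:
            path = peak_dir / f"{track.name}.bed"
            io.write_bed(track, path)
        manifest.append(
            {
                "name": track.name,
                "path": str(path.relative_to(outdir)),
                "kind": track.kind,
                "tags": sorted(tags),
            }
        )
    io.write_consequences(bundle.csq, outdir / "csq.tsv")
    io.write_shape_table(bundle.shape_table, outdir / "shape.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    import yaml

    with open(outdir / "tracks.yaml", "w") as fh:
        yaml.safe_dump({"tracks": manifest}, fh, sort_keys=False)
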