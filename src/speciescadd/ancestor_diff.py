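"""Derived-variant calling from a reference/ancestor pair.

A derived variant is a position where the current reference differs from
the inferred ancestral state: the reference carries the derived allele,
which — having survived purifying selection — makes these sites the
proxy-benign training class. Sites immediately adjacent to another
mismatch are excluded to avoid multi-nucleotide event artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    BASES,
    DERIVED,
    UNKNOWN_CODE,
    AncestorAlignment,
    GenomeSequence,
    SpeciesCaddError,
    Variant,
)


def call_derived(ref: GenomeSequence, anc: AncestorAlignment) -> list[Variant]:
    """Call derived SNVs: reference != known ancestral base, no mismatch neighbor.

    The adjacency exclusion is run-based and evaluated against the full
    pre-filter mismatch set: every mismatch with a mismatch at distance 1 on
    the same contig is dropped (both members of any adjacent cluster).
    Unknown ancestral states ('N'/'-') yield nothing and never trigger the
    exclusion. REF is the reference base; ALT stores the ancestral state.
    """
    anc.validate_against(ref)
    variants: list[Variant] = []
    for contig in ref.names():
        r = ref.codes(contig)
        a = anc.codes(contig)
        known = (r != UNKNOWN_CODE) & (a != UNKNOWN_CODE)
        mismatch = known & (r != a)
        has_neighbor = np.zeros_like(mismatch)
        has_neighbor[1:] |= mismatch[:-1]
        has_neighbor[:-1] |= mismatch[1:]
        keep = np.flatnonzero(mismatch & ~has_neighbor)
        for pos in keep.tolist():
            variants.append(
                Variant(
                    contig=contig,
                    pos=pos,
                    ref_allele=BASES[r[pos]],
                    alt_allele=BASES[a[pos]],
                    label=DERIVED,
                )
            )
    return variants


def mismatch_density(
    ref: GenomeSequence, anc: AncestorAlignment, window: int
) -> pd.DataFrame:
    """Per-window QC counts of mismatches and unknown-ancestor positions.

    Windows are non-overlapping ``[i*window, (i+1)*window)`` per contig.
    Returns a DataFrame with columns contig, window_index, start, end,
    n_mismatch, n_unknown.
    """
    if window < 1:
        raise SpeciesCaddError(f"window must be >= 1, got {window}")
    anc.validate_against(ref)
    rows = []
    for contig in ref.names():
        r = ref.codes(contig)
        a = anc.codes(contig)
        unknown = a == UNKNOWN_CODE
        mismatch = (~unknown) & (r != UNKNOWN_CODE) & (r != a)
        n = len(r)
        n_windows = (n + window - 1) // window
        widx = np.arange(n) // window
        mm = np.bincount(widx, weights=mismatch, minlength=n_windows).astype(int)
        unk = np.bincount(widx, weights=unknown, minlength=n_windows).astype(int)
        for i in range(n_windows):
            rows.append(
                {
                    "contig": contig,
                    "window_index": i,
                    "start": i * window,
                    "end": min((i + 1) * window, n),
                    "n_mismatch": int(mm[i]),
                    "n_unknown": int(unk[i]),
                }
            )
    return pd.DataFrame(rows)
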