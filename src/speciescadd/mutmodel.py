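"""Empirical substitution model and neutral SNV simulator.

Rates are estimated from the ancestor/reference pair, stratified by
100 kb window and by CpG context of the ancestral base (CpG dinucleotides
hypermutate via deamination, so they get their own 4x4 table). Simulated
SNVs drawn from this model form the proxy-deleterious training class:
they have experienced no purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BASES,
    BASE_INDEX,
    SIMULATED,
    UNKNOWN_CODE,
    AncestorAlignment,
    GenomeSequence,
    SpeciesCaddError,
    Variant,
)

CPG = "CpG"
NONCPG = "nonCpG"
CONTEXTS = (CPG, NONCPG)  # axis order: 0 = CpG, 1 = nonCpG

_C = BASE_INDEX["C"]
_G = BASE_INDEX["G"]


@dataclass
class MutationModelConfig:
    window_size: int = 100_000
    min_window_opportunities: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise SpeciesCaddError(f"window_size must be >= 1, got {self.window_size}")
        if self.min_window_opportunities < 0:
            raise SpeciesCaddError("min_window_opportunities must be >= 0")


def cpg_context_mask(codes: np.ndarray) -> np.ndarray:
    """Strand-symmetric CpG mask: C followed by G, or G preceded by C.

    Evaluated on the sequence's own bases; False at contig edges and
    wherever the base or its needed neighbor is unknown.
    """
    mask = np.zeros(codes.shape, dtype=bool)
    if len(codes) < 2:
        return mask
    mask[:-1] |= (codes[:-1] == _C) & (codes[1:] == _G)
    mask[1:] |= (codes[1:] == _G) & (codes[:-1] == _C)
    return mask


def is_cpg(anc_contig: str, pos: int) -> bool:
    """True iff the ancestral base at pos sits in a CpG dinucleotide."""
    if not 0 <= pos < len(anc_contig):
        raise SpeciesCaddError(f"position {pos} outside contig of length {len(anc_contig)}")
    base = anc_contig[pos]
    if base == "C":
        return pos + 1 < len(anc_contig) and anc_contig[pos + 1] == "G"
    if base == "G":
        return pos - 1 >= 0 and anc_contig[pos - 1] == "C"
    return False


class MutationModel:
    """Window-local, CpG-context-stratified substitution rates.

    Per contig, ``counts[w, c, a, b]`` holds observed a->b substitutions
    (ancestral base a, reference base b) and ``opps[w, c, a]`` the aligned
    positions with known ancestral base a, in window w and context c
    (axis order CpG, nonCpG). Effective rates fall back to the
    opportunity-weighted global pool when a window has fewer than
    ``min_window_opportunities`` opportunities for a base, and are zero
    when it has none at all.
    """

    def __init__(
        self,
        window_size: int,
        min_window_opportunities: int,
        counts: dict[str, np.ndarray],
        opps: dict[str, np.ndarray],
        contig_lengths: dict[str, int],
    ) -> None:
        self.window_size = window_size
        self.min_window_opportunities = min_window_opportunities
        self.counts = counts
        self.opps = opps
        self.contig_lengths = contig_lengths
        self._eff: dict[str, np.ndarray] = {}

    # -- global (pooled) tables ---------------------------------------

    @property
    def global_counts(self) -> np.ndarray:
        out = np.zeros((2, 4, 4), dtype=np.int64)
        for c in self.counts.values():
            out += c.sum(axis=0)
        return out

    @property
    def global_opps(self) -> np.ndarray:
        out = np.zeros((2, 4), dtype=np.int64)
        for o in self.opps.values():
            out += o.sum(axis=0)
        return out

    def global_rates(self) -> np.ndarray:
        """Pooled (2, 4, 4) rate tables; zero rows where no opportunities."""
        counts = self.global_counts.astype(float)
        opps = self.global_opps.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = counts / opps[:, :, None]
        rates[~np.isfinite(rates)] = 0.0
        return rates

    # -- effective per-window tables ----------------------------------

    def n_windows(self, contig: str) -> int:
        return self.counts[contig].shape[0]

    def effective_rates(self, contig: str) -> np.ndarray:
        """(n_windows, 2, 4, 4) rate tables after the fallback rule."""
        if contig not in self._eff:
            counts = self.counts[contig].astype(float)
            opps = self.opps[contig].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                rates = counts / opps[:, :, :, None]
            rates[~np.isfinite(rates)] = 0.0
            glob = self.global_rates()
            sparse = (opps > 0) & (opps < self.min_window_opportunities)
            w_idx, c_idx, a_idx = np.nonzero(sparse)
            rates[w_idx, c_idx, a_idx, :] = glob[c_idx, a_idx, :]
            self._eff[contig] = rates
        return self._eff[contig]

    def rate_table(self, contig: str, window_index: int) -> dict[str, np.ndarray]:
        eff = self.effective_rates(contig)
        return {CPG: eff[window_index, 0], NONCPG: eff[window_index, 1]}

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "speciescadd-mutation-model-v1",
            "bases": BASES,
            "contexts": list(CONTEXTS),
            "window_size": self.window_size,
            "min_window_opportunities": self.min_window_opportunities,
            "contigs": {
                name: {
                    "length": self.contig_lengths[name],
                    "counts": self.counts[name].tolist(),
                    "opportunities": self.opps[name].tolist(),
                }
                for name in self.counts
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MutationModel":
        counts = {}
        opps = {}
        lengths = {}
        for name, entry in d["contigs"].items():
            counts[name] = np.array(entry["counts"], dtype=np.int64)
            opps[name] = np.array(entry["opportunities"], dtype=np.int64)
            lengths[name] = int(entry["length"])
        return cls(
            window_size=int(d["window_size"]),
            min_window_opportunities=int(d["min_window_opportunities"]),
            counts=counts,
            opps=opps,
            contig_lengths=lengths,
        )


def estimate_rates(
    ref: GenomeSequence,
    anc: AncestorAlignment,
    cfg: MutationModelConfig | None = None,
) -> MutationModel:
    """Estimate substitution rates from the ancestor/reference pair.

    rate[a->b] = (# aligned positions with known ancestral base a, in that
    window and CpG context, whose known reference base is b != a) /
    (# such positions regardless of the reference base).
    """
    cfg = cfg or MutationModelConfig()
    anc.validate_against(ref)
    counts: dict[str, np.ndarray] = {}
    opps: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    total_known = 0
    for contig in ref.names():
        r = ref.codes(contig)
        a = anc.codes(contig)
        n = len(r)
        n_windows = (n + cfg.window_size - 1) // cfg.window_size
        known = (r != UNKNOWN_CODE) & (a != UNKNOWN_CODE)
        total_known += int(known.sum())
        ctx = np.where(cpg_context_mask(a), 0, 1)  # 0 = CpG, 1 = nonCpG
        w = np.arange(n) // cfg.window_size

        opp_idx = ((w * 2 + ctx) * 4 + a)[known]
        opp_flat = np.bincount(opp_idx, minlength=n_windows * 8)
        opps[contig] = opp_flat.reshape(n_windows, 2, 4).astype(np.int64)

        sub = known & (r != a)
        sub_idx = (((w * 2 + ctx) * 4 + a) * 4 + r)[sub]
        cnt_flat = np.bincount(sub_idx, minlength=n_windows * 32)
        counts[contig] = cnt_flat.reshape(n_windows, 2, 4, 4).astype(np.int64)
        lengths[contig] = n
    if total_known == 0:
        raise SpeciesCaddError("empty alignment: no positions with known ancestral state")
    return MutationModel(
        window_size=cfg.window_size,
        min_window_opportunities=cfg.min_window_opportunities,
        counts=counts,
        opps=opps,
        contig_lengths=lengths,
    )


def simulate_variants(
    model: MutationModel,
    ref: GenomeSequence,
    anc: AncestorAlignment,
    n: int,
    exclude: dict[str, set[int]] | set | None = None,
    cfg: MutationModelConfig | None = None,
) -> list[Variant]:
    """Draw n proxy-deleterious SNVs from the substitution model.

    Eligible sites have a known ancestral base equal to the reference base
    (sites already carrying a derived allele are not resimulated) and are
    not in ``exclude`` (a mapping contig -> set of positions). Positions
    are drawn without replacement with probability proportional to the
    site's total mutation rate; the alternative allele proportional to
    rate[a->b] within the site's window and context.
    """
    cfg = cfg or MutationModelConfig()
    anc.validate_against(ref)
    if n < 0:
        raise SpeciesCaddError(f"n must be >= 0, got {n}")
    if n == 0:
        return []
    exclude = exclude or {}
    if isinstance(exclude, set):  # single-contig convenience
        if len(ref.names()) != 1:
            raise SpeciesCaddError("set-valued exclude requires a single-contig genome")
        exclude = {ref.names()[0]: exclude}

    site_contig: list[np.ndarray] = []
    site_pos: list[np.ndarray] = []
    site_weight: list[np.ndarray] = []
    site_rates: list[np.ndarray] = []
    site_base: list[np.ndarray] = []
    for ci, contig in enumerate(ref.names()):
        r = ref.codes(contig)
        a = anc.codes(contig)
        eligible = (a != UNKNOWN_CODE) & (r != UNKNOWN_CODE) & (r == a)
        excl = exclude.get(contig)
        if excl:
            mask = np.zeros(len(r), dtype=bool)
            mask[np.fromiter(excl, dtype=np.int64)] = True
            eligible &= ~mask
        pos = np.flatnonzero(eligible)
        if pos.size == 0:
            continue
        ctx = np.where(cpg_context_mask(a), 0, 1)[pos]
        w = pos // model.window_size
        eff = model.effective_rates(contig)
        rates = eff[w, ctx, a[pos], :]  # (n_sites, 4)
        total = rates.sum(axis=1)
        site_contig.append(np.full(pos.size, ci, dtype=np.int32))
        site_pos.append(pos)
        site_weight.append(total)
        site_rates.append(rates)
        site_base.append(a[pos])

    if not site_pos:
        raise SpeciesCaddError(f"no eligible sites to simulate from (requested {n})")
    all_contig = np.concatenate(site_contig)
    all_pos = np.concatenate(site_pos)
    all_weight = np.concatenate(site_weight)
    all_rates = np.concatenate(site_rates)
    all_base = np.concatenate(site_base)
    positive = all_weight > 0
    n_avail = int(positive.sum())
    if n > n_avail:
        raise SpeciesCaddError(
            f"requested {n} simulated variants but only {n_avail} eligible sites "
            f"with positive rate (shortfall {n - n_avail})"
        )

    rng = np.random.default_rng(cfg.rng_seed)
    # Efraimidis-Spirakis keys: weighted sampling without replacement.
    u = rng.random(all_weight.shape)
    with np.errstate(divide="ignore"):
        keys = np.log(all_weight) - np.log(-np.log(u))
    keys[~positive] = -np.inf
    chosen = np.argpartition(keys, -n)[-n:]

    names = ref.names()
    # per-site alternative allele draw, proportional to rate[a->b]
    rows = all_rates[chosen]
    cum = np.cumsum(rows / rows.sum(axis=1, keepdims=True), axis=1)
    alt_u = rng.random(len(chosen))
    alt_code = np.minimum((alt_u[:, None] > cum).sum(axis=1), 3)
    variants = [
        Variant(
            contig=names[all_contig[site]],
            pos=int(all_pos[site]),
            ref_allele=BASES[all_base[site]],
            alt_allele=BASES[b],
            label=SIMULATED,
        )
        for site, b in zip(chosen.tolist(), alt_code.tolist())
    ]
    variants.sort(key=lambda v: (v.contig, v.pos))
    return variants


def build_training_set(
    derived: list[Variant],
    simulated: list[Variant],
    n_folds: int = 11,
    seed: int = 0,
) -> list[Variant]:
    """Equalize class sizes, shuffle, and assign stratified fold ids 0..n_folds-1.

    The larger class is downsampled uniformly at random; folds are dealt
    round-robin per class with a rotating offset so fold sizes differ by at
    most one and per-fold class counts differ by at most one. Fold
    ``n_folds - 1`` is the designated held-out test fold.
    """
    if n_folds < 2:
        raise SpeciesCaddError(f"n_folds must be >= 2, got {n_folds}")
    if not derived or not simulated:
        raise SpeciesCaddError("both variant classes must be non-empty")
    rng = np.random.default_rng(seed)
    m = min(len(derived), len(simulated))

    def sample(variants: list[Variant]) -> list[Variant]:
        if len(variants) == m:
            return list(variants)
        idx = rng.choice(len(variants), size=m, replace=False)
        return [variants[i] for i in np.sort(idx)]

    out: list[Variant] = []
    offset = 0
    for group in (sample(derived), sample(simulated)):
        order = rng.permutation(m)
        for i, j in enumerate(order.tolist()):
            out.append(group[j].with_fold((offset + i) % n_folds))
        offset += m % n_folds
    final = rng.permutation(len(out))
    return [out[i] for i in final.tolist()]
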