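import numpy as np
import pytest

from speciescadd import fixtures


@pytest.fixture(scope="session")
def small_species():
    """A 200 kb two-contig synthetic species with default study conditions."""
    spec = fixtures.FixtureSpec(genome_length=200_000, n_contigs=2, seed=11)
    template = fixtures.generate_genome(spec)
    ref, anc, planted = fixtures.evolve_ancestor(template, spec)
    return spec, ref, anc, planted


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pair(rng, length, mismatch_p=0.01, unknown_p=0.02):
    """Random reference/ancestor string pair with Ns, gaps and mismatches."""
    bases = np.array(list("ACGT"))
    ref_codes = rng.integers(0, 4, size=length)
    ref = bases[ref_codes].copy()
    anc = ref.copy()
    flip = rng.random(length) < mismatch_p
    anc[flip] = bases[(ref_codes[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4]
    anc[rng.random(length) < unknown_p] = "N"
    anc[rng.random(length) < unknown_p / 2] = "-"
    ref[rng.random(length) < unknown_p / 2] = "N"
    return "".join(ref), "".join(anc)


def brute_force_derived(ref: str, anc: str):
    """Independent oracle: naive scan plus adjacency filtering on mismatches."""
    acgt = set("ACGT")
    mismatches = [
        i
        for i in range(len(ref))
        if ref[i] in acgt and anc[i] in acgt and ref[i] != anc[i]
    ]
    mm = set(mismatches)
    return [
        (i, ref[i], anc[i])
        for i in mismatches
        if (i - 1) not in mm and (i + 1) not in mm
    ]
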