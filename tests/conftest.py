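import numpy as np
import pytest

from mtfounder.haplogroups import load_haplotree, load_macrogroup_table
from mtfounder.reference import default_hotspots, load_reference
from mtfounder.variants import SUBSTITUTION, Variant, VariantProfile


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def tree():
    return load_haplotree()


@pytest.fixture(scope="session")
def hotspots():
    return default_hotspots()


@pytest.fixture(scope="session")
def macro_table():
    return load_macrogroup_table()


def make_profile(sample_id, states, population="study", region="",
                 missing=(), reference=None):
    """Build a profile from (position, alt) pairs; ref alleles filled in
    from the reference genome when given."""
    variants = []
    for pos, alt in states:
        ref = reference.base_at(pos) if reference is not None else None
        variants.append(Variant(pos, ref, alt, SUBSTITUTION))
    return VariantProfile(sample_id=sample_id, variants=tuple(variants),
                          population=population, region=region,
                          missing_positions=frozenset(missing))


def exact_steiner_length(vectors):
    """Exact minimum Steiner tree length of binary vectors under the
    Hamming metric, allowing ANY latent binary vector as a Steiner
    point: the Dreyfus-Wagner dynamic program over the full k-cube.
    Independent oracle for maximum-parsimony lengths (the package never
    searches the whole hypercube)."""
    k = len(vectors[0])
    n = 1 << k
    terms = sorted({sum(b << i for i, b in enumerate(v)) for v in vectors})
    if len(terms) < 2:
        return 0
    D = np.array([[bin(x ^ y).count("1") for y in range(n)]
                  for x in range(n)], dtype=np.int64)
    t0, rest = terms[0], terms[1:]
    t = len(rest)
    INF = 10 ** 9
    dp = np.full((1 << t, n), INF, dtype=np.int64)
    for i, term in enumerate(rest):
        dp[1 << i] = D[term]
    for S in range(1, 1 << t):
        if S & (S - 1) == 0:
            continue
        best = np.full(n, INF, dtype=np.int64)
        S1 = (S - 1) & S
        while S1:
            S2 = S ^ S1
            if S1 <= S2:
                np.minimum(best, dp[S1] + dp[S2], out=best)
            S1 = (S1 - 1) & S
        dp[S] = (best[None, :] + D).min(axis=1)
    return int(dp[(1 << t) - 1][t0])


def mutate_sequence(reference, changes):
    """Apply {position: alt_base} substitutions to the reference sequence."""
    seq = list(reference.sequence)
    for pos, alt in changes.items():
        seq[pos - 1] = alt
    return "".join(seq)
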