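"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: clustering is done with
networkx over all-pairs Hamming comparisons, and consensus calling is a
plain per-column tally.
"""

import itertools
from collections import Counter

import networkx as nx


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def oracle_consensus(alleles, weights) -> str:
    """Depth-weighted per-column majority, ties to the alphabetically first base."""
    out = []
    for column in zip(*alleles):
        tally = {}
        for base, w in zip(column, weights):
            tally[base] = tally.get(base, 0) + w
        out.append(min(tally, key=lambda b: (-tally[b], b)))
    return "".join(out)


def oracle_stacks(reads, m=3, M=4, N=10, max_haplotypes=2):
    """All-pairs Hamming clustering of exact-duplicate read groups.

    Returns a set of (alleles frozenset, depth, consensus) triples: groups
    with >= m copies are primaries, primaries within M merge transitively,
    components with more than ``max_haplotypes`` primaries are discarded,
    and each low-depth group adds its count to the unique locus whose
    consensus is within N mismatches (ambiguous groups are dropped).
    """
    counts = Counter(reads)
    primaries = [s for s in counts if counts[s] >= m]
    graph = nx.Graph()
    graph.add_nodes_from(primaries)
    for a, b in itertools.combinations(primaries, 2):
        if hamming(a, b) <= M:
            graph.add_edge(a, b)
    loci = []
    for component in nx.connected_components(graph):
        if len(component) > max_haplotypes:
            continue
        alleles = sorted(component)
        depth = sum(counts[a] for a in alleles)
        consensus = oracle_consensus(alleles, [counts[a] for a in alleles])
        loci.append({"alleles": frozenset(alleles), "depth": depth, "consensus": consensus})
    for seq in counts:
        if counts[seq] >= m:
            continue
        homes = [l for l in loci if hamming(seq, l["consensus"]) <= N]
        if len(homes) == 1:
            homes[0]["depth"] += counts[seq]
    return {(l["alleles"], l["depth"], l["consensus"]) for l in loci}


def random_clustery_reads(rng, n_reads, length=16, n_templates=5):
    """Read sets with realistic collision structure: a few templates, copied
    with small perturbations over a two-letter alphabet so Hamming
    neighbourhoods actually overlap."""
    templates = ["".join(rng.choice(["A", "C"], size=length)) for _ in range(n_templates)]
    reads = []
    while len(reads) < n_reads:
        t = list(templates[rng.integers(0, n_templates)])
        for _ in range(int(rng.integers(0, 4))):
            pos = int(rng.integers(0, length))
            t[pos] = "A" if t[pos] == "C" else "C"
        reads.extend(["".join(t)] * int(rng.integers(1, 6)))
    return reads[:n_reads]
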