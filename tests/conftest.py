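import random

import pytest

from cobra_rejoin.contig_index import Contig, ContigSet, JoinParams
from cobra_rejoin.evidence import LinkageEvidence

BASES = "ACGT"


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(BASES, k=n))


def make_chain(rng: random.Random, n_contigs: int, L: int, core_len: int = 300):
    """A genome cut into n contigs whose flanks share exact L-length ends.

    Returns (genome, ContigSet, ids in order). Junction L-mers are genuinely
    part of the genome, so joined output must equal the genome exactly.
    """
    glen = n_contigs * core_len + L
    genome = random_seq(rng, glen)
    pts = [i * core_len for i in range(1, n_contigs)]
    bounds = [0] + pts + [glen]
    contigs = ContigSet()
    ids = []
    for j in range(n_contigs):
        start = bounds[j]
        end = min(bounds[j + 1] + L, glen) if j < n_contigs - 1 else bounds[j + 1]
        cid = f"g_c{j}"
        contigs.add(Contig(cid, genome[start:end], coverage=20.0))
        ids.append(cid)
    return genome, contigs, ids


def full_linkage(contigs: ContigSet, pairs=None, count: int = 5) -> LinkageEvidence:
    """Linkage evidence asserting the given adjacent id pairs (or all ordered pairs)."""
    link = LinkageEvidence()
    if pairs is None:
        ids = contigs.ids()
        pairs = list(zip(ids, ids[1:]))
    for a, b in pairs:
        link.add(a, b, count)
    return link


@pytest.fixture
def rng():
    return random.Random(42)


@pytest.fixture
def params():
    return JoinParams(assembler="metaspades", maxk=99, mink=21)
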