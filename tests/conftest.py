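import numpy as np
import pytest

from otugrad.core_io import Lineage, N_RANKS, OtuTable, RefEntry, ReferenceDB


def make_read(seq, quals=None, rid="r1", orientation="forward"):
    from otugrad.core_io import QualRead

    if quals is None:
        quals = np.full(len(seq), 35, dtype=np.int16)
    return QualRead(rid, seq, np.asarray(quals, dtype=np.int16), orientation)


def lineage_from_names(*names):
    """Build a Lineage from up to 8 rank names."""
    names = tuple(names)
    return Lineage(names + ("",) * (N_RANKS - len(names)), len(names))


def random_seq(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(seq, positions, rng):
    """Substitute the given positions with a different base."""
    chars = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != chars[p]]
        chars[p] = choices[rng.integers(3)]
    return "".join(chars)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_refdb():
    """Six references: 2 kingdoms, nested down to species."""
    rng = np.random.default_rng(7)
    entries = {}
    for k in range(2):
        base = random_seq(rng, 600)
        for g in range(2):
            gseq = mutate(base, rng.choice(600, 30, replace=False), rng)
            for s in range(2):
                if k == 1 and g == 1 and s == 1:
                    continue  # 7 entries, unbalanced on purpose
                seq = mutate(gseq, rng.choice(600, 15, replace=False), rng)
                name = f"sp{k}{g}{s}"
                lin = Lineage(
                    (
                        f"K{k}",
                        f"SG{k}",
                        f"DV{k}",
                        f"CL{k}{g}",
                        f"OR{k}{g}",
                        f"FA{k}{g}",
                        f"GE{k}{g}",
                        name,
                    ),
                    N_RANKS,
                )
                entries[name] = RefEntry(seq, lin)
    return ReferenceDB(entries)


def small_table(counts, otu_lineages=None, marker="16S", sample_ids=None):
    counts = np.asarray(counts)
    otu_ids = [f"OTU_{i + 1}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(counts.shape[1])]
    centroids = {o: "ACGT" for o in otu_ids}
    lineages = dict(zip(otu_ids, otu_lineages)) if otu_lineages else {}
    return OtuTable(otu_ids, sample_ids, counts, centroids, lineages, marker)
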