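import numpy as np
import pytest

from otugrad.consensus_taxonomy import (
    Assignment,
    CutoffScheme,
    Hit,
    HitSet,
    ManualOverride,
    align_query_to_refs,
    apply_manual_overrides,
    assign_paired,
    assign_single,
    read_hits_tsv,
    write_hits_tsv,
)
from otugrad.core_io import Lineage, N_RANKS, RefEntry, ReferenceDB, reverse_complement
from tests._oracles import brute_force_assign, make_lineage
from tests.conftest import random_seq


def hitset(qid, entries):
    return HitSet(qid, [Hit(r, i, 300, b) for r, i, b in entries])


def random_refdb(rng, n_refs):
    """References with random tree-structured lineages (sequences unused)."""
    entries = {}
    for i in range(n_refs):
        k = int(rng.integers(1, 3))
        g = int(rng.integers(1, 4))
        names = (
            f"K{k}",
            f"SG{k}",
            f"DV{k}{int(rng.integers(1, 3))}",
            f"CL{k}{g}",
            f"OR{k}{g}",
            f"FA{k}{g}",
            f"GE{k}{g}{int(rng.integers(1, 3))}",
            f"SP{i}",
        )
        entries[f"ref{i}"] = RefEntry("ACGT", Lineage(names, N_RANKS))
    return ReferenceDB(entries)


class TestCutoffScheme:
    def test_default_levels(self):
        s = CutoffScheme.default()
        assert s.cutoffs == (0.90,) * 6 + (0.97, 0.99)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            CutoffScheme((0.9,) * 6 + (0.99, 0.97))

    def test_allowed_rank_inclusive(self):
        s = CutoffScheme.default()
        assert s.allowed_rank(0.99) == 8
        assert s.allowed_rank(0.975) == 7
        assert s.allowed_rank(0.90) == 6
        assert s.allowed_rank(0.89) == 0


class TestAssignPaired:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.refdb = random_refdb(rng, 6)
        self.cutoffs = CutoffScheme.default()

    def test_single_shared_ref_species_level(self):
        fwd = hitset("q", [("ref0", 0.995, 200.0)])
        rev = hitset("q", [("ref0", 0.992, 190.0)])
        a = assign_paired(fwd, rev, self.refdb, self.cutoffs)
        assert a.depth == 8
        assert a.lineage == self.refdb.lineage("ref0")
        assert a.reason is None

    def test_single_shared_ref_truncated_at_genus(self):
        fwd = hitset("q", [("ref0", 0.975, 200.0)])
        rev = hitset("q", [("ref0", 0.99, 190.0)])
        a = assign_paired(fwd, rev, self.refdb, self.cutoffs)
        assert a.depth == 7  # min identity 0.975: genus yes, species no
        assert a.reason == "identity_cutoff"

    def test_two_refs_same_genus_conflict_at_species(self):
        entries = {
            "r1": RefEntry("A", make_lineage(*"ABCDEFG", "sp1")),
            "r2": RefEntry("A", make_lineage(*"ABCDEFG", "sp2")),
        }
        db = ReferenceDB(
            {k: RefEntry(v.seq, Lineage(v.lineage.ranks, 8)) for k, v in entries.items()}
        )
        fwd = hitset("q", [("r1", 0.995, 100.0), ("r2", 0.995, 97.5)])
        rev = hitset("q", [("r1", 0.995, 100.0), ("r2", 0.995, 97.5)])
        a = assign_paired(fwd, rev, db, self.cutoffs)
        # both retained (195 >= 0.95 * 200), agree to genus only
        assert a.depth == 7
        assert a.reason == "consensus_conflict"
        assert sorted(a.evidence) == ["r1", "r2"]

    def test_bitscore_filter_drops_weak_candidate(self):
        db = ReferenceDB(
            {
                "r1": RefEntry("A", Lineage(make_lineage(*"ABCDEFG", "sp1").ranks, 8)),
                "r2": RefEntry("A", Lineage(make_lineage(*"ABCDEFG", "sp2").ranks, 8)),
            }
        )
        fwd = hitset("q", [("r1", 0.995, 120.0), ("r2", 0.995, 80.0)])
        rev = hitset("q", [("r1", 0.995, 120.0), ("r2", 0.995, 80.0)])
        a = assign_paired(fwd, rev, db, self.cutoffs)
        assert a.evidence == ["r1"]
        assert a.depth == 8

    def test_no_shared_candidate_unclassified(self):
        fwd = hitset("q", [("ref0", 0.99, 100.0)])
        rev = hitset("q", [("ref1", 0.99, 100.0)])
        a = assign_paired(fwd, rev, self.refdb, self.cutoffs)
        assert a.depth == 0 and a.reason == "no_hits"

    def test_below_kingdom_cutoff_unclassified(self):
        fwd = hitset("q", [("ref0", 0.85, 100.0)])
        rev = hitset("q", [("ref0", 0.99, 100.0)])
        a = assign_paired(fwd, rev, self.refdb, self.cutoffs)
        assert a.depth == 0 and a.reason == "identity_cutoff"

    def test_oracle_equivalence_random_instances(self):
        """100 random miniature references: implementation == enumerator."""
        rng = np.random.default_rng(42)
        identity_grid = np.array([0.85, 0.9, 0.93, 0.96, 0.97, 0.975, 0.99, 0.995, 1.0])
        for trial in range(100):
            refdb = random_refdb(rng, int(rng.integers(2, 21)))
            ids = refdb.ids()
            n_f = int(rng.integers(1, len(ids) + 1))
            n_r = int(rng.integers(1, len(ids) + 1))
            fwd_ids = [ids[i] for i in rng.choice(len(ids), n_f, replace=False)]
            rev_ids = [ids[i] for i in rng.choice(len(ids), n_r, replace=False)]
            fwd = {
                r: (float(rng.choice(identity_grid)), float(rng.uniform(50, 200)))
                for r in fwd_ids
            }
            rev = {
                r: (float(rng.choice(identity_grid)), float(rng.uniform(50, 200)))
                for r in rev_ids
            }
            fwd_hs = hitset("q", [(r, i, b) for r, (i, b) in fwd.items()])
            rev_hs = hitset("q", [(r, i, b) for r, (i, b) in rev.items()])
            got = assign_paired(fwd_hs, rev_hs, refdb, self.cutoffs)
            depth, ranks, retained = brute_force_assign(fwd, rev, refdb, self.cutoffs)
            assert got.depth == depth, f"trial {trial}"
            assert got.lineage.ranks == ranks, f"trial {trial}"
            if depth > 0:
                assert sorted(got.evidence) == retained, f"trial {trial}"

    def test_raising_subkingdom_cutoffs_never_deepens(self):
        """Stricter cutoffs at ranks 2-8 can only shallow assignments.

        (The kingdom cutoff is excluded on purpose: raising it can eject a
        *conflicting* candidate from the hit set entirely, which deepens
        the consensus — an inherent feature of consensus classifiers.)
        """
        rng = np.random.default_rng(3)
        base = CutoffScheme.default()
        for _ in range(50):
            refdb = random_refdb(rng, int(rng.integers(2, 10)))
            ids = refdb.ids()
            fwd = hitset(
                "q", [(r, float(rng.uniform(0.9, 1.0)), float(rng.uniform(50, 200))) for r in ids]
            )
            rev = hitset(
                "q", [(r, float(rng.uniform(0.9, 1.0)), float(rng.uniform(50, 200))) for r in ids]
            )
            a0 = assign_paired(fwd, rev, refdb, base)
            level = int(rng.integers(1, 8))
            raised = list(base.cutoffs)
            raised[level] = min(1.0, raised[level] + 0.02)
            for j in range(level + 1, 8):
                raised[j] = max(raised[j], raised[level])
            a1 = assign_paired(fwd, rev, refdb, CutoffScheme(tuple(raised)))
            assert a1.depth <= a0.depth


class TestAssignSingle:
    def test_unique_full_identity_hit(self):
        rng = np.random.default_rng(1)
        db = random_refdb(rng, 4)
        a = assign_single(hitset("q", [("ref2", 1.0, 300.0)]), db, CutoffScheme.default())
        assert a.depth == 8 and a.lineage == db.lineage("ref2")

    def test_no_hits(self):
        rng = np.random.default_rng(1)
        db = random_refdb(rng, 4)
        a = assign_single(HitSet("q", []), db, CutoffScheme.default())
        assert a.depth == 0 and a.reason == "no_hits"

    def test_total_conflict_unclassified(self):
        db = ReferenceDB(
            {
                "r1": RefEntry("A", Lineage(make_lineage(*"ABCDEFGH").ranks, 8)),
                "r2": RefEntry("A", Lineage(make_lineage(*"ZYXWVUTS").ranks, 8)),
            }
        )
        a = assign_single(
            hitset("q", [("r1", 0.99, 100.0), ("r2", 0.99, 100.0)]), db, CutoffScheme.default()
        )
        assert a.depth == 0


class TestAlignment:
    def test_exact_substring_hit(self, tiny_refdb):
        query = tiny_refdb.seq("sp000")[100:400]
        hs = align_query_to_refs(query, tiny_refdb, min_aln_len=250, query_id="q")
        hit = hs.by_ref()["sp000"]
        assert hit.identity == 1.0
        assert hit.aln_len == 300

    def test_short_alignment_dropped(self, tiny_refdb):
        query = tiny_refdb.seq("sp000")[100:340]  # 240 columns max
        hs = align_query_to_refs(query, tiny_refdb, min_aln_len=250, query_id="q")
        assert "sp000" not in hs.by_ref()

    def test_strand_symmetry(self, tiny_refdb):
        query = tiny_refdb.seq("sp000")[100:400]
        fwd = align_query_to_refs(query, tiny_refdb, 250).by_ref()["sp000"]
        rev = align_query_to_refs(reverse_complement(query), tiny_refdb, 250).by_ref()["sp000"]
        assert fwd.identity == rev.identity
        assert fwd.bitscore == rev.bitscore

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            align_query_to_refs("ACGT", ReferenceDB({}))

    def test_true_reference_recovers_full_lineage(self, tiny_refdb, rng):
        """Error-free split halves assign the true species lineage."""
        for name in tiny_refdb.ids():
            seq = tiny_refdb.seq(name)
            fwd, rev = seq[:280], seq[280:560]
            fwd_hs = align_query_to_refs(fwd, tiny_refdb, query_id=name)
            rev_hs = align_query_to_refs(rev, tiny_refdb, query_id=name)
            a = assign_paired(fwd_hs, rev_hs, tiny_refdb, otu_id=name)
            assert a.depth == 8
            assert a.lineage == tiny_refdb.lineage(name)

    def test_removing_true_ref_never_deepens(self, tiny_refdb):
        for name in ["sp000", "sp110"]:
            seq = tiny_refdb.seq(name)
            fwd, rev = seq[:280], seq[280:560]
            full = assign_paired(
                align_query_to_refs(fwd, tiny_refdb),
                align_query_to_refs(rev, tiny_refdb),
                tiny_refdb,
            )
            reduced = tiny_refdb.without([name])
            shallow = assign_paired(
                align_query_to_refs(fwd, reduced),
                align_query_to_refs(rev, reduced),
                reduced,
            )
            assert shallow.depth <= full.depth


class TestOverridesAndIO:
    def test_override_gating(self):
        base = {
            "OTU_1": Assignment("OTU_1", make_lineage("A"), [], "identity_cutoff"),
        }
        good = ManualOverride("OTU_1", make_lineage(*"ABCDEFGH"), 0.999, 0.995)
        out = apply_manual_overrides(base, [good])
        assert out["OTU_1"].depth == 8
        bad = ManualOverride("OTU_1", make_lineage(*"ZBCDEFGH"), 0.999, 0.98)
        out2 = apply_manual_overrides(base, [bad])
        assert out2["OTU_1"].depth == 1  # ignored
        assert apply_manual_overrides(base, []) == base
        with pytest.raises(KeyError):
            apply_manual_overrides(base, [ManualOverride("OTU_9", make_lineage("A"), 1, 1)])

    def test_hits_tsv_roundtrip(self, tmp_path):
        hs = [hitset("q1", [("r1", 0.99, 123.4), ("r2", 0.955, 88.8)])]
        p = tmp_path / "hits.tsv"
        write_hits_tsv(hs, p)
        back = read_hits_tsv(p)
        assert back[0].query_id == "q1"
        assert back[0].by_ref()["r1"].identity == pytest.approx(0.99)
        assert back[0].by_ref()["r2"].bitscore == pytest.approx(88.8)
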