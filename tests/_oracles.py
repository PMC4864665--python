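"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive the classifier's consensus rule, greedy
clustering, rarefaction expectations and overlap search with the
simplest possible code, so they can cross-check the implementations.
"""

from math import comb

from otugrad.core_io import Lineage, N_RANKS


def brute_force_assign(fwd_hits, rev_hits, refdb, cutoffs, bitscore_fraction=0.95):
    """Enumerate the paired consensus rule step by step.

    fwd_hits/rev_hits: dict ref_id -> (identity, bitscore);
    returns (depth, lineage_names_tuple, retained_ids).
    """
    shared = sorted(set(fwd_hits) & set(rev_hits))
    if not shared:
        return 0, ("",) * N_RANKS, []
    # per-candidate allowed depth: scan all depths, keep the deepest met
    allowed = {}
    for rid in shared:
        ident = min(fwd_hits[rid][0], rev_hits[rid][0])
        depth = 0
        for d in range(1, N_RANKS + 1):
            if all(ident >= cutoffs.cutoffs[i] for i in range(d)):
                depth = d
        if depth > 0:
            allowed[rid] = depth
    if not allowed:
        return 0, ("",) * N_RANKS, []
    overall = max(allowed.values())
    if len(allowed) == 1:
        rid = next(iter(allowed))
        lin = refdb.lineage(rid)
        depth = min(allowed[rid], N_RANKS)
        return depth, lin.truncate(depth).ranks, [rid]
    scores = {rid: fwd_hits[rid][1] + rev_hits[rid][1] for rid in allowed}
    best = max(scores.values())
    retained = sorted(rid for rid in allowed if scores[rid] >= bitscore_fraction * best)
    # deepest depth at which all retained agree, found by exhaustive check
    consensus = 0
    for d in range(N_RANKS, 0, -1):
        prefixes = {refdb.lineage(rid).ranks[:d] for rid in retained}
        if len(prefixes) == 1:
            consensus = d
            break
    depth = min(consensus, overall)
    return depth, refdb.lineage(retained[0]).truncate(depth).ranks, retained


def brute_force_greedy_cluster(seqs, identity_fn, threshold):
    """First-fit greedy clustering checked by exhaustive pairwise identity.

    seqs: list of sequences already in scan order.  Returns a list of
    centroid indices and a membership list (index of centroid per seq).
    """
    centroids = []
    membership = []
    for i, seq in enumerate(seqs):
        target = None
        for c in centroids:
            if identity_fn(seq, seqs[c]) >= threshold:
                target = c
                break
        if target is None:
            centroids.append(i)
            membership.append(i)
        else:
            membership.append(target)
    return centroids, membership


def expected_rarefied_richness(counts, n):
    """Exact E[# OTUs observed] when drawing n reads without replacement."""
    total = sum(counts)
    return sum(1 - comb(total - c, n) / comb(total, n) for c in counts if c > 0)


def naive_best_overlap(fwd, rc_rev):
    """Exhaustive overlap search: (best overlap length, mismatches)."""
    best_l, best_matches = 0, -1
    for L in range(1, min(len(fwd), len(rc_rev)) + 1):
        matches = sum(a == b for a, b in zip(fwd[len(fwd) - L :], rc_rev[:L]))
        if matches >= best_matches:
            best_l, best_matches = L, matches
    return best_l, best_l - best_matches


def make_lineage(*names):
    names = tuple(names)
    return Lineage(names + ("",) * (N_RANKS - len(names)), len(names))
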