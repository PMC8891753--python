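import io
import math

import numpy as np
import pytest
from skbio.tree import TreeNode

from conftest import random_protein
from fcptools import homology, synthetic_data
from fcptools.homology import (
    FamilyAssignment,
    assign_family,
    discover_fcp,
    e_value,
    reconcile_with_clades,
    search,
    smith_waterman,
)
from fcptools.seqio import ProteinRecord


def brute_force_sw(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Local alignment score by explicit gap-length enumeration (no
    affine-state optimisation); independent of the Gotoh implementation."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = H[i - 1][j - 1] + matrix.score(a[i - 1], b[j - 1])
            for k in range(1, i + 1):
                s = max(s, H[i - k][j] - gap_open - k * gap_extend)
            for k in range(1, j + 1):
                s = max(s, H[i][j - k] - gap_open - k * gap_extend)
            H[i][j] = max(0, s)
            best = max(best, H[i][j])
    return best


def test_self_alignment_diagonal_score(blosum62):
    """Identity alignment of ACDEFGH scores the BLOSUM62 diagonal sum 44."""
    rec = ProteinRecord("a", "ACDEFGH")
    hit = smith_waterman(rec, rec, blosum62)
    assert hit.raw_score == 44
    assert hit.aligned_query == hit.aligned_target == "ACDEFGH"
    assert hit.query_span == hit.target_span == (1, 7)


def test_no_positive_pair_scores_zero(blosum62):
    hit = smith_waterman(
        ProteinRecord("a", "WWWW"), ProteinRecord("b", "PPPP"), blosum62
    )
    assert hit.raw_score == 0
    assert hit.aligned_query == ""
    assert hit.query_span == (0, -1)


def test_score_symmetric(blosum62, rng):
    a = random_protein(rng, 30, "a")
    b = random_protein(rng, 25, "b")
    assert (
        smith_waterman(a, b, blosum62).raw_score
        == smith_waterman(b, a, blosum62).raw_score
    )


@pytest.mark.parametrize("seed", range(8))
def test_matches_brute_force_on_short_sequences(blosum62, seed):
    rng = np.random.default_rng(seed)
    a = random_protein(rng, int(rng.integers(4, 13)), "a")
    b = random_protein(rng, int(rng.integers(4, 13)), "b")
    expected = brute_force_sw(a.sequence, b.sequence, blosum62, 11, 1)
    assert smith_waterman(a, b, blosum62).raw_score == expected


def test_alignment_strings_ungap_to_spans(blosum62, rng):
    a = random_protein(rng, 60, "a")
    b = random_protein(rng, 60, "b")
    hit = smith_waterman(a, b, blosum62)
    qs, qe = hit.query_span
    ts, te = hit.target_span
    assert hit.aligned_query.replace("-", "") == a.sequence[qs - 1 : qe]
    assert hit.aligned_target.replace("-", "") == b.sequence[ts - 1 : te]


def test_e_value_identities():
    # bits such that m*n*2^-bits == 1
    bits = math.log2(200 * 10**6)
    assert e_value(bits, 200, 10**6) == pytest.approx(1.0)
    # linear in database size
    assert e_value(100.0, 200, 2 * 10**6) == pytest.approx(
        2 * e_value(100.0, 200, 10**6)
    )
    # a 200-bit alignment is far below the 1e-40 survey cutoff
    ev = e_value(200.0, 200, 10**6)
    assert ev == pytest.approx(2e8 * 2.0**-200, rel=1e-12)
    assert ev < 1e-40
    with pytest.raises(ValueError):
        e_value(10.0, 0, 100)


def test_search_empty_database(blosum62, rng):
    assert search([random_protein(rng, 50, "q")], [], 1e-40, blosum62) == []


def test_search_finds_identical_entry_at_survey_cutoff(blosum62, rng):
    target = random_protein(rng, 200, "t1")
    db = [target] + [random_protein(rng, 200, f"d{i}") for i in range(5)]
    query = ProteinRecord("q", target.sequence)
    hits = search([query], db, 1e-40, blosum62)
    assert [h.target_id for h in hits] == ["t1"]


def test_shuffled_sequence_never_hits_at_cutoff(blosum62):
    rng = np.random.default_rng(99)
    db = [random_protein(rng, 200, f"d{i}") for i in range(3)]
    base = list(db[0].sequence)
    for trial in range(20):
        rng.shuffle(base)
        q = ProteinRecord("q", "".join(base))
        assert search([q], db, 1e-40, blosum62) == []


def test_search_invariant_to_database_order(blosum62, rng):
    db = [random_protein(rng, 80, f"d{i}") for i in range(6)]
    q = ProteinRecord("q", db[2].sequence)
    fwd = search([q], db, 1e-3, blosum62)
    rev = search([q], db[::-1], 1e-3, blosum62)
    assert [(h.target_id, h.raw_score) for h in fwd] == [
        (h.target_id, h.raw_score) for h in rev
    ]


def test_discover_fcp_recovers_homologs_exactly(blosum62, small_panel):
    panels, queries, truth = small_panel
    rng = np.random.default_rng(42)
    decoys = synthetic_data.decoy_records(rng, 20, 150)
    proteome = decoys[:10] + queries + decoys[10:]
    fcp_queries = [r for fam in panels.values() for r in fam]
    found = discover_fcp(proteome, fcp_queries, 1e-40, blosum62)
    assert {r.id for r in found} == {q.id for q in queries}
    assert all("best_hit=" in r.description for r in found)


def test_discover_threshold_zero_empty(blosum62, small_panel):
    panels, queries, _ = small_panel
    fcp_queries = [r for fam in panels.values() for r in fam]
    assert discover_fcp(queries, fcp_queries, 0.0, blosum62) == []


def test_discover_empty_query_panel_errors(blosum62, rng):
    with pytest.raises(ValueError):
        discover_fcp([random_protein(rng, 50, "p")], [], 1e-40, blosum62)


def test_assign_family_self_hit_unambiguous(blosum62, small_panel):
    panels, _, _ = small_panel
    candidate = ProteinRecord("cand", panels["lhcf"][0].sequence)
    asn = assign_family(candidate, panels, matrix=blosum62)
    assert asn.best_family == "lhcf"
    assert not asn.ambiguous


def test_single_weak_hit_flagged_ambiguous(blosum62, rng):
    """A candidate whose only qualifying match is one borderline hit must
    be flagged for clade-based reconciliation (the Lhcf23 situation)."""
    member = random_protein(rng, 200, "r1")
    panels = {
        "lhcf": [random_protein(rng, 200, "f1")],
        "lhcr": [member],
        "lhcx": [random_protein(rng, 200, "x1")],
    }
    # candidate shares ~45% of the lhcr member: one qualifying hit only
    seq = list(member.sequence)
    for i in range(0, len(seq), 2):
        seq[i] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(0, 20))]
    candidate = ProteinRecord("cand", "".join(seq))
    asn = assign_family(candidate, panels, e_threshold=1e-40, matrix=blosum62)
    assert asn.best_family == "lhcr"
    assert asn.ambiguous


def test_no_qualifying_hit_unclassified(blosum62, rng, small_panel):
    panels, _, _ = small_panel
    asn = assign_family(random_protein(rng, 150, "junk"), panels, matrix=blosum62)
    assert asn.best_family == "unclassified"
    assert asn.ambiguous


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def _ambiguous(seq_id: str, fam: str) -> FamilyAssignment:
    return FamilyAssignment(seq_id, fam, "hit", 1e-50, 2.0, True)


def test_ambiguous_candidate_follows_enclosing_clade():
    tree = _tree("((cand,(f1,f2),f3),(r1,r2,r3));")
    labels = {"f1": "lhcf", "f2": "lhcf", "f3": "lhcf",
              "r1": "lhcr", "r2": "lhcr", "r3": "lhcr"}
    out = reconcile_with_clades([_ambiguous("cand", "lhcr")], tree, labels)
    assert out[0].final_family == "lhcf"


def test_unambiguous_keeps_best_family_regardless_of_tree():
    tree = _tree("((cand,f1,f2),(r1,r2));")
    labels = {"f1": "lhcf", "f2": "lhcf", "r1": "lhcr", "r2": "lhcr"}
    asn = FamilyAssignment("cand", "lhcx", "hit", 1e-60, 50.0, False)
    out = reconcile_with_clades([asn], tree, labels)
    assert out[0].final_family == "lhcx"


def test_tied_clade_vote_stays_unclassified():
    tree = _tree("((cand,(f1,f2),(r1,r2)),(x1,x2));")
    labels = {"f1": "lhcf", "f2": "lhcf", "r1": "lhcr", "r2": "lhcr",
              "x1": "lhcx", "x2": "lhcx"}
    out = reconcile_with_clades([_ambiguous("cand", "lhcr")], tree, labels)
    assert out[0].final_family == "unclassified"


def test_missing_candidate_in_tree_errors():
    tree = _tree("((a,b),(c,d));")
    with pytest.raises(ValueError, match="ghost"):
        reconcile_with_clades(
            [_ambiguous("ghost", "lhcf")], tree, {"a": "lhcf", "b": "lhcf",
                                                  "c": "lhcf"}
        )
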