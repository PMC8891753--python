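"""Local alignment search and best-hit protein family classification.

The similarity engine is a full Smith-Waterman dynamic program with affine
gap penalties (Gotoh recurrences) under BLOSUM62, scored into bit scores and
Karlin-Altschul expectation values so that the classical E-value cutoffs
used in database surveys (e.g. 1e-40) are meaningful.  No heuristic seeding
is used: every query-target pair is aligned exactly.

Family assignment follows the best-similarity-match rule: a candidate is
assigned the family of its best-scoring hit against labelled reference
panels, flagged ambiguous when the margin over the runner-up family is
small or only a single weak hit exists, and ambiguous calls are reconciled
against the neighbor-joining cladogram (majority family of the smallest
enclosing clade with enough labelled leaves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .seqio import AMINO_ACIDS, ProteinRecord

LETTERS = AMINO_ACIDS + "X"
_INDEX = {c: i for i, c in enumerate(LETTERS)}

#: Gapped BLOSUM62 Karlin-Altschul parameters (gap open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue substitution scores over the 20 amino acids + X."""

    name: str
    scores: np.ndarray  # (21, 21) int array indexed by LETTERS

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.int64)
        if s.shape != (21, 21):
            raise ValueError("substitution matrix must be 21x21 (20 AAs + X)")
        if not np.array_equal(s, s.T):
            raise ValueError(f"matrix {self.name!r} is not symmetric")
        if (np.diag(s)[:20] <= 0).any():
            raise ValueError(
                f"matrix {self.name!r}: canonical diagonal must be positive"
            )
        object.__setattr__(self, "scores", s)

    def score(self, a: str, b: str) -> int:
        try:
            return int(self.scores[_INDEX[a], _INDEX[b]])
        except KeyError as exc:
            raise KeyError(f"letter {exc.args[0]!r} not in matrix {self.name!r}")

    @classmethod
    def from_name(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load(name)
        alpha = str(m.alphabet)
        s = np.zeros((21, 21), dtype=np.int64)
        for i, a in enumerate(LETTERS):
            for j, b in enumerate(LETTERS):
                s[i, j] = int(m[alpha.index(a), alpha.index(b)])
        return cls(name=name, scores=s)


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def default_matrix() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = SubstitutionMatrix.from_name("BLOSUM62")
    return _DEFAULT_MATRIX


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"letter {exc.args[0]!r} not encodable")


@dataclass
class HitResult:
    """A scored local alignment between a query and a target protein.

    Spans are 1-based inclusive; the aligned strings are equal-length and
    gapped with '-'.  A raw score of 0 means no positively scoring local
    alignment exists and the spans are empty.
    """

    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    e_value: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    aligned_query: str
    aligned_target: str


@njit(cache=True)
def _sw_fill(a, b, S, gap_open, gap_extend):
    """Gotoh affine-gap local alignment fill.

    Gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention).
    Returns H (match/end matrix), E (gap in A), F (gap in B).
    """
    n, m = a.shape[0], b.shape[0]
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i, j - 1] - gap_extend
            eo = H[i, j - 1] - gap_open - gap_extend
            E[i, j] = e if e > eo else eo
            f = F[i - 1, j] - gap_extend
            fo = H[i - 1, j] - gap_open - gap_extend
            F[i, j] = f if f > fo else fo
            h = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


def bit_score(raw_score: float, lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """Normalised (bit) score: (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(k)) / math.log(2.0)


def e_value(bits: float, query_len: int, db_residues: int) -> float:
    """Karlin-Altschul expectation E = m * n * 2^(-bits)."""
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("query length and database size must be positive")
    return float(query_len) * float(db_residues) * math.pow(2.0, -bits)


def smith_waterman(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    db_residues: int | None = None,
) -> HitResult:
    """Optimal local alignment of two proteins under affine gap penalties.

    Ties among optimal end cells break to the lowest (row, column)
    coordinate.  ``db_residues`` (default: length of ``b``) sets the search
    space for the E-value.
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    ea, eb = encode(a.sequence), encode(b.sequence)
    matrix = matrix or default_matrix()
    H, E, F = _sw_fill(ea, eb, matrix.scores, gap_open, gap_extend)
    best = int(H.max())
    n = db_residues if db_residues is not None else len(b)
    bits = bit_score(best)
    ev = e_value(bits, len(a), n)
    if best == 0:
        return HitResult(
            a.id, b.id, 0, bits, ev, (0, -1), (0, -1), "", ""
        )
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    qa, ta = [], []
    qi, tj = int(i), int(j)
    state = "H"
    while state == "H" and H[qi, tj] > 0 or state in ("E", "F"):
        if state == "H":
            if H[qi, tj] == E[qi, tj]:
                state = "E"
                continue
            if H[qi, tj] == F[qi, tj]:
                state = "F"
                continue
            qa.append(a.sequence[qi - 1])
            ta.append(b.sequence[tj - 1])
            qi -= 1
            tj -= 1
        elif state == "E":  # gap in query, consume target letter
            qa.append("-")
            ta.append(b.sequence[tj - 1])
            opened = E[qi, tj] == H[qi, tj - 1] - gap_open - gap_extend
            tj -= 1
            if opened:
                state = "H"
        else:  # gap in target, consume query letter
            qa.append(a.sequence[qi - 1])
            ta.append("-")
            opened = F[qi, tj] == H[qi - 1, tj] - gap_open - gap_extend
            qi -= 1
            if opened:
                state = "H"
    return HitResult(
        query_id=a.id,
        target_id=b.id,
        raw_score=best,
        bit_score=bits,
        e_value=ev,
        query_span=(qi + 1, int(i)),
        target_span=(tj + 1, int(j)),
        aligned_query="".join(reversed(qa)),
        aligned_target="".join(reversed(ta)),
    )


def search(
    queries: Sequence[ProteinRecord],
    database: Sequence[ProteinRecord],
    e_threshold: float = 1e-40,
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[HitResult]:
    """All query x database local-alignment hits below the E-value cutoff.

    Each database target is reported at most once per query (its optimal
    alignment).  Results are sorted by ascending E-value, then query id,
    then target id, so output is invariant to database input order.
    """
    if not queries:
        raise ValueError("search requires at least one query")
    db_residues = sum(len(r) for r in database)
    hits: list[HitResult] = []
    for q in queries:
        for t in database:
            hit = smith_waterman(
                q, t, matrix, gap_open, gap_extend, db_residues=db_residues
            )
            if hit.e_value < e_threshold:
                hits.append(hit)
    hits.sort(key=lambda h: (h.e_value, h.query_id, h.target_id))
    return hits


def discover_fcp(
    proteome: Sequence[ProteinRecord],
    fcp_queries: Sequence[ProteinRecord],
    e_threshold: float = 1e-40,
    matrix: SubstitutionMatrix | None = None,
) -> list[ProteinRecord]:
    """Candidate FCP proteins: proteome entries hit by any reference query
    below the E-value threshold, deduplicated, best hit noted as evidence.
    """
    if not fcp_queries:
        raise ValueError("discover_fcp requires a non-empty query panel")
    hits = search(fcp_queries, proteome, e_threshold, matrix)
    best: dict[str, HitResult] = {}
    for h in hits:
        if h.target_id not in best or h.e_value < best[h.target_id].e_value:
            best[h.target_id] = h
    out = []
    for rec in proteome:
        h = best.get(rec.id)
        if h is not None:
            evidence = f"best_hit={h.query_id} evalue={h.e_value:.3g}"
            desc = f"{rec.description} {evidence}".strip()
            out.append(replace(rec, description=desc))
    return out


@dataclass
class FamilyAssignment:
    """Outcome of best-hit family classification for one candidate."""

    seq_id: str
    best_family: str
    best_hit_id: str | None
    best_e_value: float
    margin: float
    ambiguous: bool
    final_family: str | None = None
    evidence: str = ""


def assign_family(
    candidate: ProteinRecord,
    panels: Mapping[str, Sequence[ProteinRecord]],
    e_threshold: float = 1e-40,
    margin_bits: float = 10.0,
    matrix: SubstitutionMatrix | None = None,
) -> FamilyAssignment:
    """Classify one candidate by its best similarity match against labelled
    family panels.

    The call is flagged ambiguous when fewer than two qualifying hits exist
    or the bit-score margin between the best and the best other family falls
    below ``margin_bits`` (including exact cross-family ties).
    """
    for fam in ("lhcf", "lhcr", "lhcx"):
        if not panels.get(fam):
            raise ValueError(f"panel for family {fam!r} is empty")
    db_residues = sum(len(r) for fam in panels.values() for r in fam)
    best_by_family: dict[str, HitResult] = {}
    n_qualifying = 0
    for fam, members in panels.items():
        for ref in members:
            hit = smith_waterman(candidate, ref, matrix, db_residues=db_residues)
            if hit.e_value >= e_threshold:
                continue
            n_qualifying += 1
            cur = best_by_family.get(fam)
            if cur is None or hit.bit_score > cur.bit_score:
                best_by_family[fam] = hit
    if not best_by_family:
        return FamilyAssignment(
            seq_id=candidate.id,
            best_family="unclassified",
            best_hit_id=None,
            best_e_value=math.inf,
            margin=0.0,
            ambiguous=True,
            evidence="no hit below threshold",
        )
    ranked = sorted(
        best_by_family.items(), key=lambda kv: (-kv[1].bit_score, kv[0])
    )
    best_fam, best_hit = ranked[0]
    if len(ranked) > 1:
        margin = best_hit.bit_score - ranked[1][1].bit_score
    else:
        margin = math.inf
    ambiguous = n_qualifying < 2 or margin < margin_bits
    return FamilyAssignment(
        seq_id=candidate.id,
        best_family=best_fam,
        best_hit_id=best_hit.target_id,
        best_e_value=best_hit.e_value,
        margin=margin,
        ambiguous=ambiguous,
        evidence=(
            f"best {best_fam} hit {best_hit.target_id} "
            f"bits={best_hit.bit_score:.1f} margin={margin:.1f} "
            f"qualifying={n_qualifying}"
        ),
    )


def reconcile_with_clades(
    assignments: Iterable[FamilyAssignment],
    tree,
    panel_labels: Mapping[str, str],
    min_labeled: int = 3,
) -> list[FamilyAssignment]:
    """Resolve ambiguous assignments with the cladogram.

    For each ambiguous candidate, the smallest enclosing clade containing at
    least ``min_labeled`` labelled panel leaves votes by majority family; a
    tie leaves the candidate unclassified.  Unambiguous candidates keep
    their best-hit family.  ``tree`` is an skbio TreeNode whose tips include
    every candidate and panel id.
    """
    tip_cache: dict[int, list[str]] = {}

    def labelled_tips(node) -> list[str]:
        key = id(node)
        if key not in tip_cache:
            tip_cache[key] = [
                t.name for t in node.tips() if t.name in panel_labels
            ]
        return tip_cache[key]

    out: list[FamilyAssignment] = []
    for asn in assignments:
        if not asn.ambiguous:
            out.append(
                replace(
                    asn,
                    final_family=asn.best_family,
                    evidence=asn.evidence + "; unambiguous best hit",
                )
            )
            continue
        try:
            leaf = tree.find(asn.seq_id)
        except Exception:
            raise ValueError(f"candidate {asn.seq_id!r} missing from tree")
        node = leaf.parent
        clade_tips: list[str] = []
        while node is not None:
            clade_tips = labelled_tips(node)
            if len(clade_tips) >= min_labeled:
                break
            node = node.parent
        if node is None or len(clade_tips) < min_labeled:
            out.append(
                replace(
                    asn,
                    final_family="unclassified",
                    evidence=asn.evidence + "; no clade with enough labels",
                )
            )
            continue
        counts: dict[str, int] = {}
        for tip in clade_tips:
            fam = panel_labels[tip]
            counts[fam] = counts.get(fam, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out.append(
                replace(
                    asn,
                    final_family="unclassified",
                    evidence=asn.evidence + "; clade vote tied",
                )
            )
            continue
        out.append(
            replace(
                asn,
                final_family=ranked[0][0],
                evidence=asn.evidence
                + f"; clade vote {ranked[0][0]} ({ranked[0][1]}/{len(clade_tips)})",
            )
        )
    return out
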