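"""Multiple sequence alignment and residue-to-column mapping.

``progressive_align`` is a classical progressive aligner: pairwise local
alignments give identity-based guide distances, a neighbor-joining guide
tree orders the merges, and profiles are merged leaf-to-root by global
profile-profile alignment with sum-of-pairs column scoring and affine gap
penalties.  It is deterministic for a fixed input order and uses no
randomness.

Residue positions are 1-based; alignment columns are exposed 1-based as
well (matching how binding sites are reported), with 0-based indices kept
internal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .homology import SubstitutionMatrix, default_matrix, encode, smith_waterman
from .seqio import ProteinRecord

GAP = "-"


@dataclass
class MSA:
    """A gapped alignment; every row ungaps to its source sequence."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("MSA must contain at least one row")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError("MSA rows have unequal lengths")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in MSA")
        self._rows = dict(self.records)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    def row(self, seq_id: str) -> str:
        try:
            return self._rows[seq_id]
        except KeyError:
            raise KeyError(f"id {seq_id!r} not in MSA")

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def encoded(self) -> np.ndarray:
        """Integer matrix (rows x columns); gaps are -1."""
        from .homology import _INDEX

        out = np.full((len(self.records), self.n_columns), -1, dtype=np.int64)
        for r, (_, seq) in enumerate(self.records):
            for c, ch in enumerate(seq):
                if ch != GAP:
                    out[r, c] = _INDEX[ch]
        return out

    def subset(self, ids: Sequence[str]) -> "MSA":
        return MSA([(i, self.row(i)) for i in ids])


def column_of(msa: MSA, seq_id: str, pos: int) -> int:
    """1-based alignment column holding residue ``pos`` of ``seq_id``."""
    row = msa.row(seq_id)
    if pos < 1:
        raise ValueError("residue positions are 1-based")
    count = 0
    for c, ch in enumerate(row):
        if ch != GAP:
            count += 1
            if count == pos:
                return c + 1
    raise ValueError(
        f"position {pos} beyond ungapped length of {seq_id!r} ({count})"
    )


def residue_at(msa: MSA, seq_id: str, column: int) -> str:
    """Residue (or gap marker) of ``seq_id`` at 1-based ``column``."""
    row = msa.row(seq_id)
    if not 1 <= column <= len(row):
        raise ValueError(f"column {column} out of range 1..{len(row)}")
    return row[column - 1]


def position_of(msa: MSA, seq_id: str, column: int) -> int | None:
    """1-based residue position at ``column``, or None if the row is gapped
    there."""
    row = msa.row(seq_id)
    if row[column - 1] == GAP:
        return None
    return len(row[:column].replace(GAP, ""))


def read_aligned_fasta(path: str | Path) -> MSA:
    from Bio import SeqIO as BioSeqIO

    records = [
        (e.id, str(e.seq).upper()) for e in BioSeqIO.parse(str(path), "fasta")
    ]
    return MSA(records)


def write_aligned_fasta(msa: MSA, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for seq_id, row in msa.records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


@njit(cache=True)
def _nw_fill(C, gap_open, gap_extend):
    """Global affine-gap (Gotoh) fill over a precomputed column-score
    matrix C (rows: profile A columns, cols: profile B columns)."""
    n, m = C.shape
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    for j in range(1, m + 1):
        E[0, j] = -(gap_open + j * gap_extend)
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -(gap_open + i * gap_extend)
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i, j - 1] - gap_extend
            eo = H[i, j - 1] - gap_open - gap_extend
            E[i, j] = e if e > eo else eo
            f = F[i - 1, j] - gap_extend
            fo = H[i - 1, j] - gap_open - gap_extend
            F[i, j] = f if f > fo else fo
            h = H[i - 1, j - 1] + C[i - 1, j - 1]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    return H, E, F


class _Profile:
    """A partial alignment plus per-column residue counts for scoring."""

    def __init__(self, rows: list[tuple[str, str]]):
        self.rows = rows
        L = len(rows[0][1])
        counts = np.zeros((L, 21))
        for _, seq in rows:
            e = encode(seq.replace(GAP, "Q"))  # placeholder, masked below
            for c, ch in enumerate(seq):
                if ch != GAP:
                    counts[c, e[c]] += 1
        self.counts = counts
        self.n = len(rows)

    def __len__(self) -> int:
        return self.counts.shape[0]


def _merge(p1: _Profile, p2: _Profile, S: np.ndarray, gap_open: int,
           gap_extend: int) -> _Profile:
    # average sum-of-pairs column score; gap pairings contribute zero
    C = (p1.counts @ S @ p2.counts.T) / (p1.n * p2.n)
    H, E, F = _nw_fill(C, float(gap_open), float(gap_extend))
    i, j = len(p1), len(p2)
    ops: list[str] = []  # 'D' diagonal, 'A' column from p1 only, 'B' from p2
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i == 0:
                ops.append("B")
                j -= 1
                continue
            if j == 0:
                ops.append("A")
                i -= 1
                continue
            if H[i, j] == E[i, j]:
                state = "E"
                continue
            if H[i, j] == F[i, j]:
                state = "F"
                continue
            ops.append("D")
            i -= 1
            j -= 1
        elif state == "E":  # gap in p1: emit a p2-only column
            ops.append("B")
            opened = E[i, j] == H[i, j - 1] - gap_open - gap_extend
            j -= 1
            if opened:
                state = "H"
        else:  # gap in p2: emit a p1-only column
            ops.append("A")
            opened = F[i, j] == H[i - 1, j] - gap_open - gap_extend
            i -= 1
            if opened:
                state = "H"
    ops.reverse()
    rows: list[tuple[str, str]] = []
    for seq_id, seq in p1.rows:
        out, k = [], 0
        for op in ops:
            if op in ("D", "A"):
                out.append(seq[k])
                k += 1
            else:
                out.append(GAP)
        rows.append((seq_id, "".join(out)))
    for seq_id, seq in p2.rows:
        out, k = [], 0
        for op in ops:
            if op in ("D", "B"):
                out.append(seq[k])
                k += 1
            else:
                out.append(GAP)
        rows.append((seq_id, "".join(out)))
    return _Profile(rows)


def pairwise_distance(a: ProteinRecord, b: ProteinRecord,
                      matrix: SubstitutionMatrix | None = None) -> float:
    """Guide distance: 1 - identity over the optimal local alignment.

    Unrelated pairs with no alignment get distance 1.
    """
    hit = smith_waterman(a, b, matrix)
    if not hit.aligned_query:
        return 1.0
    matches = sum(
        x == y and x != GAP
        for x, y in zip(hit.aligned_query, hit.aligned_target)
    )
    return 1.0 - matches / len(hit.aligned_query)


def progressive_align(
    seqs: Sequence[ProteinRecord],
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> MSA:
    """Progressive multiple alignment along a neighbor-joining guide tree."""
    from . import phylo

    if not seqs:
        raise ValueError("progressive_align requires at least one sequence")
    matrix = matrix or default_matrix()
    if len(seqs) == 1:
        return MSA([(seqs[0].id, seqs[0].sequence)])
    if len(seqs) == 2:
        p = _merge(
            _Profile([(seqs[0].id, seqs[0].sequence)]),
            _Profile([(seqs[1].id, seqs[1].sequence)]),
            matrix.scores.astype(float),
            gap_open,
            gap_extend,
        )
        return _finalise(p, seqs)
    ids = [s.id for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[i], seqs[j], matrix)
    tree = phylo.neighbor_joining(phylo.DistanceMatrix(d, ids))
    by_id = {s.id: s for s in seqs}
    S = matrix.scores.astype(float)

    def build(node) -> _Profile:
        if node.is_tip():
            rec = by_id[node.name]
            return _Profile([(rec.id, rec.sequence)])
        prof = build(node.children[0])
        for child in node.children[1:]:
            prof = _merge(prof, build(child), S, gap_open, gap_extend)
        return prof

    return _finalise(build(tree), seqs)


def _finalise(profile: _Profile, seqs: Sequence[ProteinRecord]) -> MSA:
    order = {s.id: k for k, s in enumerate(seqs)}
    rows = sorted(profile.rows, key=lambda r: order[r[0]])
    msa = MSA(rows)
    for s in seqs:
        if msa.ungapped(s.id) != s.sequence:
            raise AssertionError(
                f"alignment corrupted sequence {s.id!r}"
            )
    return msa


def sum_of_pairs_score(msa: MSA, matrix: SubstitutionMatrix | None = None) -> float:
    """Total sum-of-pairs substitution score over all columns (gap pairs
    score zero); a simple comparable objective for alignments."""
    matrix = matrix or default_matrix()
    X = msa.encoded()
    total = 0.0
    S = matrix.scores
    n = X.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            mask = (X[i] >= 0) & (X[j] >= 0)
            total += S[X[i][mask], X[j][mask]].sum()
    return float(total)
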