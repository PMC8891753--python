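"""Homology transfer of pigment-binding residues through alignment columns.

A reference Lhcf residue of known pigment-binding function (central ligand
or H-bond ligand, from crystallographic characterisation) is mapped to its
alignment column, and each target protein is scored for carrying the same
(or an allowed alternate) residue there.  If the exact column does not
match, nearby target residues within a small shift window are scanned —
binding positions can shift by a few amino acids between species while the
binding function is retained, the documented extreme being a tyrosine
displaced by 3 residues.  Offsets are measured in target residues (gaps
skipped), not raw columns.

Per-site presence percentages over a family panel ("% among Lhcf") are the
integer-rounded share of family members carrying the site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .msa import MSA, column_of, position_of, residue_at
from .seqio import BindingSiteAnnotation

#: Sites representable in annotations but excluded from default reports:
#: their reference pigments bind via chlorophyll c contacts, so cross-species
#: comparison of these cells is not meaningful.
DEFAULT_EXCLUDED_SITES = ("Fx306", "Fx307")


@dataclass
class SiteCall:
    """Transfer outcome of one binding-site annotation on one target."""

    site_id: str
    target_id: str
    present: bool
    matched_residue: str | None = None
    offset: int | None = None
    via_alternate: bool = False


@dataclass
class SiteSummary:
    """Per-site presence over a family panel."""

    site_id: str
    pigment_class: str
    ligand_class: str
    residues: str
    conserved_flag: bool
    n_present: int
    n_total: int

    @property
    def percent(self) -> int:
        # round half-up, as printed percentages do
        return int(100.0 * self.n_present / self.n_total + 0.5)


def _offset_order(w: int) -> list[int]:
    """Nearest first; tie between -k and +k goes negative first."""
    order = []
    for k in range(1, w + 1):
        order.extend([-k, k])
    return order


def transfer_site(
    msa: MSA,
    ann: BindingSiteAnnotation,
    target_ids: Sequence[str],
    shift_window: int = 3,
) -> list[SiteCall]:
    """Call one annotated reference residue on every target through the MSA.

    The reference residue's column is located; a target matches at offset 0
    when its residue in that column is the primary residue or an allowed
    alternate.  Otherwise target residues at amino-acid offsets +-1..+-w
    from the column's anchor position are scanned (nearest first, negative
    first on ties).  ``X`` never matches.
    """
    col = column_of(msa, ann.ref_seq_id, ann.ref_pos)
    if residue_at(msa, ann.ref_seq_id, col) != ann.primary_residue:
        raise ValueError(
            f"site {ann.site_id!r}: reference column residue disagrees with "
            "annotation (corrupt alignment?)"
        )
    allowed = ann.allowed_residues
    calls: list[SiteCall] = []
    for tid in target_ids:
        row = msa.row(tid)
        res0 = row[col - 1]
        if res0 in allowed:
            calls.append(
                SiteCall(
                    ann.site_id,
                    tid,
                    True,
                    res0,
                    0,
                    via_alternate=res0 != ann.primary_residue,
                )
            )
            continue
        # anchor: target residue position at the column, or the last
        # residue before it when the target is gapped there (in which case
        # the anchor itself is still an offset-0 candidate)
        anchor = position_of(msa, tid, col)
        offsets = _offset_order(shift_window)
        if anchor is None:
            anchor = len(row[: col - 1].replace("-", ""))
            offsets = [0] + offsets
        ungapped = row.replace("-", "")
        found = False
        for off in offsets:
            pos = anchor + off
            if not 1 <= pos <= len(ungapped):
                continue
            res = ungapped[pos - 1]
            if res in allowed:
                calls.append(
                    SiteCall(
                        ann.site_id,
                        tid,
                        True,
                        res,
                        off,
                        via_alternate=res != ann.primary_residue,
                    )
                )
                found = True
                break
        if not found:
            calls.append(SiteCall(ann.site_id, tid, False))
    return calls


def summarize_site(
    calls: Sequence[SiteCall], ann: BindingSiteAnnotation
) -> SiteSummary:
    """Presence percentage of one site over a panel of calls."""
    if not calls:
        raise ValueError(f"site {ann.site_id!r}: no calls to summarise")
    for c in calls:
        if c.site_id != ann.site_id:
            raise ValueError(
                f"call for {c.site_id!r} mixed into summary of {ann.site_id!r}"
            )
    residues = ann.primary_residue
    if ann.alternate_residues:
        residues += " or " + " or ".join(sorted(ann.alternate_residues))
    return SiteSummary(
        site_id=ann.site_id,
        pigment_class=ann.pigment_class,
        ligand_class=ann.ligand_class,
        residues=residues,
        conserved_flag=ann.conserved_flag,
        n_present=sum(c.present for c in calls),
        n_total=len(calls),
    )


def build_site_report(
    summaries: Iterable[SiteSummary],
    species: str = "",
    exclude_sites: Sequence[str] = DEFAULT_EXCLUDED_SITES,
) -> pd.DataFrame:
    """Tabulate site summaries with central-ligand and H-bond columns
    side by side and conserved/non-conserved sub-columns."""
    rows = []
    seen: set[tuple[str, str, str]] = set()
    for s in summaries:
        if s.site_id in exclude_sites:
            continue
        key = (s.site_id, s.residues, species)
        if key in seen:
            raise ValueError(f"duplicate report row for {key}")
        seen.add(key)
        rows.append(
            {
                "site_id": s.site_id,
                "species": species,
                "pigment_class": s.pigment_class,
                "ligand_class": s.ligand_class,
                "residues": s.residues,
                "conserved": s.conserved_flag,
                "n_present": s.n_present,
                "n_total": s.n_total,
                "percent": s.percent,
            }
        )
    columns = [
        "site_id",
        "species",
        "pigment_class",
        "ligand_class",
        "residues",
        "conserved",
        "n_present",
        "n_total",
        "percent",
    ]
    return pd.DataFrame(rows, columns=columns)


def count_sites_found(
    summaries: Iterable[SiteSummary],
    min_percent: float = 0.0,
    exclude_sites: Sequence[str] = DEFAULT_EXCLUDED_SITES,
) -> tuple[int, int]:
    """(n_chl, n_fx): pigment sites with at least one ligand residue found.

    A pigment site may have several ligand residues (central and H-bond,
    primary and alternate); it counts as found when any of its summaries
    exceeds ``min_percent`` presence.
    """
    chl_found: set[str] = set()
    fx_found: set[str] = set()
    for s in summaries:
        if s.site_id in exclude_sites or s.percent <= min_percent:
            continue
        if s.pigment_class in ("chl_a", "chl_c"):
            chl_found.add(s.site_id)
        elif s.pigment_class == "fx":
            fx_found.add(s.site_id)
    return len(chl_found), len(fx_found)
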