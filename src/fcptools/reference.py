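"""Published reference values for the Lhcf pigment-binding site system.

The packaged table holds per-site presence percentages of chlorophyll and
fucoxanthin binding residues among the Lhcf proteins of the diatom
*Phaeodactylum tricornutum* (17 Lhcf, crystallographically characterised)
and the haptophyte *Tisochrysis lutea* (28 Lhcf, annotated by homology
transfer).  These values parameterise study-scale simulations (a site
reported at p% present is implanted at retention p/100) and serve as the
comparison panel in reports.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .synthetic_data import SiteSpec

SPECIES_PANELS = {"P_tricornutum": 17, "T_lutea": 28}


def load_site_percentages() -> pd.DataFrame:
    """The packaged per-site presence percentage table."""
    with resources.files("fcptools").joinpath(
        "data/lhcf_site_percentages.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def site_specs_for_species(
    species: str = "T_lutea",
    start: int = 20,
    spacing: int = 10,
    shifted_sites: dict[str, int] | None = None,
) -> tuple[SiteSpec, ...]:
    """Turn the reference percentage rows for one species into implantable
    site specifications.

    Each (site, ligand residue) row becomes one site implanted at retention
    percent/100, at evenly spaced positions.  ``shifted_sites`` maps a
    "site_id:residue" key to a fixed residue shift (e.g. the tyrosine of
    the second fucoxanthin site sits 3 residues away from its reference
    column in the haptophyte).
    """
    table = load_site_percentages()
    if species not in set(table["species"]):
        raise ValueError(f"unknown species panel {species!r}")
    rows = table[table["species"] == species].reset_index(drop=True)
    shifted_sites = shifted_sites or {}
    specs = []
    for k, row in rows.iterrows():
        residues = [r.strip() for r in str(row["residues"]).split("or")]
        key = f"{row['site_id']}:{residues[0]}"
        shift = shifted_sites.get(key, 0)
        specs.append(
            SiteSpec(
                site_id=str(row["site_id"]),
                position=start + spacing * k + shift,
                residue=residues[0],
                alternate_residues=frozenset(residues[1:]),
                retention=row["percent"] / 100.0,
                pigment_class=row["pigment_class"],
                ligand_class=row["ligand_class"],
                conserved_flag=bool(row["conserved"]),
            )
        )
    return tuple(specs)
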