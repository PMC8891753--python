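"""Synthetic protein families with known phylogeny and implanted
pigment-binding sites.

Families are evolved down Yule (pure-birth) trees under a uniform 20-state
exchange model — the same equal-rates assumption the Jukes-Cantor
correction makes downstream, so simulated p-distances are analytically
recoverable.  Family trees are ultrametric and rescaled to unit root-to-tip
depth; the per-site substitution rate then equals the root-to-tip
Jukes-Cantor distance.  Defaults give within-family identity around 60%
and between-family identity around 25%, the regime in which best-hit
family classification of light-harvesting proteins operates.

Binding-site residues are implanted after evolution, so per-sequence
retention is an exact Bernoulli draw and presence percentages have a clean
binomial truth.  A retained site may additionally be displaced by up to
``max_shift`` residues (with probability ``shift_prob``), emulating
binding positions that migrate a few amino acids between lineages.

No indels are simulated: alignment machinery is exercised separately with
gapped fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio.tree import TreeNode

from .seqio import AMINO_ACIDS, BindingSiteAnnotation, ProteinRecord

DEFAULT_FAMILIES = ("lhcf", "lhcr", "lhcx")


def seqio_families() -> tuple[str, ...]:
    from .seqio import FAMILIES

    return FAMILIES


@dataclass(frozen=True)
class SiteSpec:
    """One binding site to implant: a residue at a 1-based position kept
    with probability ``retention`` and, when kept, displaced by up to
    ``max_shift`` residues with probability ``shift_prob``."""

    site_id: str
    position: int
    residue: str
    retention: float = 0.9
    shift_prob: float = 0.0
    max_shift: int = 3
    pigment_class: str = "chl_a"
    ligand_class: str = "central"
    alternate_residues: frozenset[str] = frozenset()
    conserved_flag: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError(f"site {self.site_id}: retention not in [0,1]")
        if not 0.0 <= self.shift_prob <= 1.0:
            raise ValueError(f"site {self.site_id}: shift_prob not in [0,1]")
        if self.position < 1:
            raise ValueError(f"site {self.site_id}: position must be >= 1")


@dataclass
class SimulationSpec:
    """Parameters of a family simulation.

    ``subst_rate`` is the expected number of substitutions per site from
    the (unit-depth) family root to a tip; ``root_divergence`` the distance
    from the shared grand-root to each family root, controlling
    between-family identity.
    """

    n_families: int = 3
    seqs_per_family: int = 20
    root_length: int = 200
    birth_rate: float = 1.0
    subst_rate: float = 0.26
    root_divergence: float = 0.48
    site_spec: tuple[SiteSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        positions = [s.position for s in self.site_spec]
        if len(set(positions)) != len(positions):
            raise ValueError("two binding sites share a position")
        for s in self.site_spec:
            if s.position > self.root_length:
                raise ValueError(
                    f"site {s.site_id} position beyond root length"
                )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside simulated sequences."""

    trees: dict[str, TreeNode] = field(default_factory=dict)
    family_of: dict[str, str] = field(default_factory=dict)
    #: rows: (seq_id, site_id, implanted position or None, present)
    site_rows: list[tuple[str, str, int | None, bool]] = field(
        default_factory=list
    )

    def presence_fraction(self, site_id: str) -> float:
        rows = [r for r in self.site_rows if r[1] == site_id]
        if not rows:
            raise KeyError(f"no truth rows for site {site_id!r}")
        return sum(r[3] for r in rows) / len(rows)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length)


def _decode(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def _yule_tree(rng: np.random.Generator, n_tips: int, birth_rate: float,
               prefix: str) -> TreeNode:
    """Ultrametric pure-birth tree with unit root-to-tip depth."""
    if n_tips == 1:
        return TreeNode(name=f"{prefix}1", length=1.0)
    starts = {0: 0.0}
    nodes = {0: TreeNode()}
    active = [0]
    nxt = 1
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = active[int(rng.integers(0, len(active)))]
        nodes[k].length = t - starts[k]
        for _ in range(2):
            child = TreeNode()
            nodes[k].append(child)
            nodes[nxt] = child
            starts[nxt] = t
            active.append(nxt)
            nxt += 1
        active.remove(k)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, k in enumerate(active):
        nodes[k].length = t - starts[k]
    root = nodes[0]
    for tip_idx, tip in enumerate(root.tips(), start=1):
        tip.name = f"{prefix}{tip_idx}"
    # rescale to unit depth (tree is ultrametric by construction)
    for node in root.traverse(include_self=True):
        if node.length is not None:
            node.length /= t
    root.length = None
    return root


def evolve(seq: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve one step under the uniform 20-state exchange model.

    ``distance`` is the expected number of substitutions per site; the
    probability a site differs after the step is (19/20)(1 - e^(-20d/19)).
    """
    if distance < 0:
        raise ValueError("evolution distance cannot be negative")
    p_diff = (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * distance))
    out = seq.copy()
    hit = rng.random(seq.shape[0]) < p_diff
    n = int(hit.sum())
    if n:
        # uniform over the 19 other residues
        out[hit] = (out[hit] + rng.integers(1, 20, size=n)) % 20
    return out


def _evolve_down(root_seq: np.ndarray, tree: TreeNode, rate: float,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    tips: dict[str, np.ndarray] = {}

    def walk(node, seq):
        for child in node.children:
            cs = evolve(seq, rate * child.length, rng)
            if child.is_tip():
                tips[child.name] = cs
            else:
                walk(child, cs)

    if tree.is_tip():
        tips[tree.name] = evolve(root_seq, rate * (tree.length or 0.0), rng)
    else:
        walk(tree, root_seq)
    return tips


def _implant_sites(
    seqs: dict[str, np.ndarray],
    sites: Sequence[SiteSpec],
    rng: np.random.Generator,
    truth: SyntheticTruth,
    always_present: frozenset[str] = frozenset(),
) -> None:
    """Overwrite site positions in place (deterministic given the rng).

    Sequences named in ``always_present`` (reference proteins) get every
    site at its exact position.
    """
    for name in sorted(seqs):
        seq = seqs[name]
        for site in sites:
            idx = site.position - 1
            res = AMINO_ACIDS.index(site.residue)
            if name in always_present:
                seq[idx] = res
                truth.site_rows.append((name, site.site_id, site.position, True))
                continue
            keep = rng.random() < site.retention
            shift = keep and site.max_shift > 0 and rng.random() < site.shift_prob
            if keep:
                pos = site.position
                if shift:
                    deltas = [
                        d
                        for d in range(-site.max_shift, site.max_shift + 1)
                        if d != 0 and 1 <= site.position + d <= len(seq)
                    ]
                    pos = site.position + deltas[int(rng.integers(0, len(deltas)))]
                if pos != site.position:
                    seq[idx] = (res + int(rng.integers(1, 20))) % 20
                seq[pos - 1] = res
                truth.site_rows.append((name, site.site_id, pos, True))
            else:
                seq[idx] = (res + int(rng.integers(1, 20))) % 20
                truth.site_rows.append((name, site.site_id, None, False))


def simulate_family(
    spec: SimulationSpec,
    family: str = "lhcf",
    rng: np.random.Generator | None = None,
    root_seq: np.ndarray | None = None,
    n_reference: int = 0,
    species: str = "synthetic",
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Simulate one family of ``spec.seqs_per_family`` proteins.

    With ``n_reference > 0`` the first tips are reference proteins carrying
    every implanted site at its exact position (so annotations can be
    validated against them).  Deterministic for a fixed seed.
    """
    if spec.seqs_per_family < 1:
        raise ValueError("seqs_per_family must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if root_seq is None:
        root_seq = _random_sequence(rng, spec.root_length)
    tree = _yule_tree(rng, spec.seqs_per_family, spec.birth_rate,
                      prefix=f"{family}_")
    seqs = _evolve_down(root_seq, tree, spec.subst_rate, rng)
    truth = SyntheticTruth(trees={family: tree})
    refs = frozenset(
        f"{family}_{i}" for i in range(1, n_reference + 1)
    )
    _implant_sites(seqs, spec.site_spec, rng, truth, always_present=refs)
    records = []
    label = family if family in seqio_families() else None
    for name in sorted(seqs, key=lambda s: int(s.rsplit("_", 1)[1])):
        truth.family_of[name] = family
        records.append(
            ProteinRecord(
                id=name,
                sequence=_decode(seqs[name]),
                species=species,
                family_label=label,
            )
        )
    return records, truth


def simulate_classification_panel(
    spec: SimulationSpec,
    holdout: int = 5,
    families: Sequence[str] | None = None,
) -> tuple[dict[str, list[ProteinRecord]], list[ProteinRecord], SyntheticTruth]:
    """Labelled family panels plus held-out unlabelled query sequences.

    Families diverge from a common grand-root by ``root_divergence`` each,
    so between-family identity sits near the configured background while
    within-family identity stays high.
    """
    if spec.n_families < 2:
        raise ValueError("need at least 2 families")
    if spec.seqs_per_family < 2:
        raise ValueError("seqs_per_family must be >= 2")
    if not 0 <= holdout < spec.seqs_per_family:
        raise ValueError("holdout must leave at least one panel member")
    names = list(families) if families else [
        DEFAULT_FAMILIES[i] if i < 3 else f"fam{i + 1}"
        for i in range(spec.n_families)
    ]
    rng = np.random.default_rng(spec.seed)
    grand_root = _random_sequence(rng, spec.root_length)
    panels: dict[str, list[ProteinRecord]] = {}
    queries: list[ProteinRecord] = []
    truth = SyntheticTruth()
    for fam in names:
        fam_root = evolve(grand_root, spec.root_divergence, rng)
        records, ftruth = simulate_family(
            spec, family=fam, rng=rng, root_seq=fam_root
        )
        truth.trees.update(ftruth.trees)
        truth.family_of.update(ftruth.family_of)
        panels[fam] = records[holdout:]
        for rec in records[:holdout]:
            queries.append(replace(rec, family_label=None))
    return panels, queries, truth


def decoy_records(
    rng: np.random.Generator, n: int, length: int, species: str = "synthetic"
) -> list[ProteinRecord]:
    """Unrelated uniform-random proteins (discovery negatives)."""
    return [
        ProteinRecord(
            id=f"decoy_{i + 1}",
            sequence=_decode(_random_sequence(rng, length)),
            species=species,
        )
        for i in range(n)
    ]


def annotations_from_sites(
    sites: Sequence[SiteSpec], ref_seq_id: str
) -> list[BindingSiteAnnotation]:
    """Binding-site annotations for a reference protein that carries every
    implanted site at its exact position."""
    return [
        BindingSiteAnnotation(
            site_id=s.site_id,
            pigment_class=s.pigment_class,
            ligand_class=s.ligand_class,
            ref_seq_id=ref_seq_id,
            ref_pos=s.position,
            primary_residue=s.residue,
            alternate_residues=s.alternate_residues,
            conserved_flag=s.conserved_flag,
        )
        for s in sites
    ]


def default_binding_sites(
    n_chl: int = 9, n_fx: int = 5, retention: float = 0.9,
    start: int = 20, spacing: int = 12,
) -> tuple[SiteSpec, ...]:
    """Evenly spaced chlorophyll and fucoxanthin sites for simulations."""
    residues = "EHQKNGFLRY"
    sites = []
    for k in range(n_chl):
        sites.append(
            SiteSpec(
                site_id=f"Chl a{401 + k}",
                position=start + spacing * k,
                residue=residues[k % len(residues)],
                retention=retention,
                pigment_class="chl_a" if k % 3 else "chl_c",
            )
        )
    for k in range(n_fx):
        sites.append(
            SiteSpec(
                site_id=f"Fx{301 + k}",
                position=start + spacing * (n_chl + k),
                residue=residues[(n_chl + k) % len(residues)],
                retention=retention,
                pigment_class="fx",
            )
        )
    return tuple(sites)


def write_fixture_dataset(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small canned dataset (panels, proteome, annotations, truth)
    used by the test suite and the worked example."""
    from . import seqio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = SimulationSpec(
        n_families=3, seqs_per_family=8, root_length=120, seed=seed,
        site_spec=default_binding_sites(n_chl=3, n_fx=2, retention=0.9,
                                        start=10, spacing=12),
    )
    panels, queries, truth = simulate_classification_panel(spec, holdout=3)
    rng = np.random.default_rng([spec.seed, 999])
    proteome = queries + decoy_records(rng, 10, spec.root_length)
    paths: dict[str, Path] = {}
    for fam, records in panels.items():
        paths[f"panel_{fam}"] = outdir / f"panel_{fam}.fasta"
        seqio.write_fasta(records, paths[f"panel_{fam}"])
    paths["proteome"] = outdir / "proteome.fasta"
    seqio.write_fasta(proteome, paths["proteome"])
    anns = annotations_from_sites(spec.site_spec, panels["lhcf"][0].id)
    paths["annotations"] = outdir / "binding_sites.tsv"
    # panel members were not force-implanted; rewrite the reference row so
    # the annotation TSV validates against it
    ref = panels["lhcf"][0]
    seq = list(ref.sequence)
    for s in spec.site_spec:
        seq[s.position - 1] = s.residue
    ref.sequence = "".join(seq)
    seqio.write_fasta(panels["lhcf"], paths[f"panel_lhcf"])
    seqio.write_site_annotations(anns, paths["annotations"])
    paths["truth"] = outdir / "truth_labels.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("seq_id\tfamily\n")
        for seq_id in sorted(truth.family_of):
            fh.write(f"{seq_id}\t{truth.family_of[seq_id]}\n")
    return paths
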