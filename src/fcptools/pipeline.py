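"""End-to-end orchestration: discover -> classify -> tree -> site transfer.

``run_pipeline`` wires the stage modules together from a single ``Config``
and writes all artefacts (candidate FASTA, assignment TSV, Newick trees
with bootstrap supports, site report TSVs, and a JSON run manifest) into
one output directory.  Every output is a deterministic function of config,
inputs and seed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, homology, msa, phylo, seqio, site_transfer

logger = logging.getLogger(__name__)


@dataclass
class Config:
    """Pipeline parameters; defaults follow the classical survey settings
    (E-value cutoff 1e-40, BLOSUM62 11/1 gaps, 100 bootstrap replicates,
    residue shift window 3)."""

    proteome: str = ""
    panels: dict[str, str] = field(default_factory=dict)
    annotations: str = ""
    annotation_refs: str = ""
    outdir: str = "fcp_out"
    e_threshold: float = 1e-40
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    margin_bits: float = 10.0
    min_labeled: int = 3
    bootstrap_reps: int = 100
    shift_window: int = 3
    min_support: float = 50.0
    min_size: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.e_threshold < 0:
            raise ValueError("e_threshold must be non-negative")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.shift_window < 0:
            raise ValueError("shift_window must be >= 0")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def write_assignments(assignments, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["seq_id", "best_family", "best_hit_id", "best_e_value",
             "margin", "ambiguous", "final_family", "evidence"]
        )
        for a in assignments:
            w.writerow(
                [a.seq_id, a.best_family, a.best_hit_id or "",
                 f"{a.best_e_value:.6g}", f"{a.margin:.3f}",
                 str(a.ambiguous).lower(), a.final_family or "", a.evidence]
            )


def run_pipeline(config: Config) -> dict:
    """Run every stage and return the manifest dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failure_marker = outdir / "FAILED"
    if failure_marker.exists():
        failure_marker.unlink()
    try:
        manifest = _run(config, outdir)
    except Exception as exc:
        failure_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _run(config: Config, outdir: Path) -> dict:
    matrix = homology.SubstitutionMatrix.from_name(config.matrix_name)
    proteome = seqio.read_fasta(config.proteome)
    panels = {
        fam: seqio.read_fasta(path) for fam, path in config.panels.items()
    }
    for fam, records in panels.items():
        for rec in records:
            rec.family_label = fam
    logger.info("stage=load proteome=%d panels=%s", len(proteome),
                {f: len(r) for f, r in panels.items()})

    # --- discovery ---
    queries = [r for fam in sorted(panels) for r in panels[fam]]
    candidates = homology.discover_fcp(
        proteome, queries, config.e_threshold, matrix
    )
    seqio.write_fasta(candidates, outdir / "candidates.fasta")
    logger.info("stage=discover candidates=%d", len(candidates))

    # --- best-hit classification ---
    assignments = [
        homology.assign_family(
            c, panels, config.e_threshold, config.margin_bits, matrix
        )
        for c in candidates
    ]

    # --- tree over candidates + panel members ---
    tree = None
    all_records = candidates + queries
    if len(all_records) >= 4:
        alignment = msa.progressive_align(
            all_records, matrix, config.gap_open, config.gap_extend
        )
        msa.write_aligned_fasta(alignment, outdir / "all_aligned.fasta")
        if config.bootstrap_reps > 0:
            tree = phylo.bootstrap_support(
                alignment, config.bootstrap_reps, config.seed
            )
        else:
            tree = phylo.nj_tree(alignment)
        phylo.write_newick(tree, outdir / "cladogram.nwk")
    panel_labels = {
        r.id: fam for fam, records in panels.items() for r in records
    }
    if tree is not None:
        assignments = homology.reconcile_with_clades(
            assignments, tree, panel_labels, config.min_labeled
        )
    else:
        from dataclasses import replace

        assignments = [
            replace(a, final_family=a.best_family if not a.ambiguous
                    else "unclassified")
            for a in assignments
        ]
    write_assignments(assignments, outdir / "assignments.tsv")
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.final_family] = counts.get(a.final_family, 0) + 1
    logger.info("stage=classify counts=%s", counts)

    # --- binding-site transfer onto Lhcf members ---
    site_counts = {}
    if config.annotations:
        refs = seqio.read_fasta(config.annotation_refs or
                                config.panels.get("lhcf", ""))
        anns = seqio.read_site_annotations(config.annotations, refs)
        lhcf_targets = [
            a.seq_id for a in assignments if a.final_family == "lhcf"
        ]
        target_records = [c for c in candidates if c.id in set(lhcf_targets)]
        ref_ids = {a.ref_seq_id for a in anns}
        ref_records = [r for r in refs if r.id in ref_ids]
        alignment = msa.progressive_align(
            ref_records + target_records, matrix,
            config.gap_open, config.gap_extend,
        )
        summaries = []
        all_calls = []
        for ann in anns:
            calls = site_transfer.transfer_site(
                alignment, ann, lhcf_targets, config.shift_window
            )
            all_calls.extend(calls)
            summaries.append(site_transfer.summarize_site(calls, ann))
        report = site_transfer.build_site_report(summaries)
        report.to_csv(outdir / "site_report.tsv", sep="\t", index=False)
        with open(outdir / "site_calls.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["site_id", "target_id", "present", "residue",
                        "offset", "via_alternate"])
            for c in all_calls:
                w.writerow([c.site_id, c.target_id,
                            str(c.present).lower(), c.matched_residue or "",
                            "" if c.offset is None else c.offset,
                            str(c.via_alternate).lower()])
        n_chl, n_fx = site_transfer.count_sites_found(summaries)
        site_counts = {"n_chl_sites_found": n_chl, "n_fx_sites_found": n_fx}
        logger.info("stage=sites chl=%d fx=%d", n_chl, n_fx)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "counts": {
            "proteome": len(proteome),
            "candidates": len(candidates),
            "families": counts,
            **site_counts,
        },
    }
    return manifest
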