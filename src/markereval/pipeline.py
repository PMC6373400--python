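"""End-to-end marker evaluation: conservation → identity partition →
diagnostic SNPs → distance tree → species clustering, with one structured
report bundle.

Every stage writes its own TSV/JSON/Newick artifact into the output
directory and contributes to ``summary.json``; the plain-text ``summary.txt``
prints the same numbers (rounded for display, full precision in the JSON).
Reruns with identical config and seed produce byte-identical outputs — no
timestamps, sorted JSON keys, deterministic tree construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from . import conservation, diagnostics, identity, phylogeny
from .alignment import (
    Alignment,
    CoordinateMap,
    StrainTable,
    read_alignment,
    read_strain_table,
)

logger = logging.getLogger("markereval.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    alignment_path: Union[str, Path]
    strain_table_path: Union[str, Path]
    output_dir: Union[str, Path]
    target_species: Optional[str] = None      # None → diagnostics for every species
    reference_strain: Optional[str] = None    # None → first alignment record
    gene_offset: int = 0
    frame_start: int = 1
    reference_gene_path: Optional[Union[str, Path]] = None
    distance_model: str = "k2p"
    bootstrap_replicates: int = 100
    seed: int = 0
    support_threshold: float = 70.0
    ambiguity: str = "exclude"
    diagnostics_mode: str = "strict"
    max_exceptions: int = 0


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the summary dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info(
        "config: model=%s B=%d seed=%d ambiguity=%s diagnostics=%s(%d) "
        "support_threshold=%.0f",
        config.distance_model, config.bootstrap_replicates, config.seed,
        config.ambiguity, config.diagnostics_mode, config.max_exceptions,
        config.support_threshold,
    )

    aln, table = _load(config)
    summary: dict = {
        "n_strains": aln.n_sequences,
        "n_species": len(table.species_labels()),
        "n_columns": aln.length,
        "settings": {
            "distance_model": config.distance_model,
            "bootstrap_replicates": config.bootstrap_replicates,
            "seed": config.seed,
            "ambiguity": config.ambiguity,
            "diagnostics_mode": config.diagnostics_mode,
            "max_exceptions": config.max_exceptions,
            "support_threshold": config.support_threshold,
            "gene_offset": config.gene_offset,
            "frame_start": config.frame_start,
        },
    }

    summary["conservation"] = _run_conservation(aln, out)
    summary["identity"] = _run_identity(aln, table, config, out)
    summary["diagnostics"] = _run_diagnostics(aln, table, config, out)
    summary["phylogeny"] = _run_phylogeny(aln, table, config, out)

    _json_dump(summary, out / "summary.json")
    (out / "summary.txt").write_text(_render_text(summary))
    return summary


@_stage("load")
def _load(config: PipelineConfig):
    aln = read_alignment(config.alignment_path)
    table = read_strain_table(config.strain_table_path)
    missing = [sid for sid in aln.ids if sid not in table]
    if missing:
        raise ValueError(f"strains missing from table: {missing}")
    if config.target_species is not None and config.target_species not in table.species_labels():
        raise ValueError(f"target species {config.target_species!r} not in table")
    return aln, table


@_stage("conservation")
def _run_conservation(aln: Alignment, out: Path) -> dict:
    report = conservation.count_variable_sites(aln)
    conservation.write_conservation_report(aln, out / "conservation.tsv", report)
    return {
        "n_columns": report.n_columns,
        "n_variable": report.n_variable,
        "fraction_variable": report.fraction_variable,
    }


@_stage("identity")
def _run_identity(aln, table, config: PipelineConfig, out: Path) -> dict:
    m = identity.identity_matrix(aln, ambiguity=config.ambiguity)
    identity.write_identity_matrix(m, out / "identity_matrix.tsv")
    part = identity.partition_similarities(m, table)
    result = part.summary()
    result["intra_range_full"] = list(part.intra_range) if part.intra_range else None
    result["inter_range_full"] = list(part.inter_range) if part.inter_range else None
    result["gap_full"] = part.gap
    _json_dump(result, out / "similarity.json")
    return result


@_stage("diagnostics")
def _run_diagnostics(aln, table, config: PipelineConfig, out: Path) -> dict:
    species_list = (
        [config.target_species]
        if config.target_species is not None
        else table.species_labels()
    )
    cmap = None
    reference_gene = None
    if config.reference_strain is not None:
        cmap = CoordinateMap(
            config.reference_strain, config.gene_offset, config.frame_start
        )
        if config.reference_gene_path is not None:
            reference_gene = _read_single_fasta(config.reference_gene_path)
    panel = []
    skipped: dict = {}
    for species in species_list:
        targets = [
            s for s in aln.ids
            if s in table and table.is_labeled(s) and table.species_of(s) == species
        ]
        background = [
            s for s in aln.ids
            if s in table and table.is_labeled(s) and table.species_of(s) != species
        ]
        if not targets or not background:
            reason = "no target strains" if not targets else "no background strains"
            skipped[species] = reason
            logger.info("diagnostics skipped for %s: %s", species, reason)
            continue
        sites = diagnostics.find_diagnostic_snps(
            aln, table, species,
            mode=config.diagnostics_mode,
            max_exceptions=config.max_exceptions,
        )
        if cmap is not None:
            annotated = []
            for site in sites:
                try:
                    annotated.append(
                        diagnostics.annotate_site(site, aln, cmap, reference_gene)
                    )
                except ValueError as exc:
                    logger.info(
                        "annotation skipped for %s column %d: %s",
                        site.species, site.column, exc,
                    )
                    annotated.append(site)
            sites = annotated
        panel.extend(sites)
    diagnostics.write_panel(panel, out / "diagnostic_panel.tsv")
    per_species: dict = {}
    for site in panel:
        per_species.setdefault(site.species, 0)
        per_species[site.species] += 1
    result = {
        "n_sites": len(panel),
        "sites_per_species": per_species,
        "skipped": skipped,
        "sites": [
            {
                "species": s.species,
                "column": s.column,
                "state": s.state,
                "background_states": "".join(sorted(s.background_states)),
                "n_background_with_state": s.n_background_with_state,
                "gene_position": s.gene_position,
                "codon_index": None if s.codon is None else s.codon.codon_index,
                "codon_position": None if s.codon is None else s.codon.codon_position,
                "is_synonymous": None if s.codon is None else s.codon.is_synonymous,
            }
            for s in panel
        ],
    }
    _json_dump(result, out / "diagnostics.json")
    return result


@_stage("phylogeny")
def _run_phylogeny(aln, table, config: PipelineConfig, out: Path) -> dict:
    if aln.n_sequences < 3:
        reason = "fewer than 3 strains; neighbor-joining needs >= 3"
        logger.info("phylogeny skipped: %s", reason)
        return {"skipped": reason}
    dm = phylogeny.distance_matrix(aln, model=config.distance_model)
    dm.write_tsv(out / "distances.tsv")
    tree = phylogeny.bootstrap_support(
        aln,
        model=config.distance_model,
        B=config.bootstrap_replicates,
        seed=config.seed,
    )
    phylogeny.write_newick(tree, out / "tree.nwk")
    _write_display_tree(tree, config.support_threshold, out / "tree_display.nwk")
    report = phylogeny.species_cluster_report(tree, table)
    clusters = {
        sp: {
            "n_strains": r.n_strains,
            "is_monophyletic": r.is_monophyletic,
            "support": r.support,
            "outliers": list(r.outliers),
        }
        for sp, r in report.items()
    }
    _json_dump(clusters, out / "clusters.json")
    multi = [r for r in report.values() if r.n_strains >= 2]
    return {
        "model": dm.model,
        "bootstrap_replicates": config.bootstrap_replicates,
        "bootstrap_skipped": getattr(tree, "bootstrap_skipped", 0),
        "n_species_multi_strain": len(multi),
        "n_monophyletic": sum(1 for r in multi if r.is_monophyletic),
        "outlier_strains": sorted(
            s for r in report.values() for s in r.outliers
        ),
        "clusters": clusters,
    }


def _write_display_tree(tree, threshold: float, path: Path) -> None:
    """Copy of the tree with supports below the display threshold blanked,
    mirroring the usual 'values >= 70% shown' figure convention."""
    import dendropy

    clone = dendropy.Tree(tree)
    for node in clone.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            if float(node.label) < threshold:
                node.label = None
        except ValueError:
            pass
    phylogeny.write_newick(clone, path)


def _read_single_fasta(path: Union[str, Path]) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one sequence in {path}")
    return str(records[0].seq).upper().replace("U", "T")


def _render_text(summary: dict) -> str:
    cons = summary["conservation"]
    ident = summary["identity"]
    diag = summary["diagnostics"]
    phy = summary["phylogeny"]
    lines = [
        "marker evaluation summary",
        "=========================",
        f"strains: {summary['n_strains']}   species: {summary['n_species']}   "
        f"columns: {summary['n_columns']}",
        "",
        f"variable sites: {cons['n_variable']}/{cons['n_columns']} "
        f"({cons['fraction_variable']:.3f})",
        "",
        f"intraspecific identity range: {_fmt_range(ident['intra_range'])} %",
        f"interspecific identity range: {_fmt_range(ident['inter_range'])} %",
        f"barcoding gap (min intra - max inter): {_fmt(ident['gap'])} points "
        f"-> {'gap present' if ident['has_gap'] else 'no gap'}",
        "",
        f"diagnostic sites: {diag['n_sites']}"
        + (
            "  (" + ", ".join(
                f"{sp}: {n}" for sp, n in sorted(diag["sites_per_species"].items())
            ) + ")"
            if diag["sites_per_species"] else ""
        ),
        "",
    ]
    if "skipped" in phy:
        lines.append(f"tree: skipped ({phy['skipped']})")
    else:
        lines += [
            f"tree: {phy['model']} + NJ, {phy['bootstrap_replicates']} bootstrap "
            f"replicates ({phy['bootstrap_skipped']} skipped)",
            f"monophyletic species: {phy['n_monophyletic']}/"
            f"{phy['n_species_multi_strain']} (of species with >= 2 strains)",
            f"outlier strains: {', '.join(phy['outlier_strains']) or 'none'}",
            "",
            "note: the distance/NJ tree is a clustering surrogate; comparisons "
            "with likelihood trees are qualitative (cluster membership), not "
            "branch-for-branch.",
        ]
    return "\n".join(lines) + "\n"


def _fmt(x) -> str:
    return "n/a" if x is None else f"{x:.1f}"


def _fmt_range(r) -> str:
    return "n/a" if r is None else f"{r[0]:.1f}-{r[1]:.1f}"
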