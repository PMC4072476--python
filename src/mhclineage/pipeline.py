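"""End-to-end orchestration: screen -> mask -> distances -> date -> compat -> map.

`run_pipeline` executes the analysis stages in their fixed order, persists
every intermediate as TSV/FASTA/JSON under the output directory, and returns
a report whose numbers are taken directly from the stage results (no
recomputation).  Sequences with internal stop codons are dropped at
ingestion (the full-length-CDS filter); recombinant screening runs before
any distance is computed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alleles_io import (
    AlleleSet,
    RegionMask,
    apply_region_mask,
    read_fasta,
    read_mask,
    write_fasta,
)
from .codon_evol import (
    STOP_CODONS,
    distance_matrices,
    group_summary,
)
from .divergence_dating import ClockConfig, date_groups, dating_table
from .parsimony_map import Phylogeny, fitch_map, ks_matrix
from .recomb_screen import ScreenConfig, flags_table, screen_recombinants
from .site_compat import compatibility_report, site_table

logger = logging.getLogger("mhclineage")


@dataclass
class RunConfig:
    fasta: str
    outdir: str
    newick: "str | None" = None
    outgroup: "str | None" = None
    mask_file: "str | None" = None
    mask_offset: int = 0
    mask_mode: str = "exclude"
    groups_file: "str | None" = None  # TSV: name<TAB>group
    kappa: float = 1.0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    clock: ClockConfig = field(default_factory=ClockConfig)
    run_screen: bool = True
    run_compat: bool = True
    synonymous_only: bool = True


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def has_internal_stop(seq: str) -> bool:
    n = len(seq) // 3
    for c in range(n - 1):  # terminal codon may be a stop
        if seq[3 * c : 3 * c + 3] in STOP_CODONS:
            return True
    return False


def full_length_filter(a: AlleleSet) -> tuple[AlleleSet, list[str]]:
    """Drop sequences with internal stop codons; return (kept, dropped)."""
    dropped = [
        n.raw
        for n, s in zip(a.names, a.sequences)
        if has_internal_stop(s)
    ]
    if not dropped:
        return a, []
    return a.subset(set(a.name_strings()) - set(dropped)), dropped


def read_groups(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, group = line.split("\t")[:2]
        out[name] = group
    return out


def label_groups_by_root_split(t: Phylogeny) -> dict[str, str]:
    """Helper: label leaves A/B by the two clades under the root."""
    children = t.tree.seed_node.child_nodes()
    labels: dict[str, str] = {}
    for tag, child in zip("ABCDEFGH", children):
        for leaf in child.leaf_iter():
            if leaf.taxon is not None:
                labels[leaf.taxon.label] = tag
    return labels


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; persist intermediates; return the run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # --- ingest -----------------------------------------------------------
    s = stage("ingest")
    try:
        alleles = read_fasta(cfg.fasta)
        alleles, dropped = full_length_filter(alleles)
        report["stages"][s] = {
            "n_input": len(alleles) + len(dropped),
            "n_kept": len(alleles),
            "dropped_internal_stop": dropped,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e

    # --- screen -----------------------------------------------------------
    s = stage("screen")
    try:
        if cfg.run_screen:
            sr = screen_recombinants(alleles, cfg.screen)
            flags_table(sr).to_csv(
                outdir / "screen_flags.tsv", sep="\t", index=False
            )
            write_fasta(sr.retained, outdir / "screened.fasta")
            alleles = sr.retained
            report["stages"][s] = {
                "removed": sr.removed,
                "n_flagged_windows": len(sr.flagged),
                "corrected_alpha": sr.corrected_alpha,
                "n_retained": len(alleles),
            }
        else:
            report["stages"][s] = {"skipped": True}
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e

    # --- mask -------------------------------------------------------------
    s = stage("mask")
    try:
        if cfg.mask_file is not None:
            mask = read_mask(cfg.mask_file, offset=cfg.mask_offset)
            analysed = apply_region_mask(alleles, mask, mode=cfg.mask_mode)
            report["stages"][s] = {
                "mode": cfg.mask_mode,
                "mask_codons": len(mask.codon_positions),
                "n_codons_out": analysed.n_codons,
            }
        else:
            analysed = alleles
            report["stages"][s] = {"skipped": True}
        write_fasta(analysed, outdir / "analysed.fasta")
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e

    # --- distances + dating ----------------------------------------------
    s = stage("distances")
    try:
        dmat = distance_matrices(analysed, kappa=cfg.kappa)
        import pandas as pd

        pd.DataFrame(
            dmat.dS, index=dmat.names, columns=dmat.names
        ).to_csv(outdir / "dS.tsv", sep="\t")
        pd.DataFrame(
            dmat.dN, index=dmat.names, columns=dmat.names
        ).to_csv(outdir / "dN.tsv", sep="\t")
        labels = (
            read_groups(cfg.groups_file) if cfg.groups_file else None
        )
        summaries = group_summary(dmat, labels)
        dated = date_groups(summaries, cfg.clock)
        table = dating_table(dated)
        table.to_csv(outdir / "dating.tsv", sep="\t", index=False)
        report["stages"][s] = {
            "kappa": cfg.kappa,
            "LS_mean": dmat.LS_mean,
            "saturated_pairs": len(dmat.saturated_pairs),
        }
        report["dating"] = table.to_dict(orient="records")
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e

    # --- compatibility ----------------------------------------------------
    s = stage("compat")
    try:
        if cfg.run_compat:
            rep = compatibility_report(
                analysed, synonymous_only=cfg.synonymous_only
            )
            site_table(rep.site_classes).to_csv(
                outdir / "sites.tsv", sep="\t", index=False
            )
            report["stages"][s] = {
                "n_informative": len(rep.informative_sites),
                "n_pairs": rep.n_pairs,
                "n_incompatible": rep.n_incompatible,
            }
        else:
            report["stages"][s] = {"skipped": True}
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e

    # --- parsimony re-count ----------------------------------------------
    s = stage("map")
    try:
        if cfg.newick is not None:
            phylo = Phylogeny.from_file(cfg.newick, outgroup=cfg.outgroup)
            present = set(analysed.name_strings())
            tree_leaves = [l for l in phylo.leaf_names() if l in present]
            pruned = Phylogeny.from_newick(
                phylo.newick(), outgroup=None
            )
            missing = set(pruned.leaf_names()) - present
            if missing:
                pruned.tree.retain_taxa_with_labels(tree_leaves)
            classes = None
            sites = None
            if cfg.synonymous_only:
                from .site_compat import classify_sites

                sub = analysed.subset(tree_leaves)
                classes = classify_sites(sub)
                sites = [
                    c.column
                    for c in classes
                    if c.is_segregating and c.effect == "synonymous"
                ]
                bmap = fitch_map(pruned, sub, sites=sites)
            else:
                bmap = fitch_map(pruned, analysed.subset(tree_leaves))
            km = ks_matrix(bmap, pruned)
            pd.DataFrame(
                km.matrix, index=km.names, columns=km.names
            ).to_csv(outdir / "ks_matrix.tsv", sep="\t")
            from .divergence_dating import round_mya, tmrca_from_ks

            tm = tmrca_from_ks(km.ks_max, dmat.LS_mean, cfg.clock)
            report["stages"][s] = {
                "n_sites_mapped": len(bmap.sites),
                "total_changes": bmap.total_changes,
                "ks_max": km.ks_max,
                "LS_mean": dmat.LS_mean,
                "tmrca_recount_years": tm,
                "tmrca_recount_mya": round_mya(tm),
            }
        else:
            report["stages"][s] = {"skipped": True}
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e

    payload = json.dumps(report, indent=1, sort_keys=True, default=str)
    report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str)
    )
    return report
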