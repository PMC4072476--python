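"""Synthetic allele-set generator with ground truth.

Emulates aligned MHC-class-II-like coding alignments: a random in-frame
ancestral sequence evolves down a tree (supplied newick or random Yule) with
transition bias ``kappa``, an elevated nonsynonymous rate inside a
peptide-binding-region codon mask, and optional splice recombinants.
Branch lengths are in expected synonymous substitutions per synonymous
site, so a two-leaf tree ``(A:0.01,B:0.01)`` yields dS near 0.02.

Selection is modeled by proposal thinning/boosting: nucleotide changes are
proposed at the neutral rate, synonymous changes are always accepted,
nonsynonymous changes are accepted with probability ``omega`` when
``omega <= 1`` and proposed at an ``omega``-fold rate when ``omega > 1``
(stop-creating changes are always rejected).  This is a deliberately simple
stand-in for a full codon substitution model; the synonymous process it
induces is the neutral clock the analyses assume.

Ground truth — the tree, realized per-branch synonymous/nonsynonymous
change counts, per-pair synonymous path counts and the recombinant
registry — is recorded so every downstream stage can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .alleles_io import AlleleName, AlleleSet, RegionMask
from .codon_evol import (
    NUCS,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
    translate_codon,
)
from .parsimony_map import Phylogeny, _node_key

DEFAULT_PBR_POSITIONS = frozenset(
    {9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65, 67, 68,
     70, 71, 74, 78, 81, 82, 85, 86, 89, 90}
)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults mirror a DRB1-like allele set.

    257 codons with a 27-codon PBR mask leave a 690-nt non-PBR region;
    ``branch_scale`` is the expected root-to-tip synonymous divergence used
    when a random Yule tree is generated (ignored when ``tree`` is given,
    whose branch lengths are then taken as-is).
    """

    seed: int = 0
    n_alleles: int = 30
    n_codons: int = 257
    tree: "str | None" = None  # newick with branch lengths, or None -> Yule
    branch_scale: float = 0.03
    kappa: float = 2.0
    omega_background: float = 0.5
    omega_pbr: float = 5.0
    pbr_mask: "RegionMask | None" = None
    infinite_sites: bool = False
    recombinants: tuple = ()  # (parent1, parent2, breakpoint_codon)

    def __post_init__(self) -> None:
        if self.n_alleles < 2 or self.n_codons < 2:
            raise ValueError("need at least 2 alleles and 2 codons")
        if self.branch_scale < 0:
            raise ValueError("branch_scale must be non-negative")
        if self.omega_background < 0 or self.omega_pbr < 0:
            raise ValueError("omega values must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the sequences."""

    newick: str
    branch_syn: dict[str, int]
    branch_nonsyn: dict[str, int]
    syn_columns: list[int]  # 0-based columns hit by >=1 synonymous change
    pair_syn_path: dict[str, int]  # "name1|name2" -> path sum of syn changes
    recombinants: list[dict]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _random_yule_tree(
    n_leaves: int, depth: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Ultrametric Yule tree scaled to the requested root-to-tip depth."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.birth_time = 0.0
    tips = [tree.seed_node]
    now = 0.0
    while len(tips) < n_leaves:
        now += rng.exponential(1.0 / len(tips))
        idx = rng.integers(len(tips))
        parent = tips.pop(int(idx))
        parent.split_time = now
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = now
            tips.append(child)
    now += rng.exponential(1.0 / len(tips))
    for i, tip in enumerate(tips):
        tip.taxon = taxa.new_taxon(label=f"SIM-DRB1*{i + 1:02d}:01")
        tip.split_time = now
    for node in tree.preorder_node_iter():
        node.edge.length = (
            0.0
            if node.parent_node is None
            else node.split_time - node.birth_time
        )
    scale = depth / now if now > 0 else 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def _random_ancestor(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def make_recombinant(s1: str, s2: str, breakpoint_codon: int) -> str:
    """Splice: first ``breakpoint_codon`` codons of s1, remainder of s2."""
    if len(s1) != len(s2):
        raise ValueError("parent sequences differ in length")
    n_codons = len(s1) // 3
    if not 0 < breakpoint_codon < n_codons:
        raise ValueError(
            f"breakpoint must be strictly inside 1..{n_codons - 1}"
        )
    cut = 3 * breakpoint_codon
    return s1[:cut] + s2[cut:]


def _evolve_branch(
    seq: list[str],
    length: float,
    region_sites: dict[float, np.ndarray],
    kappa: float,
    rng: np.random.Generator,
    infinite_sites: bool,
    hit_columns: set[int],
) -> tuple[int, int, list[int]]:
    """Mutate ``seq`` in place along one branch; return (syn, nonsyn, syn_cols).

    ``region_sites`` maps omega -> array of nucleotide positions evolving
    under that omega.
    """
    n_syn = n_nonsyn = 0
    syn_cols: list[int] = []
    trans = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for omega, positions in region_sites.items():
        if positions.size == 0 or length == 0.0:
            continue
        multiplier = max(1.0, omega)
        n_prop = rng.poisson(length * positions.size * multiplier)
        for _ in range(n_prop):
            col = int(positions[rng.integers(positions.size)])
            if infinite_sites and col in hit_columns:
                continue
            codon_idx, pos = divmod(col, 3)
            codon = "".join(seq[3 * codon_idx : 3 * codon_idx + 3])
            cur = codon[pos]
            # target choice with transition bias
            u = rng.random() * (kappa + 2.0)
            if u < kappa:
                alt = trans[cur]
            else:
                tv = [b for b in NUCS if b != cur and b != trans[cur]]
                alt = tv[0] if u < kappa + 1.0 else tv[1]
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            synonymous = translate_codon(mut) == translate_codon(codon)
            if synonymous:
                accept = rng.random() < 1.0 / multiplier
            else:
                accept = rng.random() < omega / multiplier
            if not accept:
                continue
            seq[col] = alt
            hit_columns.add(col)
            if synonymous:
                n_syn += 1
                syn_cols.append(col)
            else:
                n_nonsyn += 1
    return n_syn, n_nonsyn, syn_cols


def simulate(cfg: SimConfig) -> tuple[AlleleSet, SimTruth]:
    """Generate an allele set and its ground truth; same seed, same bytes."""
    rng = np.random.default_rng(cfg.seed)
    n_nt = 3 * cfg.n_codons
    if cfg.infinite_sites and n_nt < 50:
        raise ValueError("infinite_sites needs a reasonably long alignment")

    if cfg.tree is not None:
        tree = dendropy.Tree.get(
            data=cfg.tree, schema="newick", preserve_underscores=True
        )
    else:
        tree = _random_yule_tree(cfg.n_alleles, cfg.branch_scale, rng)
    phylo = Phylogeny(tree=tree)
    phylo._label_internals()

    mask = cfg.pbr_mask
    if mask is None:
        positions = {p for p in DEFAULT_PBR_POSITIONS if p <= cfg.n_codons}
        mask = RegionMask(codon_positions=frozenset(positions), offset=0)
    pbr_codons = mask.alignment_codons(cfg.n_codons)
    pbr_nt = np.array(
        sorted(i for c in pbr_codons for i in range(3 * c, 3 * c + 3)),
        dtype=int,
    )
    bg_nt = np.array(
        sorted(set(range(n_nt)) - set(pbr_nt.tolist())), dtype=int
    )
    regions = {cfg.omega_background: bg_nt, cfg.omega_pbr: pbr_nt}
    if cfg.omega_background == cfg.omega_pbr:
        regions = {cfg.omega_background: np.arange(n_nt)}

    ancestor = list(_random_ancestor(cfg.n_codons, rng))
    hit_columns: set[int] = set()
    branch_syn: dict[str, int] = {}
    branch_nonsyn: dict[str, int] = {}
    syn_columns: set[int] = set()
    leaf_seqs: dict[str, str] = {}

    def descend(node: dendropy.Node, seq: list[str]) -> None:
        for child in node.child_nodes():
            child_seq = list(seq)
            ns, nn, cols = _evolve_branch(
                child_seq,
                child.edge.length or 0.0,
                regions,
                cfg.kappa,
                rng,
                cfg.infinite_sites,
                hit_columns,
            )
            key = _node_key(child)
            branch_syn[key] = ns
            branch_nonsyn[key] = nn
            syn_columns.update(cols)
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = "".join(child_seq)
            else:
                descend(child, child_seq)

    descend(tree.seed_node, ancestor)

    names = [AlleleName.parse(n) for n in sorted(leaf_seqs)]
    seqs = [leaf_seqs[n.raw] for n in names]

    # per-pair synonymous path counts from branch truth
    pair_syn: dict[str, int] = {}
    leaf_names = sorted(leaf_seqs)
    from .parsimony_map import _path_edges

    for i, n1 in enumerate(leaf_names):
        for n2 in leaf_names[i + 1 :]:
            total = sum(
                branch_syn.get(e, 0) for e in _path_edges(phylo, n1, n2)
            )
            pair_syn[f"{n1}|{n2}"] = total

    rec_registry: list[dict] = []
    for ridx, (p1, p2, bp) in enumerate(cfg.recombinants, start=1):
        child = make_recombinant(leaf_seqs[p1], leaf_seqs[p2], bp)
        rname = f"recombinant_{ridx}"
        names.append(AlleleName.parse(rname))
        seqs.append(child)
        rec_registry.append(
            {"name": rname, "parent1": p1, "parent2": p2,
             "breakpoint_codon": bp}
        )

    alleles = AlleleSet(names=names, sequences=seqs)
    truth = SimTruth(
        newick=phylo.newick(),
        branch_syn=branch_syn,
        branch_nonsyn=branch_nonsyn,
        syn_columns=sorted(syn_columns),
        pair_syn_path=pair_syn,
        recombinants=rec_registry,
        seed=cfg.seed,
    )
    return alleles, truth
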