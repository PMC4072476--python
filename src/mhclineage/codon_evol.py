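"""Codon-level synonymous/nonsynonymous distances.

Implements the modified Nei–Gojobori method: potential synonymous and
nonsynonymous site counts weight transitions by a bias factor ``kappa``
(transversions weight 1; ``kappa=1`` recovers the classic NG86 counts),
observed differences between codons are averaged over all mutational
pathways, and proportions are corrected with the Jukes–Cantor formula

    d = -(3/4) * ln(1 - 4p/3).

Pairwise matrices use pairwise deletion of codons containing gaps or N, and
the site denominator for a pair is the average of the two sequences' counts,
as in NG86.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

from .alleles_io import AlleleSet

NUCS = "ACGT"
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in (a + b + d for a in NUCS for b in NUCS for d in NUCS)
           if c not in STOP_CODONS)
)


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or ``*`` for a stop codon."""
    return "*" if codon in STOP_CODONS else CODON_TABLE[codon]


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITION


class SaturationError(ValueError):
    """Proportion of differences at or beyond the Jukes–Cantor domain (3/4)."""


@dataclass(frozen=True)
class SiteCounts:
    """Potential synonymous (S) and nonsynonymous (N) site counts."""

    S: float
    N: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.S + other.S, self.N + other.N)


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(c not in NUCS for c in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon not allowed: {codon}")


def count_sites(codon: str, kappa: float = 1.0) -> SiteCounts:
    """Bias-weighted potential site counts for one codon.

    Each of the three positions contributes one site, split into a
    synonymous fraction equal to the kappa-weighted share of the three
    possible single-nucleotide changes that are synonymous (transitions
    weight ``kappa``, transversions weight 1).  Changes creating a stop
    codon count as nonsynonymous.
    """
    _check_codon(codon)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    aa = translate_codon(codon)
    S = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            w = kappa if is_transition(codon[pos], alt) else 1.0
            tot_w += w
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if translate_codon(mut) == aa:  # stop translates to '*': nonsyn
                syn_w += w
        S += syn_w / tot_w
    return SiteCounts(S=S, N=3.0 - S)


def count_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two codons.

    Multi-difference codon pairs are averaged over all orderings of the
    single-nucleotide steps; pathways passing through a stop codon are
    excluded.  If every pathway is blocked, each differing position is
    classified independently in the first codon's context.
    Returns ``(sd, nd)`` with ``sd + nd`` equal to the Hamming distance.
    """
    _check_codon(c1)
    _check_codon(c2)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    ndiff = len(diff_pos)
    if ndiff == 0:
        return (0.0, 0.0)
    if ndiff == 1:
        pos = diff_pos[0]
        syn = translate_codon(c1) == translate_codon(c2)
        return (1.0, 0.0) if syn else (0.0, 1.0)

    path_sd, path_nd, n_paths = 0.0, 0.0, 0
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            path_sd += sd
            path_nd += nd
            n_paths += 1
    if n_paths:
        return (path_sd / n_paths, path_nd / n_paths)

    # all pathways pass through stops: unordered per-position fallback
    sd = nd = 0.0
    for pos in diff_pos:
        mut = c1[:pos] + c2[pos] + c1[pos + 1 :]
        if translate_codon(mut) == translate_codon(c1):
            sd += 1
        else:
            nd += 1
    return (sd, nd)


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a difference proportion."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"p={p} at or beyond Jukes-Cantor domain (3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_kappa(a: AlleleSet) -> float:
    """Moment estimate of the transition/transversion bias.

    ``kappa = 2 R`` where ``R`` is the ratio of observed pairwise transition
    to transversion differences (the factor 2 accounts for one transition
    versus two transversion alternatives per nucleotide).
    """
    ts = tv = 0
    n = len(a)
    for i in range(n):
        for j in range(i + 1, n):
            for x, y in zip(a.sequences[i], a.sequences[j]):
                if x == y or x not in NUCS or y not in NUCS:
                    continue
                if is_transition(x, y):
                    ts += 1
                else:
                    tv += 1
    if tv == 0:
        return 2.0 if ts == 0 else float("inf")
    return 2.0 * ts / tv


@dataclass
class PairwiseDistances:
    """Symmetric dS and dN matrices plus per-sequence synonymous sites."""

    names: list[str]
    dS: np.ndarray
    dN: np.ndarray
    LS_per_seq: np.ndarray
    kappa: float
    saturated_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def LS_mean(self) -> float:
        return float(np.mean(self.LS_per_seq))

    def pair(self, n1: str, n2: str) -> tuple[float, float]:
        i, j = self.names.index(n1), self.names.index(n2)
        return float(self.dS[i, j]), float(self.dN[i, j])


def _complete(codon: str) -> bool:
    return all(c in NUCS for c in codon)


def distance_matrices(a: AlleleSet, kappa: float = 1.0) -> PairwiseDistances:
    """All-pairs modified Nei–Gojobori dS/dN with Jukes–Cantor correction.

    Codons containing gaps or N in either member of a pair are deleted for
    that pair only.  A saturated pair (p >= 3/4) gets NaN and is recorded in
    ``saturated_pairs`` rather than raising.
    """
    n = len(a)
    if n < 2:
        raise ValueError("need at least two sequences")
    nc = a.n_codons

    # per-sequence, per-codon site counts (NaN marks incomplete codons)
    S_tab = np.full((n, nc), np.nan)
    N_tab = np.full((n, nc), np.nan)
    codons = [[a.codon(i, c) for c in range(nc)] for i in range(n)]
    site_cache: dict[str, SiteCounts] = {}
    for i in range(n):
        for c in range(nc):
            cod = codons[i][c]
            if not _complete(cod) or cod in STOP_CODONS:
                continue
            sc = site_cache.get(cod)
            if sc is None:
                sc = count_sites(cod, kappa)
                site_cache[cod] = sc
            S_tab[i, c] = sc.S
            N_tab[i, c] = sc.N

    LS_per_seq = np.nansum(S_tab, axis=1)

    dS = np.zeros((n, n))
    dN = np.zeros((n, n))
    saturated: list[tuple[str, str, str]] = []
    diff_cache: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            sd_tot = nd_tot = 0.0
            S_i = S_j = N_i = N_j = 0.0
            for c in range(nc):
                if np.isnan(S_tab[i, c]) or np.isnan(S_tab[j, c]):
                    continue
                S_i += S_tab[i, c]
                S_j += S_tab[j, c]
                N_i += N_tab[i, c]
                N_j += N_tab[j, c]
                ci, cj = codons[i][c], codons[j][c]
                if ci == cj:
                    continue
                key = (ci, cj) if ci <= cj else (cj, ci)
                d = diff_cache.get(key)
                if d is None:
                    d = count_pair_differences(*key)
                    diff_cache[key] = d
                sd_tot += d[0]
                nd_tot += d[1]
            S_bar = 0.5 * (S_i + S_j)
            N_bar = 0.5 * (N_i + N_j)
            pS = sd_tot / S_bar if S_bar > 0 else 0.0
            pN = nd_tot / N_bar if N_bar > 0 else 0.0
            try:
                dS[i, j] = dS[j, i] = jc_correct(pS)
            except SaturationError:
                dS[i, j] = dS[j, i] = np.nan
                saturated.append((a.names[i].raw, a.names[j].raw, "dS"))
            try:
                dN[i, j] = dN[j, i] = jc_correct(pN)
            except SaturationError:
                dN[i, j] = dN[j, i] = np.nan
                saturated.append((a.names[i].raw, a.names[j].raw, "dN"))

    return PairwiseDistances(
        names=a.name_strings(),
        dS=dS,
        dN=dN,
        LS_per_seq=LS_per_seq,
        kappa=kappa,
        saturated_pairs=saturated,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Within-group synonymous divergence summary (one Table-style row)."""

    group: str
    n_members: int
    mean_dS: float
    dS_max: float
    mean_dN: float
    LS_mean: float


def group_summary(
    d: PairwiseDistances, labels: "dict[str, str] | None" = None
) -> list[GroupSummary]:
    """Mean and maximum within-group pairwise dS per group label.

    Singleton groups are skipped.  With ``labels=None`` all sequences form
    one group named ``all``.
    """
    if labels is None:
        labels = {n: "all" for n in d.names}
    groups: dict[str, list[int]] = {}
    for idx, name in enumerate(d.names):
        g = labels.get(name)
        if g is not None:
            groups.setdefault(g, []).append(idx)

    out: list[GroupSummary] = []
    for g in sorted(groups):
        idxs = groups[g]
        if len(idxs) < 2:
            continue
        ds_vals, dn_vals = [], []
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1 :]:
                ds_vals.append(d.dS[i, j])
                dn_vals.append(d.dN[i, j])
        ds_arr = np.array(ds_vals)
        dn_arr = np.array(dn_vals)
        out.append(
            GroupSummary(
                group=g,
                n_members=len(idxs),
                mean_dS=float(np.nanmean(ds_arr)),
                dS_max=float(np.nanmax(ds_arr)),
                mean_dN=float(np.nanmean(dn_arr)),
                LS_mean=float(np.mean(d.LS_per_seq[idxs])),
            )
        )
    return out
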