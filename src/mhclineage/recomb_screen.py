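"""Recombinant-allele screening by a binomial regional-clustering test.

For every unordered allele pair, the nucleotide differences between the two
sequences are counted in sliding windows.  Under the null of uniformly
scattered differences, the count ``m`` in a window of length ``l`` out of
``n`` total differences over length ``L`` is Binomial(n, l/L); an upper-tail
probability below the (window-corrected) significance level flags regional
clustering, the footprint of a splice recombinant or gene-conversion tract.
Alleles flagged against at least two distinct partners are removed — a
recombinant clusters differences against both parental lineages, whereas
removing both members of every flagged pair would discard the parents too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import binom

from .alleles_io import AlleleSet
from .codon_evol import NUCS


class ScreenConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenConfig:
    """Sliding-window binomial test settings.

    window/step are in codons (defaults: 30-codon window, roughly the exon-2
    scale, stepped by 5); ``alpha`` is the per-pair significance level;
    ``correction='sidak_per_pair'`` applies a Sidak correction over the
    number of windows tested for each pair.
    """

    window_codons: int = 30
    step_codons: int = 5
    alpha: float = 0.01
    correction: str = "sidak_per_pair"
    min_partners: int = 2

    def __post_init__(self) -> None:
        if self.window_codons <= 0 or self.step_codons <= 0:
            raise ScreenConfigError("window and step must be positive")
        if not 0 < self.alpha < 1:
            raise ScreenConfigError("alpha must be in (0, 1)")
        if self.correction not in ("none", "sidak_per_pair"):
            raise ScreenConfigError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class WindowFlag:
    """One significant window for one allele pair."""

    allele1: str
    allele2: str
    start_codon: int  # 1-based, inclusive
    end_codon: int  # 1-based, inclusive
    m: int
    n: int
    p_value: float


@dataclass
class ScreenResult:
    flagged: list[WindowFlag]
    removed: list[str]
    retained: AlleleSet
    corrected_alpha: float
    partner_counts: dict[str, int] = field(default_factory=dict)


def binomial_region_tail(m: int, n: int, l: float, L: float) -> float:
    """Exact upper-tail P(X >= m) for X ~ Binomial(n, l/L).

    ``m`` differences observed in a region of length ``l`` out of ``n``
    total differences over length ``L``.
    """
    if not 0 <= m <= n:
        raise ValueError(f"need 0 <= m <= n, got m={m}, n={n}")
    if not 0 < l < L:
        raise ValueError(f"need 0 < l < L, got l={l}, L={L}")
    if m == 0:
        return 1.0
    return float(binom.sf(m - 1, n, l / L))


def _pair_diff_columns(s1: str, s2: str) -> tuple[list[int], list[int]]:
    """Usable columns (both unambiguous nucleotides) and differing columns."""
    usable, diffs = [], []
    for i, (x, y) in enumerate(zip(s1, s2)):
        if x in NUCS and y in NUCS:
            usable.append(i)
            if x != y:
                diffs.append(i)
    return usable, diffs


def sidak_alpha(alpha: float, n_tests: int) -> float:
    if n_tests <= 1:
        return alpha
    return 1.0 - (1.0 - alpha) ** (1.0 / n_tests)


def screen_recombinants(
    a: AlleleSet, cfg: ScreenConfig = ScreenConfig()
) -> ScreenResult:
    """Flag window/pair combinations with clustered differences; remove
    alleles flagged against ``cfg.min_partners`` or more distinct partners.
    """
    if len(a) < 2:
        raise ValueError("need at least two sequences")
    if cfg.window_codons >= a.n_codons:
        raise ScreenConfigError(
            f"window ({cfg.window_codons} codons) must be smaller than the "
            f"alignment ({a.n_codons} codons)"
        )

    window_nt = 3 * cfg.window_codons
    step_nt = 3 * cfg.step_codons
    starts = list(range(0, a.alignment_length - window_nt + 1, step_nt))
    corrected = (
        sidak_alpha(cfg.alpha, len(starts))
        if cfg.correction == "sidak_per_pair"
        else cfg.alpha
    )

    flags: list[WindowFlag] = []
    partners: dict[str, set[str]] = {n: set() for n in a.name_strings()}
    names = a.name_strings()
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            usable, diffs = _pair_diff_columns(a.sequences[i], a.sequences[j])
            n_tot = len(diffs)
            L = len(usable)
            if n_tot == 0 or L == 0:
                continue
            usable_set = set(usable)
            diff_set = set(diffs)
            pair_flagged = False
            for s in starts:
                cols = range(s, s + window_nt)
                l = sum(1 for c in cols if c in usable_set)
                if not 0 < l < L:
                    continue
                m = sum(1 for c in cols if c in diff_set)
                p = binomial_region_tail(m, n_tot, l, L)
                if p <= corrected:
                    n1, n2 = sorted((names[i], names[j]))
                    flags.append(
                        WindowFlag(
                            allele1=n1,
                            allele2=n2,
                            start_codon=s // 3 + 1,
                            end_codon=s // 3 + cfg.window_codons,
                            m=m,
                            n=n_tot,
                            p_value=p,
                        )
                    )
                    pair_flagged = True
            if pair_flagged:
                partners[names[i]].add(names[j])
                partners[names[j]].add(names[i])

    removed = sorted(
        n for n, ps in partners.items() if len(ps) >= cfg.min_partners
    )
    retained = a.subset(set(names) - set(removed))
    return ScreenResult(
        flagged=flags,
        removed=removed,
        retained=retained,
        corrected_alpha=corrected,
        partner_counts={n: len(ps) for n, ps in partners.items()},
    )


def flags_table(result: ScreenResult) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "allele1": f.allele1,
                "allele2": f.allele2,
                "start_codon": f.start_codon,
                "end_codon": f.end_codon,
                "diffs_in_window": f.m,
                "diffs_total": f.n,
                "p_value": f.p_value,
            }
            for f in result.flagged
        ]
    )
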