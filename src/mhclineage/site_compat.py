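"""Segregating-site classification and four-gamete compatibility.

A variable alignment column is *synonymous* when every observed nucleotide
state leaves the translated amino acid unchanged within each sequence's own
codon context, *nonsynonymous* when it changes the amino acid in every
context, and *mixed* otherwise (synonymous in some codon backgrounds only;
mixed columns are excluded from the synonymous tally).  Frequency categories
follow the standard definitions: a singleton has exactly two states with the
minor state in one sequence; an informative site has at least two states
each carried by at least two sequences.

Two biallelic sites are incompatible with a single mutation history on one
tree when all four two-site state combinations (gametes) occur — the
four-gamete test.  Incompatibility indicates recombination/gene conversion
or repeated mutation at a site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from .alleles_io import AlleleSet
from .codon_evol import NUCS, translate_codon


@dataclass(frozen=True)
class SiteClassification:
    """Per-column variability record (column is 1-based in reports)."""

    column: int  # 0-based alignment position
    effect: str  # synonymous | nonsynonymous | mixed | invariant
    spectrum: dict[str, int]
    category: str  # invariant | singleton | informative | other

    @property
    def is_segregating(self) -> bool:
        return self.category != "invariant"


def _category(spectrum: Counter) -> str:
    states = [c for c in spectrum.values() if c > 0]
    if len(states) <= 1:
        return "invariant"
    if len(states) == 2 and min(states) == 1:
        return "singleton"
    if sum(1 for c in states if c >= 2) >= 2:
        return "informative"
    return "other"


def classify_sites(a: AlleleSet) -> list[SiteClassification]:
    """Classify every alignment column by effect and frequency category.

    Gap/N states are ignored in the spectra; a sequence whose codon at the
    column is incomplete does not contribute to the effect call.
    """
    out: list[SiteClassification] = []
    for col in range(a.alignment_length):
        codon_idx, pos = divmod(col, 3)
        spectrum = Counter()
        for s in a.sequences:
            c = s[col]
            if c in NUCS:
                spectrum[c] += 1
        category = _category(spectrum)
        if category == "invariant":
            out.append(
                SiteClassification(
                    column=col,
                    effect="invariant",
                    spectrum=dict(spectrum),
                    category=category,
                )
            )
            continue

        observed = sorted(spectrum)
        syn_contexts = nonsyn_contexts = 0
        for s in a.sequences:
            codon = s[3 * codon_idx : 3 * codon_idx + 3]
            if any(c not in NUCS for c in codon):
                continue
            aas = {
                translate_codon(codon[:pos] + state + codon[pos + 1 :])
                for state in observed
            }
            if len(aas) == 1:
                syn_contexts += 1
            else:
                nonsyn_contexts += 1
        if nonsyn_contexts == 0 and syn_contexts > 0:
            effect = "synonymous"
        elif syn_contexts == 0 and nonsyn_contexts > 0:
            effect = "nonsynonymous"
        else:
            effect = "mixed"
        out.append(
            SiteClassification(
                column=col,
                effect=effect,
                spectrum=dict(spectrum),
                category=category,
            )
        )
    return out


def four_gamete_compatible(
    states1: "list[str]", states2: "list[str]"
) -> bool:
    """True unless all four two-site state combinations occur.

    ``states1`` and ``states2`` are the per-sequence states at two columns
    (aligned by sequence index); pairs with a gap/ambiguity at either column
    are dropped.  Both columns must be biallelic after gap removal.
    """
    pairs = [
        (x, y)
        for x, y in zip(states1, states2)
        if x in NUCS and y in NUCS
    ]
    alleles1 = {x for x, _ in pairs}
    alleles2 = {y for _, y in pairs}
    if len(alleles1) != 2 or len(alleles2) != 2:
        raise ValueError("four-gamete test requires biallelic columns")
    return len(set(pairs)) < 4


@dataclass
class CompatibilityReport:
    informative_sites: list[int]  # 0-based columns
    n_pairs: int
    incompatible_pairs: list[tuple[int, int]]
    excluded_multiallelic: list[int] = field(default_factory=list)
    site_classes: list[SiteClassification] = field(default_factory=list)

    @property
    def n_incompatible(self) -> int:
        return len(self.incompatible_pairs)


def compatibility_report(
    a: AlleleSet, synonymous_only: bool = True
) -> CompatibilityReport:
    """Four-gamete test over all unordered pairs of informative sites.

    With ``synonymous_only`` (default, matching the usual use on selectively
    neutral variation) only columns classified synonymous are considered.
    The test is defined for biallelic sites, so columns with more than two
    states are listed in ``excluded_multiallelic`` rather than tested.
    """
    classes = classify_sites(a)
    candidates = [
        c
        for c in classes
        if c.category == "informative"
        and (not synonymous_only or c.effect == "synonymous")
    ]

    informative: list[int] = []
    excluded: list[int] = []
    col_states: dict[int, list[str]] = {}
    for c in candidates:
        if len(c.spectrum) > 2:
            excluded.append(c.column)
            continue
        informative.append(c.column)
        col_states[c.column] = [s[c.column] for s in a.sequences]

    n_pairs = len(informative) * (len(informative) - 1) // 2
    incompatible: list[tuple[int, int]] = []
    for c1, c2 in combinations(informative, 2):
        if not four_gamete_compatible(col_states[c1], col_states[c2]):
            incompatible.append((c1, c2))

    return CompatibilityReport(
        informative_sites=informative,
        n_pairs=n_pairs,
        incompatible_pairs=incompatible,
        excluded_multiallelic=excluded,
        site_classes=classes,
    )


def site_table(classes: list[SiteClassification]) -> "pd.DataFrame":
    """1-based TSV-ready site classification table (segregating sites only)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "column": c.column + 1,
                "codon": c.column // 3 + 1,
                "position_in_codon": c.column % 3 + 1,
                "effect": c.effect,
                "category": c.category,
                "spectrum": ",".join(
                    f"{k}:{v}" for k, v in sorted(c.spectrum.items())
                ),
            }
            for c in classes
            if c.is_segregating
        ]
    )
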