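"""Binomial regional-clustering screen for recombinant alleles."""

import math

import numpy as np
import pytest

from mhclineage.alleles_io import AlleleName, AlleleSet
from mhclineage.recomb_screen import (
    ScreenConfig,
    ScreenConfigError,
    binomial_region_tail,
    screen_recombinants,
    sidak_alpha,
)
from mhclineage.synthetic_data import make_recombinant

from conftest import make_alleles


def exact_tail(m, n, p):
    """Direct-summation oracle for the binomial upper tail."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(m, n + 1)
    )


@pytest.mark.parametrize(
    "m, n, l, L, expected",
    [
        (0, 7, 10, 100, 1.0),  # tail from zero is certain
        (3, 3, 50, 100, 0.125),  # (1/2)^3
        (5, 10, 10, 100, exact_tail(5, 10, 0.1)),  # ~1.63e-3
    ],
)
def test_binomial_region_tail_values(m, n, l, L, expected):
    assert binomial_region_tail(m, n, l, L) == pytest.approx(expected)


def test_binomial_region_tail_matches_direct_summation():
    for n in (1, 4, 11, 25):
        for l, L in ((5, 50), (30, 90), (90, 690)):
            for m in range(n + 1):
                assert binomial_region_tail(m, n, l, L) == pytest.approx(
                    exact_tail(m, n, l / L), rel=1e-9, abs=1e-300
                )


def test_binomial_tail_monotone_nonincreasing_in_m():
    vals = [binomial_region_tail(m, 12, 20, 100) for m in range(13)]
    assert vals[0] == 1.0
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_binomial_tail_argument_errors():
    with pytest.raises(ValueError):
        binomial_region_tail(5, 3, 10, 100)
    with pytest.raises(ValueError):
        binomial_region_tail(1, 3, 100, 100)


def test_screen_config_validation():
    with pytest.raises(ScreenConfigError):
        ScreenConfig(window_codons=0)
    with pytest.raises(ScreenConfigError):
        ScreenConfig(alpha=1.5)
    with pytest.raises(ScreenConfigError):
        ScreenConfig(correction="bonferroni")


def test_identical_sequences_nothing_flagged():
    a = make_alleles({"x": "ATGAAA" * 20, "y": "ATGAAA" * 20})
    res = screen_recombinants(a, ScreenConfig(window_codons=10, step_codons=5))
    assert res.flagged == []
    assert res.removed == []
    assert len(res.retained) == 2


def test_window_larger_than_alignment_rejected():
    a = make_alleles({"x": "ATGAAA" * 5, "y": "ATGAAA" * 5})
    with pytest.raises(ScreenConfigError):
        screen_recombinants(a, ScreenConfig(window_codons=50))


def _spliced_trio(n_codons=100, n_diffs=40, seed=0):
    """Two parents with scattered differences and their midpoint splice."""
    rng = np.random.default_rng(seed)
    base = ["GGT"] * n_codons
    p1 = "".join(base)
    p2c = list(base)
    # third-position synonymous changes at n_diffs scattered codons
    for c in sorted(rng.choice(n_codons, size=n_diffs, replace=False)):
        p2c[c] = "GGA"
    p2 = "".join(p2c)
    rec = make_recombinant(p1, p2, n_codons // 2)
    return p1, p2, rec


def test_spliced_recombinant_flagged_against_both_parents():
    p1, p2, rec = _spliced_trio()
    a = make_alleles({"parent1": p1, "parent2": p2, "rec": rec})
    cfg = ScreenConfig(window_codons=50, step_codons=10, alpha=0.01)
    res = screen_recombinants(a, cfg)
    flagged_pairs = {frozenset((f.allele1, f.allele2)) for f in res.flagged}
    assert frozenset(("rec", "parent1")) in flagged_pairs
    assert frozenset(("rec", "parent2")) in flagged_pairs
    assert res.removed == ["rec"]
    assert "rec" not in res.retained.name_strings()

    # oracle check on the constructed counts: all of the splice's ~n/2
    # differences to parent1 lie in the right half-window
    diffs = [i for i, (x, y) in enumerate(zip(rec, p1)) if x != y]
    n = len(diffs)
    in_right = sum(1 for d in diffs if d >= 150)
    assert in_right == n  # construction property
    p_oracle = exact_tail(n, n, 150 / 300)
    matching = [
        f
        for f in res.flagged
        if {f.allele1, f.allele2} == {"rec", "parent1"}
        and f.start_codon == 51
    ]
    assert matching and matching[0].p_value == pytest.approx(p_oracle)


def test_screen_permutation_invariant_to_input_order():
    p1, p2, rec = _spliced_trio(seed=3)
    cfg = ScreenConfig(window_codons=50, step_codons=10)
    r1 = screen_recombinants(
        make_alleles({"parent1": p1, "parent2": p2, "rec": rec}), cfg
    )
    r2 = screen_recombinants(
        make_alleles({"rec": rec, "parent2": p2, "parent1": p1}), cfg
    )
    assert r1.removed == r2.removed
    assert {
        (f.allele1, f.allele2, f.start_codon, f.p_value) for f in r1.flagged
    } == {(f.allele1, f.allele2, f.start_codon, f.p_value) for f in r2.flagged}


def test_uniform_null_pair_flag_rate_bounded_by_alpha(rng):
    """Family-wise flag rate under uniform scatter stays at or below alpha
    (Sidak over overlapping windows is conservative)."""
    n_codons, n_diffs, alpha = 80, 30, 0.05
    cfg = ScreenConfig(
        window_codons=20, step_codons=10, alpha=alpha,
        correction="sidak_per_pair",
    )
    n_pairs, flagged = 400, 0
    for _ in range(n_pairs):
        base = ["GGT"] * n_codons
        alt = list(base)
        for c in rng.choice(n_codons, size=n_diffs, replace=False):
            alt[c] = "GGA"
        a = make_alleles({"u": "".join(base), "v": "".join(alt)})
        res = screen_recombinants(a, cfg)
        flagged += bool(res.flagged)
    rate = flagged / n_pairs
    # 95% binomial upper bound around alpha
    assert rate <= alpha + 1.96 * math.sqrt(alpha * (1 - alpha) / n_pairs)


def test_sidak_alpha():
    assert sidak_alpha(0.05, 1) == 0.05
    a10 = sidak_alpha(0.05, 10)
    assert 1 - (1 - a10) ** 10 == pytest.approx(0.05)
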