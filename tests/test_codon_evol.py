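"""Modified Nei-Gojobori counting against independent enumeration oracles."""

import math
from itertools import product

import numpy as np
import pytest
from Bio.Seq import Seq

from mhclineage.codon_evol import (
    SENSE_CODONS,
    SaturationError,
    count_pair_differences,
    count_sites,
    distance_matrices,
    estimate_kappa,
    group_summary,
    jc_correct,
)

from conftest import make_alleles

NUCS = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def aa(codon: str) -> str:
    """Oracle translation via Biopython (stop = '*')."""
    return str(Seq(codon).translate())


def oracle_sites(codon: str, kappa: float) -> float:
    """Independent bias-weighted potential-site count."""
    S = 0.0
    for pos in range(3):
        syn = tot = 0.0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            w = kappa if (codon[pos], alt) in TRANSITIONS else 1.0
            tot += w
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if aa(mut) == aa(codon) and aa(mut) != "*":
                syn += w
        S += syn / tot
    return S


def oracle_pair(c1: str, c2: str) -> tuple[float, float]:
    """Recursive pathway enumeration, skipping stop intermediates."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results: list[tuple[int, int]] = []

    def walk(cur, remaining, sd, nd):
        if not remaining:
            results.append((sd, nd))
            return
        for p in remaining:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if aa(nxt) == "*":
                continue
            step_syn = aa(cur) == aa(nxt)
            walk(
                nxt,
                [q for q in remaining if q != p],
                sd + step_syn,
                nd + (not step_syn),
            )

    walk(c1, diff, 0, 0)
    if results:
        return (
            sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results),
        )
    sd = nd = 0.0
    for p in diff:
        mut = c1[:p] + c2[p] + c1[p + 1 :]
        if aa(mut) == aa(c1):
            sd += 1
        else:
            nd += 1
    return (sd, nd)


# ---------------------------------------------------------------- site counts


@pytest.mark.parametrize(
    "codon, kappa, expected_S",
    [
        ("TTT", 1.0, 1 / 3),  # only TTT->TTC synonymous among 9 changes
        ("TTT", 2.0, 0.5),  # third-position transition weighted 2 vs 1+1
        ("CTC", 1.0, 1.0),  # CTA/CTG/CTT all Leu: fully synonymous 3rd pos
    ],
)
def test_count_sites_examples(codon, kappa, expected_S):
    sc = count_sites(codon, kappa)
    assert sc.S == pytest.approx(expected_S)
    assert sc.S + sc.N == pytest.approx(3.0)


@pytest.mark.parametrize("kappa", [1.0, 2.0, 5.0])
def test_count_sites_matches_enumeration_oracle(kappa):
    for codon in SENSE_CODONS:
        sc = count_sites(codon, kappa)
        assert sc.S == pytest.approx(oracle_sites(codon, kappa)), codon
        assert sc.S + sc.N == pytest.approx(3.0)


def test_count_sites_rejects_stops_and_ambiguity():
    with pytest.raises(ValueError):
        count_sites("TAA")
    with pytest.raises(ValueError):
        count_sites("ANA")


# ------------------------------------------------------------ pair differences


@pytest.mark.parametrize(
    "c1, c2, expected",
    [
        ("TTT", "TTT", (0.0, 0.0)),
        ("TTT", "TTC", (1.0, 0.0)),  # Phe->Phe
        ("TTT", "GTA", (0.5, 1.5)),  # two pathways averaged
    ],
)
def test_count_pair_differences_examples(c1, c2, expected):
    assert count_pair_differences(c1, c2) == pytest.approx(expected)


def test_pair_differences_match_pathway_oracle_all_sense_pairs():
    """Full 61x61 equivalence with the recursive enumeration oracle."""
    for c1, c2 in product(SENSE_CODONS, repeat=2):
        got = count_pair_differences(c1, c2)
        exp = oracle_pair(c1, c2)
        assert got == pytest.approx(exp), (c1, c2)
        hamming = sum(a != b for a, b in zip(c1, c2))
        assert got[0] + got[1] == pytest.approx(hamming)


def test_pair_differences_symmetric():
    rng = np.random.default_rng(1)
    idx = rng.integers(len(SENSE_CODONS), size=(200, 2))
    for i, j in idx:
        a_, b_ = SENSE_CODONS[i], SENSE_CODONS[j]
        assert count_pair_differences(a_, b_) == pytest.approx(
            count_pair_differences(b_, a_)
        )


# ------------------------------------------------------------------ JC & misc


def test_jc_correct_values():
    assert jc_correct(0.0) == 0.0
    assert jc_correct(0.05) == pytest.approx(
        -0.75 * math.log(1 - 4 * 0.05 / 3)
    )
    with pytest.raises(SaturationError):
        jc_correct(0.75)
    with pytest.raises(ValueError):
        jc_correct(-0.01)


def test_estimate_kappa_moment():
    # one transition difference, one transversion difference -> R=1, kappa=2
    a = make_alleles({"x": "AAATTT", "y": "AGATTA"})
    assert estimate_kappa(a) == pytest.approx(2.0)


# ----------------------------------------------------------- distance matrices


def test_distance_matrices_worked_example():
    # 9 codons: AAAx8 + TTT vs AAAx8 + TTC; S=3 per sequence, one syn diff
    a = make_alleles({"x": "AAA" * 8 + "TTT", "y": "AAA" * 8 + "TTC"})
    d = distance_matrices(a, kappa=1.0)
    assert d.LS_per_seq[0] == pytest.approx(3.0)
    pS = 1.0 / 3.0
    assert d.dS[0, 1] == pytest.approx(jc_correct(pS))
    assert d.dS[0, 1] == pytest.approx(0.44084, abs=1e-4)
    assert d.dN[0, 1] == 0.0


def test_distance_matrices_zero_for_duplicates():
    a = make_alleles({"x": "ATGAAATTT", "y": "ATGAAATTT", "z": "ATGAAATTT"})
    d = distance_matrices(a)
    assert np.all(d.dS == 0.0)
    assert np.all(d.dN == 0.0)


def test_distance_matrices_codon_block_permutation_invariance(rng):
    pad = ["GGT"] * 8
    s1 = "".join(["ATG", "AAA", "TTT", "GGC", "CAT", "TGC"] + pad)
    s2 = "".join(["ATG", "AAG", "TTC", "GGA", "CAT", "TGT"] + pad)
    perm = rng.permutation(14)
    p1 = "".join(s1[3 * i : 3 * i + 3] for i in perm)
    p2 = "".join(s2[3 * i : 3 * i + 3] for i in perm)
    d0 = distance_matrices(make_alleles({"x": s1, "y": s2}), kappa=2.0)
    d1 = distance_matrices(make_alleles({"x": p1, "y": p2}), kappa=2.0)
    assert d0.dS[0, 1] == pytest.approx(d1.dS[0, 1])
    assert d0.dN[0, 1] == pytest.approx(d1.dN[0, 1])


def test_distance_matrices_symmetry_and_diagonal(rng):
    from mhclineage.synthetic_data import SimConfig, simulate

    a, _ = simulate(SimConfig(seed=2, n_alleles=6, n_codons=60))
    d = distance_matrices(a, kappa=2.0)
    assert np.allclose(d.dS, d.dS.T)
    assert np.allclose(d.dN, d.dN.T)
    assert np.all(np.diag(d.dS) == 0)
    assert np.all(d.dS[~np.isnan(d.dS)] >= 0)


def test_distance_matrices_pairwise_deletion_of_gapped_codons():
    # first codon gapped in y: deleted for the pair, leaving 5 Gly codons
    # with one fully synonymous third-position difference (S=1 per codon)
    a = make_alleles({"x": "AAA" + "GGT" * 5, "y": "AA-" + "GGT" * 4 + "GGG"})
    d = distance_matrices(a)
    assert d.dS[0, 1] == pytest.approx(jc_correct(1.0 / 5.0))
    assert d.dN[0, 1] == 0.0


def test_distance_matrices_saturation_flagged():
    # every third position differs synonymously: pS > 3/4 after many diffs
    a = make_alleles({"x": "GGT" * 30, "y": "GGG" * 30})
    d = distance_matrices(a)
    # pS = 30 / 30 = 1.0 -> saturated, NaN + recorded
    assert np.isnan(d.dS[0, 1])
    assert ("x", "y", "dS") in d.saturated_pairs


# --------------------------------------------------------------- group summary


def test_group_summary_arithmetic():
    pad = "GGT" * 10
    a = make_alleles(
        {
            "p": pad + "AAATTT",
            "q": pad + "AAATTC",
            "r": pad + "AAGTTC",
            "s": pad + "AAATTT",
        }
    )
    d = distance_matrices(a)
    labels = {"p": "G1", "q": "G1", "r": "G1", "s": "G2"}
    out = group_summary(d, labels)
    assert len(out) == 1  # singleton G2 skipped
    g = out[0]
    pair_vals = [d.dS[0, 1], d.dS[0, 2], d.dS[1, 2]]
    assert g.mean_dS == pytest.approx(np.mean(pair_vals))
    assert g.dS_max == pytest.approx(np.max(pair_vals))
    assert g.dS_max >= g.mean_dS >= 0


def test_group_summary_mean_max_small_values():
    class FakeD:
        names = ["a", "b", "c"]
        dS = np.array([[0, 0.01, 0.02], [0.01, 0, 0.03], [0.02, 0.03, 0]])
        dN = np.zeros((3, 3))
        LS_per_seq = np.array([10.0, 10.0, 10.0])

    out = group_summary(FakeD(), {"a": "g", "b": "g", "c": "g"})
    assert out[0].mean_dS == pytest.approx(0.02)
    assert out[0].dS_max == pytest.approx(0.03)
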