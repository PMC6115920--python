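import itertools
import math

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table
from hypothesis import given
from hypothesis import strategies as st

from nlrscan.kaks import (CodonAlignment, KaKsResult, clade_average,
                          count_sites, jukes_cantor, pairwise_kaks)
from nlrscan.synth import gen_codon_pairs

TABLE = dict(standard_dna_table.forward_table)
STOPS = set(standard_dna_table.stop_codons)
SENSE = sorted(set(TABLE) - STOPS)


# ---------------------------------------------------------------------------
# Independent literal re-implementation used as the oracle


def oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut not in STOPS and TABLE[mut] == TABLE[codon]:
                syn += 1 / 3
    return 3 - syn, syn


def oracle_diffs(ca, cb):
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    paths = {"clean": [], "stop": []}
    for order in itertools.permutations(positions):
        cur, nd, sd, stopped = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOPS or cur in STOPS:
                stopped = True
                nd += 1
            elif TABLE[nxt] == TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths["stop" if stopped else "clean"].append((nd, sd))
    use = paths["clean"] or paths["stop"]
    return (sum(p[0] for p in use) / len(use), sum(p[1] for p in use) / len(use))


def oracle_kaks(seq_a, seq_b):
    N = S = Nd = Sd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if ca in STOPS or cb in STOPS or set(ca + cb) - set("ACGT"):
            continue
        na, sa = oracle_sites(ca)
        nb, sb = oracle_sites(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = oracle_diffs(ca, cb)
        Nd += nd
        Sd += sd
    pN, pS = Nd / N, Sd / S
    ka = None if pN >= 0.75 else (-0.75 * math.log(1 - 4 * pN / 3) if pN else 0.0)
    ks = None if pS >= 0.75 else (-0.75 * math.log(1 - 4 * pS / 3) if pS else 0.0)
    return N, S, Nd, Sd, ka, ks


class TestCountSites:
    @pytest.mark.parametrize("codon,n,s", [
        ("TTT", 8 / 3, 1 / 3),   # Phe: only third-position C is synonymous
        ("TGG", 3.0, 0.0),       # Trp has no synonymous single-step neighbour
        ("CTC", 2.0, 1.0),       # Leu CTN: third position fully synonymous
    ])
    def test_hand_enumerated_codons(self, codon, n, s):
        got_n, got_s = count_sites(codon)
        assert got_n == pytest.approx(n) and got_s == pytest.approx(s)

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE:
            assert count_sites(codon) == pytest.approx(oracle_sites(codon))
            n, s = count_sites(codon)
            assert n + s == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")


class TestPairwiseKaks:
    def test_identical_sequences(self):
        res = pairwise_kaks(CodonAlignment("a", "b", "ATGGCT", "ATGGCT"))
        assert res.Nd == res.Sd == 0.0
        assert res.Ka == res.Ks == 0.0
        assert res.ratio is None

    def test_hand_derived_single_codon_case(self):
        """TTT vs TTA: N=2.5, S=0.5, one nonsynonymous difference."""
        res = pairwise_kaks(CodonAlignment("a", "b", "TTT", "TTA"))
        assert res.N_sites == pytest.approx(2.5)
        assert res.S_sites == pytest.approx(0.5)
        assert (res.Nd, res.Sd) == (1.0, 0.0)
        assert res.pN == pytest.approx(0.4)
        assert res.Ka == pytest.approx(0.5716, abs=1e-4)
        assert res.Ks == 0.0 and res.ratio is None

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq_a = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), 100))
        seq_b = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), 100))
        res = pairwise_kaks(CodonAlignment("a", "b", seq_a, seq_b))
        N, S, Nd, Sd, ka, ks = oracle_kaks(seq_a, seq_b)
        assert res.N_sites == pytest.approx(N, abs=1e-9)
        assert res.S_sites == pytest.approx(S, abs=1e-9)
        assert res.Nd == pytest.approx(Nd, abs=1e-9)
        assert res.Sd == pytest.approx(Sd, abs=1e-9)
        if ka is None:
            assert res.Ka is None
        else:
            assert res.Ka == pytest.approx(ka, abs=1e-9)

    @given(st.lists(st.sampled_from(SENSE), min_size=1, max_size=20),
           st.lists(st.sampled_from(SENSE), min_size=1, max_size=20))
    def test_symmetry_property(self, codons_a, codons_b):
        n = min(len(codons_a), len(codons_b))
        seq_a, seq_b = "".join(codons_a[:n]), "".join(codons_b[:n])
        ab = pairwise_kaks(CodonAlignment("a", "b", seq_a, seq_b))
        ba = pairwise_kaks(CodonAlignment("b", "a", seq_b, seq_a))
        assert (ab.N_sites, ab.S_sites, ab.Nd, ab.Sd) == \
            (ba.N_sites, ba.S_sites, ba.Nd, ba.Sd)

    def test_symmetry(self):
        rng = np.random.default_rng(17)
        seq_a = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), 60))
        seq_b = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), 60))
        ab = pairwise_kaks(CodonAlignment("a", "b", seq_a, seq_b))
        ba = pairwise_kaks(CodonAlignment("b", "a", seq_b, seq_a))
        assert (ab.N_sites, ab.S_sites, ab.Nd, ab.Sd) == \
            (ba.N_sites, ba.S_sites, ba.Nd, ba.Sd)

    def test_concatenation_additivity_of_site_counts(self):
        a1, b1 = "ATGGCT", "ATGGCA"
        a2, b2 = "CTCAAA", "CTGAAG"
        r1 = pairwise_kaks(CodonAlignment("a", "b", a1, b1))
        r2 = pairwise_kaks(CodonAlignment("a", "b", a2, b2))
        rc = pairwise_kaks(CodonAlignment("a", "b", a1 + a2, b1 + b2))
        assert rc.N_sites == pytest.approx(r1.N_sites + r2.N_sites)
        assert rc.S_sites == pytest.approx(r1.S_sites + r2.S_sites)
        assert rc.Nd == pytest.approx(r1.Nd + r2.Nd)
        assert rc.Sd == pytest.approx(r1.Sd + r2.Sd)

    def test_more_nonsynonymous_changes_never_lower_ka(self):
        anc = "ATGGCTCTCAAAGGT" * 4
        prev = -1.0
        codons = [anc[i:i + 3] for i in range(0, len(anc), 3)]
        mutated = list(codons)
        for i, codon in enumerate(codons[:8]):
            for nt in "ACGT":
                cand = nt + codon[1:]
                if cand not in STOPS and cand != codon and TABLE[cand] != TABLE[codon]:
                    mutated[i] = cand
                    break
            res = pairwise_kaks(CodonAlignment("a", "b", anc, "".join(mutated)))
            assert res.Ka >= prev
            prev = res.Ka

    def test_uncorrectable_proportion_flagged(self):
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.2) == pytest.approx(-0.75 * math.log(1 - 0.8 / 3))

    def test_no_comparable_codons_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_kaks(CodonAlignment("a", "b", "TAA", "TGA"))

    def test_ambiguous_and_stop_codons_skipped_pairwise(self):
        res = pairwise_kaks(CodonAlignment("a", "b", "ATGNNNGCT", "ATGAAAGCA"))
        assert res.codons_used == 2 and res.codons_skipped == 1


class TestCladeAverage:
    def _res(self, ratio):
        return KaKsResult(1, 1, 1, 1, 0.1, 0.1, 0.1, 0.1, ratio, 1, 0)

    def test_mean_of_defined_ratios(self):
        mean, excluded = clade_average([self._res(0.5), self._res(1.0)])
        assert mean == pytest.approx(0.75) and excluded == 0

    def test_undefined_pairs_excluded_and_counted(self):
        mean, excluded = clade_average([self._res(0.5), self._res(None)])
        assert mean == pytest.approx(0.5) and excluded == 1

    def test_all_undefined_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            clade_average([self._res(None)])

    def test_simulated_clade_recovers_target_omega(self):
        pairs, _truth = gen_codon_pairs(30, 300, omega=0.3, ks_target=0.2, seed=5)
        mean, excluded = clade_average([pairwise_kaks(p) for p in pairs])
        assert excluded == 0
        assert abs(mean - 0.3) < 0.05
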