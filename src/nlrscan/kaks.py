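"""Pairwise Ka/Ks by the Nei-Gojobori (1986) method with Jukes-Cantor correction.

Synonymous and nonsynonymous *sites* are counted per codon by enumerating
all nine single-nucleotide mutants against the standard genetic code
(mutations to stop codons count as nonsynonymous) and averaged over the two
sequences. *Differences* between codons with more than one mismatch are
averaged over all minimal mutational pathways, excluding pathways that pass
through a stop codon unless every pathway does. Proportions are corrected
with the one-parameter Jukes-Cantor formula K = -(3/4) ln(1 - (4/3) p),
undefined when p >= 3/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass
class CodonAlignment:
    """A gap-free in-frame pairwise alignment of two coding sequences."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"{self.id_a}/{self.id_b}: aligned lengths differ "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.id_a}/{self.id_b}: length not divisible by 3")

    def codon_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[i:i + 3], self.seq_b[i:i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]


@dataclass
class KaKsResult:
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float | None  # None when pN >= 3/4 (uncorrectable)
    Ks: float | None
    ratio: float | None  # None when Ks is 0 or either distance is undefined
    codons_used: int
    codons_skipped: int


def _is_codon(codon: str) -> bool:
    return len(codon) == 3 and all(c in NUCLEOTIDES for c in codon)


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon.

    Each of the nine single-nucleotide mutants contributes 1/3 of a
    synonymous site at its position if it encodes the same amino acid;
    mutants that create stop codons are nonsynonymous. n + s = 3 always.
    """
    if not _is_codon(codon) or codon in STOP_CODONS:
        raise ValueError(f"count_sites requires a sense codon, got {codon!r}")
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant not in STOP_CODONS and CODON_TABLE[mutant] == aa:
                s += 1.0 / 3.0
    return 3.0 - s, s


def _pathway_differences(ca: str, cb: str) -> tuple[float, float]:
    """(Nd, Sd) between two codons, averaged over minimal mutational pathways.

    Pathways through stop codons are excluded unless all pass through stops.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    clean: list[tuple[int, int]] = []   # (nonsyn steps, syn steps)
    through_stop: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = ca
        nd = sd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                hit_stop = True
                nd += 1  # a step into/through a stop is nonsynonymous
            elif cur in STOP_CODONS:
                hit_stop = True
                nd += 1
            elif CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (through_stop if hit_stop else clean).append((nd, sd))
    paths = clean if clean else through_stop
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


def jukes_cantor(p: float) -> float | None:
    """JC69-corrected distance; None when p is at or beyond the 3/4 ceiling."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0


def pairwise_kaks(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori Ka/Ks of one codon alignment.

    Codon positions where either sequence has a non-ACGT character or a stop
    codon are excluded pairwise. Raises when no comparable codon remains.
    """
    N = S = Nd = Sd = 0.0
    used = skipped = 0
    for ca, cb in aln.codon_pairs():
        if (not _is_codon(ca) or not _is_codon(cb)
                or ca in STOP_CODONS or cb in STOP_CODONS):
            skipped += 1
            continue
        na, sa = count_sites(ca)
        nb, sb = count_sites(cb)
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = _pathway_differences(ca, cb)
        Nd += nd
        Sd += sd
        used += 1
    if used == 0:
        raise ValueError(f"{aln.id_a}/{aln.id_b}: no comparable codons")
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    Ka = jukes_cantor(pN)
    Ks = jukes_cantor(pS)
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(
        N_sites=N, S_sites=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS,
        Ka=Ka, Ks=Ks, ratio=ratio, codons_used=used, codons_skipped=skipped,
    )


def clade_average(results: list[KaKsResult]) -> tuple[float, int]:
    """(mean of defined Ka/Ks ratios, count of excluded undefined pairs).

    Raises when every pair is undefined.
    """
    defined = [r.ratio for r in results if r.ratio is not None]
    excluded = len(results) - len(defined)
    if not defined:
        raise ValueError("all pairwise Ka/Ks ratios are undefined")
    return sum(defined) / len(defined), excluded
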