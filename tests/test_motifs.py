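import numpy as np
import pytest

from nlrscan.core_io import SequenceRecord
from nlrscan.motifs import (AA20, DEFAULT_PATTERNS, MotifModel,
                            discover_zoops_motifs, extract_signatures,
                            resolve_overlaps, scan_known_motifs,
                            zoops_objective_trace, _encode, _window_scores,
                            MotifHit)

from conftest import PLANTED_MOTIF


class TestZoopsEM:
    def test_planted_motif_recovered_as_consensus(self, planted_motif_seqs):
        """A 9-mer planted in every sequence dominates the fitted PPM."""
        models = discover_zoops_motifs(planted_motif_seqs, nmotifs=1,
                                       minw=6, maxw=12, seed=7)
        assert models[0].consensus == PLANTED_MOTIF
        assert models[0].zoops_gamma > 0.9

    def test_objective_monotone_nondecreasing(self, planted_motif_seqs):
        trace = zoops_objective_trace(planted_motif_seqs, width=9, seed=3)
        assert len(trace) >= 2
        assert all(b - a >= -1e-8 for a, b in zip(trace, trace[1:]))

    def test_oops_degeneracy_with_gamma_fixed_at_one(self, planted_motif_seqs):
        """Pinning the occurrence prior at 1 reduces ZOOPS to OOPS."""
        models = discover_zoops_motifs(planted_motif_seqs, nmotifs=1,
                                       minw=9, maxw=9, seed=7, fixed_gamma=1.0)
        assert models[0].zoops_gamma == 1.0
        assert models[0].consensus == PLANTED_MOTIF

    def test_identical_sequences_align_at_identical_offsets(self):
        rng = np.random.default_rng(0)
        residues = "".join(rng.choice(list(AA20), size=60))
        seqs = [SequenceRecord(id=f"d{i}", residues=residues) for i in range(10)]
        from nlrscan.motifs import best_occurrence
        (model,) = discover_zoops_motifs(seqs, nmotifs=1, minw=6, maxw=8, seed=1)
        offsets = {best_occurrence(s, model).start for s in seqs}
        assert len(offsets) == 1

    def test_input_guards(self, planted_motif_seqs):
        with pytest.raises(ValueError, match="at least 2"):
            discover_zoops_motifs(planted_motif_seqs[:1])
        short = [SequenceRecord(id=f"t{i}", residues="MKV") for i in range(3)]
        with pytest.raises(ValueError, match="minw"):
            discover_zoops_motifs(short, minw=6)
        big = [SequenceRecord(id=f"b{i}", residues="A" * 10_000) for i in range(11)]
        with pytest.raises(ValueError, match="maxsize"):
            discover_zoops_motifs(big)


def _brute_force_model_scan(seq, model, threshold):
    """Oracle: score every offset by an explicit loop, then greedy non-overlap."""
    lo = np.log(model.ppm) - np.log(model.background)[None, :]
    hits = []
    for start in range(len(seq.residues) - model.width + 1):
        window = seq.residues[start:start + model.width]
        score = 0.0
        for j, aa in enumerate(window):
            if aa in AA20:
                score += lo[j, AA20.index(aa)]
        if score > threshold:
            hits.append(MotifHit(seq.id, model.name, start + 1, window, score))
    chosen = []
    for h in sorted(hits, key=lambda h: (-h.log_odds, h.start)):
        if all(h.start + model.width <= c.start or h.start >= c.start + model.width
               for c in chosen):
            chosen.append(h)
    return sorted(chosen, key=lambda h: h.start)


class TestScanning:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(5)
        ppm = rng.dirichlet(np.full(20, 0.3), size=7)
        ppm = np.clip(ppm, 1e-6, None)
        ppm /= ppm.sum(axis=1, keepdims=True)
        return MotifModel(name="m", ppm=ppm, background=np.full(20, 0.05))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_sliding_window_oracle(self, model, seed):
        rng = np.random.default_rng(seed)
        seq = SequenceRecord(id="q", residues="".join(rng.choice(list(AA20), 200)))
        mine = scan_known_motifs(seq, [model], threshold=0.0)
        oracle = _brute_force_model_scan(seq, model, 0.0)
        assert [(h.start, h.matched) for h in mine] == \
            [(h.start, h.matched) for h in oracle]
        assert np.allclose([h.log_odds for h in mine],
                           [h.log_odds for h in oracle])

    def test_kinase2_default_pattern(self):
        seq = SequenceRecord(id="p", residues="AAAALLDDVWNAAAA")
        hits = [h for h in scan_known_motifs(seq) if h.motif_name == "Kinase-2"]
        assert len(hits) == 1
        assert hits[0].matched == "LLDDVW"

    def test_empty_catalog(self):
        seq = SequenceRecord(id="p", residues="MKVLLDDVW")
        assert scan_known_motifs(seq, catalog={}) == []

    def test_invariance_under_renaming_and_flanking(self, model):
        rng = np.random.default_rng(9)
        core = "".join(rng.choice(list(AA20), 80))
        a = scan_known_motifs(SequenceRecord(id="x", residues=core), [model])
        b = scan_known_motifs(SequenceRecord(id="y", residues=core), [model])
        assert [(h.start, h.matched) for h in a] == [(h.start, h.matched) for h in b]
        flank = "G" * 11
        c = scan_known_motifs(
            SequenceRecord(id="x", residues=flank + core), [model])
        shifted = {(h.start + len(flank), h.matched) for h in a}
        assert shifted <= {(h.start, h.matched) for h in c}

    def test_overlap_resolution_greedy_leftmost(self):
        hits = [MotifHit("p", "m", 1, "AAAA", 5.0),
                MotifHit("p", "m", 3, "AAAA", 5.0),
                MotifHit("p", "m", 8, "AAAA", 9.0)]
        chosen = resolve_overlaps(hits)
        assert [(h.start, h.log_odds) for h in chosen] == [(1, 5.0), (8, 9.0)]


class TestSignatures:
    def _k2_hit(self, matched, start=10):
        return MotifHit("p", "Kinase-2", start, matched, 6.0)

    @pytest.mark.parametrize("matched,expected", [
        ("VLDDVWDK", "DDVW"),
        ("VLDDVDNE", "DDVD"),
        ("LLDDVR", "DDVR"),
    ])
    def test_kinase2_dyad_extraction(self, matched, expected):
        seq = SequenceRecord(id="p", residues="A" * 9 + matched + "A" * 5)
        sig = extract_signatures(seq, [self._k2_hit(matched)])
        assert sig.kinase2 == expected

    def test_missing_hit_gives_absent_signature(self):
        seq = SequenceRecord(id="p", residues="MKVA")
        sig = extract_signatures(seq, [])
        assert sig.kinase2 is None and sig.rnbsb is None

    def test_hit_without_dd_dyad_warns(self):
        seq = SequenceRecord(id="p", residues="A" * 9 + "VLEDVWDK" + "AAA")
        with pytest.warns(UserWarning, match="DD dyad"):
            sig = extract_signatures(seq, [self._k2_hit("VLEDVWDK")])
        assert sig.kinase2 is None

    @pytest.mark.parametrize("block,expected", [
        ("GSRIIITSRA", "TSR"),
        ("GSRIIITTRD", "TTRD"),
    ])
    def test_rnbsb_signature(self, block, expected):
        seq = SequenceRecord(id="p", residues="A" * 5 + block + "A" * 5)
        hits = scan_known_motifs(seq)
        sig = extract_signatures(seq, hits)
        assert sig.rnbsb == expected
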