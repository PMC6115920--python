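import pytest
from hypothesis import given
from hypothesis import strategies as st

from nlrscan.core_io import DomainHit
from nlrscan.grammar import (Architecture, NbsGeneRecord, NoNbsDomain,
                             build_architecture, classify, classify_proteins,
                             count_lrr_signatures, merge_intervals, subtype_nl)
from nlrscan.synth import gen_proteome


class TestLrrCounting:
    @pytest.mark.parametrize("residues,expected", [
        ("LAALAALAA", 1),
        ("LAALAALAALAALAALAA", 2),
        ("AAAA", 0),
        ("LAALAALA", 0),            # one residue short
        ("ALAALAALAAA", 1),         # offset start
    ])
    def test_greedy_nonoverlapping_count(self, residues, expected):
        assert count_lrr_signatures(residues) == expected

    @given(st.text(alphabet="LAG", max_size=60))
    def test_greedy_count_matches_inline_oracle(self, residues):
        count = pos = 0
        while pos <= len(residues) - 9:
            if (residues[pos] == "L" and residues[pos + 3] == "L"
                    and residues[pos + 6] == "L"):
                count += 1
                pos += 9
            else:
                pos += 1
        assert count_lrr_signatures(residues) == count

    def test_agrees_with_exhaustive_window_oracle(self):
        """Greedy left-to-right equals manual scan over every window."""
        residues = "LAALAALAALAALAALAA"
        count = pos = 0
        while pos <= len(residues) - 9:
            window = residues[pos:pos + 9]
            if window[0] == "L" and window[3] == "L" and window[6] == "L":
                count += 1
                pos += 9
            else:
                pos += 1
        assert count_lrr_signatures(residues) == count == 2


class TestArchitecture:
    def test_cc_then_nbs(self):
        hits = [DomainHit("p", "CC", 5, 40), DomainHit("p", "NBS", 200, 480)]
        arch = build_architecture("p", hits, lrr_count=12)
        assert arch.letters == "CN" and arch.has_lrr

    def test_ordering_by_start(self):
        hits = [DomainHit("p", "NBS", 600, 880), DomainHit("p", "TIR", 10, 170),
                DomainHit("p", "NBS", 220, 500)]
        arch = build_architecture("p", hits, lrr_count=4)
        assert arch.letters == "TNN"

    def test_overlapping_same_kind_hits_merge(self):
        hits = [DomainHit("p", "NBS", 200, 400), DomainHit("p", "NBS", 350, 480)]
        arch = build_architecture("p", hits, lrr_count=0)
        assert arch.letters == "N"
        # interval-union oracle
        union = set(range(200, 401)) | set(range(350, 481))
        merged = merge_intervals([(200, 400), (350, 480)])
        assert set(range(merged[0][0], merged[0][1] + 1)) == union

    def test_no_nbs_is_excluded_with_reason(self):
        with pytest.raises(NoNbsDomain, match="no NBS domain"):
            build_architecture("p", [DomainHit("p", "TIR", 1, 100)], 0)


class TestClassification:
    def _arch(self, letters, has_lrr=False, lrr_segments=(), letter_starts=None):
        return Architecture(
            protein_id="p", letters=letters, has_lrr=has_lrr,
            lrr_count=2 if has_lrr else 0,
            lrr_segments=list(lrr_segments),
            letter_starts=letter_starts or list(range(1, 1001, 100))[:len(letters)],
        )

    @pytest.mark.parametrize("letters,has_lrr,expected", [
        ("CN", True, ("CNL", "CNL")),
        ("TN", False, ("TNL", "TN")),
        ("RCN", True, ("RNL", "RCNL")),
        ("CTN", True, ("TNL", "CTNL")),
        ("N", False, ("NL", "N")),
        ("NN", True, ("NL", "NNL")),
        ("TTN", True, ("TNL", "TTNL")),
    ])
    def test_group_dominance_and_subgroup_codes(self, letters, has_lrr, expected):
        assert classify(self._arch(letters, has_lrr)) == expected

    def test_tnltnl_requires_interleaved_lrr_blocks(self):
        arch = Architecture(
            protein_id="p", letters="TNTN", has_lrr=True, lrr_count=4,
            letter_starts=[10, 100, 400, 500],
            lrr_segments=[(250, 300), (700, 760)],
        )
        assert classify(arch) == ("TNL", "TNLTNL")

    def test_unknown_code_reported_not_dropped(self):
        group, sub = classify(self._arch("CCN", has_lrr=False))
        assert group == "CNL" and sub == "unclassified_architecture"

    def test_architecture_without_nbs_rejected(self):
        with pytest.raises(NoNbsDomain):
            classify(self._arch("CT"))


class TestNlSubtype:
    @pytest.mark.parametrize("kinase2,expected", [
        ("DDVW", "N_CC"), ("DDVD", "N_TIR"), (None, "unassigned"),
        ("DDIW", "unassigned"),
    ])
    def test_signature_mapping(self, kinase2, expected):
        rec = NbsGeneRecord(protein_id="p", group="NL", subgroup="NL",
                            kinase2=kinase2)
        assert subtype_nl(rec) == expected

    def test_non_nl_record_is_an_error(self):
        rec = NbsGeneRecord(protein_id="p", group="CNL", subgroup="CNL",
                            kinase2="DDVW")
        with pytest.raises(ValueError, match="NL group"):
            subtype_nl(rec)


class TestPartitionProperty:
    def test_every_nbs_protein_maps_to_exactly_one_subgroup(self, small_blueprint):
        seqs, hits, truth = gen_proteome(small_blueprint)
        by_protein = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        lrr = {s.id: count_lrr_signatures(s) for s in seqs}
        records, excluded = classify_proteins(by_protein, lrr)
        assert not excluded
        assert len(records) == len(seqs)
        group_totals = {}
        subgroup_by_group = {}
        for r in records:
            group_totals[r.group] = group_totals.get(r.group, 0) + 1
            subgroup_by_group.setdefault(r.group, {}).setdefault(r.subgroup, 0)
            subgroup_by_group[r.group][r.subgroup] += 1
        for g, n in group_totals.items():
            assert sum(subgroup_by_group[g].values()) == n

    def test_planted_subgroups_recovered_exactly(self, small_blueprint):
        seqs, hits, truth = gen_proteome(small_blueprint)
        by_protein = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        for s in seqs:
            arch = build_architecture(s.id, by_protein[s.id],
                                      count_lrr_signatures(s))
            group, subgroup = classify(arch)
            planted = truth.genes[s.id]
            assert (group, subgroup) == (planted.group, planted.subgroup), s.id
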