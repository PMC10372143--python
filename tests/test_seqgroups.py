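"""Conservation profiling, pairwise identity and DCR scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import msa_from_rows
from zipswap.seqgroups import (AMINO_ACIDS, AllGapOverlapError, DcrParams,
                               SeqRecord, column_composition,
                               conservation_profile, pairwise_identity,
                               scan_dcrs, select_orthologs)
from zipswap.synthdata import gen_families

protein = st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=40)


class TestPairwiseIdentity:
    @pytest.mark.parametrize("s1, s2, expected", [
        ("ACDE", "ACDF", 75.0),          # one mismatch, no gaps
        ("ACDE", "ACDE", 100.0),
        ("AC-E", "ACDE", 100.0),         # aligned input, gap column excluded
    ])
    def test_hand_counted_examples(self, s1, s2, expected):
        got = pairwise_identity(SeqRecord("a", s1), SeqRecord("b", s2))
        assert got == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(a=protein, b=protein)
    def test_symmetric_and_bounded(self, a, b):
        ra, rb = SeqRecord("a", a), SeqRecord("b", b)
        pid = pairwise_identity(ra, rb)
        assert pid == pairwise_identity(rb, ra)
        assert 0.0 <= pid <= 100.0

    @settings(max_examples=30, derandomize=True)
    @given(a=protein)
    def test_self_identity_is_100(self, a):
        r = SeqRecord("a", a)
        assert pairwise_identity(r, r) == 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SeqRecord("a", "")

    def test_all_gap_overlap_is_an_error(self):
        a = SeqRecord("a", "AC--")
        b = SeqRecord("b", "--DE")
        with pytest.raises(AllGapOverlapError):
            pairwise_identity(a, b)


class TestSelectOrthologs:
    def test_threshold_application(self):
        # candidates engineered at ~48 / 52 / 90 % identity to a 50-mer query
        base = ("ACDEFGHIKLMNPQRSTVWY" * 3)[:50]
        def mutate(s, k):
            out = list(s)
            for i in range(k):
                out[i] = "W" if s[i] != "W" else "Y"
            return "".join(out)
        query = SeqRecord("q", base)
        cands = [SeqRecord("c48", mutate(base, 26)),
                 SeqRecord("c52", mutate(base, 24)),
                 SeqRecord("c90", mutate(base, 5))]
        for c, pid in zip(cands, (48, 52, 90)):
            assert pairwise_identity(query, c) == pytest.approx(pid, abs=2)
        group = select_orthologs(query, cands, cutoff_percent=50)
        assert {m.id for m in group.members} == {"q", "c52", "c90"}

    def test_cutoff_100_keeps_only_duplicates(self):
        q = SeqRecord("q", "MKLVA")
        group = select_orthologs(
            q, [SeqRecord("dup", "MKLVA"), SeqRecord("near", "MKLVC")],
            cutoff_percent=100)
        assert {m.id for m in group.members} == {"q", "dup"}

    def test_no_candidates_warns(self):
        with pytest.warns(UserWarning):
            group = select_orthologs(SeqRecord("q", "MKLVA"), [])
        assert len(group) == 1

    def test_generated_family_all_retained(self):
        # background drift of 10% leaves every member >=60% identical
        msa, _ = gen_families(n_seqs=5, length=100,
                              background_mut_prob=0.1, seed=7)
        members = msa.rows_of("group1")
        group = select_orthologs(members[0], members[1:], cutoff_percent=50)
        assert len(group) == len(members)


class TestGroupedMsa:
    def test_reference_numbering_skips_gaps(self):
        msa = msa_from_rows({"ref": "M-KL", "o": "MAKL"},
                            {"ref": "g1", "o": "g2"}, "ref")
        assert msa.colmap == {1: 0, 2: 2, 3: 3}

    def test_row_order_does_not_change_colmap(self, tiny_msa):
        rows = {r.id: r.seq for r in tiny_msa.records}
        shuffled = dict(reversed(list(rows.items())))
        msa2 = msa_from_rows(shuffled, tiny_msa.group_of, tiny_msa.ref_id)
        assert msa2.colmap == tiny_msa.colmap

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            msa_from_rows({"a": "MKL", "b": "MK"},
                          {"a": "g1", "b": "g2"}, "a")

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            msa_from_rows({"a": "MKL"}, {"a": "g1"}, "zzz")

    def test_member_without_group_rejected(self):
        with pytest.raises(ValueError, match="without group"):
            msa_from_rows({"a": "MKL", "b": "MKL"}, {"a": "g1"}, "a")


class TestConservationProfile:
    def test_invariant_and_split_columns(self):
        msa = msa_from_rows(
            {"a1": "QQ", "a2": "QQ", "a3": "QH", "a4": "QH",
             "b1": "HH", "b2": "HH", "b3": "HH", "b4": "HH"},
            {k: ("A" if k.startswith("a") else "B")
             for k in ("a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4")},
            "a1")
        prof = conservation_profile(msa)
        col0_a = prof.stats["A"][0]
        assert col0_a.consensus == "Q" and col0_a.fraction == 1.0
        assert col0_a.is_invariant
        col1_a = prof.stats["A"][1]
        assert col1_a.fraction == 0.5 and not col1_a.is_invariant
        assert col1_a.tie and col1_a.consensus == "H"  # lexicographic tie-break

    def test_all_gap_column_flagged(self):
        msa = msa_from_rows({"a": "M-", "b": "M-", "c": "MK", "d": "MK"},
                            {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, "c")
        stats = conservation_profile(msa).stats["g1"][1]
        assert stats.consensus is None and np.isnan(stats.fraction)

    def test_single_group_rejected(self):
        msa = msa_from_rows({"a": "MK", "b": "MK"},
                            {"a": "g1", "b": "g1"}, "a")
        with pytest.raises(ValueError):
            conservation_profile(msa)


def brute_force_dcr_columns(msa, min_conservation=1.0, max_gap=0.5):
    """Independent per-column oracle: enumerate group residue counts directly."""
    labels = msa.group_labels
    target, reference = labels[0], labels[1]
    hits = []
    for col in range(msa.width):
        if col not in msa.col_to_ref:
            continue
        cons = {}
        ok = True
        for g in labels:
            column = msa.column(col, g)
            residues = [c for c in column if c != "-"]
            if not residues or (len(column) - len(residues)) / len(column) > max_gap:
                ok = False
                break
            counts = {r: residues.count(r) for r in set(residues)}
            top = max(counts.values())
            if top / len(residues) < min_conservation:
                ok = False
                break
            cons[g] = min(r for r, c in counts.items() if c == top)
        if ok and cons[target] != cons[reference] and "X" not in (
                cons[target], cons[reference]):
            hits.append(col)
    return hits


class TestScanDcrs:
    def test_tiny_alignment_hits_and_swaps(self, tiny_msa):
        hits = scan_dcrs(conservation_profile(tiny_msa))
        assert [(h.ref_position, h.swap) for h in hits] == [
            (2, "Q2H"), (4, "E4H")]
        for h in hits:
            # round-trip: re-reading the column confirms the criteria
            for g in ("multi_metal", "zn_preferring"):
                column = tiny_msa.column(h.column, g)
                assert set(column) == {h.residues_by_group[g]}

    def test_identical_groups_give_no_hits(self):
        msa = msa_from_rows({"a": "MKL", "b": "MKL", "c": "MKL", "d": "MKL"},
                            {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, "a")
        assert scan_dcrs(conservation_profile(msa)) == []

    def test_planted_recovery_matches_brute_force(self):
        planted = [(5, ("Q", "H")), (40, ("E", "H")), (77, ("C", "G")),
                   (130, ("N", "H")), (181, ("D", "K"))]
        msa, _ = gen_families(length=200, planted=planted,
                              background_mut_prob=0.3, seed=11)
        hits = scan_dcrs(conservation_profile(msa))
        oracle = brute_force_dcr_columns(msa)
        assert [h.column for h in hits] == oracle
        assert {h.column for h in hits} == {c for c, _ in planted}

    def test_invariant_under_row_permutation_and_relabeling(self):
        msa, _ = gen_families(length=80, planted=[(9, ("Q", "H"))], seed=3)
        rows = {r.id: r.seq for r in msa.records}
        renamed = {f"x_{k}": v for k, v in reversed(list(rows.items()))}
        groups = {f"x_{k}": msa.group_of[k] for k in rows}
        msa2 = msa_from_rows(renamed, groups, f"x_{msa.ref_id}")
        h1 = scan_dcrs(conservation_profile(msa))
        h2 = scan_dcrs(conservation_profile(msa2))
        assert [(h.column, h.swap) for h in h1] == [
            (h.column, h.swap) for h in h2]

    def test_conservative_pair_filter_drops_ts_swap(self):
        msa = msa_from_rows(
            {"a": "MTKE", "b": "MTKE", "c": "MSKH", "d": "MSKH"},
            {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, "a")
        prof = conservation_profile(msa)
        all_hits = scan_dcrs(prof)
        assert {h.swap for h in all_hits} == {"T2S", "E4H"}
        strict = scan_dcrs(prof, DcrParams(non_conservative_only=True))
        assert {h.swap for h in strict} == {"E4H"}  # T->S is conservative

    def test_gap_ceiling_excludes_column(self):
        # column 2 is 2/3 gapped in g1 (> the 50% ceiling) -> excluded
        msa = msa_from_rows(
            {"a": "MQ", "b": "M-", "c": "M-",
             "d": "MH", "e": "MH", "f": "MH"},
            {"a": "g1", "b": "g1", "c": "g1",
             "d": "g2", "e": "g2", "f": "g2"}, "a")
        assert scan_dcrs(conservation_profile(msa)) == []

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            DcrParams(min_within_conservation=0.0)
        with pytest.raises(ValueError):
            DcrParams(max_group_gap_fraction=1.5)


class TestColumnComposition:
    def test_pure_column_and_row_sum(self):
        msa = msa_from_rows({"a": "MH", "b": "MH", "c": "MH"},
                            {"a": "s", "b": "s", "c": "s"}, "a")
        table = column_composition({"fam": msa}, [2])
        row = table.iloc[0]
        assert row["H"] == 1.0
        assert sum(row[aa] for aa in AMINO_ACIDS) == pytest.approx(1.0,
                                                                   abs=1e-9)

    def test_multinomial_frequencies_within_3_se(self):
        rng = np.random.default_rng(42)
        p = {"H": 0.7, "E": 0.2, "Q": 0.1}
        n = 400
        residues = rng.choice(list(p), size=n, p=list(p.values()))
        rows = {f"s{i}": f"M{r}" for i, r in enumerate(residues)}
        msa = msa_from_rows(rows, {k: "fam" for k in rows}, "s0")
        table = column_composition({"liv1": msa}, [2])
        row = table.iloc[0]
        for aa, prob in p.items():
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(row[aa] - prob) <= 3 * se

    def test_missing_position_warns_and_is_omitted(self):
        msa = msa_from_rows({"a": "MK", "b": "MK"},
                            {"a": "s", "b": "s"}, "a")
        with pytest.warns(UserWarning, match="absent"):
            table = column_composition({"fam": msa}, [2, 99])
        assert list(table["ref_position"]) == [2]
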