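"""Similarity computations and cold-split protocol guarantees."""

import numpy as np
import pytest

from cpifuse.data import InteractionDataset, InteractionRecord, generate_synthetic
from cpifuse.splits import (
    check_disjoint,
    filter_hard,
    kfold,
    protein_similarity,
    split_novel_compound,
    split_novel_pair,
    split_novel_protein,
    tanimoto,
)


def test_tanimoto_hand_cases():
    assert tanimoto(np.array([1, 1, 0, 1]), np.array([1, 1, 0, 1])) == 1.0
    assert tanimoto(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0
    # a = 1100, b = 1010: intersection 1, union 3
    assert tanimoto(np.array([1, 1, 0, 0]),
                    np.array([1, 0, 1, 0])) == pytest.approx(1 / 3)


def test_tanimoto_all_zero_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert tanimoto(np.zeros(4), np.zeros(4)) == 0.0


def test_tanimoto_length_mismatch():
    with pytest.raises(ValueError):
        tanimoto(np.zeros(4), np.zeros(5))


def test_tanimoto_self_similarity_is_one():
    from cpifuse.featurize import smiles_to_fingerprint

    for s in ("CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O"):
        fp = smiles_to_fingerprint(s, 2, 512)
        assert tanimoto(fp, fp) == 1.0


def test_protein_similarity_identical_and_disjoint():
    seq = "ACDEFGHIKLMNPQRSTVWY" * 25  # length 500
    assert protein_similarity(seq, seq, fixed_len=500) == 1.0
    assert protein_similarity("AAAA", "GGGG", fixed_len=4) == 0.0


def test_protein_similarity_hand_alignment():
    """ACDEF vs ACDFF align with 4 identities -> 4/5 at fixed length 5."""
    assert protein_similarity("ACDEF", "ACDFF", fixed_len=5) \
        == pytest.approx(0.8)


def test_protein_similarity_empty_rejected():
    with pytest.raises(ValueError):
        protein_similarity("", "ACD")


def test_protein_similarity_capped_at_one():
    seq = "A" * 600
    assert protein_similarity(seq, seq, fixed_len=500) == 1.0


def _crossed_dataset():
    """2 compounds x 2 proteins, fully crossed (4 records)."""
    recs = []
    for ci, smi in (("c0", "CCO"), ("c1", "c1ccccc1")):
        for pi, seq in (("p0", "ACDEFGHIKL"), ("p1", "MNPQRSTVWY")):
            recs.append(InteractionRecord(ci, smi, pi, seq, 5.0))
    return InteractionDataset(recs)


def test_novel_pair_two_by_two_grid():
    """50/50 entity split of a fully crossed 2x2 grid: 1 test record,
    2 dropped straddlers."""
    ds = _crossed_dataset()
    asg = split_novel_pair(ds, test_fraction=0.5, seed=0, val_fraction=0.0)
    assert len(asg.indices("test")) == 1
    assert asg.n_dropped == 2
    assert len(asg.indices("train")) == 1
    assert all(check_disjoint(asg, ds).values())


def test_novel_pair_disjointness_and_determinism(small_dataset):
    a1 = split_novel_pair(small_dataset, test_fraction=0.3, seed=5)
    a2 = split_novel_pair(small_dataset, test_fraction=0.3, seed=5)
    assert a1.assignment == a2.assignment
    assert all(check_disjoint(a1, small_dataset).values())
    # validation carved at 80/20 from the training side
    n_train = len(a1.indices("train"))
    n_val = len(a1.indices("validation"))
    assert n_val == pytest.approx(0.25 * n_train, abs=1.5)


def test_novel_compound_entity_integrity(small_dataset):
    asg = split_novel_compound(small_dataset, test_fraction=0.3, seed=2)
    recs = small_dataset.records
    test_compounds = {recs[i].compound_id for i in asg.indices("test")}
    train_compounds = {recs[i].compound_id
                       for i in asg.indices("train") + asg.indices("validation")}
    assert not (test_compounds & train_compounds)
    # every record of a compound lands on the same side
    side = {}
    for i, part in asg.assignment.items():
        cid = recs[i].compound_id
        s = "test" if part == "test" else "train"
        assert side.setdefault(cid, s) == s
    assert asg.n_dropped == 0


def test_novel_compound_three_compounds_counting():
    recs = [InteractionRecord(f"c{i}", "CCO", f"p{j}", "ACDEF", 5.0)
            for i in range(3) for j in range(4)]
    ds = InteractionDataset(recs)
    asg = split_novel_compound(ds, test_fraction=1 / 3, seed=1,
                               val_fraction=0.0)
    test_c = {recs[i].compound_id for i in asg.indices("test")}
    assert len(test_c) == 1
    assert len(asg.indices("test")) == 4


def test_novel_protein_mirror(small_dataset):
    asg = split_novel_protein(small_dataset, test_fraction=0.3, seed=2)
    recs = small_dataset.records
    test_p = {recs[i].protein_id for i in asg.indices("test")}
    train_p = {recs[i].protein_id
               for i in asg.indices("train") + asg.indices("validation")}
    assert not (test_p & train_p)
    assert all(check_disjoint(asg, small_dataset).values())


def test_split_infeasible_fraction_raises():
    ds = _crossed_dataset()
    with pytest.raises(ValueError):
        split_novel_compound(ds, test_fraction=0.01, seed=0)


def test_filter_hard_thresholds(small_dataset):
    asg = split_novel_pair(small_dataset, test_fraction=0.3, seed=3)
    recs = small_dataset.records
    test = [recs[i] for i in asg.indices("test")]
    trainv = [recs[i] for i in
              asg.indices("train") + asg.indices("validation")]
    assert filter_hard(test, trainv, threshold=0.0) == []
    kept_all = filter_hard(test, trainv, threshold=1.0)
    # novel-pair guarantees no identical compound/protein across sides,
    # so nearest-neighbour similarity < 1 and everything stays
    assert kept_all == list(range(len(test)))


def test_filter_hard_monotone_in_threshold(small_dataset):
    asg = split_novel_pair(small_dataset, test_fraction=0.3, seed=3)
    recs = small_dataset.records
    test = [recs[i] for i in asg.indices("test")]
    trainv = [recs[i] for i in
              asg.indices("train") + asg.indices("validation")]
    prev = set()
    for thr in (0.05, 0.2, 0.5, 0.9):
        kept = set(filter_hard(test, trainv, threshold=thr))
        assert prev <= kept
        prev = kept


def test_filter_hard_removes_similar_compound():
    """A test compound at Tanimoto ~1 to training is removed at 0.3."""
    train = [InteractionRecord("c0", "CCO", "p0", "ACDEFGHIKL", 5.0)]
    test_same = [InteractionRecord("c1", "OCC", "p1", "MNPQRSTVWY", 5.0)]
    kept = filter_hard(test_same, train, threshold=0.3, mode="both")
    assert kept == []  # identical molecule, similarity 1 >= 0.3
    kept_either = filter_hard(test_same, train, threshold=0.3, mode="either")
    assert kept_either == [0]  # protein side is dissimilar


def test_kfold_rotation_and_coverage(small_dataset):
    folds = kfold(small_dataset, k=5, protocol="novel_compound", seed=9)
    recs = small_dataset.records
    seen = []
    for asg in folds:
        test_c = {recs[i].compound_id for i in asg.indices("test")}
        assert len(test_c) == 4  # 20 compounds over 5 folds
        assert all(check_disjoint(asg, small_dataset).values())
        seen.append(test_c)
    all_test = set().union(*seen)
    assert all_test == {r.compound_id for r in recs}
    for a, b in zip(seen, seen[1:]):
        assert not (a & b)


def test_kfold_deterministic(small_dataset):
    f1 = kfold(small_dataset, k=3, protocol="novel_protein", seed=4)
    f2 = kfold(small_dataset, k=3, protocol="novel_protein", seed=4)
    assert [a.assignment for a in f1] == [a.assignment for a in f2]


def test_kfold_too_few_entities():
    ds = _crossed_dataset()
    with pytest.raises(ValueError):
        kfold(ds, k=5, protocol="novel_compound", seed=0)
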