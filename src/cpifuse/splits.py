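"""Benchmark split protocols and similarity computations.

Cold-start protocols partition *entities* (compounds and/or proteins), not
records: ``novel_compound`` keeps test-set compounds unseen in training,
``novel_protein`` does the same for proteins, and ``novel_pair`` partitions
both sides and drops the records that straddle the partition.  The "hard"
variant additionally removes test records whose compound (Tanimoto) or
protein (alignment identity over a fixed length) similarity to the training
set reaches a threshold (0.3 in the benchmark protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from cpifuse.featurize import MorganFingerprint, smiles_to_fingerprint


def tanimoto(a: MorganFingerprint | np.ndarray, b: MorganFingerprint | np.ndarray) -> float:
    """|a AND b| / |a OR b| on binary bit vectors; 0 (with warning) if both empty."""
    av = a.bits if isinstance(a, MorganFingerprint) else np.asarray(a)
    bv = b.bits if isinstance(b, MorganFingerprint) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError("fingerprint length mismatch")
    av = av.astype(bool)
    bv = bv.astype(bool)
    union = np.logical_or(av, bv).sum()
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 0",
                      stacklevel=2)
        return 0.0
    return float(np.logical_and(av, bv).sum() / union)


def _aligner(gap_penalty: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -gap_penalty
    aligner.extend_gap_score = -gap_penalty
    return aligner


def protein_similarity(
    seq_a: str, seq_b: str, fixed_len: int = 500, gap_penalty: float = 0.5
) -> float:
    """Aligned identical residues over ``fixed_len`` (capped at 1).

    Global pairwise alignment with identity scoring (match 1, mismatch 0)
    and a linear gap penalty.
    """
    if not seq_a or not seq_b:
        raise ValueError("protein_similarity needs non-empty sequences")
    aln = _aligner(gap_penalty).align(seq_a.upper(), seq_b.upper())[0]
    identities = aln.counts().identities
    return min(identities / fixed_len, 1.0)


@dataclass
class SplitAssignment:
    """Record-level train/validation/test assignment for one protocol run."""

    assignment: dict[int, str]
    protocol: str
    seed: int
    params: dict = field(default_factory=dict)
    dropped: list[int] = field(default_factory=list)

    def indices(self, part: str) -> list[int]:
        return sorted(i for i, p in self.assignment.items() if p == part)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def _entity_partition(entities: list, test_fraction: float,
                      rng: np.random.Generator) -> tuple[set, set]:
    entities = sorted(set(entities))
    n_test = int(round(len(entities) * test_fraction))
    if n_test == 0 or n_test == len(entities):
        raise ValueError(
            f"test fraction {test_fraction} infeasible for "
            f"{len(entities)} entities (would give {n_test} test entities)"
        )
    order = rng.permutation(len(entities))
    test = {entities[i] for i in order[:n_test]}
    train = {e for e in entities if e not in test}
    return train, test


def _carve_validation(train_idx: list[int], val_fraction: float,
                      rng: np.random.Generator) -> tuple[list[int], list[int]]:
    order = rng.permutation(len(train_idx))
    n_val = int(round(len(train_idx) * val_fraction))
    val = [train_idx[i] for i in order[:n_val]]
    tr = [train_idx[i] for i in order[n_val:]]
    return tr, val


def _records(dataset):
    return dataset.records if hasattr(dataset, "records") else list(dataset)


def _make_assignment(train_idx, val_idx, test_idx, dropped, protocol, seed,
                     params) -> SplitAssignment:
    assignment = {}
    for i in train_idx:
        assignment[i] = "train"
    for i in val_idx:
        assignment[i] = "validation"
    for i in test_idx:
        assignment[i] = "test"
    return SplitAssignment(assignment=assignment, protocol=protocol,
                           seed=seed, params=params, dropped=sorted(dropped))


def split_novel_pair(dataset, test_fraction: float = 0.2, seed: int = 0,
                     val_fraction: float = 0.2) -> SplitAssignment:
    """Partition compounds AND proteins; test records use only test-side
    entities, train records only train-side; straddling records are dropped.
    """
    recs = _records(dataset)
    rng = np.random.default_rng(seed)
    c_train, c_test = _entity_partition([r.compound_id for r in recs],
                                        test_fraction, rng)
    p_train, p_test = _entity_partition([r.protein_id for r in recs],
                                        test_fraction, rng)
    train_idx, test_idx, dropped = [], [], []
    for i, r in enumerate(recs):
        if r.compound_id in c_test and r.protein_id in p_test:
            test_idx.append(i)
        elif r.compound_id in c_train and r.protein_id in p_train:
            train_idx.append(i)
        else:
            dropped.append(i)
    train_idx, val_idx = _carve_validation(train_idx, val_fraction, rng)
    return _make_assignment(
        train_idx, val_idx, test_idx, dropped, "novel_pair", seed,
        {"test_fraction": test_fraction, "val_fraction": val_fraction},
    )


def _split_by_entity(dataset, key, protocol, test_fraction, seed,
                     val_fraction) -> SplitAssignment:
    recs = _records(dataset)
    rng = np.random.default_rng(seed)
    e_train, e_test = _entity_partition([key(r) for r in recs],
                                        test_fraction, rng)
    train_idx = [i for i, r in enumerate(recs) if key(r) in e_train]
    test_idx = [i for i, r in enumerate(recs) if key(r) in e_test]
    train_idx, val_idx = _carve_validation(train_idx, val_fraction, rng)
    return _make_assignment(
        train_idx, val_idx, test_idx, [], protocol, seed,
        {"test_fraction": test_fraction, "val_fraction": val_fraction},
    )


def split_novel_compound(dataset, test_fraction: float = 0.2, seed: int = 0,
                         val_fraction: float = 0.2) -> SplitAssignment:
    """Compound-cold split: train and test compound sets are disjoint."""
    return _split_by_entity(dataset, lambda r: r.compound_id,
                            "novel_compound", test_fraction, seed,
                            val_fraction)


def split_novel_protein(dataset, test_fraction: float = 0.2, seed: int = 0,
                        val_fraction: float = 0.2) -> SplitAssignment:
    """Protein-cold split: train and test protein sets are disjoint."""
    return _split_by_entity(dataset, lambda r: r.protein_id,
                            "novel_protein", test_fraction, seed,
                            val_fraction)


def filter_hard(test_records, train_records, threshold: float = 0.3,
                mode: str = "both", fixed_len: int = 500,
                fp_radius: int = 2, fp_bits: int = 2048) -> list[int]:
    """Indices of test records that stay below the similarity threshold.

    For each test record the nearest-neighbour similarity to the training
    set is computed on both sides: max Tanimoto over training compounds and
    max alignment identity over training proteins.  ``mode="both"`` keeps a
    record only when *both* are below ``threshold`` (the stricter reading);
    ``mode="either"`` keeps it when at least one is.
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    train_records = list(train_records)
    test_records = list(test_records)
    train_fps = {}
    for r in train_records:
        if r.compound_id not in train_fps:
            train_fps[r.compound_id] = smiles_to_fingerprint(
                r.smiles, fp_radius, fp_bits
            )
    train_seqs = {r.protein_id: r.sequence for r in train_records}

    kept = []
    fp_cache, sim_cache = {}, {}
    for i, rec in enumerate(test_records):
        if rec.compound_id not in fp_cache:
            fp = smiles_to_fingerprint(rec.smiles, fp_radius, fp_bits)
            fp_cache[rec.compound_id] = max(
                (tanimoto(fp, tfp) for tfp in train_fps.values()), default=0.0
            )
        if rec.protein_id not in sim_cache:
            sim_cache[rec.protein_id] = max(
                (protein_similarity(rec.sequence, ts, fixed_len)
                 for ts in train_seqs.values()),
                default=0.0,
            )
        c_ok = fp_cache[rec.compound_id] < threshold
        p_ok = sim_cache[rec.protein_id] < threshold
        keep = (c_ok and p_ok) if mode == "both" else (c_ok or p_ok)
        if keep:
            kept.append(i)
    if not kept:
        warnings.warn("hard filter removed every test record", stacklevel=2)
    return kept


def kfold(dataset, k: int = 5, protocol: str = "novel_compound",
          seed: int = 0, val_fraction: float = 0.2) -> list[SplitAssignment]:
    """Entity-level k-fold cross-validation honoring a cold-split protocol.

    Entities (compounds, proteins, or both for ``novel_pair``) are shuffled
    once and dealt into k folds; fold i's test set uses fold-i entities only.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    recs = _records(dataset)
    rng = np.random.default_rng(seed)

    def fold_entities(values):
        ents = sorted(set(values))
        if len(ents) < k:
            raise ValueError(
                f"cannot make {k} folds from {len(ents)} entities"
            )
        order = rng.permutation(len(ents))
        folds = [set() for _ in range(k)]
        for pos, j in enumerate(order):
            folds[pos % k].add(ents[j])
        return folds

    c_folds = (fold_entities([r.compound_id for r in recs])
               if protocol in ("novel_pair", "novel_compound") else None)
    p_folds = (fold_entities([r.protein_id for r in recs])
               if protocol in ("novel_pair", "novel_protein") else None)
    if c_folds is None and p_folds is None:
        raise ValueError(f"unknown protocol: {protocol!r}")

    out = []
    for f in range(k):
        train_idx, test_idx, dropped = [], [], []
        for i, r in enumerate(recs):
            c_in = c_folds is not None and r.compound_id in c_folds[f]
            p_in = p_folds is not None and r.protein_id in p_folds[f]
            if protocol == "novel_pair":
                if c_in and p_in:
                    test_idx.append(i)
                elif not c_in and not p_in:
                    train_idx.append(i)
                else:
                    dropped.append(i)
            elif protocol == "novel_compound":
                (test_idx if c_in else train_idx).append(i)
            else:
                (test_idx if p_in else train_idx).append(i)
        train_idx, val_idx = _carve_validation(train_idx, val_fraction, rng)
        out.append(_make_assignment(
            train_idx, val_idx, test_idx, dropped, protocol, seed,
            {"fold": f, "k": k, "val_fraction": val_fraction},
        ))
    return out


def check_disjoint(split: SplitAssignment, dataset) -> dict[str, bool]:
    """Evaluate the protocol's disjointness predicate on an assignment."""
    recs = _records(dataset)
    parts = {p: set(split.indices(p)) for p in ("train", "validation", "test")}
    train_like = parts["train"] | parts["validation"]
    c_train = {recs[i].compound_id for i in train_like}
    p_train = {recs[i].protein_id for i in train_like}
    c_test = {recs[i].compound_id for i in parts["test"]}
    p_test = {recs[i].protein_id for i in parts["test"]}
    checks = {
        "partition": sum(len(v) for v in parts.values())
        == len(split.assignment)
        and not (parts["train"] & parts["test"]),
    }
    if split.protocol in ("novel_pair", "novel_compound"):
        checks["compounds_disjoint"] = not (c_train & c_test)
    if split.protocol in ("novel_pair", "novel_protein"):
        checks["proteins_disjoint"] = not (p_train & p_test)
    return checks
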