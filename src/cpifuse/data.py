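"""Dataset I/O, statistics and the synthetic interaction generator.

Interaction tables are delimited text with one (compound, protein, affinity)
row per measured cell of the compound x protein matrix.  The density of such
a matrix -- measured interactions as a percentage of all cells -- is the
headline statistic of the public affinity benchmarks; the printed counts of
those benchmarks ship here as :data:`BENCHMARK_TABLES` so the density
arithmetic can be exercised without downloads.

The synthetic generator emulates the benchmarks' structure: a sparse
interaction matrix at a configurable density, pKd-scale labels produced by a
planted sparse linear function of fingerprint bits and residue composition
(plus Gaussian noise), and an optional point-mass mode that concentrates a
fraction of the labels at a constant, mimicking the strong mode at pKd = 5
seen in kinase panels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from cpifuse._molecules import DRUG_SMILES
from cpifuse.featurize import smiles_to_fingerprint

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class InteractionRecord:
    compound_id: str
    smiles: str
    protein_id: str
    sequence: str
    affinity: float
    activity: int | None = None


@dataclass
class InteractionDataset:
    records: list[InteractionRecord]
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, indices) -> "InteractionDataset":
        return InteractionDataset([self.records[i] for i in indices],
                                  manifest=dict(self.manifest))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([r.affinity for r in self.records])


@dataclass
class DatasetStats:
    n_proteins: int
    n_drugs: int
    n_interactions: int
    density_percent: float

    def report(self) -> dict:
        # two-decimal display uses round-half-even
        return {
            "proteins": self.n_proteins,
            "drugs": self.n_drugs,
            "interactions": self.n_interactions,
            "density_percent": round(self.density_percent, 2),
        }


#: Printed summary counts of the public affinity benchmarks
#: (proteins, drugs, interactions).  The GPCR screen counts positive and
#: negative pairs separately; its interaction count is their sum.
BENCHMARK_TABLES: dict[str, dict[str, int]] = {
    "davis": {"proteins": 442, "drugs": 68, "interactions": 30056},
    "kiba": {"proteins": 229, "drugs": 2068, "interactions": 117657},
    "metz": {"proteins": 170, "drugs": 1423, "interactions": 35259},
    "pdbbind": {"proteins": 2079, "drugs": 5535, "interactions": 6989},
    "gpcr": {"proteins": 356, "drugs": 5359, "interactions": 7989 + 7354},
}


def dataset_stats(dataset: InteractionDataset | dict) -> DatasetStats:
    """Distinct-entity counts and matrix density (percent).

    Accepts a dataset or a plain counts dict with keys
    ``proteins/drugs/interactions`` (as in :data:`BENCHMARK_TABLES`).
    Density counts distinct IDs, not distinct structures.
    """
    if isinstance(dataset, dict):
        p, d, i = (dataset["proteins"], dataset["drugs"],
                   dataset["interactions"])
    else:
        if len(dataset) == 0:
            raise ValueError("empty dataset has no statistics")
        p = len({r.protein_id for r in dataset.records})
        d = len({r.compound_id for r in dataset.records})
        i = len(dataset)
    if p < 1 or d < 1 or i < 1:
        raise ValueError("counts must be positive")
    return DatasetStats(
        n_proteins=p, n_drugs=d, n_interactions=i,
        density_percent=100.0 * i / (p * d),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMNS = ("compound_id", "smiles", "protein_id", "sequence", "affinity")


def read_interactions(path, fmt: str = "csv",
                      column_map: dict[str, str] | None = None,
                      validate: bool = True) -> InteractionDataset:
    """Load a delimited interaction table; invalid rows are rejected with
    their line numbers recorded in the dataset manifest."""
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'tsv')")
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")

    records: list[InteractionRecord] = []
    rejected: list[dict] = []
    lg = RDLogger.logger()
    lg.setLevel(RDLogger.CRITICAL)
    try:
        for pos, row in enumerate(df.itertuples(index=False)):
            line_no = pos + 2  # header is line 1
            affinity = float(row.affinity)
            reason = None
            if not np.isfinite(affinity):
                reason = "non-finite affinity"
            elif validate and Chem.MolFromSmiles(str(row.smiles)) is None:
                reason = f"unparsable SMILES {row.smiles!r}"
            if reason:
                rejected.append({"line": line_no, "reason": reason})
                continue
            activity = None
            if "activity" in df.columns:
                raw = getattr(row, "activity")
                activity = None if pd.isna(raw) else int(raw)
            records.append(InteractionRecord(
                compound_id=str(row.compound_id), smiles=str(row.smiles),
                protein_id=str(row.protein_id), sequence=str(row.sequence),
                affinity=affinity, activity=activity,
            ))
    finally:
        lg.setLevel(RDLogger.ERROR)
    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} of {len(df)} rows "
            f"(lines {[r['line'] for r in rejected]})",
            stacklevel=2,
        )
    return InteractionDataset(records, manifest={"rejected": rejected,
                                                 "source": str(path)})


def write_interactions(dataset: InteractionDataset, path,
                       fmt: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    dataset.to_dataframe().to_csv(path, sep=sep, index=False)


def attach_fasta_sequences(dataset: InteractionDataset, fasta_path) -> None:
    """Fill record sequences by joining protein_id against a FASTA file."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    for r in dataset.records:
        if r.protein_id in seqs:
            r.sequence = seqs[r.protein_id]


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


def _alkane_variants(n: int) -> list[str]:
    """Deterministic supply of simple distinct molecules beyond the fixture:
    linear and singly-branched alkanes/alcohols."""
    out = []
    k = 2
    while len(out) < n:
        out.append("C" * k)
        if len(out) < n:
            out.append("C" * k + "O")
        if len(out) < n and k >= 3:
            out.append("CC(C)" + "C" * (k - 2))
        k += 1
    return out[:n]


def _residue_composition(seq: str) -> np.ndarray:
    counts = np.zeros(len(_AA20))
    for ch in seq:
        idx = _AA20.find(ch)
        if idx >= 0:
            counts[idx] += 1
    return counts / max(len(seq), 1)


def planted_label(manifest: dict, smiles: str, sequence: str) -> float:
    """Recompute the noiseless planted label g(compound, protein) from a
    generator manifest; the test suite uses this to verify reproducibility."""
    g = manifest["planted"]
    fp = smiles_to_fingerprint(smiles, g["fp_radius"], g["fp_bits"]).bits
    comp = _residue_composition(sequence)
    value = g["intercept"]
    value += float(np.dot(np.asarray(g["fp_weights"]),
                          fp[np.asarray(g["fp_indices"], dtype=int)]))
    value += float(np.dot(np.asarray(g["res_weights"]),
                          comp[np.asarray(g["res_indices"], dtype=int)]))
    return value


def generate_synthetic(
    n_compounds: int = 20,
    n_proteins: int = 10,
    density: float = 0.5,
    noise_sd: float = 0.3,
    seed: int = 0,
    length_range: tuple[int, int] = (50, 500),
    point_mass_fraction: float = 0.0,
    point_mass_value: float = 5.0,
    n_fp_terms: int = 10,
    n_res_terms: int = 5,
    fp_radius: int = 2,
    fp_bits: int = 2048,
    activity_threshold: float | None = None,
) -> InteractionDataset:
    """Generate a sparse synthetic compound x protein interaction table.

    Compounds come from the packaged drug-like fixture (alkane variants
    beyond 50); proteins are uniform random sequences over the 20-letter
    alphabet with lengths in ``length_range``.  ``density`` of the cells are
    observed (sampled without replacement).  Labels are pKd-scale:
    ``g(compound, protein) + N(0, noise_sd)`` where g is a sparse linear
    function of fingerprint bits and residue-composition fractions whose
    coefficients are recorded in the dataset manifest; with
    ``point_mass_fraction`` > 0 that fraction of labels is set to
    ``point_mass_value``, mimicking the benchmark skew.  Setting
    ``activity_threshold`` adds a binary activity flag (affinity >=
    threshold) for screening-mode evaluation.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if n_compounds < 1 or n_proteins < 1:
        raise ValueError("need at least one compound and one protein")
    n_cells = n_compounds * n_proteins
    n_obs = int(round(density * n_cells))
    if n_obs < 1:
        raise ValueError(
            f"density {density} over a {n_compounds}x{n_proteins} grid "
            "yields no observed cells"
        )
    rng = np.random.default_rng(seed)

    if n_compounds <= len(DRUG_SMILES):
        smiles_list = DRUG_SMILES[:n_compounds]
    else:
        smiles_list = DRUG_SMILES + _alkane_variants(
            n_compounds - len(DRUG_SMILES)
        )
    compounds = [(f"CMP{i:04d}", s) for i, s in enumerate(smiles_list)]

    proteins = []
    for j in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(_AA20), size=length))
        proteins.append((f"PRT{j:04d}", seq))

    fp_indices = rng.choice(fp_bits, size=n_fp_terms, replace=False)
    fp_weights = rng.normal(0.0, 1.0, size=n_fp_terms)
    res_indices = rng.choice(len(_AA20), size=n_res_terms, replace=False)
    res_weights = rng.normal(0.0, 8.0, size=n_res_terms)
    planted = {
        "intercept": 6.0,
        "fp_indices": [int(i) for i in fp_indices],
        "fp_weights": [float(w) for w in fp_weights],
        "res_indices": [int(i) for i in res_indices],
        "res_weights": [float(w) for w in res_weights],
        "fp_radius": fp_radius,
        "fp_bits": fp_bits,
    }
    manifest = {
        "generator": {
            "n_compounds": n_compounds, "n_proteins": n_proteins,
            "density": density, "noise_sd": noise_sd, "seed": seed,
            "length_range": list(length_range),
            "point_mass_fraction": point_mass_fraction,
            "point_mass_value": point_mass_value,
        },
        "planted": planted,
    }

    cells = rng.choice(n_cells, size=n_obs, replace=False)
    fps = {cid: smiles_to_fingerprint(s, fp_radius, fp_bits).bits
           for cid, s in compounds}
    comps = {pid: _residue_composition(seq) for pid, seq in proteins}

    records = []
    for cell in np.sort(cells):
        ci, pj = divmod(int(cell), n_proteins)
        cid, smi = compounds[ci]
        pid, seq = proteins[pj]
        value = (planted["intercept"]
                 + float(np.dot(fp_weights, fps[cid][fp_indices]))
                 + float(np.dot(res_weights, comps[pid][res_indices])))
        label = value + rng.normal(0.0, noise_sd)
        if point_mass_fraction > 0 and rng.random() < point_mass_fraction:
            label = point_mass_value
        activity = (None if activity_threshold is None
                    else int(label >= activity_threshold))
        records.append(InteractionRecord(
            compound_id=cid, smiles=smi, protein_id=pid, sequence=seq,
            affinity=float(label), activity=activity,
        ))
    return InteractionDataset(records, manifest=manifest)


def label_distribution(dataset: InteractionDataset, bin_edges) -> np.ndarray:
    """Histogram fractions of the affinity labels over the given bins."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    counts, _ = np.histogram(dataset.labels, bins=edges)
    return counts / len(dataset)


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
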