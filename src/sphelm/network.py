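"""Drug-target interaction networks and the gold-standard file dialects.

A :class:`DTINetwork` bundles the three objects every chemogenomic DTI
method consumes: a drug-drug similarity matrix (chemical-structure
similarity, e.g. SIMCOMP scores), a target-target similarity matrix
(sequence similarity) and a sparse binary interaction matrix linking the
two entity sets.  The file formats mirror the Yamanishi gold-standard
distribution: whitespace/tab-delimited labeled square matrices, and
two-column ``target<TAB>drug`` interaction pair lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DTINetwork",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_interaction_pairs",
    "write_interaction_pairs",
    "write_ranked_predictions",
    "read_ranked_predictions",
    "load_network",
    "save_network",
]


class FormatError(ValueError):
    """A file does not conform to the expected gold-standard dialect."""


@dataclass
class DTINetwork:
    """A bipartite drug-target network with per-side similarity matrices.

    Parameters
    ----------
    drug_ids, target_ids
        Ordered entity identifiers; row/column order of the matrices.
    drug_sim
        ``n x n`` drug-drug similarity, unit diagonal, values in [0, 1].
        Not required to be symmetric (SIMCOMP scores can be asymmetric).
    target_sim
        ``m x m`` target-target similarity with the same conventions.
    interactions
        ``n x m`` binary matrix; 1 marks a known interaction.
    """

    drug_ids: list[str]
    target_ids: list[str]
    drug_sim: np.ndarray
    target_sim: np.ndarray
    interactions: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = list(self.drug_ids)
        self.target_ids = list(self.target_ids)
        self.drug_sim = np.asarray(self.drug_sim, dtype=float)
        self.target_sim = np.asarray(self.target_sim, dtype=float)
        self.interactions = np.asarray(self.interactions)
        n, m = len(self.drug_ids), len(self.target_ids)
        if self.drug_sim.shape != (n, n):
            raise ValueError(f"drug_sim shape {self.drug_sim.shape} != ({n}, {n})")
        if self.target_sim.shape != (m, m):
            raise ValueError(f"target_sim shape {self.target_sim.shape} != ({m}, {m})")
        if self.interactions.shape != (n, m):
            raise ValueError(
                f"interactions shape {self.interactions.shape} != ({n}, {m})"
            )
        for name, sim in (("drug_sim", self.drug_sim), ("target_sim", self.target_sim)):
            if not np.allclose(np.diag(sim), 1.0):
                raise ValueError(f"{name} must have unit diagonal")
            if sim.min() < 0.0 or sim.max() > 1.0:
                raise ValueError(f"{name} values must lie in [0, 1]")
        vals = np.unique(self.interactions)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("interactions must be exactly 0 or 1")
        self.interactions = self.interactions.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_interactions(self) -> int:
        return int(self.interactions.sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DTINetwork(n_drugs={self.n_drugs}, n_targets={self.n_targets}, "
            f"n_interactions={self.n_interactions})"
        )


def _read_labeled_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_similarity_matrix(path: str | Path, symmetrize: bool = False) -> pd.DataFrame:
    """Read a labeled square similarity matrix.

    The file has a header row of entity ids and one id-labeled row per
    entity, whitespace or tab delimited.  Values must lie in [0, 1].
    Symmetry is *not* enforced; ``symmetrize=True`` averages the matrix
    with its transpose.
    """
    df = _read_labeled_table(path)
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"{path}: similarity table is {df.shape[0]}x{df.shape[1]}, not square"
        )
    if df.index.duplicated().any() or df.columns.duplicated().any():
        dupes = sorted(
            set(df.index[df.index.duplicated()]) | set(df.columns[df.columns.duplicated()])
        )
        raise FormatError(f"{path}: duplicate ids {dupes}")
    if not df.index.equals(df.columns):
        # tolerate a transposed header ordering only if the id sets agree
        if set(df.index) != set(df.columns):
            raise FormatError(f"{path}: row ids do not match column ids")
        df = df.loc[:, df.index]
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite similarity values")
    if values.min() < 0.0 or values.max() > 1.0:
        raise FormatError(f"{path}: similarity values outside [0, 1]")
    if symmetrize:
        df = (df + df.T) / 2.0
    return df


def write_similarity_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled similarity matrix in the same dialect ``read`` expects."""
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def read_interaction_pairs(
    path: str | Path,
    drug_ids: list[str],
    target_ids: list[str],
    columns: str = "target_drug",
) -> np.ndarray:
    """Read a two-column interaction pair list into an ``n x m`` binary matrix.

    The default column order is ``(target id, drug id)``, matching the
    gold-standard ``bind_orfhsa_drug_*`` files; ``columns="drug_target"``
    covers the transposed dialect.  Unknown ids raise with the offending
    line numbers; duplicate pairs are accepted once with a warning.
    """
    if columns not in ("target_drug", "drug_target"):
        raise ValueError(f"unknown column order {columns!r}")
    drug_pos = {d: i for i, d in enumerate(drug_ids)}
    target_pos = {t: j for j, t in enumerate(target_ids)}
    Y = np.zeros((len(drug_ids), len(target_ids)), dtype=np.int8)
    bad: list[str] = []
    n_dupes = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                bad.append(f"line {lineno}: expected 2 columns, got {len(parts)}")
                continue
            if columns == "target_drug":
                t_id, d_id = parts
            else:
                d_id, t_id = parts
            if d_id not in drug_pos or t_id not in target_pos:
                bad.append(f"line {lineno}: unknown pair ({d_id!r}, {t_id!r})")
                continue
            k, j = drug_pos[d_id], target_pos[t_id]
            if Y[k, j]:
                n_dupes += 1
            Y[k, j] = 1
    if bad:
        raise FormatError(f"{path}: " + "; ".join(bad))
    if n_dupes:
        warnings.warn(f"{path}: {n_dupes} duplicate pair(s) accepted once")
    return Y


def write_interaction_pairs(
    network: DTINetwork, path: str | Path, columns: str = "target_drug"
) -> None:
    """Write the known interactions as a two-column pair list (row-major order)."""
    ks, js = np.nonzero(network.interactions)
    with open(path, "w") as fh:
        for k, j in zip(ks, js):
            d, t = network.drug_ids[k], network.target_ids[j]
            if columns == "target_drug":
                fh.write(f"{t}\t{d}\n")
            else:
                fh.write(f"{d}\t{t}\n")


def write_ranked_predictions(
    pairs: list[tuple[str, str, float]], path: str | Path
) -> None:
    """Write ``(drug_id, target_id, score)`` triples as a TSV, best first.

    Sorted by descending score; ties keep their input order (stable sort).
    """
    scores = np.array([p[2] for p in pairs], dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("prediction scores must be finite")
    order = np.argsort(-scores, kind="stable")
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tscore\n")
        for i in order:
            d, t, s = pairs[i]
            fh.write(f"{d}\t{t}\t{s:.6f}\n")


def read_ranked_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})


# Conventional file names used by save_network/load_network and the CLI.
_DRUG_SIM = "drug_similarity.tsv"
_TARGET_SIM = "target_similarity.tsv"
_INTERACTIONS = "interactions.tsv"


def save_network(network: DTINetwork, directory: str | Path) -> Path:
    """Write the three network files into ``directory`` (created if absent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_similarity_matrix(
        pd.DataFrame(network.drug_sim, index=network.drug_ids, columns=network.drug_ids),
        directory / _DRUG_SIM,
    )
    write_similarity_matrix(
        pd.DataFrame(
            network.target_sim, index=network.target_ids, columns=network.target_ids
        ),
        directory / _TARGET_SIM,
    )
    write_interaction_pairs(network, directory / _INTERACTIONS)
    return directory


def load_network(directory: str | Path, symmetrize: bool = False) -> DTINetwork:
    """Load a network written by :func:`save_network` (or hand-assembled)."""
    directory = Path(directory)
    drug = read_similarity_matrix(directory / _DRUG_SIM, symmetrize=symmetrize)
    target = read_similarity_matrix(directory / _TARGET_SIM, symmetrize=symmetrize)
    drug_ids = list(drug.index)
    target_ids = list(target.index)
    Y = read_interaction_pairs(directory / _INTERACTIONS, drug_ids, target_ids)
    return DTINetwork(drug_ids, target_ids, drug.to_numpy(), target.to_numpy(), Y)
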