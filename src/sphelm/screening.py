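"""Reliable-negative screening for drug-target pairs.

Unlabeled drug-target pairs vastly outnumber known interactions, and
sampling negatives at random risks labeling undiscovered interactions as
negative.  Screening instead scores every unlabeled pair (k, j) by how
strongly the similarity neighborhoods of drug k and target j support an
interaction, and keeps only the lowest-scoring pairs as negatives: total
dissimilarity from every known interaction is the strongest available
evidence of non-interaction.

The score is a two-sided weighted profile.  With ``PS`` the
target-target similarity, ``CS`` the drug-drug similarity and ``y`` the
binary interaction matrix,

    SPC_jk = sum_{l != j} PS_jl * y_kl / sum_{l != j} PS_jl
    SCP_kj = sum_{i != k} CS_ki * y_ij / sum_{i != k} CS_ki
    S_kj   = (SPC_jk + SCP_kj) / 2

i.e. the similarity-weighted fraction of target j's neighborhood already
targeted by drug k, averaged with the drug-side mirror.  A side whose
denominator vanishes, or whose entity has no known interactions at all,
carries no evidence; it contributes 0 and is flagged undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import DTINetwork

__all__ = [
    "NegativeScoreMatrix",
    "LabeledPairSet",
    "score_pair",
    "score_all",
    "build_balanced_training_set",
    "build_feature_vectors",
]


@dataclass
class NegativeScoreMatrix:
    """Screening scores for every unlabeled pair of a network.

    ``scores`` holds S_kj (NaN at known-positive positions, which are
    never screened); ``spc`` and ``scp`` are the two one-sided matrices
    with 0 where undefined; ``undefined_mask`` marks pairs where *both*
    sides were undefined.
    """

    scores: np.ndarray
    spc: np.ndarray
    scp: np.ndarray
    undefined_mask: np.ndarray
    positive_mask: np.ndarray


@dataclass
class LabeledPairSet:
    """(drug index, target index, label) triples with screening scores.

    Labels are 1 for known interactions, 0 for screened negatives.
    Screening scores are NaN for positives (they are never scored).
    """

    drug_idx: np.ndarray
    target_idx: np.ndarray
    labels: np.ndarray
    scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.drug_idx = np.asarray(self.drug_idx, dtype=int)
        self.target_idx = np.asarray(self.target_idx, dtype=int)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.scores is None:
            self.scores = np.full(len(self.labels), np.nan)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.drug_idx)
        if not (len(self.target_idx) == len(self.labels) == len(self.scores) == n):
            raise ValueError("pair arrays must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positives(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negatives(self) -> int:
        return int((self.labels == 0).sum())

    def to_dataframe(self, network: DTINetwork | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "drug_idx": self.drug_idx,
                "target_idx": self.target_idx,
                "label": self.labels,
                "score": self.scores,
            }
        )
        if network is not None:
            df.insert(0, "drug_id", [network.drug_ids[k] for k in self.drug_idx])
            df.insert(1, "target_id", [network.target_ids[j] for j in self.target_idx])
        return df


def _side_scores(network: DTINetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized SPC/SCP matrices plus their per-side defined masks."""
    Y = network.interactions.astype(float)  # (n, m)
    PS = network.target_sim.copy()
    CS = network.drug_sim.copy()
    np.fill_diagonal(PS, 0.0)  # self-pair excluded from both sums
    np.fill_diagonal(CS, 0.0)

    # SPC[k, j]: target-side profile of drug k around target j.
    denom_t = PS.sum(axis=1)  # (m,)
    num_spc = Y @ PS.T  # (n, m): sum_l y_kl * PS_jl
    drug_has_support = Y.sum(axis=1) > 0  # drug k has at least one known target
    spc_defined = (denom_t[None, :] > 0) & drug_has_support[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        spc = np.where(spc_defined, num_spc / denom_t[None, :], 0.0)

    # SCP[k, j]: drug-side profile of target j around drug k.
    denom_d = CS.sum(axis=1)  # (n,)
    num_scp = CS @ Y  # (n, m): sum_i CS_ki * y_ij
    target_has_support = Y.sum(axis=0) > 0
    scp_defined = (denom_d[:, None] > 0) & target_has_support[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        scp = np.where(scp_defined, num_scp / denom_d[:, None], 0.0)

    return spc, scp, spc_defined, scp_defined


def score_pair(network: DTINetwork, k: int, j: int) -> float:
    """Screening score S_kj for drug index ``k`` and target index ``j``.

    Intended for unlabeled pairs; a known positive's own label never
    enters its score (the self-pair is excluded from both sums), so the
    value is well defined for any pair.
    """
    n, m = network.n_drugs, network.n_targets
    if not (0 <= k < n) or not (0 <= j < m):
        raise IndexError(f"pair index ({k}, {j}) out of range for {n}x{m} network")
    Y = network.interactions.astype(float)
    ps_row = network.target_sim[j].copy()
    ps_row[j] = 0.0
    cs_row = network.drug_sim[k].copy()
    cs_row[k] = 0.0

    spc = 0.0
    denom_t = ps_row.sum()
    if denom_t > 0 and Y[k].sum() > 0:
        spc = float(ps_row @ Y[k]) / denom_t
    scp = 0.0
    denom_d = cs_row.sum()
    if denom_d > 0 and Y[:, j].sum() > 0:
        scp = float(cs_row @ Y[:, j]) / denom_d
    return (spc + scp) / 2.0


def score_all(network: DTINetwork) -> NegativeScoreMatrix:
    """Score every unlabeled pair of the network (vectorized)."""
    spc, scp, spc_def, scp_def = _side_scores(network)
    scores = (spc + scp) / 2.0
    positive = network.interactions.astype(bool)
    scores = np.where(positive, np.nan, scores)
    undefined = ~spc_def & ~scp_def & ~positive
    return NegativeScoreMatrix(
        scores=scores,
        spc=spc,
        scp=scp,
        undefined_mask=undefined,
        positive_mask=positive,
    )


def build_balanced_training_set(
    network: DTINetwork,
    scores: NegativeScoreMatrix | None = None,
    ratio: float = 1.0,
) -> LabeledPairSet:
    """All known positives plus the lowest-scoring unlabeled pairs as negatives.

    Selects ``ceil(ratio * n_positives)`` negatives; ties in the score
    break by row-major pair index, so the selection is deterministic.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if scores is None:
        scores = score_all(network)
    Y = network.interactions
    n, m = Y.shape
    pos_k, pos_j = np.nonzero(Y)
    n_pos = len(pos_k)
    n_neg = math.ceil(ratio * n_pos)

    unl_k, unl_j = np.nonzero(Y == 0)
    if len(unl_k) < n_neg:
        raise ValueError(
            f"need {n_neg} negatives but only {len(unl_k)} unlabeled pairs exist"
        )
    unl_scores = scores.scores[unl_k, unl_j]
    flat = unl_k * m + unl_j  # row-major tie-break
    order = np.lexsort((flat, unl_scores))
    chosen = order[:n_neg]

    drug_idx = np.concatenate([pos_k, unl_k[chosen]])
    target_idx = np.concatenate([pos_j, unl_j[chosen]])
    labels = np.concatenate([np.ones(n_pos, dtype=np.int8), np.zeros(n_neg, dtype=np.int8)])
    pair_scores = np.concatenate([np.full(n_pos, np.nan), unl_scores[chosen]])
    return LabeledPairSet(drug_idx, target_idx, labels, pair_scores)


def build_feature_vectors(network: DTINetwork, pairs: LabeledPairSet) -> np.ndarray:
    """Concatenated similarity-profile features for each pair.

    Pair (k, j) maps to ``[target_sim[j, :], drug_sim[k, :]]`` of length
    m + n: the target's similarity profile followed by the drug's.
    Labels travel separately on the pair set.
    """
    if len(pairs) == 0:
        return np.empty((0, network.n_targets + network.n_drugs))
    if pairs.drug_idx.max() >= network.n_drugs or pairs.target_idx.max() >= network.n_targets:
        raise IndexError("pair indices out of range for network")
    return np.hstack(
        [network.target_sim[pairs.target_idx], network.drug_sim[pairs.drug_idx]]
    )
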