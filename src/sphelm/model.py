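"""Model/Results objects for the full DTI prediction experiment.

:class:`DTIModel` is built from a :class:`~sphelm.network.DTINetwork`
and holds the experiment design (screening ratio, hidden-layer size,
activation, CV folds).  ``fit()`` runs the whole pipeline — screen
reliable negatives, build similarity-profile features, tune the ELM's
hidden weights and biases with spherical search against the
cross-validated (AUC+AUPR)/2 fitness, and retrain the final ELM on the
complete balanced set — and returns a :class:`DTIResults` carrying the
optimum, per-fold metrics, the optimizer trace, and prediction and
summary methods.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, screening, spherical
from .elm import ELMModel, decode_params, random_params
from .network import DTINetwork, load_network, write_ranked_predictions

__all__ = ["DTIModel", "DTIResults"]


class DTIModel:
    """Drug-target interaction prediction experiment on one network.

    Parameters
    ----------
    network
        The DTI network (similarities plus known interactions).
    ratio
        Negatives per positive in the screened training set (default 1,
        a class-balanced set).
    hidden_nodes
        ELM hidden-layer size L.  The optimizer's search space has
        dimension ``L * (d + 1)`` with ``d = n_targets + n_drugs``.
    activation
        Hidden activation: ``sigmoid`` (default), ``tanh`` or
        ``identity``.
    folds
        Cross-validation folds for the fitness (default 10).
    """

    def __init__(
        self,
        network: DTINetwork,
        *,
        ratio: float = 1.0,
        hidden_nodes: int = 100,
        activation: str = "sigmoid",
        folds: int = 10,
    ) -> None:
        self.network = network
        self.ratio = ratio
        self.hidden_nodes = hidden_nodes
        self.activation = activation
        self.folds = folds
        self._scores: screening.NegativeScoreMatrix | None = None
        self._pairs: screening.LabeledPairSet | None = None
        self._X: np.ndarray | None = None

    @classmethod
    def from_directory(cls, directory: str | Path, **kwargs) -> "DTIModel":
        return cls(load_network(directory), **kwargs)

    # -- pipeline stages ----------------------------------------------
    @property
    def screening_scores(self) -> screening.NegativeScoreMatrix:
        if self._scores is None:
            self._scores = screening.score_all(self.network)
        return self._scores

    @property
    def pairs(self) -> screening.LabeledPairSet:
        """The class-balanced training pairs (positives + screened negatives)."""
        if self._pairs is None:
            self._pairs = screening.build_balanced_training_set(
                self.network, self.screening_scores, ratio=self.ratio
            )
        return self._pairs

    @property
    def features(self) -> np.ndarray:
        if self._X is None:
            self._X = screening.build_feature_vectors(self.network, self.pairs)
        return self._X

    @property
    def n_params(self) -> int:
        d = self.network.n_targets + self.network.n_drugs
        return self.hidden_nodes * (d + 1)

    def fitness(self, parameter_vector: np.ndarray, fold_seed: int = 0) -> float:
        """CV fitness of a flat hidden-layer parameter vector."""
        return metrics.fitness(
            parameter_vector,
            self.features,
            self.pairs.labels,
            self.hidden_nodes,
            activation=self.activation,
            k=self.folds,
            fold_seed=fold_seed,
        )

    def fit(
        self,
        budget: int = 10_000,
        seed: int = 0,
        ss_config: spherical.SSConfig | None = None,
        fold_seed: int | None = None,
    ) -> "DTIResults":
        """Run the experiment and return the fitted results.

        ``budget`` is the spherical-search evaluation budget; 0 disables
        the optimizer and evaluates a single random parameter draw (the
        plain random-parameter ELM baseline).  ``fold_seed`` fixes the
        CV split used by every fitness evaluation (defaults to ``seed``)
        so the optimizer sees a stationary objective.
        """
        t0 = time.perf_counter()
        fold_seed = seed if fold_seed is None else fold_seed
        X, y = self.features, self.pairs.labels
        objective = lambda v: -self.fitness(v, fold_seed=fold_seed)

        if budget > 0:
            config = ss_config or spherical.SSConfig(
                nfes_max=budget, lower=-1.0, upper=1.0, seed=seed
            )
            ss = spherical.optimize(objective, self.n_params, config)
            best_params, trace, nfes = ss.best_x, ss.trace, ss.nfes
        else:
            rng = np.random.default_rng(seed)
            best_params = random_params(
                self.hidden_nodes, X.shape[1], rng, scale=1.0
            )
            trace = pd.DataFrame(
                [(0, 1, 1, objective(best_params))],
                columns=["iteration", "nfes", "pop_size", "best_value"],
            )
            nfes = 1

        W, b = decode_params(best_params, self.hidden_nodes, X.shape[1])
        cv = metrics.cross_validate(
            W, b, X, y, activation=self.activation, k=self.folds, seed=fold_seed
        )
        final_elm = ELMModel(W, b, self.activation).fit(X, y)
        return DTIResults(
            model=self,
            best_params=best_params,
            elm=final_elm,
            cv=cv,
            trace=trace,
            seed=seed,
            fold_seed=fold_seed,
            budget=budget,
            nfes=nfes,
            wall_time=time.perf_counter() - t0,
        )


@dataclass
class DTIResults:
    """Fitted experiment: optimum, per-fold metrics, trace, predictions."""

    model: DTIModel
    best_params: np.ndarray
    elm: ELMModel
    cv: metrics.CVResult
    trace: pd.DataFrame
    seed: int
    fold_seed: int
    budget: int
    nfes: int
    wall_time: float = 0.0

    @property
    def fold_auc(self) -> np.ndarray:
        return self.cv.fold_auc

    @property
    def fold_aupr(self) -> np.ndarray:
        return self.cv.fold_aupr

    @property
    def auc(self) -> float:
        return self.cv.auc

    @property
    def aupr(self) -> float:
        return self.cv.aupr

    @property
    def fitness(self) -> float:
        return self.cv.fitness

    def reevaluate(self, fold_seed: int) -> metrics.CVResult:
        """Re-run CV at the optimum with a fresh fold split.

        The gap between this and the in-search fitness quantifies the
        selection optimism of optimizing on a fixed split.
        """
        W, b = decode_params(
            self.best_params, self.model.hidden_nodes, self.model.features.shape[1]
        )
        return metrics.cross_validate(
            W, b, self.model.features, self.model.pairs.labels,
            activation=self.model.activation, k=self.model.folds, seed=fold_seed,
        )

    def predict_novel(self, mode: str = "unlabeled") -> pd.DataFrame:
        """Score and rank candidate interactions, best first.

        ``mode="unlabeled"`` scores every pair without a known
        interaction; ``mode="exclude_training"`` additionally drops the
        screened training negatives.  Ties keep row-major pair order
        (stable sort).
        """
        if mode not in ("unlabeled", "exclude_training"):
            raise ValueError(f"unknown mode {mode!r}")
        net = self.model.network
        Y = net.interactions
        mask = Y == 0
        if mode == "exclude_training":
            pairs = self.model.pairs
            neg = pairs.labels == 0
            mask = mask.copy()
            mask[pairs.drug_idx[neg], pairs.target_idx[neg]] = False
        ks, js = np.nonzero(mask)
        pair_set = screening.LabeledPairSet(ks, js, np.zeros(len(ks), dtype=np.int8))
        X = screening.build_feature_vectors(net, pair_set)
        scores = self.elm.predict(X)
        order = np.argsort(-scores, kind="stable")
        return pd.DataFrame(
            {
                "drug_id": [net.drug_ids[k] for k in ks[order]],
                "target_id": [net.target_ids[j] for j in js[order]],
                "score": scores[order],
            }
        )

    def save_predictions(self, path: str | Path, mode: str = "unlabeled") -> None:
        df = self.predict_novel(mode=mode)
        write_ranked_predictions(
            list(zip(df["drug_id"], df["target_id"], df["score"])), path
        )

    def summary(self) -> str:
        """Human-readable results table."""
        m = self.model
        lines = [
            "Spherical-search ELM DTI experiment",
            "=" * 52,
            f"network            {m.network.n_drugs} drugs x {m.network.n_targets} targets, "
            f"{m.network.n_interactions} known interactions",
            f"training pairs     {m.pairs.n_positives} positives + "
            f"{m.pairs.n_negatives} screened negatives",
            f"hidden nodes (L)   {m.hidden_nodes}   activation: {m.activation}",
            f"search dimension   {self.best_params.size}",
            f"SS budget          {self.budget} evaluations (used {self.nfes})",
            f"CV folds           {m.folds}   fold seed {self.fold_seed}   seed {self.seed}",
            "-" * 52,
            f"mean AUC           {self.auc:.4f}",
            f"mean AUPR          {self.aupr:.4f}",
            f"fitness            {self.fitness:.4f}  (fold sum {self.cv.fitness_sum:.4f})",
            "-" * 52,
            "fold   AUC      AUPR",
        ]
        for i, (a, p) in enumerate(zip(self.fold_auc, self.fold_aupr)):
            lines.append(f"{i + 1:>4d}   {a:.4f}   {p:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "config": {
                "n_drugs": self.model.network.n_drugs,
                "n_targets": self.model.network.n_targets,
                "n_interactions": self.model.network.n_interactions,
                "ratio": self.model.ratio,
                "hidden_nodes": self.model.hidden_nodes,
                "activation": self.model.activation,
                "folds": self.model.folds,
                "budget": self.budget,
                "seed": self.seed,
                "fold_seed": self.fold_seed,
            },
            "nfes": self.nfes,
            "metrics": self.cv.to_dict(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def plot_trace(self, ax=None):
        """Best-so-far fitness (= -objective) against evaluations used."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace["nfes"], -self.trace["best_value"], drawstyle="steps-post")
        ax.set_xlabel("objective evaluations")
        ax.set_ylabel("best CV fitness")
        ax.set_title("Spherical-search convergence")
        return ax
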