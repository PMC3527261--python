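"""Model-level interface: build, fit, predict.

`TFActivityModel` bundles an expression set with the (approximately known)
training network; `fit` runs the training-phase MCMC and returns a
:class:`~tftarget.training.TrainingResults` posterior, from which a
:class:`~tftarget.predict.StructureScorer` performs genome-wide scoring.
"""

from __future__ import annotations

import logging

import pandas as pd

from .data import ExpressionSet, TrainingNetwork
from .predict import PredictionConfig, StructureScorer
from .training import TrainingConfig, TrainingResults, robust_filter, run_training

logger = logging.getLogger(__name__)

__all__ = ["TFActivityModel"]


class TFActivityModel:
    """Two-phase Bayesian model of combinatorial transcriptional regulation.

    Parameters
    ----------
    data : ExpressionSet
        Expression series for the training genes and the TF mRNAs, across
        one or more conditions/replicates.
    network : TrainingNetwork
        Binary genes x TFs matrix declaring which TF regulates which
        training gene (may contain errors; weights of absent links are
        clamped to zero).
    config : TrainingConfig, optional

    Examples
    --------
    >>> model = TFActivityModel(data, network, TrainingConfig(iterations=2000))
    >>> posterior = model.fit(seed=1)
    >>> print(posterior.delta_summary())
    >>> scores = model.predict(posterior, test_data, seed=1)
    """

    def __init__(self, data: ExpressionSet, network: TrainingNetwork,
                 config: TrainingConfig | None = None):
        self.data = data
        self.network = network
        self.config = config or TrainingConfig()

    @classmethod
    def from_frames(cls, expression: pd.DataFrame, network: pd.DataFrame,
                    config: TrainingConfig | None = None):
        """Build from raw long-form expression and wide network DataFrames."""
        return cls(ExpressionSet(expression), TrainingNetwork(network), config)

    def fit(self, seed: int = 0) -> TrainingResults:
        """Run the training-phase MCMC (deterministic given the seed)."""
        training_set = self.data.subset(
            list(self.network.genes) + list(self.network.tf_names)
        )
        return run_training(training_set, self.network, self.config, seed=seed)

    def fit_robust(self, seed: int = 0, threshold: float | None = None):
        """Two-stage robustified fit.

        Stage 1 trains with per-gene adaptive noise variances; genes needing
        more extra variance than the threshold (i.e. genes the modelled TFs
        cannot explain) are excluded, and stage 2 retrains on the survivors
        without adaptive variances.  Returns (posterior, retained_genes).
        """
        from dataclasses import replace

        threshold = self.config.adaptive_threshold if threshold is None else threshold
        stage1 = replace(self.config, use_adaptive=True)
        post1 = TFActivityModel(self.data, self.network, stage1).fit(seed=seed)
        retained = robust_filter(post1, threshold)
        logger.info("robust filter retained %d/%d genes", len(retained),
                    len(self.network.genes))
        if not retained:
            raise ValueError("robust filter removed every training gene")
        net2 = TrainingNetwork(self.network.frame.loc[retained])
        stage2 = replace(self.config, use_adaptive=False)
        post2 = TFActivityModel(self.data, net2, stage2).fit(seed=seed + 1)
        return post2, retained

    def predict(self, posterior: TrainingResults, data: ExpressionSet,
                genes=None, config: PredictionConfig | None = None,
                seed: int = 0, n_jobs: int = 1):
        """Score all regulation structures for the given test genes."""
        scorer = StructureScorer(posterior, config)
        return scorer.score_genes(data, genes=genes, seed=seed, n_jobs=n_jobs)
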