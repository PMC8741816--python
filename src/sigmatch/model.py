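"""Model/Results interface over the congruence pipeline.

:class:`CongruenceModel` is constructed from data (model signatures plus a
reference — either a prebuilt portrait or the human datasets to build one
from) and :meth:`CongruenceModel.fit` returns a
:class:`CongruenceResults` carrying the hypergeometric ranking, the optional
machine-learning ranking, their agreement, and a ``summary()`` table.
Simulation, congruent-gene extraction, RRHO heatmaps and the 2-D embedding
hang off these two objects; the functional modules remain usable directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import congruent, embedding, ml, rrho, scoring
from .exceptions import InsufficientDataError, InvalidInputError
from .portrait import Portrait, build_portrait
from .signatures import GeneSignature, load_manifest, top_ranked_sets
from .simulate import SimulationConfig, simulate_human_datasets, simulate_models

__all__ = ["CongruenceModel", "CongruenceResults"]


class CongruenceModel:
    """Congruence of many model signatures with one reference condition.

    Parameters
    ----------
    models : list of GeneSignature
        Candidate model datasets (typically animal CNS contrasts).
    reference : GeneSignature or Portrait, optional
        The condition signature the models are judged against.  If omitted,
        it is built as a consensus portrait from ``human_datasets``.
    human_datasets : list of GeneSignature, optional
        Individual datasets of the reference condition.  Needed to build
        the portrait when ``reference`` is None and to construct the
        real-data ML training set.
    n_top : int
        Up/down list size for the quadrant tests.
    min_shared : int
        Minimum genes a model must share with the reference to be scored.
    min_presence_frac : float
        Presence floor used when building the portrait from
        ``human_datasets``.
    """

    def __init__(
        self,
        models: list[GeneSignature],
        reference: GeneSignature | Portrait | None = None,
        human_datasets: list[GeneSignature] | None = None,
        n_top: int = 1000,
        min_shared: int = 100,
        min_presence_frac: float = 0.5,
    ):
        if not models:
            raise InvalidInputError("need at least one model signature")
        if reference is None and not human_datasets:
            raise InvalidInputError("need a reference portrait or human datasets to build one")
        self.models = list(models)
        self.human_datasets = list(human_datasets or [])
        self.n_top = n_top
        self.min_shared = min_shared
        if reference is None:
            reference = build_portrait(
                self.human_datasets, min_presence_frac=min_presence_frac,
                portrait_id="DEPRESSION_PORTRAIT",
            )
        self.portrait = reference if isinstance(reference, Portrait) else None
        self.reference = (
            reference.as_signature() if isinstance(reference, Portrait) else reference
        )

    @classmethod
    def from_manifest(cls, path, **kwargs) -> "CongruenceModel":
        """Build from a manifest CSV listing model/human/portrait signature files."""
        manifest = load_manifest(path)
        models = manifest.load_group("model")
        humans = manifest.load_group("human")
        prebuilt = manifest.load_group("portrait")
        if len(prebuilt) > 1:
            raise InvalidInputError("manifest lists more than one prebuilt portrait")
        reference = prebuilt[0] if prebuilt else None
        return cls(models=models, reference=reference, human_datasets=humans, **kwargs)

    @classmethod
    def from_simulation(cls, cfg: SimulationConfig, **kwargs) -> "CongruenceModel":
        """Build from a synthetic suite with planted congruence."""
        truth, humans = simulate_human_datasets(cfg)
        models = simulate_models(cfg, truth)
        obj = cls(models=models, human_datasets=humans, **kwargs)
        obj.truth = truth
        return obj

    def fit(
        self,
        ml_ranking: bool = True,
        seed: int = 0,
        n_features: int = 2000,
        n_shuffles: int = 20,
        classifiers: list | None = None,
        exclude_features: tuple[str, ...] = (),
    ) -> "CongruenceResults":
        """Score and rank every model; optionally add the ML ranking.

        The hypergeometric ranking is always computed.  When ``ml_ranking``
        is true, the classifier committee is trained on the real (if human
        datasets are available) and shuffled training sets and the mean-rank
        ML ordering plus its agreement with the hypergeometric ranking are
        attached to the results.
        """
        ranking = scoring.rank_models(
            self.models, self.reference, n_top=self.n_top, min_shared=self.min_shared
        )

        ml_table = None
        agreement = None
        feature_space = None
        if ml_ranking:
            source = self.portrait if self.portrait is not None else self.reference
            feature_space = ml.FeatureSpace.from_portrait(
                source, n_features=n_features, exclude=exclude_features
            )
            training = []
            if len(self.human_datasets) >= 2:
                training.append(ml.build_training_real(self.human_datasets, feature_space))
            training.append(
                ml.build_training_shuffled(source, feature_space, n_shuffles=n_shuffles, seed=seed)
            )
            clfs = classifiers if classifiers is not None else ml.default_classifiers(seed=seed)
            ml_table = ml.ml_rank(self.models, training, clfs, feature_space)
            agreement = self._agreement(ranking, ml_table)

        return CongruenceResults(
            model=self,
            ranking=ranking,
            ml_ranking=ml_table,
            rank_agreement=agreement,
            feature_space=feature_space,
            seed=seed,
        )

    @staticmethod
    def _agreement(ranking: scoring.RankingTable, ml_table: pd.DataFrame):
        hg = ranking.ranks()
        mlr = ml_table.set_index("dataset_id")["ml_rank"]
        shared = hg.index.intersection(mlr.index)
        if len(shared) < 3:
            return None
        from scipy import stats

        res = stats.pearsonr(hg.loc[shared].astype(float), mlr.loc[shared].astype(float))
        return float(res.statistic), float(res.pvalue)


@dataclass
class CongruenceResults:
    """Fitted congruence ranking plus diagnostics.

    Attributes
    ----------
    ranking : RankingTable
        Hypergeometric quadrant-score ranking (rank 1 = most congruent).
    ml_ranking : DataFrame or None
        Per-classifier probabilities, per-pair ranks and the averaged final
        ML rank.
    rank_agreement : (r, p) or None
        Pearson correlation between the two rank orderings.
    """

    model: CongruenceModel
    ranking: scoring.RankingTable
    ml_ranking: pd.DataFrame | None = None
    rank_agreement: tuple[float, float] | None = None
    feature_space: ml.FeatureSpace | None = field(default=None, repr=False)
    seed: int = 0

    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the fit: header, agreement, top models."""
        ref = self.model.reference.dataset_id
        scored = self.ranking.frame[self.ranking.frame["status"] == "scored"]
        lines = [
            "Signature congruence ranking",
            "=" * 60,
            f"Reference:            {ref}",
            f"Models scored:        {len(scored)} "
            f"(skipped: {len(self.ranking.frame) - len(scored)})",
            f"Top-list size n_top:  {self.model.n_top}",
        ]
        if self.rank_agreement is not None:
            r, p = self.rank_agreement
            lines.append(f"ML vs hypergeometric ranks: Pearson r = {r:.3f} (p = {p:.3g})")
        lines.append("")
        cols = ["rank", "dataset_id", "score", "kA", "kB", "kC", "kD", "n_shared"]
        head = scored.head(top)[cols].copy()
        head["rank"] = head["rank"].astype(int)
        head["score"] = head["score"].map(lambda v: f"{v:.3f}")
        lines.append(head.to_string(index=False))
        return "\n".join(lines)

    def congruent_genes(self, top_k: int = 3, k_min: int = 3):
        """(up_up, down_down) per top-ranked model, and the recurrent genes.

        Returns ``(per_model, common_up, common_down)`` where ``per_model``
        maps dataset_id to its congruent sets against the reference.
        ``k_min`` is clipped to the number of models examined.
        """
        ids = self.ranking.frame[self.ranking.frame["status"] == "scored"].head(top_k)[
            "dataset_id"
        ]
        by_id = {m.dataset_id: m for m in self.model.models}
        per_model = {}
        for mid in ids:
            rs_m, rs_ref = top_ranked_sets(by_id[mid], self.model.reference, self.model.n_top)
            per_model[mid] = congruent.pairwise_congruent(rs_m, rs_ref)
        pairs = [(c.up_up, c.down_down) for c in per_model.values()]
        eff_k = min(k_min, len(pairs))
        common_up, common_down = congruent.common_across_models(pairs, k_min=eff_k)
        return per_model, common_up, common_down

    def rrho(self, dataset_id: str, step: int | None = None) -> rrho.RRHOMatrix:
        """RRHO heatmap of one model (Y) against the reference (X)."""
        by_id = {m.dataset_id: m for m in self.model.models}
        if dataset_id not in by_id:
            raise InvalidInputError(f"unknown model {dataset_id!r}")
        return rrho.rrho_matrix(by_id[dataset_id], self.model.reference, step=step)

    def embed(
        self, n_features: int = 2000, backend: str = "umap", seed: int | None = None
    ) -> pd.DataFrame:
        """2-D embedding of all models plus the reference portrait."""
        source = self.model.portrait if self.model.portrait is not None else self.model.reference
        return embedding.embed_models(
            self.model.models, source, n_features=n_features,
            seed=self.seed if seed is None else seed, backend=backend,
        )

    def recovery_spearman(self) -> float:
        """Spearman correlation of scores with planted congruence (synthetic fits).

        Only available when the model was built via ``from_simulation`` or
        the model signatures carry ``planted_congruence`` metadata.
        """
        planted = {
            m.dataset_id: m.metadata["planted_congruence"]
            for m in self.model.models
            if "planted_congruence" in m.metadata
        }
        sc = self.ranking.scores()
        shared = [i for i in sc.index if i in planted]
        if len(shared) < 3:
            raise InsufficientDataError("no planted congruence metadata to recover")
        from scipy import stats

        return float(
            stats.spearmanr([planted[i] for i in shared], sc.loc[shared]).statistic
        )
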