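"""Ranking of model signatures against a reference portrait.

Every candidate model is scored with the fixed-cutoff quadrant congruence
score (:mod:`sigmatch.rrho`) against the reference; the ranking table orders
models best-first.  Two rankings over the same models are compared with a
Pearson correlation on the rank integers (equivalent to a Spearman
correlation on the underlying scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyRankingError, InsufficientDataError, InvalidInputError
from .portrait import Portrait
from .rrho import quadrant_score
from .signatures import GeneSignature, top_ranked_sets

__all__ = ["RankingTable", "rank_models", "rank_correlation"]


@dataclass
class RankingTable:
    """Models ordered by congruence score (rank 1 = most congruent).

    ``frame`` has one row per model: dataset_id, score, rank, the quadrant
    evidence A..D and overlap counts kA..kD, the shared-universe size and a
    status column (``"scored"`` or ``"skipped"`` when the model shared too
    few genes with the reference to score).  Skipped rows carry NaN score
    and rank; scored ranks are a permutation of 1..n_scored.
    """

    frame: pd.DataFrame
    reference_id: str

    def ranks(self) -> pd.Series:
        """Rank per dataset_id, scored rows only."""
        scored = self.frame[self.frame["status"] == "scored"]
        return scored.set_index("dataset_id")["rank"].astype(int)

    def scores(self) -> pd.Series:
        scored = self.frame[self.frame["status"] == "scored"]
        return scored.set_index("dataset_id")["score"].astype(float)

    def to_csv(self, path, float_format: str = "%.10g") -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False, float_format=float_format, lineterminator="\n")
        return path


def rank_models(
    models: list[GeneSignature],
    reference: GeneSignature | Portrait,
    n_top: int = 1000,
    min_shared: int = 100,
) -> RankingTable:
    """Score every model against the reference and rank best-first.

    Parameters
    ----------
    models : list of GeneSignature
        Candidate model datasets.
    reference : GeneSignature or Portrait
        The signature the models are judged against (typically the human
        depression portrait).
    n_top : int
        Size of the up/down gene lists entering the quadrant tests.
    min_shared : int
        Models sharing fewer genes than this with the reference are reported
        with status ``"skipped"`` instead of an unstable score.
    """
    if not models:
        raise InvalidInputError("need at least one model to rank")
    if isinstance(reference, Portrait):
        reference = reference.as_signature()

    rows = []
    for m in models:
        shared = len(m.genes & reference.genes)
        meta = {
            "accession": m.metadata.get("accession", ""),
            "species": m.species,
            "sex": m.metadata.get("sex", ""),
            "tissue": m.metadata.get("tissue", ""),
        }
        if shared < min_shared:
            rows.append(
                {"dataset_id": m.dataset_id, "status": "skipped", "n_shared": shared,
                 "score": np.nan, "A": np.nan, "B": np.nan, "C": np.nan, "D": np.nan,
                 "kA": 0, "kB": 0, "kC": 0, "kD": 0, **meta}
            )
            continue
        rs_m, rs_ref = top_ranked_sets(m, reference, n_top=n_top)
        q = quadrant_score(rs_m, rs_ref)
        rows.append(
            {"dataset_id": m.dataset_id, "status": "scored", "n_shared": shared,
             "score": q.score, "A": q.A, "B": q.B, "C": q.C, "D": q.D,
             "kA": q.kA, "kB": q.kB, "kC": q.kC, "kD": q.kD, **meta}
        )

    frame = pd.DataFrame(rows)
    scored = frame[frame["status"] == "scored"].copy()
    if scored.empty:
        raise EmptyRankingError(
            f"every model shared fewer than {min_shared} genes with "
            f"{reference.dataset_id!r}; nothing to rank"
        )
    scored = scored.sort_values(["score", "dataset_id"], ascending=[False, True], kind="mergesort")
    scored["rank"] = np.arange(1, len(scored) + 1)
    skipped = frame[frame["status"] == "skipped"].copy()
    skipped["rank"] = np.nan
    out = pd.concat([scored, skipped], ignore_index=True)
    cols = ["rank", "dataset_id", "score", "A", "B", "C", "D",
            "kA", "kB", "kC", "kD", "n_shared", "status",
            "accession", "species", "sex", "tissue"]
    return RankingTable(frame=out[cols], reference_id=reference.dataset_id)


def rank_correlation(r1: RankingTable, r2: RankingTable) -> tuple[float, float]:
    """Pearson correlation of the rank integers shared by two ranking tables.

    Because the inputs are ranks, this equals a Spearman correlation on the
    underlying scores.  Returns ``(r, two-sided p)``.
    """
    a, b = r1.ranks(), r2.ranks()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"rank correlation needs >= 3 shared datasets; got {len(shared)}"
        )
    res = stats.pearsonr(a.loc[shared].to_numpy(float), b.loc[shared].to_numpy(float))
    return float(res.statistic), float(res.pvalue)
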