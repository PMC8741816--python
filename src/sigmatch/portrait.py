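"""Consensus portraits: one signature summarising many datasets of a condition.

Given several signed-significance signatures of the same condition (e.g. 29
human depression case/control studies), the portrait keeps, per gene, a
consensus value that rewards direction-consistent change and cancels
conflicting change:

    consensus(g) = mean(values of g) * (2 * consistency(g) - 1)

where ``consistency(g)`` is the largest fraction of nonzero entries sharing
one sign (0.5 = even split, 1.0 = unanimous).  A gene present in fewer than
``ceil(min_presence_frac * n_datasets)`` datasets is omitted, so rarely
measured genes cannot dominate.  A 50/50 direction conflict therefore maps
to consensus 0, and a unanimous gene keeps its mean magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .signatures import GeneSignature

__all__ = ["Portrait", "build_portrait"]


@dataclass
class Portrait:
    """Consensus signature over several datasets of one condition."""

    values: dict[str, float]
    n_datasets: int
    presence: dict[str, int]
    consistency: dict[str, float]
    portrait_id: str = "PORTRAIT"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def as_signature(self, dataset_id: str | None = None) -> GeneSignature:
        """View the portrait as a plain signature so every comparison applies."""
        return GeneSignature(
            dataset_id=dataset_id or self.portrait_id,
            values=dict(self.values),
            species="consensus",
            metadata=dict(self.metadata),
        )

    def top_genes(self, n: int) -> list[str]:
        """The ``n`` genes with largest |consensus| (ties by ascending symbol)."""
        return sorted(self.values, key=lambda g: (-abs(self.values[g]), g))[:n]


def build_portrait(
    datasets: list[GeneSignature],
    min_presence_frac: float = 0.5,
    portrait_id: str = "PORTRAIT",
) -> Portrait:
    """Combine >= 2 signatures of one condition into a consensus portrait.

    Parameters
    ----------
    datasets : list of GeneSignature
        Input signatures; order is irrelevant.
    min_presence_frac : float in (0, 1]
        A gene must appear in at least ``ceil(min_presence_frac * n)``
        datasets to enter the portrait.
    """
    n = len(datasets)
    if n < 2:
        raise InvalidInputError(f"a portrait needs >= 2 datasets; got {n}")
    if not (0.0 < min_presence_frac <= 1.0):
        raise InvalidInputError(f"min_presence_frac must be in (0, 1]; got {min_presence_frac}")
    floor = int(np.ceil(min_presence_frac * n))

    table = pd.concat([d.to_series() for d in datasets], axis=1)
    arr = table.to_numpy(dtype=float)  # genes x datasets, NaN where absent
    present = np.isfinite(arr)
    presence = present.sum(axis=1)

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(present, arr, np.nan), axis=1)
    n_pos = ((arr > 0) & present).sum(axis=1)
    n_neg = ((arr < 0) & present).sum(axis=1)
    nonzero = n_pos + n_neg
    # zero entries count toward presence but carry no direction information
    frac_major = np.where(nonzero > 0, np.maximum(n_pos, n_neg) / np.maximum(nonzero, 1), 0.5)
    consensus = mean * (2.0 * frac_major - 1.0)

    genes = table.index.to_numpy()
    keep = presence >= floor
    values = {str(g): float(v) for g, v in zip(genes[keep], consensus[keep])}
    return Portrait(
        values=values,
        n_datasets=n,
        presence={str(g): int(c) for g, c in zip(genes, presence)},
        consistency={str(g): float(c) for g, c in zip(genes[keep], frac_major[keep])},
        portrait_id=portrait_id,
        metadata={"n_datasets": n, "min_presence_frac": min_presence_frac},
    )
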