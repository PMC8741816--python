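"""Congruent-gene extraction.

After scoring, the genes driving a match matter more than the score itself:
which genes move in the same direction in a model and in human depression
(up-up or down-down), and which of those recur across many independent
models.  Recurrent congruent genes (e.g. NR4A1-style hits found down in
every congruent model) are candidates for shared mechanism.

Gene lists are exported one symbol per line so they can be pasted into
external enrichment tools (STRING, Enrichr, ToppCluster); calling those
services is out of scope here.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .exceptions import ContractError, InvalidInputError
from .signatures import RankedSets

__all__ = [
    "CongruentSets",
    "pairwise_congruent",
    "common_across_models",
    "write_gene_list",
    "write_common_counts",
]


class CongruentSets(NamedTuple):
    """Directional overlaps of two top-ranked set pairs."""

    up_up: frozenset[str]
    down_down: frozenset[str]
    discordant: frozenset[str]


def pairwise_congruent(a: RankedSets, b: RankedSets) -> CongruentSets:
    """Split the overlap of two ranked-set pairs by direction agreement.

    ``up_up`` and ``down_down`` are the congruent genes; ``discordant``
    collects genes in the top lists of both datasets but with opposite
    direction.  The three sets are pairwise disjoint.
    """
    if a.universe != b.universe:
        raise ContractError("ranked sets built on different universes")
    a_up, a_dn = frozenset(a.up), frozenset(a.down)
    b_up, b_dn = frozenset(b.up), frozenset(b.down)
    return CongruentSets(
        up_up=a_up & b_up,
        down_down=a_dn & b_dn,
        discordant=(a_up & b_dn) | (a_dn & b_up),
    )


def common_across_models(
    per_model_congruent: Iterable[tuple[Iterable[str], Iterable[str]]],
    k_min: int = 3,
) -> tuple[dict[str, int], dict[str, int]]:
    """Genes congruent with the reference in at least ``k_min`` models.

    Parameters
    ----------
    per_model_congruent : iterable of (up_up, down_down) gene collections
        One pair per model, e.g. from :func:`pairwise_congruent` against a
        common reference.
    k_min : int
        Minimum number of models a gene must appear in.

    Returns
    -------
    (common_up, common_down) : dict gene -> count
        Counts support statements like "down in all seven models".
    """
    pairs = [(frozenset(u), frozenset(d)) for u, d in per_model_congruent]
    if k_min < 1:
        raise InvalidInputError(f"k_min must be >= 1; got {k_min}")
    if k_min > len(pairs):
        raise InvalidInputError(
            f"k_min={k_min} exceeds the number of model lists ({len(pairs)})"
        )
    up_counts: Counter[str] = Counter()
    down_counts: Counter[str] = Counter()
    for up, down in pairs:
        up_counts.update(up)
        down_counts.update(down)
    common_up = {g: c for g, c in sorted(up_counts.items()) if c >= k_min}
    common_down = {g: c for g, c in sorted(down_counts.items()) if c >= k_min}
    return common_up, common_down


def write_gene_list(genes: Iterable[str], path) -> Path:
    """One gene symbol per line, sorted — ready for external enrichment tools."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")
    return path


def write_common_counts(
    common_up: dict[str, int], common_down: dict[str, int], path
) -> Path:
    """CSV of (gene, direction, n_models) rows for the recurrent congruent genes."""
    rows = [{"gene": g, "direction": "up", "n_models": c} for g, c in sorted(common_up.items())]
    rows += [{"gene": g, "direction": "down", "n_models": c} for g, c in sorted(common_down.items())]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["gene", "direction", "n_models"]).to_csv(
        path, index=False, lineterminator="\n"
    )
    return path
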