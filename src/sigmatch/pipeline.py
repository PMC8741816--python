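"""End-to-end orchestration: manifest in, ranked outputs out.

``run_full_ranking`` drives the whole analysis — portrait construction,
hypergeometric ranking, ML ranking and their agreement, RRHO grids and
congruent-gene tables for the top models, and the 2-D embedding — writing
every product as plain text into one output directory together with a
machine-readable provenance log.  All randomness flows from the single
``seed``, so a rerun with the same inputs and configuration reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

from . import __version__, congruent
from .exceptions import InsufficientDataError
from .ml import write_ml_ranking
from .model import CongruenceModel
from .rrho import write_rrho
from .signatures import write_signature

__all__ = ["run_full_ranking", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "n_top": 1000,
    "n_features": 2000,
    "min_shared": 100,
    "min_presence": 0.5,
    "k_min": 3,
    "top_k": 3,
    "step": None,
    "seed": 0,
    "ml": True,
    "n_shuffles": 20,
    "embedding_backend": "umap",
}


def run_full_ranking(manifest_path, out_dir, config: dict | None = None) -> dict:
    """Run the full pipeline on a manifest; returns a map of output paths.

    ``config`` overrides :data:`DEFAULT_CONFIG` key-wise.  Outputs:
    ``portrait.tsv``, ``ranking.csv``, ``ml_ranking.csv``,
    ``rank_agreement.json``, ``rrho_<id>.tsv`` and congruent-gene files for
    the ``top_k`` models, ``embedding.csv``, and ``run_log.json``.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    cm = CongruenceModel.from_manifest(
        manifest_path,
        n_top=cfg["n_top"],
        min_shared=cfg["min_shared"],
        min_presence_frac=cfg["min_presence"],
    )
    logger.info(
        "loaded %d models, %d human datasets (reference: %s)",
        len(cm.models), len(cm.human_datasets), cm.reference.dataset_id,
    )

    if cm.portrait is not None:
        p = write_signature(cm.reference, out_dir / "portrait.tsv")
        outputs["portrait"] = str(p)

    want_ml = bool(cfg["ml"]) and (len(cm.human_datasets) >= 2 or cm.portrait is not None)
    res = cm.fit(
        ml_ranking=want_ml,
        seed=cfg["seed"],
        n_features=cfg["n_features"],
        n_shuffles=cfg["n_shuffles"],
    )
    outputs["ranking"] = str(res.ranking.to_csv(out_dir / "ranking.csv"))

    if res.ml_ranking is not None:
        outputs["ml_ranking"] = str(write_ml_ranking(res.ml_ranking, out_dir / "ml_ranking.csv"))
        agreement = {"n_models": int(len(res.ranking.ranks()))}
        if res.rank_agreement is not None:
            r, p = res.rank_agreement
            agreement.update({"pearson_r": r, "p_value": p})
        else:
            agreement["note"] = "fewer than 3 ranked models; correlation skipped"
            logger.warning("rank agreement skipped: fewer than 3 ranked models")
        path = out_dir / "rank_agreement.json"
        path.write_text(json.dumps(agreement, indent=2, sort_keys=True) + "\n")
        outputs["rank_agreement"] = str(path)

    # RRHO grids and congruent genes for the top-k models
    scored_ids = list(
        res.ranking.frame[res.ranking.frame["status"] == "scored"]
        .head(cfg["top_k"])["dataset_id"]
    )
    for mid in scored_ids:
        m = res.rrho(mid, step=cfg["step"])
        outputs[f"rrho_{mid}"] = str(write_rrho(m, out_dir / f"rrho_{mid}.tsv"))
    per_model, common_up, common_down = res.congruent_genes(
        top_k=cfg["top_k"], k_min=cfg["k_min"]
    )
    for mid, sets in per_model.items():
        congruent.write_gene_list(sets.up_up, out_dir / f"congruent_up_{mid}.txt")
        congruent.write_gene_list(sets.down_down, out_dir / f"congruent_down_{mid}.txt")
    outputs["common_genes"] = str(
        congruent.write_common_counts(common_up, common_down, out_dir / "common_genes.csv")
    )

    if len(cm.models) >= 3:
        coords = res.embed(
            n_features=cfg["n_features"], backend=cfg["embedding_backend"], seed=cfg["seed"]
        )
        path = out_dir / "embedding.csv"
        coords.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
        outputs["embedding"] = str(path)
    else:
        logger.warning("embedding skipped: fewer than 3 models")

    log = {
        "sigmatch_version": __version__,
        "python_version": sys.version.split()[0],
        "manifest": str(Path(manifest_path).name),
        "config": {k: cfg[k] for k in sorted(cfg)},
        "n_models": len(cm.models),
        "n_human_datasets": len(cm.human_datasets),
        "reference_id": cm.reference.dataset_id,
        "outputs": {k: str(Path(v).name) for k, v in sorted(outputs.items())},
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    outputs["run_log"] = str(log_path)
    return outputs
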