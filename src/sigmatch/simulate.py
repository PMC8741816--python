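"""Synthetic signature suites with planted ground truth.

The real study inputs (hundreds of GEO-derived differential-expression
tables and a 29-dataset human portrait) are not redistributable, so this
module generates signature collections with the statistical structure the
analysis assumes and a known answer key:

* a *truth* signature over a shared gene universe in which a fraction of
  "signal" genes carry a consistent signed effect and the rest are null
  (p ~ Uniform(0,1] with a random sign);
* ``n_human_datasets`` noisy replicates of the truth, standing in for the
  human case/control studies that feed the consensus portrait;
* model signatures whose per-gene direction copies the truth with a planted
  congruence ``c`` in [-1, 1]: ``c = +1`` copies every signal-gene direction,
  ``c = 0`` is independent, ``c = -1`` systematically opposes it.

Because ``c`` is the recoverable ground truth, every downstream stage
(portrait building, quadrant scoring, ML ranking, embedding) can be tested
for order recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .signatures import GeneSignature, write_signature

__all__ = [
    "SimulationConfig",
    "simulate_human_datasets",
    "simulate_models",
    "default_congruence",
    "write_suite",
]

#: Minimum |signed significance| of a signal gene: -log10(0.05) ~ 1.3, i.e.
#: every planted effect is at least nominally significant.
SIGNAL_FLOOR = 1.3


def default_congruence(n_models: int) -> dict[str, float]:
    """Evenly spaced planted congruence values on [-0.9, 0.9], best first."""
    cs = np.linspace(0.9, -0.9, n_models)
    return {f"M{i + 1:03d}": float(c) for i, c in enumerate(cs)}


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic suite.

    Defaults mirror the scale of the real analysis: ~5000 shared genes after
    cross-platform intersection, 29 human datasets feeding the portrait, 20%
    of genes carrying signal with mean |effect| 3 on the -log10 p scale, and
    unit gene-wise noise between datasets.
    """

    seed: int
    n_genes: int = 5000
    n_human_datasets: int = 29
    n_models: int = 50
    signal_fraction: float = 0.2
    effect_scale: float = 3.0
    noise_sd: float = 1.0
    congruence: dict[str, float] = field(default_factory=dict)
    #: per-dataset probability range for sign flips of null genes in the
    #: human replicates (models draw null genes independently instead)
    null_flip_range: tuple[float, float] = (0.25, 0.5)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidInputError("a seed is mandatory for reproducibility")
        if not (0.0 < self.signal_fraction < 1.0):
            raise InvalidInputError(
                f"signal_fraction must be in (0, 1); got {self.signal_fraction}"
            )
        if self.effect_scale <= SIGNAL_FLOOR:
            raise InvalidInputError(
                f"effect_scale must exceed the signal floor {SIGNAL_FLOOR}"
            )
        if self.noise_sd < 0:
            raise InvalidInputError(f"noise_sd must be >= 0; got {self.noise_sd}")
        if self.n_genes < 10 or self.n_human_datasets < 2 or self.n_models < 1:
            raise InvalidInputError("suite too small: need >=10 genes, >=2 human datasets, >=1 model")
        if not self.congruence:
            self.congruence = default_congruence(self.n_models)
        if len(self.congruence) != self.n_models:
            raise InvalidInputError(
                f"congruence map has {len(self.congruence)} entries for {self.n_models} models"
            )
        for mid, c in self.congruence.items():
            if not (-1.0 <= c <= 1.0):
                raise InvalidInputError(f"congruence for {mid!r} outside [-1, 1]: {c}")

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


def _null_values(rng: np.random.Generator, n: int) -> np.ndarray:
    """Null signed significances: -log10 U(0,1] with a fair random sign."""
    p = 1.0 - rng.random(n)  # uniform on (0, 1]
    sign = rng.choice([-1.0, 1.0], size=n)
    return -np.log10(p) * sign


def simulate_human_datasets(
    cfg: SimulationConfig,
) -> tuple[GeneSignature, list[GeneSignature]]:
    """Generate the truth signature and the noisy human replicates.

    Truth: ``n_genes * signal_fraction`` randomly placed signal genes get a
    fair-coin sign and magnitude ``SIGNAL_FLOOR + Exponential`` with mean
    ``effect_scale``; the rest are null.  Each human replicate is truth plus
    N(0, noise_sd) gene-wise noise; null genes additionally have their sign
    flipped with a per-dataset probability drawn from ``null_flip_range``,
    so no spurious consensus accumulates on them.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    genes = cfg.genes
    n = cfg.n_genes
    n_signal = int(round(cfg.signal_fraction * n))
    signal_idx = rng.choice(n, size=n_signal, replace=False)
    is_signal = np.zeros(n, dtype=bool)
    is_signal[signal_idx] = True

    truth_vals = _null_values(rng, n)
    mags = SIGNAL_FLOOR + rng.exponential(cfg.effect_scale - SIGNAL_FLOOR, size=n_signal)
    signs = rng.choice([-1.0, 1.0], size=n_signal)
    truth_vals[signal_idx] = mags * signs

    truth = GeneSignature(
        dataset_id="TRUTH",
        values=dict(zip(genes, truth_vals.astype(float))),
        species="synthetic",
        metadata={"group": "truth", "signal_genes": [genes[i] for i in sorted(signal_idx)]},
    )

    datasets = []
    for d in range(cfg.n_human_datasets):
        vals = truth_vals + rng.normal(0.0, cfg.noise_sd, size=n)
        flip_p = rng.uniform(*cfg.null_flip_range)
        flip = (~is_signal) & (rng.random(n) < flip_p)
        vals = np.where(flip, -vals, vals)
        datasets.append(
            GeneSignature(
                dataset_id=f"H{d + 1:02d}",
                values=dict(zip(genes, vals.astype(float))),
                species="human",
                metadata={"group": "human"},
            )
        )
    return truth, datasets


def simulate_models(cfg: SimulationConfig, truth: GeneSignature) -> list[GeneSignature]:
    """Generate model signatures with the planted congruence map.

    For each signal gene, model ``m`` copies the truth direction with
    probability ``(1 + |c_m|) / 2`` — toward the truth sign when
    ``c_m >= 0``, toward the opposite sign when ``c_m < 0`` — and draws its
    magnitude as ``|truth| + N(0, noise_sd)`` (floored at a small positive
    value).  Null genes are drawn independently per model.
    """
    genes = cfg.genes
    if set(truth.values) != set(genes):
        raise InvalidInputError("truth signature does not match the configured gene universe")
    truth_vals = np.array([truth.values[g] for g in genes])
    signal_set = set(truth.metadata.get("signal_genes", []))
    if not signal_set:
        raise InvalidInputError("truth signature lacks signal-gene annotations")
    is_signal = np.array([g in signal_set for g in genes])
    n = cfg.n_genes

    models = []
    for j, (mid, c) in enumerate(sorted(cfg.congruence.items())):
        rng = np.random.default_rng([cfg.seed, 1, j])
        vals = _null_values(rng, n)  # null genes independent of truth
        copy_prob = (1.0 + abs(c)) / 2.0
        toward = np.sign(truth_vals) * (1.0 if c >= 0 else -1.0)
        copied = rng.random(n) < copy_prob
        model_sign = np.where(copied, toward, -toward)
        mags = np.maximum(np.abs(truth_vals) + rng.normal(0.0, cfg.noise_sd, size=n), 0.01)
        vals = np.where(is_signal, model_sign * mags, vals)
        models.append(
            GeneSignature(
                dataset_id=mid,
                values=dict(zip(genes, vals.astype(float))),
                species="synthetic",
                metadata={"group": "model", "planted_congruence": float(c)},
            )
        )
    return models


def write_suite(cfg: SimulationConfig, out_dir) -> Path:
    """Write a full synthetic suite: signature TSVs, manifest CSV and truth table.

    The layout is directly consumable by the pipeline: ``manifest.csv``
    points at every generated signature with the proper group labels, and
    ``truth.tsv`` records per gene the true sign and signal status so runs
    can be evaluated against the answer key.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth, humans = simulate_human_datasets(cfg)
    models = simulate_models(cfg, truth)

    rows = []
    for sig in humans + models:
        rel = f"signatures/{sig.dataset_id}.tsv"
        write_signature(sig, out_dir / rel)
        rows.append(
            {
                "id": sig.dataset_id,
                "path": rel,
                "species": sig.species,
                "sex": "",
                "tissue": "",
                "accession": "",
                "group": sig.metadata["group"],
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")

    signal_set = set(truth.metadata["signal_genes"])
    with open(out_dir / "truth.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\ttrue_signed_value\ttrue_sign\tis_signal\n")
        for g in cfg.genes:
            v = truth.values[g]
            fh.write(f"{g}\t{v!r}\t{int(np.sign(v))}\t{int(g in signal_set)}\n")
    with open(out_dir / "planted_congruence.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("dataset_id,planted_congruence\n")
        for mid in sorted(cfg.congruence):
            fh.write(f"{mid},{cfg.congruence[mid]!r}\n")
    return out_dir
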