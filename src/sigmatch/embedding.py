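"""2-D similarity embedding of model signatures around the reference portrait.

Every model is projected onto the top portrait genes (the same feature space
the ML ranking uses) and the resulting high-dimensional points, together
with the portrait itself, are flattened to two dimensions.  Axes are
arbitrary; only relative distances are meaningful, and the Euclidean
distance of each model to the embedded portrait point is reported as a
convenience.

The backend is pluggable: ``"umap"`` (neighbour embedding, the default) or
``"pca"`` (deterministic linear projection, useful for fast exact tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .ml import FeatureSpace, feature_vector
from .portrait import Portrait
from .signatures import GeneSignature

__all__ = ["embed_models"]


def embed_models(
    models: list[GeneSignature],
    portrait: Portrait | GeneSignature,
    n_features: int = 2000,
    seed: int = 0,
    backend: str = "umap",
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """Embed models plus portrait in 2-D over the top portrait genes.

    Returns a DataFrame (dataset_id, x, y, distance_to_portrait, is_portrait)
    with one row per model and a final row for the portrait itself
    (distance 0).  Deterministic given ``seed``.  Backend parameters are
    recorded in ``DataFrame.attrs["params"]``.
    """
    if len(models) < 3:
        raise InvalidInputError(f"embedding needs >= 3 models; got {len(models)}")
    space = FeatureSpace.from_portrait(portrait, n_features=n_features)
    ref_sig = portrait.as_signature() if isinstance(portrait, Portrait) else portrait
    ids = [m.dataset_id for m in models] + [ref_sig.dataset_id]
    X = np.vstack(
        [feature_vector(m, space) for m in models] + [feature_vector(ref_sig, space)]
    )

    params: dict = {"backend": backend, "n_features": len(space), "seed": seed}
    if backend == "umap":
        import umap  # deferred: heavy import

        nn = min(n_neighbors, X.shape[0] - 1)
        reducer = umap.UMAP(
            n_components=2, n_neighbors=nn, min_dist=min_dist, random_state=seed
        )
        coords = np.asarray(reducer.fit_transform(X), dtype=float)
        params.update({"n_neighbors": nn, "min_dist": min_dist})
    elif backend == "pca":
        from sklearn.decomposition import PCA

        reducer = PCA(n_components=2, random_state=seed)
        coords = reducer.fit_transform(X)
        params.update({"explained_variance_ratio": reducer.explained_variance_ratio_.tolist()})
    else:
        raise InvalidInputError(f"unknown embedding backend {backend!r}")

    ref_pt = coords[-1]
    dist = np.linalg.norm(coords - ref_pt, axis=1)
    out = pd.DataFrame(
        {
            "dataset_id": ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "distance_to_portrait": dist,
            "is_portrait": [False] * len(models) + [True],
        }
    )
    out.attrs["params"] = params
    return out
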