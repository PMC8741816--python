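"""Optional matplotlib renderings of RRHO grids and embeddings.

Cosmetic only: analyses never depend on these, and the numerical exports
(TSV/CSV) are the tested interface.
"""

from __future__ import annotations

import numpy as np


def plot_rrho(matrix, ax=None, cmap: str = "RdBu_r", vmax: float | None = None):
    """Render an RRHO grid as a heatmap (reference on X, model on Y)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if vmax is None:
        vmax = float(np.abs(matrix.cells).max()) or 1.0
    im = ax.imshow(
        matrix.cells, origin="lower", aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
        extent=(0, matrix.steps_x[-1], 0, matrix.steps_y[-1]),
    )
    ax.set_xlabel(f"{matrix.x_id} rank")
    ax.set_ylabel(f"{matrix.y_id} rank")
    ax.figure.colorbar(im, ax=ax, label="signed -log10 p")
    return ax


def plot_embedding(coords, ax=None, annotate_portrait: bool = True):
    """Scatter the 2-D embedding; the portrait is highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    models = coords[~coords["is_portrait"]]
    ref = coords[coords["is_portrait"]]
    ax.scatter(models["x"], models["y"], s=20, c="tab:green", label="models")
    ax.scatter(ref["x"], ref["y"], s=80, c="tab:red", marker="*", label="portrait")
    if annotate_portrait and len(ref):
        ax.annotate(ref.iloc[0]["dataset_id"], (ref.iloc[0]["x"], ref.iloc[0]["y"]))
    ax.set_xlabel("embedding dim 1 (arbitrary)")
    ax.set_ylabel("embedding dim 2 (arbitrary)")
    ax.legend(frameon=False)
    return ax
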