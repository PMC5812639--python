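"""Optional heatmap visualization of Monte Carlo grid summaries."""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["grid_heatmap"]


def grid_heatmap(
    tidy: pd.DataFrame,
    value: str = "bias_pct",
    parameter: str = "Ki",
    ax=None,
):
    """Heatmap of a summary statistic over the (θ_min, θ_max) grid.

    ``tidy`` is the output of :func:`irrevkin.simulation.summaries_to_tidy`
    restricted to one sf / parameter combination; cells are (θ_min, θ_max).
    Requires matplotlib (``pip install irrevkin[plot]``).
    """
    import matplotlib.pyplot as plt

    sub = tidy[tidy["parameter"] == parameter]
    pivot = sub.pivot_table(index="theta_min", columns="theta_max", values=value)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(pivot.values, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(np.arange(pivot.shape[1]), [f"{v:g}" for v in pivot.columns])
    ax.set_yticks(np.arange(pivot.shape[0]), [f"{v:g}" for v in pivot.index])
    ax.set_xlabel("theta_max (1/min)")
    ax.set_ylabel("theta_min (1/min)")
    ax.set_title(f"{value} of {parameter}")
    plt.colorbar(im, ax=ax)
    return ax
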