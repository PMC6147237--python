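"""Basic plots: reporter calibration bars, MCA heatmap, tissue responses."""

from __future__ import annotations

import numpy as np


def plot_calibration(result, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    factors = list(result.observed)
    x = np.arange(len(factors))
    ax.bar(x - 0.2, [result.observed[f] for f in factors], 0.4, label="measured")
    ax.bar(x + 0.2, [result.predicted[f] for f in factors], 0.4, label="model")
    ax.set_xticks(x, factors)
    ax.set_ylabel("fold change (RLU)")
    ax.legend()
    return ax


def plot_mca_heatmap(C, ax=None, normalized=True):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    m = C.normalized() if normalized else C.matrix
    im = ax.imshow(m.to_numpy(), aspect="auto", cmap="magma")
    ax.set_xticks(range(len(m.columns)), m.columns, rotation=45)
    ax.set_ylabel("reaction index")
    plt.colorbar(im, ax=ax, label="|C| / column max" if normalized else "C")
    return ax


def plot_response_map(rmap, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    for code in rmap.responses.columns:
        ax.plot(rmap.times, rmap.responses[code], label=code)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("% response")
    ax.legend(ncol=3, fontsize="small")
    return ax
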