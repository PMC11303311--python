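"""Tornado-diagram rendering."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; no display required
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_tornado"]


def plot_tornado(tornado_df: pd.DataFrame, path: str | Path,
                 base_icer: float | None = None,
                 title: str = "One-way sensitivity of the ICER") -> Path:
    """Render a tornado table (see :func:`markovcea.sensitivity.tornado`).

    Bars span the ICER between the low and high bound of each parameter,
    widest on top.  A bound with no defined ICER (dominance) is drawn as an
    annotated marker instead of a bar edge.
    """
    df = tornado_df.iloc[::-1]  # widest bar on top
    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.45 * len(df) + 1.2)))
    y = range(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = row["icer_low"], row["icer_high"]
        if lo is not None and hi is not None \
                and pd.notna(lo) and pd.notna(hi):
            left, width = min(lo, hi), abs(hi - lo)
            ax.barh(i, width, left=left, height=0.6, color="#4878b0")
        else:
            anchor = base_icer if base_icer is not None else 0.0
            for v, flag in ((lo, row["flag_low"]), (hi, row["flag_high"])):
                if v is not None and pd.notna(v):
                    ax.barh(i, abs(v - anchor), left=min(v, anchor),
                            height=0.6, color="#4878b0")
                elif flag:
                    ax.annotate(flag, xy=(anchor, i), fontsize=8,
                                va="center", color="#a33")
    if base_icer is not None:
        ax.axvline(base_icer, color="k", lw=1, ls="--", label="base case")
        ax.legend(loc="lower right", fontsize=8)
    ax.set_yticks(list(y))
    ax.set_yticklabels(df["parameter"], fontsize=8)
    ax.set_xlabel("ICER (QAR/QALY)")
    ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
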