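"""Manhattan-style plot of per-window variance shares."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ssgwas import SnpWindowResult  # noqa: E402


def manhattan_windows(result: SnpWindowResult, path, title: str | None = None):
    """Plot window midpoints against the % of additive variance explained.

    Chromosomes are laid out consecutively with alternating colours; the
    QTL threshold is drawn as a horizontal line.
    """
    df = result.windows
    fig, ax = plt.subplots(figsize=(9, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, (ch, block) in enumerate(df.groupby("chrom", sort=False)):
        mid = (block["start"] + block["end"]) / 2.0 + offset
        ax.scatter(mid, block["pct_variance"], s=12,
                   color="C0" if i % 2 == 0 else "C1")
        ticks.append(float(mid.mean()))
        labels.append(str(ch))
        offset += float(block["end"].max())
    ax.axhline(result.threshold, color="grey", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% of additive genetic variance")
    ax.set_title(title or f"{result.effect_kind} window variance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
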