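"""Grouped bar chart of per-species GAGA/GAG upstream counts."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["motif_count_barplot"]


def motif_count_barplot(
    table: pd.DataFrame,
    path: Union[str, Path],
    window_length: int = 2000,
) -> None:
    """Plot motif counts per subject for one upstream window length.

    Expects the long-format table produced by ``species_motif_table``
    (columns subject, window_length, motif, count).
    """
    sub = table[table["window_length"] == window_length].dropna(subset=["count"])
    subjects = list(dict.fromkeys(sub["subject"]))
    motifs = list(dict.fromkeys(sub["motif"]))
    x = np.arange(len(subjects))
    width = 0.8 / max(1, len(motifs))
    fig, ax = plt.subplots(figsize=(1.2 * len(subjects) + 2, 4))
    colors = {"GAGA": "#e6c229", "GAG": "#8d8d8d"}
    for k, motif in enumerate(motifs):
        counts = [
            int(sub[(sub["subject"] == s) & (sub["motif"] == motif)]["count"].iloc[0])
            if not sub[(sub["subject"] == s) & (sub["motif"] == motif)].empty
            else 0
            for s in subjects
        ]
        ax.bar(x + k * width, counts, width, label=motif, color=colors.get(motif))
    ax.set_xticks(x + width * (len(motifs) - 1) / 2)
    ax.set_xticklabels(subjects, rotation=30, ha="right")
    ax.set_ylabel(f"occurrences in {window_length // 1000} kb upstream")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
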