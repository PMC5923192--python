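"""Small matplotlib helpers for the standard figures."""
from __future__ import annotations

import numpy as np
import pandas as pd


def plot_profile(profiles: pd.DataFrame, ax=None):
    """Recombination rate against relative chromosomal position.

    ``profiles`` as written by the pipeline (columns breed, sex,
    rel_pos, rate_per_mb); males solid, females dotted.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for (breed, sex), grp in profiles.groupby(["breed", "sex"]):
        ls = "-" if sex == "M" else ":"
        ax.plot(grp["rel_pos"], grp["rate_per_mb"], ls, label=f"{breed} {sex}")
    ax.set_xlabel("relative chromosomal position")
    ax.set_ylabel("recombination rate (cM/Mb equivalent)")
    ax.legend(fontsize=8)
    return ax


def plot_manhattan(scan: pd.DataFrame, threshold: float | None = None, ax=None):
    """Manhattan plot from a scan table with chrom, bp and p columns."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    d = scan.dropna(subset=["p"]).copy()
    d["neglog10p"] = -np.log10(d["p"])
    offset = 0
    for i, (_, grp) in enumerate(d.groupby("chrom", sort=True)):
        ax.scatter(offset + grp["bp"], grp["neglog10p"], s=4,
                   color="C0" if i % 2 == 0 else "C1")
        offset += grp["bp"].max()
    if threshold is not None:
        ax.axhline(-np.log10(threshold), ls="--", color="grey")
    ax.set_xlabel("genome position")
    ax.set_ylabel("-log10 p")
    return ax
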