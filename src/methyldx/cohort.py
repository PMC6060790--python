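"""Cohort-level CNV frequency summaries.

For a set of samples sharing bin boundaries, the summary gives the per-bin
percentage of samples showing a gain or a loss — irrespective of amplitude,
so an amplification and a single-copy gain count identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnv import CHROMOSOMES, BinProfile

__all__ = ["CohortFrequency", "summarize_cohort", "write_frequency_table", "render_summary"]


@dataclass
class CohortFrequency:
    """Per-bin % frequency of gain and loss across a cohort."""

    bins: pd.DataFrame  # chrom, start, end
    gain_pct: np.ndarray
    loss_pct: np.ndarray
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        df = self.bins[["chrom", "start", "end"]].copy()
        df["gain_pct"] = self.gain_pct
        df["loss_pct"] = self.loss_pct
        df["n"] = self.n_samples
        return df


def summarize_cohort(profiles: list, threshold: float = 0.15) -> CohortFrequency:
    """Count, per bin, the cohort fraction beyond ±``threshold`` (log2, baseline-relative).

    A bin with missing data in a sample drops out of that sample's
    denominator for that bin.  All profiles must share bin boundaries and
    carry a fitted baseline.
    """
    if not profiles:
        raise ValueError("empty cohort")
    key_cols = ["chrom", "start", "end"]
    ref_bins = profiles[0].bins[key_cols]
    for p in profiles[1:]:
        if not ref_bins.equals(p.bins[key_cols]):
            raise ValueError("profiles do not share bin boundaries")
    stack = np.vstack([p.baselined() for p in profiles])
    ok = ~np.isnan(stack)
    denom = ok.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = 100.0 * np.where(ok, stack >= threshold, False).sum(axis=0) / denom
        loss = 100.0 * np.where(ok, stack <= -threshold, False).sum(axis=0) / denom
    return CohortFrequency(ref_bins.copy(), gain, loss, len(profiles))


def write_frequency_table(freq: CohortFrequency, path) -> None:
    freq.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def render_summary(freq: CohortFrequency, path, title: str = "cohort CNV frequency") -> None:
    """Mirrored bar plot: gains up, losses down, chromosome boundaries marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = freq.bins
    offsets = {}
    cum = 0
    for c in CHROMOSOMES:
        cmask = bins["chrom"] == c
        if not cmask.any():
            continue
        offsets[c] = cum
        cum += int(bins.loc[cmask, "end"].max())
    x = np.array(
        [offsets[c] + (s + e) / 2 for c, s, e in zip(bins["chrom"], bins["start"], bins["end"])]
    )
    width = np.array([e - s for s, e in zip(bins["start"], bins["end"])], dtype=float)
    fig, ax = plt.subplots(figsize=(14, 4))
    ax.bar(x, freq.gain_pct, width=width, color="#2ca02c", label="gain")
    ax.bar(x, -freq.loss_pct, width=width, color="#d62728", label="loss")
    for o in offsets.values():
        ax.axvline(o, color="grey", lw=0.5)
    ax.set_ylim(-105, 105)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("% of samples (gain up / loss down)")
    ax.set_title(f"{title} (n={freq.n_samples})")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
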