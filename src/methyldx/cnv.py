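"""Single-sample copy-number profiles from combined array intensities.

Pipeline: per-probe log2 ratio against a flat-genome reference panel →
median aggregation into genomic bins (default 8000 genome-wide) → a
minimal-MAD neutral baseline → piecewise-constant segmentation (recursive
binary splitting with a permutation test) → focal amplification /
homozygous-deletion and arm-level gain/loss calls against a highlight-gene
list → IGV/SEG export and plotting.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_model import (
    AUTOSOMES,
    CHROMOSOMES,
    ProbeManifest,
    ReferencePanel,
    SampleIntensities,
    combined_intensity,
    normalize_chrom,
)

__all__ = [
    "BinConfig",
    "EventThresholds",
    "BinningScheme",
    "BinProfile",
    "Segment",
    "FocalEvent",
    "probe_log2",
    "build_bins",
    "bin_profile",
    "fit_baseline",
    "segment_profile",
    "call_events",
    "load_highlight_genes",
    "export_igv",
    "export_seg",
    "render_plot",
]


@dataclass(frozen=True)
class BinConfig:
    """Genome binning configuration.

    target_bins is the genome-wide bin count (8000 at full array scale);
    bins are contiguous equal-probe runs within a chromosome, allocated to
    chromosomes in proportion to their probe supply, never crossing a
    chromosome boundary and never thinner than min_probes probes.
    """

    target_bins: int = 8000
    min_probes: int = 15
    include_x: bool = True
    include_y: bool = False


@dataclass(frozen=True)
class EventThresholds:
    """Baseline-relative log2 thresholds for event calling."""

    amplification: float = 0.4
    gain: float = 0.15
    focal_cap_bp: int = 10_000_000


@dataclass
class BinningScheme:
    """Bin boundaries plus the probe→bin assignment they were built from."""

    bins: pd.DataFrame  # chrom, start, end, probe_count
    probe_bin: np.ndarray  # per-manifest-probe bin index, -1 if unbinned

    def __len__(self) -> int:
        return len(self.bins)


@dataclass
class BinProfile:
    """Binned log2 copy-number ratios for one sample."""

    sample_id: str
    bins: pd.DataFrame  # chrom, start, end, probe_count, log2_value
    baseline: float = float("nan")
    noise_score: float = float("nan")

    @property
    def values(self) -> np.ndarray:
        return self.bins["log2_value"].to_numpy(np.float64)

    def baselined(self) -> np.ndarray:
        """Baseline-subtracted bin values; baseline must be fitted."""
        if np.isnan(self.baseline):
            raise ValueError("baseline not fitted; call fit_baseline first")
        return self.values - self.baseline


@dataclass
class Segment:
    chromosome: str
    start: int
    end: int
    n_bins: int
    mean_log2: float  # baseline-subtracted


@dataclass
class FocalEvent:
    gene: str  # highlight symbol, or "chrom:start-end" for ad-hoc regions
    kind: str  # amplification | homozygous_deletion | gain | loss
    chromosome: str
    start: int
    end: int
    log2: float
    length: int


def probe_log2(
    sample: SampleIntensities,
    panel: ReferencePanel,
    scaling: str = "median-match",
) -> np.ndarray:
    """Per-probe log2 ratio of sample vs reference combined intensity.

    Sample intensities are first rescaled so their genome-wide median
    matches the reference median (the total signal level of an array is
    arbitrary; only relative dosage is meaningful).  Excluded probes and
    probes missing from the sample return NaN.
    """
    if scaling not in {"median-match", "none"}:
        raise ValueError(f"unknown scaling {scaling!r}")
    manifest = panel.manifest
    comb = combined_intensity(sample)
    ref = panel.per_probe_reference
    valid = ~manifest.excluded & ~np.isnan(comb) & ~np.isnan(ref)
    if np.any(valid & (ref <= 0)):
        raise ValueError("zero/negative reference at a non-excluded probe")
    out = np.full(len(manifest), np.nan)
    if not valid.any():
        return out
    if scaling == "median-match":
        s_med = np.median(comb[valid])
        if s_med <= 0:
            raise ValueError("sample combined-intensity median is not positive")
        scale = np.median(ref[valid]) / s_med
    else:
        scale = 1.0
    with np.errstate(divide="ignore"):
        out[valid] = np.log2(scale * comb[valid] / ref[valid])
    return out


def _allocate_bins(counts: dict, target: int, min_probes: int) -> dict:
    """Largest-remainder apportionment of bins to chromosomes.

    Each chromosome with probes gets >= 1 bin and <= floor(probes/min_probes)
    bins (but at least 1); surplus from capped chromosomes is redistributed.
    """
    chroms = [c for c, n in counts.items() if n > 0]
    caps = {c: max(1, counts[c] // min_probes) for c in chroms}
    total = sum(counts[c] for c in chroms)
    if total == 0:
        return {}
    alloc = {c: 1 for c in chroms}
    remaining = target - len(chroms)
    if remaining <= 0:
        return alloc
    # proportional shares of the remaining bins, capped, largest remainder
    free = {c for c in chroms if alloc[c] < caps[c]}
    while remaining > 0 and free:
        weight = sum(counts[c] for c in free)
        quota = {c: remaining * counts[c] / weight for c in free}
        gave = 0
        for c in sorted(free, key=lambda c: -(quota[c] % 1)):
            take = min(int(quota[c]), caps[c] - alloc[c])
            alloc[c] += take
            gave += take
        remaining -= gave
        if gave == 0:
            # distribute leftovers one by one, by remainder, respecting caps
            order = sorted(free, key=lambda c: -(quota[c] % 1))
            for c in order:
                if remaining == 0:
                    break
                if alloc[c] < caps[c]:
                    alloc[c] += 1
                    remaining -= 1
        free = {c for c in chroms if alloc[c] < caps[c]}
    return alloc


def build_bins(manifest: ProbeManifest, config: BinConfig = BinConfig()) -> BinningScheme:
    """Partition the manifest's probes into genomic bins.

    Bins are contiguous equal-probe runs per chromosome.  The genome-wide
    count equals ``config.target_bins`` whenever the probe supply allows
    (i.e. unless per-chromosome minimum-probe caps bind).  Excluded probes
    are not binned.  Chromosome Y is left out by default.
    """
    wanted = set(AUTOSOMES)
    if config.include_x:
        wanted.add("X")
    if config.include_y:
        wanted.add("Y")
    usable = ~manifest.excluded & np.array([c in wanted for c in manifest.chrom], dtype=bool)
    probe_bin = np.full(len(manifest), -1, dtype=np.int64)
    counts = {}
    for c in CHROMOSOMES:
        if c in wanted:
            counts[c] = int(np.sum(usable & (manifest.chrom == c)))
    alloc = _allocate_bins(counts, config.target_bins, config.min_probes)
    rows = []
    bin_idx = 0
    for c in CHROMOSOMES:
        n_bins = alloc.get(c, 0)
        if n_bins == 0:
            continue
        mask = usable & (manifest.chrom == c)
        probe_rows = np.flatnonzero(mask)
        for chunk in np.array_split(probe_rows, n_bins):
            if chunk.size == 0:
                continue
            start = int(manifest.pos[chunk[0]])
            end = int(manifest.pos[chunk[-1]]) + 1
            probe_bin[chunk] = bin_idx
            rows.append((c, start, end, int(chunk.size)))
            bin_idx += 1
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_count"])
    return BinningScheme(bins, probe_bin)


def bin_profile(
    sample_id: str,
    probe_log2_values: np.ndarray,
    scheme: BinningScheme,
) -> BinProfile:
    """Median-aggregate probe log2 ratios into the scheme's bins."""
    values = np.asarray(probe_log2_values, dtype=np.float64)
    n_bins = len(scheme)
    out = np.full(n_bins, np.nan)
    ok = (scheme.probe_bin >= 0) & ~np.isnan(values)
    if ok.any():
        df = pd.DataFrame({"b": scheme.probe_bin[ok], "v": values[ok]})
        med = df.groupby("b")["v"].median()
        out[med.index.to_numpy()] = med.to_numpy()
    bins = scheme.bins.copy()
    bins["log2_value"] = out
    return BinProfile(sample_id, bins)


def fit_baseline(profile: BinProfile, grid_step: float = 0.001) -> float:
    """Neutral-state baseline: the shift minimising the MAD to all bins.

    Grid search over [min, max] of the bin values at ``grid_step``
    resolution.  The minimiser set of the MAD objective can be a flat
    plateau; ties are broken toward the candidate nearest the profile
    median (the bulk of a median-scaled genome is copy-number neutral), a
    rule that keeps the fit translation-equivariant.  The fitted value is
    stored on the profile and returned.
    """
    v = profile.values
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("profile has no finite bins")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < grid_step:
        b = (lo + hi) / 2.0
        profile.baseline = b
        return b
    if v.size < 10:
        raise ValueError("need >= 10 bins to fit a baseline")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    mads = np.empty(grid.size)
    # chunk the |v - b| median over candidates to bound memory
    for i in range(0, grid.size, 1024):
        g = grid[i : i + 1024]
        mads[i : i + g.size] = np.median(np.abs(v[None, :] - g[:, None]), axis=1)
    candidates = grid[mads <= mads.min() + 1e-12]
    best_b = float(candidates[np.argmin(np.abs(candidates - np.median(v)))])
    profile.baseline = best_b
    return best_b


# ---------------------------------------------------------------------------
# segmentation: recursive binary splitting with a permutation test


def _best_pair(x: np.ndarray, min_size: int):
    """Best interior run x[i:j] vs the rest, by a z statistic.

    The circular scan over all (i, j) pairs lets a short focal event be
    found with both edges at once — a plain binary split would have to
    isolate it in two underpowered steps.  Plain prefix/suffix splits are
    the i=0 / j=n special cases and are included.  Returns
    ((i, j), statistic) or (None, 0.0) when no split is allowed.
    """
    n = x.size
    if n < 2 * min_size:
        return None, 0.0
    sd = float(np.std(x))
    if sd <= 1e-12:
        return None, 0.0
    cs = np.concatenate(([0.0], np.cumsum(x)))
    total = cs[-1]
    i = np.arange(0, n - min_size + 1)
    j = np.arange(min_size, n + 1)
    # run length m = j - i, constrained to [min_size, n - min_size]
    m = j[None, :] - i[:, None]
    valid = (m >= min_size) & (m <= n - min_size)
    m = np.where(valid, m, 1)
    s_in = cs[j][None, :] - cs[i][:, None]
    mean_in = s_in / m
    mean_out = (total - s_in) / (n - m)
    z = np.abs(mean_in - mean_out) / (sd * np.sqrt(1.0 / m + 1.0 / (n - m)))
    z = np.where(valid, z, -np.inf)
    flat = int(np.argmax(z))
    ii, jj = np.unravel_index(flat, z.shape)
    return (int(i[ii]), int(j[jj])), float(z[ii, jj])


def _segment_chromosome(
    x: np.ndarray,
    alpha: float,
    min_size: int,
    n_perm: int,
    rng: np.random.Generator,
) -> list:
    """Breakpoint indices within one chromosome (recursive CBS-style splitting)."""
    breaks: set[int] = set()

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        pair, t_obs = _best_pair(seg, min_size)
        if pair is None or t_obs <= 0:
            return
        exceed = 0
        for _ in range(n_perm):
            _, t_p = _best_pair(rng.permutation(seg), min_size)
            if t_p >= t_obs:
                exceed += 1
                # early exit once significance is impossible
                if (exceed + 1) / (n_perm + 1) > alpha:
                    return
        p = (exceed + 1) / (n_perm + 1)
        if p <= alpha:
            cuts = sorted({lo + k for k in pair} - {lo, hi})
            if not cuts:
                return
            breaks.update(cuts)
            edges = [lo] + cuts + [hi]
            for a, b in zip(edges[:-1], edges[1:]):
                recurse(a, b)

    recurse(0, x.size)
    return sorted(breaks)


def segment_profile(
    profile: BinProfile,
    alpha: float = 0.01,
    min_size: int = 2,
    n_perm: int = 200,
    seed: int = 0,
) -> list:
    """Piecewise-constant fit of the baselined profile, per chromosome.

    Candidate splits maximise a two-sample t statistic; a split is accepted
    when a permutation test on the segment rejects homogeneity at level
    ``alpha``.  Segment means are unweighted means of member bins
    (baseline-subtracted).  Flat input yields one segment per chromosome.
    """
    values = profile.baselined()
    bins = profile.bins
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for c in bins["chrom"].unique():
        mask = (bins["chrom"] == c).to_numpy()
        x = values[mask]
        starts = bins.loc[mask, "start"].to_numpy()
        ends = bins.loc[mask, "end"].to_numpy()
        finite = ~np.isnan(x)
        if not finite.any():
            continue
        xs = x[finite]
        starts = starts[finite]
        ends = ends[finite]
        brk = _segment_chromosome(xs, alpha, min_size, n_perm, rng)
        edges = [0] + brk + [xs.size]
        for a, b in zip(edges[:-1], edges[1:]):
            segments.append(
                Segment(
                    chromosome=str(c),
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    n_bins=b - a,
                    mean_log2=float(np.mean(xs[a:b])),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# event calling


def load_highlight_genes(path=None) -> pd.DataFrame:
    """Highlight-gene table (chrom, start, end, symbol); 29 genes bundled."""
    if path is None:
        ref = importlib.resources.files("methyldx.data") / "highlight_genes.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "symbol"}
    if not required.issubset(df.columns):
        raise ValueError(f"highlight gene table needs columns {sorted(required)}")
    df["chrom"] = [normalize_chrom(c) for c in df["chrom"]]
    return df


def _overlapping_symbol(genes: pd.DataFrame, chrom: str, start: int, end: int):
    hits = genes[(genes["chrom"] == chrom) & (genes["start"] < end) & (genes["end"] > start)]
    if hits.empty:
        return None
    return ",".join(hits["symbol"].tolist())


def call_events(
    segments: list,
    highlight_genes: pd.DataFrame,
    thresholds: EventThresholds = EventThresholds(),
    required_genes=None,
    autosomes_only: bool = True,
) -> list:
    """Call amplifications, homozygous deletions, gains and losses.

    A segment with |mean| >= the amplification threshold (default 0.4, all
    thresholds baseline-relative) and length <= the focal cap (default
    10 Mb) is an amplification / homozygous deletion; any other deviation
    beyond the gain threshold (default ±0.15) is a gain / loss.  Events
    overlapping a highlight gene carry the gene symbol, otherwise an
    ad-hoc region label.  Sex chromosomes are skipped by default (their
    dosage reflects germline sex relative to the panel, not somatic change).
    """
    if required_genes is not None:
        known = set(highlight_genes["symbol"])
        missing = sorted(set(required_genes) - known)
        if missing:
            raise ValueError(f"unknown highlight genes: {', '.join(missing)}")
    events: list[FocalEvent] = []
    for seg in segments:
        if autosomes_only and seg.chromosome not in AUTOSOMES:
            continue
        length = seg.end - seg.start
        m = seg.mean_log2
        focal = length <= thresholds.focal_cap_bp
        if m >= thresholds.amplification and focal:
            kind = "amplification"
        elif m <= -thresholds.amplification and focal:
            kind = "homozygous_deletion"
        elif m >= thresholds.gain:
            kind = "gain"
        elif m <= -thresholds.gain:
            kind = "loss"
        else:
            continue
        symbol = _overlapping_symbol(highlight_genes, seg.chromosome, seg.start, seg.end)
        events.append(
            FocalEvent(
                gene=symbol or f"{seg.chromosome}:{seg.start}-{seg.end}",
                kind=kind,
                chromosome=seg.chromosome,
                start=seg.start,
                end=seg.end,
                log2=m,
                length=length,
            )
        )
    return events


def profile_sample(
    sample: SampleIntensities,
    panel: ReferencePanel,
    scheme: BinningScheme,
    alpha: float = 0.01,
    thresholds: EventThresholds = EventThresholds(),
    highlight_genes: pd.DataFrame | None = None,
    seed: int = 0,
):
    """Full single-sample pipeline: log2 ratios → bins → baseline → segments → events.

    Returns (profile, segments, events).
    """
    if highlight_genes is None:
        highlight_genes = load_highlight_genes()
    lr = probe_log2(sample, panel)
    profile = bin_profile(sample.sample_id, lr, scheme)
    fit_baseline(profile)
    segments = segment_profile(profile, alpha=alpha, seed=seed)
    events = call_events(segments, highlight_genes, thresholds)
    return profile, segments, events


# ---------------------------------------------------------------------------
# export & plotting


def export_igv(profile: BinProfile, path, feature_prefix: str = "bin") -> None:
    """Write bins as an IGV track (Chromosome, Start, End, Feature, <sample>)."""
    bins = profile.bins
    with open(path, "w") as fh:
        fh.write(f"Chromosome\tStart\tEnd\tFeature\t{profile.sample_id}\n")
        for i, row in enumerate(bins.itertuples(index=False)):
            v = row.log2_value
            if np.isnan(v):
                continue
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{feature_prefix}_{i}\t{v:.6f}\n")


def export_seg(segments: list, sample_id: str, path) -> None:
    """Write segments in SEG format (ID, chrom, loc.start, loc.end, num.mark, seg.mean)."""
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for s in segments:
            fh.write(
                f"{sample_id}\t{s.chromosome}\t{s.start}\t{s.end}\t{s.n_bins}\t{s.mean_log2:.6f}\n"
            )


def read_igv(path) -> pd.DataFrame:
    """Parse an IGV track written by :func:`export_igv`."""
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    return df


def render_plot(
    profile: BinProfile,
    segments: list,
    events: list,
    path,
    highlight_genes: pd.DataFrame | None = None,
) -> None:
    """Genome-ordered CNV plot: bin dots colored by sign, segment line, baseline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = profile.bins
    v = profile.baselined()
    # cumulative genome coordinate
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
    fig, ax = plt.subplots(figsize=(14, 4))
    colors = np.where(v >= 0, "#2ca02c", "#d62728")
    ax.scatter(x, v, s=4, c=colors, alpha=0.6, linewidths=0)
    for seg in segments:
        if seg.chromosome not in offsets:
            continue
        o = offsets[seg.chromosome]
        ax.plot([o + seg.start, o + seg.end], [seg.mean_log2] * 2, color="#1f4e9c", lw=2)
    ax.axhline(0.0, color="black", lw=0.8, ls="--")
    for c, o in offsets.items():
        ax.axvline(o, color="grey", lw=0.5)
    if highlight_genes is not None:
        for row in highlight_genes.itertuples(index=False):
            if row.chrom in offsets:
                gx = offsets[row.chrom] + (row.start + row.end) / 2
                ax.annotate(row.symbol, (gx, 0), fontsize=5, rotation=90, alpha=0.5)
    for ev in events:
        if ev.chromosome in offsets:
            ex = offsets[ev.chromosome] + (ev.start + ev.end) / 2
            ax.annotate(f"{ev.gene} ({ev.kind})", (ex, ev.log2), fontsize=6, color="#1f4e9c")
    ax.set_xlabel("genome position")
    ax.set_ylabel("log2 ratio (baseline-relative)")
    ax.set_title(profile.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
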