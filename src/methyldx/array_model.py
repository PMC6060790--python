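"""Probe manifest, sample intensities and reference-panel arithmetic.

Methylation arrays interrogate each CpG with a methylated and an
unmethylated channel.  Methylation analysis uses the beta value
``meth / (meth + unmeth + offset)``; copy-number analysis instead uses the
*combined* intensity ``meth + unmeth``, which is proportional to the local
DNA copy number and is compared against a panel of copy-number-neutral
("flat genome") reference samples.

All per-probe vectors in this package are numpy arrays aligned to a
:class:`ProbeManifest`; alignment happens once, at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOSOMES",
    "AUTOSOMES",
    "ProbeManifest",
    "SampleIntensities",
    "ReferencePanel",
    "compute_beta",
    "combined_intensity",
    "build_reference",
    "read_manifest",
    "read_intensity_table",
    "load_idat_pair",
]

#: canonical chromosome order (string labels, no "chr" prefix)
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 23))

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def normalize_chrom(label: str) -> str:
    """Strip a 'chr' prefix and validate against the canonical label set."""
    c = str(label)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in _CHROM_RANK:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return c


@dataclass
class ProbeManifest:
    """Array design: one row per probe, sorted by (chromosome, position).

    Parameters
    ----------
    probe_id, chrom, pos
        Parallel arrays.  Positions are 0-based.
    excluded
        QC exclusion flags (cross-reactive/SNP probes, low-reference
        probes); excluded probes never enter copy-number ratios.
    """

    probe_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.chrom = np.asarray(
            [normalize_chrom(c) for c in np.asarray(self.chrom)], dtype=object
        )
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.excluded is None:
            self.excluded = np.zeros(len(self.probe_id), dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not (len(self.probe_id) == len(self.chrom) == len(self.pos) == len(self.excluded)):
            raise ValueError("manifest columns have unequal lengths")
        if self.pos.size and self.pos.min() < 0:
            raise ValueError("probe positions must be non-negative")
        if len(set(self.probe_id)) != len(self.probe_id):
            raise ValueError("probe ids must be unique")
        order = np.lexsort((self.pos, np.array([_CHROM_RANK[c] for c in self.chrom])))
        self.probe_id = self.probe_id[order]
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.excluded = self.excluded[order]
        self._index = {p: i for i, p in enumerate(self.probe_id)}

    def __len__(self) -> int:
        return len(self.probe_id)

    def indexer(self, probe_ids: np.ndarray) -> np.ndarray:
        """Manifest row index for each probe id; KeyError on unknown probes."""
        return np.array([self._index[p] for p in probe_ids], dtype=np.int64)

    def chrom_mask(self, chromosomes) -> np.ndarray:
        wanted = {normalize_chrom(c) for c in chromosomes}
        return np.array([c in wanted for c in self.chrom])

    def exclude_probes(self, probe_ids) -> None:
        """Mark the listed probes excluded (user-supplied blocklist)."""
        self.excluded[self.indexer(np.asarray(list(probe_ids), dtype=object))] = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "excluded": self.excluded,
            }
        )


@dataclass
class SampleIntensities:
    """Per-probe methylated/unmethylated signals aligned to a manifest.

    ``meth`` and ``unmeth`` are float arrays of the manifest's length;
    probes absent from the input carry NaN.
    """

    sample_id: str
    manifest: ProbeManifest
    meth: np.ndarray
    unmeth: np.ndarray
    reported_sex: str = "unknown"

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.float64)
        self.unmeth = np.asarray(self.unmeth, dtype=np.float64)
        if self.meth.shape != (len(self.manifest),) or self.unmeth.shape != (len(self.manifest),):
            raise ValueError("intensity vectors must match the manifest length")
        for name, v in (("meth", self.meth), ("unmeth", self.unmeth)):
            finite = v[~np.isnan(v)]
            if np.any(~np.isfinite(finite)):
                raise ValueError(f"{name} intensities must be finite")
            if finite.size and finite.min() < 0:
                raise ValueError(f"{name} intensities must be non-negative")
        if self.reported_sex not in {"male", "female", "unknown"}:
            raise ValueError(f"reported_sex must be male/female/unknown, got {self.reported_sex!r}")

    @classmethod
    def from_probe_table(
        cls,
        sample_id: str,
        manifest: ProbeManifest,
        probe_ids,
        meth,
        unmeth,
        reported_sex: str = "unknown",
    ) -> "SampleIntensities":
        """Build from (probe_id, meth, unmeth) triples; probes must exist in the manifest."""
        idx = manifest.indexer(np.asarray(probe_ids, dtype=object))
        m = np.full(len(manifest), np.nan)
        u = np.full(len(manifest), np.nan)
        m[idx] = np.asarray(meth, dtype=np.float64)
        u[idx] = np.asarray(unmeth, dtype=np.float64)
        return cls(sample_id, manifest, m, u, reported_sex)


def compute_beta(meth, unmeth, offset: float = 100.0):
    """Methylation fraction ``meth / (meth + unmeth + offset)``.

    The additive offset stabilises low-intensity probes (platform
    convention); with ``offset=0`` the plain ratio is returned.  Works on
    scalars and arrays.
    """
    meth = np.asarray(meth, dtype=np.float64)
    unmeth = np.asarray(unmeth, dtype=np.float64)
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if np.any(meth[~np.isnan(meth)] < 0) or np.any(unmeth[~np.isnan(unmeth)] < 0):
        raise ValueError("intensities must be non-negative")
    denom = meth + unmeth + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, meth / denom, np.nan)
    return float(beta) if beta.ndim == 0 else beta


def combined_intensity(sample: SampleIntensities) -> np.ndarray:
    """Total signal per probe, ``meth + unmeth`` — the copy-number proxy."""
    return sample.meth + sample.unmeth


@dataclass
class ReferencePanel:
    """Aggregated flat-genome reference: one combined intensity per probe."""

    manifest: ProbeManifest
    samples: list
    per_probe_reference: np.ndarray
    aggregator: str = "median"

    def __post_init__(self) -> None:
        self.per_probe_reference = np.asarray(self.per_probe_reference, dtype=np.float64)
        keep = ~self.manifest.excluded
        ref = self.per_probe_reference[keep]
        if np.any(~(ref[~np.isnan(ref)] > 0)):
            raise ValueError("reference must be strictly positive at non-excluded probes")


def build_reference(
    samples: list,
    aggregator: str = "median",
    reference_floor: float = 0.0,
) -> ReferencePanel:
    """Aggregate a panel of copy-number-neutral samples into a per-probe reference.

    Probes whose aggregated combined intensity falls below
    ``reference_floor`` are flagged excluded on the manifest (a copy), so
    they never enter log2 ratios downstream.
    """
    if len(samples) < 3:
        raise ValueError("insufficient reference panel: need >= 3 samples")
    manifest = samples[0].manifest
    for s in samples[1:]:
        if s.manifest is not manifest and not np.array_equal(s.manifest.probe_id, manifest.probe_id):
            raise ValueError("panel samples must share the manifest")
    stack = np.vstack([combined_intensity(s) for s in samples])
    if aggregator == "median":
        ref = np.nanmedian(stack, axis=0)
    elif aggregator == "mean":
        ref = np.nanmean(stack, axis=0)
    else:
        raise ValueError(f"aggregator must be 'median' or 'mean', got {aggregator!r}")
    manifest = ProbeManifest(
        manifest.probe_id.copy(),
        manifest.chrom.copy(),
        manifest.pos.copy(),
        manifest.excluded.copy(),
    )
    low = np.isnan(ref) | (ref < reference_floor) | (ref <= 0)
    manifest.excluded |= low
    return ReferencePanel(manifest, list(samples), ref, aggregator)


# ---------------------------------------------------------------------------
# I/O


def read_manifest(path) -> ProbeManifest:
    """Read a tab-separated manifest: probe_id, chrom, pos[, excluded]."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}, got {list(df.columns)}")
    excluded = df["excluded"].to_numpy(bool) if "excluded" in df.columns else None
    return ProbeManifest(
        df["probe_id"].to_numpy(object),
        df["chrom"].to_numpy(object),
        df["pos"].to_numpy(),
        excluded,
    )


def read_intensity_table(path, manifest: ProbeManifest) -> list:
    """Read a wide intensity table: probe_id, then <sample>_meth / <sample>_unmeth pairs."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise ValueError("intensity table needs a probe_id column")
    sample_ids = []
    for col in df.columns:
        if col.endswith("_meth"):
            sid = col[: -len("_meth")]
            if f"{sid}_unmeth" not in df.columns:
                raise ValueError(f"missing unmeth column for sample {sid!r}")
            sample_ids.append(sid)
    samples = []
    for sid in sample_ids:
        samples.append(
            SampleIntensities.from_probe_table(
                sid,
                manifest,
                df["probe_id"].to_numpy(object),
                df[f"{sid}_meth"].to_numpy(),
                df[f"{sid}_unmeth"].to_numpy(),
            )
        )
    return samples


def write_intensity_table(path, samples: list) -> None:
    """Inverse of :func:`read_intensity_table`."""
    manifest = samples[0].manifest
    data = {"probe_id": manifest.probe_id}
    for s in samples:
        data[f"{s.sample_id}_meth"] = s.meth
        data[f"{s.sample_id}_unmeth"] = s.unmeth
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.4f")


def load_idat_pair(grn_path, red_path, manifest: ProbeManifest) -> SampleIntensities:
    """Ingestion hook for raw IDAT pairs.

    Raw IDAT decoding is delegated to an external reader (e.g. methylprep);
    this package only defines the boundary.  Raises ImportError when no
    reader is installed.
    """
    try:
        import methylprep  # noqa: F401
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "IDAT ingestion requires an external IDAT reader (methylprep); "
            "provide intensities as a tab-separated table instead"
        ) from exc
    raise NotImplementedError(
        "IDAT adapter boundary: wire your reader's output through "
        "SampleIntensities.from_probe_table"
    )  # pragma: no cover
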