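"""Synthetic array data with known truth.

Generates everything the rest of the package consumes: probe manifests
(a genome-wide layout and a down-scaled test layout over real hg19
chromosome lengths), flat-genome reference panels, tumor samples with known
integer copy-number segments diluted by tumor purity, cross-contamination
mixtures, bisulfite-failure-like noisy samples, and calibrated score
vectors with controllable top class/family structure.

Intensity model: each probe has a multiplicative affinity drawn once per
manifest (log-normal, capturing probe-to-probe brightness differences that
cancel in sample/reference ratios).  A sample's combined intensity at a
probe is ``scale · affinity · dosage · 2^ε`` with ε ~ N(0, noise_sd) in
log2 units, where dosage is the purity-weighted copy-number factor
``(p·n + (1−p)·2) / 2`` (germline sex chromosomes use the germline copy in
all cells, so purity does not dilute them).  The methylated share of the
combined signal is an independent per-probe Beta draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_model import CHROMOSOMES, ProbeManifest, SampleIntensities, normalize_chrom
from .scores import ClassSchema, ScoreVector

__all__ = [
    "HG19_CHROM_LENGTHS",
    "CopyNumberTruth",
    "simulate_manifest",
    "full_scale_manifest",
    "test_scale_manifest",
    "simulate_reference_panel",
    "simulate_tumor",
    "simulate_contamination",
    "add_noise",
    "simulate_scores",
]

#: hg19 chromosome lengths (bp)
HG19_CHROM_LENGTHS: dict = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

#: approximate p-arm extents (centromere positions), used for arm-level truths
HG19_P_ARM_END: dict = {
    "1": 125_000_000, "19": 26_500_000, "7": 59_900_000, "9": 49_000_000,
    "10": 40_200_000, "17": 24_000_000, "22": 14_700_000,
}

_DEFAULT_MIN_DOSAGE = 0.05  # floor for homozygous deletions (residual signal)


@dataclass
class CopyNumberTruth:
    """Ground-truth somatic copy-number state of a simulated tumor.

    segments: list of (chromosome, start, end, integer copy number); the
    rest of the genome sits at copy 2 (germline sex chromosomes at their
    germline copy).  purity is the tumor-cell fraction diluting every
    somatic segment.
    """

    segments: list = field(default_factory=list)
    sex: str = "female"
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.sex not in {"male", "female"}:
            raise ValueError("sex must be male or female")
        by_chrom: dict[str, list] = {}
        norm = []
        for chrom, start, end, cn in self.segments:
            c = normalize_chrom(chrom)
            if end <= start:
                raise ValueError(f"empty truth segment on {c}")
            if cn < 0 or int(cn) != cn:
                raise ValueError("copy numbers must be non-negative integers")
            by_chrom.setdefault(c, []).append((int(start), int(end)))
            norm.append((c, int(start), int(end), int(cn)))
        for c, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping truth segments on chromosome {c}")
        self.segments = norm

    def expected_log2(self, copy_number: int) -> float:
        """Closed-form expected log2 ratio of a segment at this purity."""
        dosage = (self.purity * copy_number + (1 - self.purity) * 2) / 2
        return float(np.log2(max(dosage, _DEFAULT_MIN_DOSAGE)))

    def to_bed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments, columns=["chrom", "start", "end", "copy_number"])


def simulate_manifest(n_probes: int, seed: int = 0, include_y: bool = True) -> ProbeManifest:
    """Probe manifest over real hg19 chromosome lengths, probes spread
    proportionally to chromosome size at jittered regular spacing."""
    rng = np.random.default_rng(seed)
    chroms = [c for c in CHROMOSOMES if include_y or c != "Y"]
    total = sum(HG19_CHROM_LENGTHS[c] for c in chroms)
    ids, cs, ps = [], [], []
    for c in chroms:
        n_c = max(2, round(n_probes * HG19_CHROM_LENGTHS[c] / total))
        spacing = HG19_CHROM_LENGTHS[c] / n_c
        base = (np.arange(n_c) + 0.5) * spacing
        jitter = rng.uniform(-0.45, 0.45, n_c) * spacing
        pos = np.unique(np.clip((base + jitter).astype(np.int64), 0, HG19_CHROM_LENGTHS[c] - 1))
        cs.extend([c] * len(pos))
        ps.extend(pos.tolist())
        ids.extend(f"cg_{c}_{i:06d}" for i in range(len(pos)))
    return ProbeManifest(np.array(ids, dtype=object), np.array(cs, dtype=object), np.array(ps))


def full_scale_manifest(seed: int = 0) -> ProbeManifest:
    """Genome-wide manifest at methylation-array scale (~450k probes)."""
    return simulate_manifest(450_000, seed=seed)


def test_scale_manifest(seed: int = 0) -> ProbeManifest:
    """Down-scaled manifest (~30k probes) so full pipelines run in seconds."""
    return simulate_manifest(30_000, seed=seed)


def _probe_affinity(manifest: ProbeManifest, affinity_sd: float = 0.3) -> np.ndarray:
    # drawn once per manifest (deterministic in the manifest layout) so all
    # samples share it and it cancels in sample/reference ratios
    rng = np.random.default_rng(len(manifest) * 7919 + 17)
    return np.exp(rng.normal(0.0, affinity_sd, len(manifest)))


def _dosage_vector(manifest: ProbeManifest, truth: CopyNumberTruth) -> np.ndarray:
    dosage = np.ones(len(manifest))
    # germline sex baseline (not purity-diluted: every cell carries it)
    if truth.sex == "male":
        dosage[manifest.chrom == "X"] = 0.5
        dosage[manifest.chrom == "Y"] = 0.5
    else:
        dosage[manifest.chrom == "Y"] = _DEFAULT_MIN_DOSAGE
    p = truth.purity
    for chrom, start, end, cn in truth.segments:
        mask = (manifest.chrom == chrom) & (manifest.pos >= start) & (manifest.pos < end)
        germline = dosage[mask] * 2  # local germline copy
        dosage[mask] = (p * cn + (1 - p) * germline) / 2
    return np.maximum(dosage, _DEFAULT_MIN_DOSAGE)


def _make_sample(
    sample_id: str,
    manifest: ProbeManifest,
    dosage: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    intensity_scale: float,
    reported_sex: str,
) -> SampleIntensities:
    affinity = _probe_affinity(manifest)
    combined = intensity_scale * affinity * dosage
    if noise_sd > 0:
        combined = combined * np.exp2(rng.normal(0.0, noise_sd, len(manifest)))
    meth_frac = rng.beta(2.0, 2.0, len(manifest))
    return SampleIntensities(
        sample_id, manifest, combined * meth_frac, combined * (1 - meth_frac), reported_sex
    )


def simulate_reference_panel(
    n: int,
    manifest: ProbeManifest,
    intensity_scale: float = 5000.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> list:
    """Flat-genome (copy-neutral, female) reference samples."""
    if n < 3:
        raise ValueError("reference panel needs n >= 3")
    rng = np.random.default_rng(seed)
    flat = CopyNumberTruth(sex="female", purity=1.0)
    dosage = _dosage_vector(manifest, flat)
    return [
        _make_sample(f"ref_{i:02d}", manifest, dosage, noise_sd, rng, intensity_scale, "female")
        for i in range(n)
    ]


def simulate_tumor(
    truth: CopyNumberTruth,
    manifest: ProbeManifest,
    noise_sd: float = 0.1,
    seed: int = 0,
    sample_id: str = "tumor",
    intensity_scale: float = 5000.0,
) -> SampleIntensities:
    """Tumor sample whose combined intensity tracks the purity-diluted truth."""
    rng = np.random.default_rng(seed)
    dosage = _dosage_vector(manifest, truth)
    return _make_sample(sample_id, manifest, dosage, noise_sd, rng, intensity_scale, truth.sex)


def simulate_contamination(
    recipient: SampleIntensities,
    donor: SampleIntensities,
    fraction: float,
    sample_id: str | None = None,
) -> SampleIntensities:
    """Convex per-channel mixture (1−f)·recipient + f·donor.

    Mixing each channel preserves the meth/unmeth split proportionally, so
    the combined intensity is the same convex mixture.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("contamination fraction must be in (0, 0.5]")
    if recipient.manifest is not donor.manifest and not np.array_equal(
        recipient.manifest.probe_id, donor.manifest.probe_id
    ):
        raise ValueError("recipient and donor must share the manifest")
    f = fraction
    return SampleIntensities(
        sample_id or f"{recipient.sample_id}+{donor.sample_id}@{f:g}",
        recipient.manifest,
        (1 - f) * recipient.meth + f * donor.meth,
        (1 - f) * recipient.unmeth + f * donor.unmeth,
        recipient.reported_sex,
    )


def add_noise(sample: SampleIntensities, extra_sd: float, seed: int = 0) -> SampleIntensities:
    """Overlay extra multiplicative noise (bisulfite-failure-like dispersion)."""
    rng = np.random.default_rng(seed)
    factor = np.exp2(rng.normal(0.0, extra_sd, len(sample.manifest)))
    return SampleIntensities(
        f"{sample.sample_id}_noisy",
        sample.manifest,
        sample.meth * factor,
        sample.unmeth * factor,
        sample.reported_sex,
    )


def simulate_scores(
    schema: ClassSchema,
    target: str,
    top_mass: float,
    concentration: float = 1.0,
    seed: int = 0,
    sample_id: str = "case",
) -> ScoreVector:
    """Calibrated score vector with a controlled top class or family.

    ``target`` names a schema class or family.  ``top_mass`` goes to the
    target (split across members by a Dirichlet draw favouring the first
    member when a family is targeted); the remainder is spread over the
    other classes by a symmetric Dirichlet(concentration) draw.  The output
    sums to 1 to within 1e-9.
    """
    if not 0 < top_mass <= 1:
        raise ValueError("top mass must be in (0, 1]")
    rng = np.random.default_rng(seed)
    scores = {c: 0.0 for c in schema.classes}
    if target in schema.families:
        members = schema.families[target]
        w = rng.dirichlet([4.0] + [1.0] * (len(members) - 1))
        for m, wi in zip(members, w):
            scores[m] = top_mass * wi
        rest = [c for c in schema.classes if c not in members]
    elif target in schema.classes:
        scores[target] = top_mass
        rest = [c for c in schema.classes if c != target]
    else:
        raise ValueError(f"unknown target class or family: {target!r}")
    remainder = 1.0 - top_mass
    if remainder > 0 and rest:
        w = rng.dirichlet([concentration] * len(rest))
        for c, wi in zip(rest, w):
            scores[c] = remainder * wi
    total = sum(scores.values())
    scores = {c: s / total for c, s in scores.items()}
    return ScoreVector(sample_id, scores)


def gbm_worked_example(schema: ClassSchema, sample_id: str = "gbm_case") -> ScoreVector:
    """The canonical IDH-wildtype glioblastoma score vector.

    Six GBM family members score 0.6 / 0.2 / 0.07 / 0.04 / 0.01 / 0.01
    (family sum 0.93); the remaining 0.07 is spread evenly over all other
    classes.
    """
    fixed = {
        "GBM, RTK I": 0.6,
        "GBM, MES": 0.2,
        "GBM, RTK II": 0.07,
        "GBM, MID": 0.04,
        "GBM, RTK III": 0.01,
        "GBM, MYCN": 0.01,
    }
    missing = set(fixed) - set(schema.classes)
    if missing:
        raise ValueError(f"schema lacks GBM family members: {sorted(missing)}")
    rest = [c for c in schema.classes if c not in fixed]
    remainder = 1.0 - sum(fixed.values())
    scores = dict(fixed)
    for c in rest:
        scores[c] = remainder / len(rest)
    return ScoreVector(sample_id, scores)
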