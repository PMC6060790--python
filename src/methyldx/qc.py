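"""Batch quality control for methylation-array runs.

Five checks applied to every run before sign-out: (1) predicted vs reported
sex per sample; (2) a noise score on each CNV profile (bisulfite failure,
low input and poor DNA quality all disperse the plot); (3) a
cross-contamination scan — a sample with any amplification is checked
against the rest of the run for focal gains/amplifications at the identical
region, since contaminating DNA surfaces almost exclusively through its
massively over-represented amplicons; (4) consistency of predicted classes
against expectations (mix-up / plate-order detection); (5) re-analysis
flagging for unusable profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .array_model import AUTOSOMES, ProbeManifest, SampleIntensities, combined_intensity
from .cnv import BinProfile, FocalEvent

__all__ = [
    "SexThresholds",
    "NoiseCutoffs",
    "QCReport",
    "predict_sex",
    "noise_score",
    "grade_noise",
    "contamination_scan",
    "consistency_check",
]


@dataclass(frozen=True)
class SexThresholds:
    """Intensity-ratio cutoffs for sex prediction (relative to autosomal median).

    A male genome carries one X (ratio ≈ 0.5) and one Y (clearly nonzero);
    a female genome two X (ratio ≈ 1) and only background on Y.
    """

    y_present: float = 0.2
    x_female_min: float = 0.8
    x_male_max: float = 0.7


@dataclass(frozen=True)
class NoiseCutoffs:
    """Noise-score grading: crisp below, unusable above (log2 units)."""

    crisp: float = 0.1
    unusable: float = 0.3


@dataclass
class QCReport:
    sample_id: str
    predicted_sex: str = "undetermined"
    sex_concordant: object = None  # True/False/None(unknown reported sex)
    noise_score: float = float("nan")
    noise_grade: str = "unknown"
    contamination_partners: list = field(default_factory=list)
    reanalysis_recommended: bool = False
    notes: list = field(default_factory=list)

    def finalize(self) -> "QCReport":
        if self.noise_grade == "unusable":
            self.reanalysis_recommended = True
            self.notes.append("unusable noise level: reanalysis recommended")
        if self.sex_concordant is False:
            self.notes.append("reported/predicted sex mismatch: check for case mix-up")
        if self.contamination_partners:
            self.notes.append("possible cross-contamination: shared focal amplified regions")
        return self


def predict_sex(
    sample: SampleIntensities,
    manifest: ProbeManifest | None = None,
    thresholds: SexThresholds = SexThresholds(),
) -> str:
    """Sex from X/Y combined-intensity dosage relative to the autosomal median."""
    manifest = manifest or sample.manifest
    comb = combined_intensity(sample)
    ok = ~np.isnan(comb)
    auto = ok & np.array([c in AUTOSOMES for c in manifest.chrom])
    x = ok & (manifest.chrom == "X")
    y = ok & (manifest.chrom == "Y")
    if x.sum() < 100 or auto.sum() < 100:
        return "undetermined"
    auto_med = np.median(comb[auto])
    if auto_med <= 0:
        return "undetermined"
    x_ratio = float(np.median(comb[x]) / auto_med)
    if not y.any():
        # X dosage alone, only when unambiguous
        if x_ratio >= thresholds.x_female_min:
            return "female"
        if x_ratio <= thresholds.x_male_max - 0.1:
            return "male"
        return "undetermined"
    y_ratio = float(np.median(comb[y]) / auto_med)
    if y_ratio >= thresholds.y_present and x_ratio <= thresholds.x_male_max:
        return "male"
    if y_ratio < thresholds.y_present and x_ratio >= thresholds.x_female_min:
        return "female"
    return "undetermined"


def noise_score(profile: BinProfile) -> float:
    """Median |difference| of consecutive within-chromosome bin log2 values.

    A derivative-based dispersion metric: shift-invariant, and robust to
    genuine copy-number steps because steps touch only a sparse minority of
    bin junctions.  For i.i.d. Gaussian bin noise of sd σ the score is
    ≈ 0.6745·σ·√2.
    """
    bins = profile.bins
    diffs = []
    for c in bins["chrom"].unique():
        v = bins.loc[bins["chrom"] == c, "log2_value"].to_numpy(np.float64)
        v = v[~np.isnan(v)]
        if v.size >= 2:
            diffs.append(np.abs(np.diff(v)))
    if not diffs:
        raise ValueError("noise score needs >= 2 bins on some chromosome")
    return float(np.median(np.concatenate(diffs)))


def grade_noise(score: float, cutoffs: NoiseCutoffs = NoiseCutoffs()) -> str:
    if score < cutoffs.crisp:
        return "crisp"
    if score > cutoffs.unusable:
        return "unusable"
    return "elevated"


def _reciprocal_overlap(a: FocalEvent, b: FocalEvent) -> float:
    if a.chromosome != b.chromosome:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def contamination_scan(
    batch: list,
    min_reciprocal_overlap: float = 0.5,
    focal_cap_bp: int = 10_000_000,
) -> list:
    """Scan a batch for shared focal amplified regions.

    ``batch`` is a list of (sample_id, [FocalEvent, ...]).  For every sample
    with at least one amplification, every other sample's amplifications and
    focal gains are checked for reciprocal overlap ≥ the cutoff; pairs
    sharing ≥ 1 region are flagged once with their shared regions.  Flags
    are advisory — contamination between amplification-free samples cannot
    be detected this way.
    """
    flagged: dict[tuple, list] = {}
    for i, (sid_a, events_a) in enumerate(batch):
        amps_a = [e for e in events_a if e.kind == "amplification"]
        if not amps_a:
            continue
        for sid_b, events_b in batch:
            if sid_b == sid_a:
                continue
            candidates = [
                e
                for e in events_b
                if e.kind == "amplification"
                or (e.kind == "gain" and e.length <= focal_cap_bp)
            ]
            shared = []
            for a in amps_a:
                for b in candidates:
                    if _reciprocal_overlap(a, b) >= min_reciprocal_overlap:
                        shared.append((a.chromosome, max(a.start, b.start), min(a.end, b.end)))
                        break
            if shared:
                key = tuple(sorted((sid_a, sid_b)))
                if key not in flagged or len(shared) > len(flagged[key]):
                    flagged[key] = shared
    return [
        {"samples": key, "shared_regions": regions, "n_shared": len(regions)}
        for key, regions in sorted(flagged.items())
    ]


def consistency_check(decisions: list, expected: dict | None = None) -> dict:
    """Compare predicted top classes with per-sample expectations.

    Returns mismatching samples and, when every expectation fails, a
    batch-level warning (a systematic pattern such as an array loaded in
    reverse order).
    """
    mismatches = []
    checked = 0
    for rep in decisions:
        exp = (expected or {}).get(rep.sample_id)
        if exp is None:
            continue
        checked += 1
        if rep.top_class != exp:
            mismatches.append(
                {"sample_id": rep.sample_id, "expected": exp, "predicted": rep.top_class}
            )
    systematic = checked >= 2 and len(mismatches) == checked
    return {
        "mismatches": mismatches,
        "systematic_warning": (
            "all expectations mismatched: check for systematic error "
            "(e.g., array loaded in reverse order)"
            if systematic
            else None
        ),
    }
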