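"""Calibrated classifier-score semantics: families, sum rule, threshold ladder.

The classifier emits one calibrated probability per methylation class
(v11b4: 82 tumor + 9 control classes, all summing to 1).  Closely related
classes are grouped into eight methylation class families; since the
calibrated scores are probability estimates, the family score is simply the
sum of its members' class scores.  Decision making applies a single ladder
to the best of (best class score, best family score):

    >= 0.9          classifiable (class- or family-level)
    [0.84, 0.9)     borderline — the maximised-Youden-index cutoff; a valid
                    classification if nothing else speaks against it
    [0.5, 0.84)     suggestive — an indication to seek further evidence
    < 0.5           no match

Within a classifiable family, the most likely subclass is reported when the
best member's class score reaches 0.5.  Reports list only scores above a
0.3 floor.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClassSchema",
    "ScoreVector",
    "Thresholds",
    "DecisionReport",
    "load_schema",
    "family_scores",
    "decide",
    "format_report",
    "read_score_table",
]

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class Thresholds:
    """Score cutoffs of the decision ladder (strictly decreasing)."""

    classifiable: float = 0.9
    borderline_floor: float = 0.84
    suggestive_floor: float = 0.5
    reporting_floor: float = 0.3
    subclass_cutoff: float = 0.5
    control_elevated: float = 0.3

    def __post_init__(self) -> None:
        if not (
            self.classifiable > self.borderline_floor > self.suggestive_floor > self.reporting_floor
        ):
            raise ValueError(
                "thresholds must satisfy classifiable > borderline_floor "
                "> suggestive_floor > reporting_floor"
            )


@dataclass
class ClassSchema:
    """Class list with tumor/control categories and family membership."""

    classes: dict  # name -> category ("tumor" | "control")
    families: dict  # family name -> list of member class names

    def __post_init__(self) -> None:
        bad = {c for c, cat in self.classes.items() if cat not in {"tumor", "control"}}
        if bad:
            raise ValueError(f"class categories must be tumor/control: {sorted(bad)}")
        seen: set[str] = set()
        for fam, members in self.families.items():
            if not 2 <= len(members) <= 6:
                raise ValueError(f"family {fam!r} must have 2-6 members, has {len(members)}")
            unknown = set(members) - set(self.classes)
            if unknown:
                raise ValueError(f"family {fam!r} has unknown members: {sorted(unknown)}")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"family members not disjoint: {sorted(overlap)}")
            seen |= set(members)

    @property
    def tumor_classes(self) -> list:
        return [c for c, cat in self.classes.items() if cat == "tumor"]

    @property
    def control_classes(self) -> list:
        return [c for c, cat in self.classes.items() if cat == "control"]

    def family_of(self, class_name: str):
        for fam, members in self.families.items():
            if class_name in members:
                return fam
        return None

    def to_yaml(self, path) -> None:
        doc = {
            "classes": [{"name": c, "category": cat} for c, cat in self.classes.items()],
            "families": [{"name": f, "members": list(m)} for f, m in self.families.items()],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def load_schema(path=None) -> ClassSchema:
    """Load a class schema YAML; default is the bundled v11b4-layout schema."""
    if path is None:
        ref = importlib.resources.files("methyldx.data") / "schema_v11b4.yaml"
        with importlib.resources.as_file(ref) as p:
            with open(p) as fh:
                doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    classes = {c["name"]: c["category"] for c in doc["classes"]}
    families = {f["name"]: list(f["members"]) for f in doc["families"]}
    return ClassSchema(classes, families)


@dataclass
class ScoreVector:
    """One calibrated probability per schema class, summing to 1."""

    sample_id: str
    scores: dict  # class name -> probability

    def validate(self, schema: ClassSchema) -> None:
        missing = set(schema.classes) - set(self.scores)
        if missing:
            raise ValueError(f"score vector missing classes: {sorted(missing)[:5]}...")
        extra = set(self.scores) - set(schema.classes)
        if extra:
            raise ValueError(f"score vector has unknown classes: {sorted(extra)[:5]}...")
        vals = np.array(list(self.scores.values()), dtype=np.float64)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("scores must lie in [0, 1]")
        total = float(vals.sum())
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"scores must sum to 1 (got {total:.8f}); not renormalizing")


@dataclass
class DecisionReport:
    sample_id: str
    category: str  # classifiable_class | classifiable_family | borderline | suggestive | no_match
    top_class: str
    top_class_score: float
    top_family: str | None = None
    family_score: float | None = None
    subclass: str | None = None
    listed_scores: list = field(default_factory=list)  # (name, score), descending, > floor
    flags: dict = field(default_factory=dict)  # low_purity, control_elevated
    note: str = ""


def family_scores(v: ScoreVector, schema: ClassSchema) -> dict:
    """Sum-rule family scores: exact sum of member class probabilities."""
    v.validate(schema)
    return {fam: float(sum(v.scores[m] for m in members)) for fam, members in schema.families.items()}


def decide(
    v: ScoreVector,
    schema: ClassSchema,
    thresholds: Thresholds = Thresholds(),
    low_purity: bool = False,
) -> DecisionReport:
    """Apply the threshold ladder to a calibrated score vector.

    The ladder is driven by max(best class score, best family score).  A
    classifiable result reached only through the family sum is reported at
    family level; the most likely subclass is attached when its own class
    score reaches the subclass cutoff.  With ``low_purity`` set, borderline
    and suggestive outcomes carry an annotation that a lower score may be
    accepted as an indication of a specific diagnosis.  Control-class scores
    summing past their threshold raise the control_elevated flag (typical of
    low tumor content / infiltration-zone material).
    """
    v.validate(schema)
    fam = family_scores(v, schema)
    top_class = max(v.scores, key=lambda c: v.scores[c])
    top_class_score = v.scores[top_class]
    top_family, top_family_score = (None, -1.0)
    if fam:
        top_family = max(fam, key=lambda f: fam[f])
        top_family_score = fam[top_family]
    best = max(top_class_score, top_family_score)

    subclass = None
    note = ""
    if top_class_score >= thresholds.classifiable:
        category = "classifiable_class"
        cf = schema.family_of(top_class)
        if cf is not None and fam[cf] >= thresholds.classifiable:
            note = f"family {cf} also classifiable (score {fam[cf]:.2f})"
    elif top_family_score >= thresholds.classifiable:
        category = "classifiable_family"
        best_member = max(schema.families[top_family], key=lambda m: v.scores[m])
        if v.scores[best_member] >= thresholds.subclass_cutoff:
            subclass = best_member
        else:
            note = "no subclass reaches the subclass cutoff; family-level result only"
    elif best >= thresholds.borderline_floor:
        category = "borderline"
        note = "valid classification if nothing else strongly speaks against it"
    elif best >= thresholds.suggestive_floor:
        category = "suggestive"
        note = "suggestion of a relation to this class; seek further evidence"
    else:
        category = "no_match"

    flags = {}
    control_sum = sum(v.scores[c] for c in schema.control_classes)
    if control_sum >= thresholds.control_elevated:
        flags["control_elevated"] = True
    if low_purity:
        flags["low_purity"] = True
        if category in {"borderline", "suggestive"}:
            note = (
                "low tumor cell content: a lower score may be accepted as an "
                "indication of a specific diagnosis"
            )

    listed = sorted(
        ((c, s) for c, s in v.scores.items() if s > thresholds.reporting_floor),
        key=lambda cs: -cs[1],
    )
    return DecisionReport(
        sample_id=v.sample_id,
        category=category,
        top_class=top_class,
        top_class_score=float(top_class_score),
        top_family=top_family if top_family_score > 0 else None,
        family_score=float(top_family_score) if top_family is not None else None,
        subclass=subclass,
        listed_scores=listed,
        flags=flags,
        note=note,
    )


def format_report(report: DecisionReport) -> str:
    """Deterministic plain-text rendering of a decision report."""
    lines = [
        f"sample: {report.sample_id}",
        f"category: {report.category}",
        f"top class: {report.top_class} (score {report.top_class_score:.2f})",
    ]
    if report.top_family is not None:
        lines.append(f"top family: {report.top_family} (family score {report.family_score:.2f})")
    if report.subclass is not None:
        lines.append(f"subclass: {report.subclass}")
    if report.listed_scores:
        lines.append("scores above reporting floor:")
        for name, score in report.listed_scores:
            lines.append(f"  {name}: {score:.2f}")
    for flag in sorted(report.flags):
        lines.append(f"flag: {flag}")
    if report.note:
        lines.append(f"note: {report.note}")
    return "\n".join(lines) + "\n"


def read_score_table(path, schema: ClassSchema) -> list:
    """Read score vectors from a tab-separated sample × class table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vectors = []
    for sid, row in df.iterrows():
        vectors.append(ScoreVector(str(sid), {c: float(row[c]) for c in df.columns}))
    return vectors


def write_score_table(path, vectors: list, schema: ClassSchema) -> None:
    cols = list(schema.classes)
    rows = {v.sample_id: [v.scores[c] for c in cols] for v in vectors}
    pd.DataFrame.from_dict(rows, orient="index", columns=cols).to_csv(
        path, sep="\t", index_label="sample_id", float_format="%.8g"
    )
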