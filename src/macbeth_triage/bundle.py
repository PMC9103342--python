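"""Model-bundle I/O: the whole decision model in one YAML/JSON document.

A bundle carries the value tree, per-criterion judgment matrices and/or
fixture-supplied anchored scales, sector weight vectors and swing
rankings, and the routing table.  Scales may be supplied directly when the
underlying expert judgments are unknown, which is the case for the entire
packaged Bauru model.  Loading validates referential integrity (every id
must resolve) and returns structural warnings — e.g. a published scale
that violates strict monotonicity — without refusing to load.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .macbeth import AnchoredValueScale, JudgmentMatrix
from .value_model import (
    CaseProfile,
    Criterion,
    Descriptor,
    PerformanceLevel,
    ValueTree,
    validate_tree,
)
from .evaluation import SectorModel
from .weighting import SwingRanking, WeightVector


class BundleError(ValueError):
    """Schema or reference error in a model bundle, with a document path."""


@dataclass
class ModelBundle:
    name: str
    tree: ValueTree
    sectors: dict[str, SectorModel]
    judgments: dict[str, JudgmentMatrix] = field(default_factory=dict)
    routing: dict = field(default_factory=dict)
    group_id: str | None = None
    format_version: int = 1
    notes: str = ""
    warnings: list[str] = field(default_factory=list)

    def sector_model(self, sector_id: str) -> SectorModel:
        try:
            return self.sectors[sector_id]
        except KeyError:
            raise BundleError(
                f"unknown sector {sector_id!r}; have {sorted(self.sectors)}"
            ) from None

    @property
    def group_model(self) -> SectorModel | None:
        return self.sectors.get(self.group_id) if self.group_id else None


def _parse_tree(doc: dict) -> ValueTree:
    try:
        criteria = []
        for c in doc["criteria"]:
            d = c["descriptor"]
            levels = [
                PerformanceLevel(
                    id=lv["id"],
                    label=lv["label"],
                    rank=rank,
                    definition=lv.get("definition", ""),
                    supplementary=bool(lv.get("supplementary", False)),
                )
                for rank, lv in enumerate(d["levels"])
            ]
            criteria.append(
                Criterion(
                    id=c["id"],
                    name=c.get("name", c["id"]),
                    area_of_concern=c["area_of_concern"],
                    descriptor=Descriptor(
                        levels=levels,
                        good_level=d["good"],
                        neutral_level=d["neutral"],
                    ),
                )
            )
    except (KeyError, TypeError) as exc:
        raise BundleError(f"tree: malformed criterion entry ({exc})") from exc
    return ValueTree(
        objective=doc.get("objective", ""),
        areas_of_concern=list(doc.get("areas_of_concern", [])),
        criteria=criteria,
    )


def _parse_sector(sector_id: str, doc: dict, tree: ValueTree, warnings: list[str]) -> SectorModel:
    where = f"sectors.{sector_id}"
    criteria = list(doc.get("criteria", []))
    for crit_id in criteria:
        try:
            tree.criterion(crit_id)
        except KeyError:
            raise BundleError(f"{where}: unknown criterion {crit_id!r}") from None
    ranking = SwingRanking(groups=[list(g) for g in doc.get("ranking", [])])
    weights = WeightVector(weights={k: float(v) for k, v in doc.get("weights", {}).items()},
                           ranking=ranking)
    scales: dict[str, AnchoredValueScale] = {}
    for crit_id, level_scores in doc.get("scales", {}).items():
        descriptor = tree.criterion(crit_id).descriptor
        known = set(descriptor.level_ids())
        for lid in level_scores:
            if lid not in known:
                raise BundleError(
                    f"{where}.scales.{crit_id}: unknown level {lid!r}"
                )
        scale = AnchoredValueScale(
            scores={k: float(v) for k, v in level_scores.items()},
            good_level=descriptor.good_level,
            neutral_level=descriptor.neutral_level,
            criterion=crit_id,
        )
        warnings.extend(
            scale.validate(descriptor, where=f"{where}.scales.{crit_id}")
        )
        scales[crit_id] = scale
    model = SectorModel(
        sector_id=sector_id,
        criteria=criteria,
        scales=scales,
        weights=weights,
        ranking=ranking,
        notes=doc.get("name", ""),
    )
    warnings.extend(model.validate())
    warnings.extend(weights.validate())
    return model


def parse_bundle(doc: dict) -> ModelBundle:
    if not isinstance(doc, dict) or "tree" not in doc:
        raise BundleError("document is not a model bundle (no `tree` section)")
    tree = _parse_tree(doc["tree"])
    report = validate_tree(tree)
    warnings = [] if report.ok else list(report.violations)

    judgments: dict[str, JudgmentMatrix] = {}
    for crit_id, jdoc in (doc.get("judgments") or {}).items():
        stimuli = list(jdoc["stimuli"])
        judgments[crit_id] = JudgmentMatrix(
            stimuli=stimuli,
            judgments=[
                (stimuli.index(a), stimuli.index(b), k)
                for a, b, k in jdoc.get("judgments", [])
            ],
        )

    sectors = {
        sid: _parse_sector(sid, sdoc, tree, warnings)
        for sid, sdoc in (doc.get("sectors") or {}).items()
    }
    for sid, model in sectors.items():
        for crit_id in model.criteria:
            if crit_id not in model.scales and crit_id not in judgments:
                raise BundleError(
                    f"sectors.{sid}: criterion {crit_id!r} has neither a scale "
                    "nor a judgment matrix"
                )
    group_id = doc.get("group_id")
    if group_id is not None and group_id not in sectors:
        raise BundleError(f"group_id {group_id!r} names no sector")
    return ModelBundle(
        name=doc.get("name", "bundle"),
        tree=tree,
        sectors=sectors,
        judgments=judgments,
        routing=doc.get("routing") or {},
        group_id=group_id,
        format_version=int(doc.get("format_version", 1)),
        notes=doc.get("notes", ""),
        warnings=warnings,
    )


def bundle_to_doc(bundle: ModelBundle) -> dict:
    """Inverse of :func:`parse_bundle`; parse∘serialize is the identity."""
    tree_doc = {
        "objective": bundle.tree.objective,
        "areas_of_concern": list(bundle.tree.areas_of_concern),
        "criteria": [
            {
                "id": c.id,
                "name": c.name,
                "area_of_concern": c.area_of_concern,
                "descriptor": {
                    "good": c.descriptor.good_level,
                    "neutral": c.descriptor.neutral_level,
                    "levels": [
                        {
                            "id": lv.id,
                            "label": lv.label,
                            **({"definition": lv.definition} if lv.definition else {}),
                            **({"supplementary": True} if lv.supplementary else {}),
                        }
                        for lv in sorted(c.descriptor.levels, key=lambda lv: lv.rank)
                    ],
                },
            }
            for c in bundle.tree.criteria
        ],
    }
    sectors_doc = {}
    for sid, m in bundle.sectors.items():
        sectors_doc[sid] = {
            "name": m.notes,
            "criteria": list(m.criteria),
            "ranking": [list(g) for g in m.ranking.groups],
            "weights": dict(m.weights.weights),
            "scales": {cid: dict(sc.scores) for cid, sc in m.scales.items()},
        }
    doc = {
        "format_version": bundle.format_version,
        "name": bundle.name,
        "notes": bundle.notes,
        "tree": tree_doc,
        "judgments": {
            cid: {
                "stimuli": list(jm.stimuli),
                "judgments": [[jm.stimuli[i], jm.stimuli[j], k] for i, j, k in jm.judgments],
            }
            for cid, jm in bundle.judgments.items()
        },
        "sectors": sectors_doc,
        "routing": bundle.routing,
    }
    if bundle.group_id:
        doc["group_id"] = bundle.group_id
    return doc


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    # Unicode minus, as printed in typeset severity tables, normalises to '-'
    text = text.replace("−", "-")
    if not text.strip():
        raise BundleError(f"{path}: empty document")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return parse_bundle(doc)


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    path = Path(path)
    doc = bundle_to_doc(bundle)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True),
                        encoding="utf-8")


def load_case_profile(path: str | Path) -> CaseProfile:
    """Case profile from JSON ({case_id, assignments}) or CSV
    (case_id, criterion, level; one case per file)."""
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        return CaseProfile(
            case_id=doc.get("case_id", path.stem),
            assignments=dict(doc.get("assignments", {})),
            provenance=doc.get("provenance", ""),
        )
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        return CaseProfile(case_id=path.stem)
    case_ids = {r["case_id"] for r in rows}
    if len(case_ids) > 1:
        raise BundleError(f"{path}: multiple case ids {sorted(case_ids)}")
    return CaseProfile(
        case_id=rows[0]["case_id"],
        assignments={r["criterion"]: r["level"] for r in rows},
    )


# --- packaged Bauru fixtures ----------------------------------------------

def _fixture_path(name: str) -> Path:
    return Path(resources.files("macbeth_triage").joinpath("fixtures", name))


def load_bauru_bundle() -> ModelBundle:
    return load_bundle(_fixture_path("bauru_bundle.yaml"))


def load_typical_case() -> CaseProfile:
    return load_case_profile(_fixture_path("typical_case.json"))


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture file (Delphi CSVs etc.)."""
    return _fixture_path(name)
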