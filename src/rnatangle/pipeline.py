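"""Batch audit of a directory of predicted 3D RNA models.

``scan`` runs the entanglement and knot analyses over every model file in a
directory, attaches target/group metadata (natural vs synthetic target,
traditional vs machine-learning method, server vs human participant), and
``summarize``/``write_reports`` emit per-model JSON reports plus cohort
tables with the column structure Models / Interlaces / Lassos / Trefoils /
Other knots / TTC.

Model identifiers following the CASP convention ``R<target>TS<group>_<idx>``
(e.g. ``R1107TS416_2``) are parsed from file names; editable CSV tables map
the 12 CASP15 RNA targets to natural/synthetic + difficulty and prediction
groups to method/participant class, so the stratified tables are
reproducible without hard-coding.  Unknown models fall into a default
stratum.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .elements import all_elements  # noqa: F401  (re-exported for callers)
from .entangle import Entanglement, detect_all
from .knots import InvalidCoordinatesError, KnotAssessment, assess_knot
from .structure_io import (
    EmptyModelError,
    FormatError,
    TooShortError,
    annotate_base_pairs,
    detect_duplicate_coordinates,
    extract_backbone,
    read_model,
)

logger = logging.getLogger(__name__)

__all__ = ["ModelReport", "CohortSummary", "ScanOptions", "scan", "summarize",
           "write_reports", "parse_model_id", "load_metadata"]

_MODEL_ID_RE = re.compile(r"^(?P<target>R\d+)(?P<group>TS\d+)_(?P<index>\d+)$")

SUMMARY_COLUMNS = ["Models", "Interlaces", "Lassos", "Trefoils", "Other knots", "TTC"]


def parse_model_id(model_id: str):
    """Split a CASP-style model id into (target_id, group_id) or (None, None)."""
    m = _MODEL_ID_RE.match(model_id)
    if not m:
        return None, None
    return m.group("target"), m.group("group")


def load_metadata(targets_csv=None, groups_csv=None):
    """Load target and group stratum tables (packaged defaults when None)."""
    data_dir = importlib.resources.files("rnatangle") / "data"
    targets = pd.read_csv(targets_csv or str(data_dir / "targets.csv"))
    groups = pd.read_csv(groups_csv or str(data_dir / "groups.csv"))
    return targets.set_index("target_id"), groups.set_index("group_id")


@dataclass
class ScanOptions:
    n_closures: int = 200
    seed: int = 0
    crossing_budget: int = 50
    unknot_threshold: float = 0.5
    ss_source: str = "auto"  # auto | detect | dotbracket
    discard_ambiguous: bool = False
    subdivision_rounds: int = 3
    run_knots: bool = True


@dataclass
class ModelReport:
    model_id: str
    target_id: str | None
    group_id: str | None
    target_class: str = "unknown"
    difficulty: str = "unknown"
    method_class: str = "unknown"
    participant_class: str = "unknown"
    entanglements: list[Entanglement] = field(default_factory=list)
    knots: list[KnotAssessment] = field(default_factory=list)
    status: str = "ok"  # ok | invalid-coordinates | ttc | error
    error: str = ""

    @property
    def entangled_elements(self) -> bool:
        return bool(self.entanglements)

    def knotted(self, discard_ambiguous: bool = False) -> bool:
        for k in self.knots:
            if k.knotted and not (discard_ambiguous and k.ambiguous):
                return True
        return False

    @property
    def dominant_knot(self) -> str:
        labels = [k.dominant_label for k in self.knots if k.knotted]
        return labels[0] if labels else "unknot"

    @property
    def ttc(self) -> bool:
        return self.status == "ttc" or any(k.ttc for k in self.knots)

    def to_dict(self, discard_ambiguous: bool = False) -> dict:
        return {
            "model_id": self.model_id,
            "target_id": self.target_id,
            "group_id": self.group_id,
            "strata": {
                "target_class": self.target_class,
                "difficulty": self.difficulty,
                "method_class": self.method_class,
                "participant_class": self.participant_class,
            },
            "status": self.status,
            "error": self.error,
            "entangled_elements": self.entangled_elements,
            "knotted": self.knotted(discard_ambiguous),
            "ttc": self.ttc,
            "entanglements": [e.to_dict() for e in self.entanglements],
            "knots": [k.to_dict() for k in self.knots],
        }


@dataclass
class CohortSummary:
    table: pd.DataFrame  # one row per stratum value + total
    venn: dict  # only_elements / only_knots / both / entangled_models
    probabilities: dict  # stratum value -> entangled fraction (2 decimals)

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="index"),
            "venn": self.venn,
            "probabilities": self.probabilities,
        }


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _sidecar_dotbracket(path: Path):
    dbn = path.with_suffix(".dbn")
    if not dbn.exists():
        return None
    lines = [ln.strip() for ln in dbn.read_text().splitlines() if ln.strip()]
    if not lines:
        return None
    return lines[-1]


def scan(models_dir, metadata=None, options: ScanOptions | None = None) -> list[ModelReport]:
    """Audit every model file in a directory.

    Parse failures never abort the batch: the affected model is reported with
    ``status='error'``.  Models with duplicate atom coordinates are excluded
    from knot analysis (``status='invalid-coordinates'``) but still screened
    for element entanglements.  Deterministic for a given seed.
    """
    options = options or ScanOptions()
    models_dir = Path(models_dir)
    if not models_dir.is_dir():
        raise IOError(f"not a directory: {models_dir}")
    targets_meta, groups_meta = metadata if metadata is not None else load_metadata()
    files = sorted(
        p for p in models_dir.iterdir() if p.suffix.lower() in (".pdb", ".cif", ".mmcif", ".ent")
    )
    if not files:
        logger.warning("no model files found in %s", models_dir)
    reports = []
    for path in files:
        reports.append(_scan_one(path, targets_meta, groups_meta, options))
    return reports


def _scan_one(path: Path, targets_meta, groups_meta, options: ScanOptions) -> ModelReport:
    model_id = path.stem
    target_id, group_id = parse_model_id(model_id)
    report = ModelReport(model_id=model_id, target_id=target_id, group_id=group_id)
    if target_id is not None and target_id in targets_meta.index:
        row = targets_meta.loc[target_id]
        report.target_class = row["target_class"]
        report.difficulty = row["difficulty"]
    if group_id is not None and group_id in groups_meta.index:
        row = groups_meta.loc[group_id]
        report.method_class = row["method_class"]
        report.participant_class = row["participant_class"]
    try:
        model = read_model(path)
    except (FormatError, EmptyModelError, FileNotFoundError) as err:
        report.status = "error"
        report.error = str(err)
        return report

    dup = detect_duplicate_coordinates(model)
    invalid_coords = bool(dup)

    # entanglements of structure elements
    try:
        ss = _secondary_structure(model, path, options)
        report.entanglements = detect_all(model, ss, options.subdivision_rounds)
    except Exception as err:  # keep the batch alive
        logger.warning("entanglement analysis failed for %s: %s", model_id, err)
        report.error = f"entangle: {err}"

    # backbone knots, one assessment per chain
    if invalid_coords:
        report.status = "invalid-coordinates"
    elif options.run_knots:
        for chain in model.chains:
            try:
                backbone = extract_backbone(model, chain.chain_id)
                report.knots.append(
                    assess_knot(
                        backbone,
                        n_closures=options.n_closures,
                        unknot_threshold=options.unknot_threshold,
                        crossing_budget=options.crossing_budget,
                        seed=options.seed,
                    )
                )
            except TooShortError:
                continue
            except InvalidCoordinatesError:
                report.status = "invalid-coordinates"
                break
        if report.status == "ok" and any(k.ttc for k in report.knots):
            report.status = "ttc"
    return report


def _secondary_structure(model, path: Path, options: ScanOptions):
    source = options.ss_source
    db = _sidecar_dotbracket(path) if source in ("auto", "dotbracket") else None
    if source == "dotbracket" and db is None:
        raise FileNotFoundError(f"no dot-bracket sidecar for {path}")
    if db is not None and len(model.chains) == 1:
        return annotate_base_pairs(model, "dotbracket", db)
    return annotate_base_pairs(model, "detect")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _count_row(reports: list[ModelReport], discard_ambiguous: bool) -> dict:
    interlaces = sum(1 for r in reports for e in r.entanglements if e.is_interlace)
    lassos = sum(1 for r in reports for e in r.entanglements if not e.is_interlace)
    trefoils = sum(
        1 for r in reports if r.knotted(discard_ambiguous) and r.dominant_knot == "3_1"
    )
    others = sum(
        1
        for r in reports
        if r.knotted(discard_ambiguous)
        and r.dominant_knot not in ("3_1", "unknot", "too_complex")
    )
    ttc = sum(1 for r in reports if r.ttc)
    return {
        "Models": len(reports),
        "Interlaces": interlaces,
        "Lassos": lassos,
        "Trefoils": trefoils,
        "Other knots": others,
        "TTC": ttc,
    }


def summarize(
    reports: list[ModelReport],
    strata: str = "target_class",
    discard_ambiguous: bool = False,
) -> CohortSummary:
    """Cohort table stratified by one metadata column, plus the Venn split.

    ``strata`` is one of ``target_class``, ``difficulty``, ``method_class``,
    ``participant_class``.  Entanglement probability per stratum is the
    entangled-model fraction rounded to 2 decimals.  The Venn decomposition
    counts models with only element entanglements, only knots, and both.
    """
    valid = {"target_class", "difficulty", "method_class", "participant_class"}
    if strata not in valid:
        raise ValueError(f"unknown stratum {strata!r}; choose one of {sorted(valid)}")
    groups: dict[str, list[ModelReport]] = {}
    for r in reports:
        groups.setdefault(getattr(r, strata), []).append(r)
    rows = {}
    probabilities = {}
    for value in sorted(groups):
        sub = groups[value]
        rows[value] = _count_row(sub, discard_ambiguous)
        entangled = sum(
            1 for r in sub if r.entangled_elements or r.knotted(discard_ambiguous)
        )
        probabilities[value] = round(entangled / len(sub), 2) if sub else 0.0
    rows["total"] = _count_row(reports, discard_ambiguous)
    only_elements = sum(
        1 for r in reports if r.entangled_elements and not r.knotted(discard_ambiguous)
    )
    only_knots = sum(
        1 for r in reports if r.knotted(discard_ambiguous) and not r.entangled_elements
    )
    both = sum(
        1 for r in reports if r.entangled_elements and r.knotted(discard_ambiguous)
    )
    venn = {
        "only_elements": only_elements,
        "only_knots": only_knots,
        "both": both,
        "entangled_models": only_elements + only_knots + both,
    }
    table = pd.DataFrame.from_dict(rows, orient="index")[SUMMARY_COLUMNS]
    return CohortSummary(table=table, venn=venn, probabilities=probabilities)


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

def write_reports(
    reports: list[ModelReport],
    summary: CohortSummary,
    out_dir,
    options: ScanOptions | None = None,
) -> dict[str, Path]:
    """Write per-model JSON, a flat entanglement CSV, the summary table and a
    run manifest into ``out_dir``.  Output is deterministic for a given seed
    (no timestamps inside the data files)."""
    options = options or ScanOptions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model_dir = out_dir / "models"
    model_dir.mkdir(exist_ok=True)
    for r in reports:
        payload = r.to_dict(options.discard_ambiguous)
        (model_dir / f"{r.model_id}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
    ent_csv = out_dir / "entanglements.csv"
    with ent_csv.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["model_id", "subclass", "element_x", "element_y", "n_intersections",
             "linking", "depth", "depth_class", "artifact"]
        )
        for r in reports:
            for e in r.entanglements:
                writer.writerow(
                    [r.model_id, e.subclass, e.element_x.describe(), e.element_y.describe(),
                     len(e.intersections), e.linking,
                     "" if e.depth is None else e.depth, e.depth_class, e.artifact]
                )
    summary_csv = out_dir / "summary.csv"
    summary.table.to_csv(summary_csv, index_label="stratum")
    venn_json = out_dir / "venn.json"
    venn_json.write_text(json.dumps(summary.venn, indent=2, sort_keys=True) + "\n")
    manifest = out_dir / "manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "rnatangle_version": __version__,
                "seed": options.seed,
                "n_closures": options.n_closures,
                "crossing_budget": options.crossing_budget,
                "unknot_threshold": options.unknot_threshold,
                "ss_source": options.ss_source,
                "discard_ambiguous": options.discard_ambiguous,
                "subdivision_rounds": options.subdivision_rounds,
                "n_models": len(reports),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return {"models": model_dir, "entanglements": ent_csv, "summary": summary_csv,
            "venn": venn_json, "manifest": manifest}
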