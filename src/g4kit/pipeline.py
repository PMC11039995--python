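"""Per-structure analysis pipeline and report serialization.

``analyze`` runs the full chain -- tetrad detection, strand assembly,
discontinuities, gc classification, grooves, stack steps, classification
-- on one :class:`~g4kit.io.StructureModel` and returns a
:class:`StructureReport`.  ``analyze_paths`` maps it over PDB files with
per-file failure logging (a corrupt file never aborts the batch), and
``write_report`` emits the JSON + flat TSV row consumed by the cohort
layer.  These functions are the package's operational entry points; the
examples/ scripts show them in context.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import classify, geom
from .config import AnalysisConfig
from .glyco import GcRecord, classify_gc
from .io import StructureModel, is_guanine, load_structures
from .stem import Stem, build_stem_from_model

__all__ = ["StructureReport", "analyze", "analyze_paths", "write_report"]

logger = logging.getLogger("g4kit")


@dataclass
class StructureReport:
    """Everything the analysis computed for one chain of one structure."""

    label: str
    n_tetrads: int
    blocks: list[tuple[int, int]]
    topology: classify.TopologyCall
    directions: str
    gc_records: dict[tuple, GcRecord]
    gc_patterns: list[str]
    gc_predicted: tuple[str, str] | None
    gc_mismatches: list[dict]
    grooves: dict[str, geom.GrooveProfile]
    min_distances: dict[int, list[float]]
    steps: list[geom.StackStep]
    handedness: str
    anticlockwise: bool
    reversed_first_guanine: bool
    loops: classify.LoopAnnotation
    stacking: classify.StackingTypeCall
    platypus: classify.PlatypusReport
    planarity_flags: list[bool]
    discontinuities: list[dict]
    notes: list[str] = field(default_factory=list)
    stem: Stem | None = None

    @property
    def is_regular(self) -> bool:
        """One-block, right-handed, no 5'-5' inversion of polarity."""
        return (
            len(self.blocks) == 1
            and self.handedness == "right"
            and not any(d["kind"] == "inversion_5p5p" for d in self.discontinuities)
        )

    def to_dict(self) -> dict:
        prof = {
            kind: {
                "per_tetrad": np.round(p.per_tetrad, 3).tolist(),
                "width": [round(w, 3) for w in p.width],
                "width_sd": [round(w, 3) for w in p.width_sd],
                "perimeter": round(p.perimeter, 3),
                "signature": p.signature,
                "signature_threshold": p.signature_threshold,
            }
            for kind, p in self.grooves.items()
        }
        return {
            "label": self.label,
            "n_tetrads": self.n_tetrads,
            "blocks": self.blocks,
            "topology": {
                "code": self.topology.code,
                "name": self.topology.name,
                "suggestion": self.topology.suggestion,
            },
            "directions": self.directions,
            "handedness": self.handedness,
            "anticlockwise": self.anticlockwise,
            "reversed_first_guanine": self.reversed_first_guanine,
            "regular": self.is_regular,
            "gc": {
                "patterns": self.gc_patterns,
                "predicted": self.gc_predicted,
                "mismatches": self.gc_mismatches,
                "records": [
                    {
                        "residue": list(r.residue_key),
                        "chi": None if r.chi is None else round(r.chi, 2),
                        "call": r.call.value,
                        "rule": r.rule.value,
                    }
                    for r in self.gc_records.values()
                ],
            },
            "grooves": prof,
            "min_distances": {
                str(g): [round(x, 3) for x in xs] for g, xs in self.min_distances.items()
            },
            "steps": [
                {
                    "strand": s.strand,
                    "tetrads": list(s.tetrads),
                    "succession": s.succession,
                    "psi": round(s.psi, 2),
                    "twist": round(s.twist, 2),
                    "tilt": round(s.tilt, 2),
                    "pseudo_average": round(s.pseudo_average, 2),
                    "block": s.block,
                }
                for s in self.steps
            ],
            "loops": {
                "combination": self.loops.combination,
                "full": self.loops.full_combination,
                "loops": [
                    {
                        "kind": l.kind, "sign": l.sign, "length": l.length,
                        "strands": list(l.strands), "snapback": l.snapback,
                    }
                    for l in self.loops.loops
                ],
            },
            "stacking_types": self.stacking.per_strand,
            "stacking_successions": self.stacking.successions,
            "platypus": {
                "is_platypus": self.platypus.is_platypus,
                "implied": {k: sorted(v) for k, v in self.platypus.implied.items()},
            },
            "planarity_flags": self.planarity_flags,
            "discontinuities": self.discontinuities,
            "notes": self.notes,
        }

    def tsv_row(self) -> dict:
        c5 = self.grooves.get("C5'")
        return {
            "label": self.label,
            "n_tetrads": self.n_tetrads,
            "n_blocks": len(self.blocks),
            "topology": self.topology.name,
            "code": self.topology.code,
            "directions": self.directions,
            "handedness": self.handedness,
            "regular": self.is_regular,
            "anticlockwise": self.anticlockwise,
            "signature": c5.signature if c5 else "",
            "signature_threshold": c5.signature_threshold if c5 else "",
            "widths": ";".join(f"{w:.2f}" for w in (c5.width if c5 else [])),
            "perimeter": round(c5.perimeter, 2) if c5 else float("nan"),
            "gc_patterns": ";".join(self.gc_patterns),
            "loops": self.loops.combination,
            "stacking_types": ";".join(
                str(self.stacking.per_strand.get(i, 0)) for i in range(1, 5)),
            "platypus": self.platypus.is_platypus,
            "mean_twist": round(float(np.mean([s.twist for s in self.steps])), 2)
            if self.steps else float("nan"),
            "mean_tilt": round(float(np.mean([s.tilt for s in self.steps])), 2)
            if self.steps else float("nan"),
            "mean_pseudo_average": round(
                float(np.mean([s.pseudo_average for s in self.steps])), 2)
            if self.steps else float("nan"),
        }


def analyze(model: StructureModel, config: AnalysisConfig | None = None) -> StructureReport:
    """Run the full structural characterization of one chain."""
    config = config or AnalysisConfig()
    stem = build_stem_from_model(model, config.hbond)
    gc_records = {
        g.key: classify_gc(g)
        for s in stem.strands for g in s.guanosines
    }
    topo = classify.topology(stem, gc_records)
    gc_report = classify.gc_pattern(stem, gc_records)
    grooves = {}
    for kind in ("C5'", "C3'", "P"):
        grooves[kind] = geom.groove_widths(stem, geom.groove_distances(stem, kind))
    min_d = geom.minimum_groove_distances(
        stem, config.min_distance_atom, config.min_distance_window)
    steps = geom.twist_tilt(stem, gc_records)
    hand = geom.handedness(steps).value if steps else "undetermined"
    loops = classify.annotate_loops(stem)
    stacking = classify.stacking_types(stem, gc_records)
    platypus = classify.platypus_check(topo, gc_report, grooves["C5'"], loops)
    directions = "".join(
        {"down": "d", "up": "u", "undetermined": "?"}[s.direction]
        for s in stem.strands)
    discs = [
        {"kind": d.kind, "strand": d.strand, "tetrads": d.tetrads, "span": d.span}
        for d in stem.all_discontinuities()
    ]
    report = StructureReport(
        label=model.label,
        n_tetrads=stem.n_tetrads,
        blocks=stem.blocks,
        topology=topo,
        directions=directions,
        gc_records=gc_records,
        gc_patterns=gc_report["patterns"],
        gc_predicted=gc_report["predicted"],
        gc_mismatches=gc_report["mismatches"],
        grooves=grooves,
        min_distances=min_d,
        steps=steps,
        handedness=hand,
        anticlockwise=stem.anticlockwise,
        reversed_first_guanine=(
            geom.reversed_first_guanine_check(steps, config.pseudo_average_band)
            if steps else False),
        loops=loops,
        stacking=stacking,
        platypus=platypus,
        planarity_flags=[t.planarity_flag for t in stem.tetrads],
        discontinuities=discs,
        stem=stem,
    )
    report.notes.extend(stem.notes)
    return report


def analyze_paths(
    paths: Iterable[str | Path],
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[StructureReport], list[tuple[str, str]]]:
    """Analyze many PDB files; per-file failures are logged and skipped.

    Returns (reports, failures) where failures is a list of
    (path, error message).  With ``out_dir`` set, JSON and TSV reports are
    written as they are produced.
    """
    reports: list[StructureReport] = []
    failures: list[tuple[str, str]] = []
    for path in paths:
        try:
            models = load_structures(path)
        except Exception as exc:
            logger.warning("skipping %s: %s", path, exc)
            failures.append((str(path), str(exc)))
            continue
        for model in models:
            try:
                report = analyze(model, config)
            except Exception as exc:
                logger.warning("skipping %s: %s", model.label, exc)
                failures.append((model.label, str(exc)))
                continue
            reports.append(report)
            if out_dir is not None:
                write_report(report, out_dir)
    return reports, failures


def write_report(report: StructureReport, out_dir: str | Path) -> Path:
    """Write <label>.json and append to reports.tsv under ``out_dir``."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    safe = report.label.replace("/", "_").replace(":", "_")
    json_path = out_dir / f"{safe}.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=1))
    tsv_path = out_dir / "reports.tsv"
    row = pd.DataFrame([report.tsv_row()])
    header = not tsv_path.exists()
    row.to_csv(tsv_path, sep="\t", index=False, mode="a", header=header)
    return json_path
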