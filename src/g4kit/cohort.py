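"""Cohort-level aggregation: groove classes, Psi distributions,
twist/tilt tables and correlations.

The cohort layer pools per-structure reports into the dataset-level
summaries: groove-width class statistics by adjacent strand direction
(up-down narrow, same-direction medium, down-up wide), Psi histograms per
gc succession type (1 degree bins), the per-succession twist/tilt table,
and Pearson correlations between the stacking angles and the minimum
groove distances.  Correlations and the twist/tilt table apply the
"regular G4" filter: one-block, right-handed, no 5'-5' inversion of
polarity.  Exclusions are per-analysis (a structure dropped from the
groove statistics may still contribute Psi angles) and always audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config
from .geom import StackStep
from .pipeline import StructureReport

__all__ = [
    "CohortConfig",
    "CorrelationResult",
    "groove_summary",
    "psi_summary",
    "angle_correlations",
    "table3_summary",
    "write_cohort_tables",
]

P_VALUE_FLOOR = 1e-15


@dataclass(frozen=True)
class CohortConfig:
    """Per-analysis exclusion lists (labels) and histogram bins."""

    exclude_grooves: tuple[str, ...] = ()     # e.g. poor-quality + platypus entries
    exclude_signature: tuple[str, ...] = ()   # e.g. non-planar-base entries
    exclude_psi: tuple[str, ...] = ()
    groove_bin: float = config.GROOVE_HIST_BIN
    psi_bin: float = config.PSI_HIST_BIN
    groove_atom: str = "C5'"


@dataclass
class CorrelationResult:
    pair: str
    r: float
    p_value: float
    n: int

    @property
    def p_text(self) -> str:
        return f"<{P_VALUE_FLOOR:g}" if self.p_value < P_VALUE_FLOOR else f"{self.p_value:.3g}"


def _audit(reports, excluded: Iterable[str], reason: str) -> list[dict]:
    present = {r.label for r in reports}
    return [
        {"label": label, "reason": reason, "present": label in present}
        for label in excluded
    ]


_DIR_CLASS = {
    ("up", "down"): "up-down",
    ("down", "up"): "down-up",
    ("down", "down"): "same",
    ("up", "up"): "same",
}


def groove_summary(reports: Sequence[StructureReport], cfg: CohortConfig | None = None) -> dict:
    """Groove-width statistics by strand-direction class.

    Returns class means/SDs, 0.1 A histograms, the per-topology signature
    table, perimeter statistics per atom kind, and the exclusion audit.
    """
    cfg = cfg or CohortConfig()
    kept = [r for r in reports if r.label not in set(cfg.exclude_grooves)]
    if not kept:
        raise ValueError("no structures left after exclusions")
    rows = []
    for rep in kept:
        prof = rep.grooves.get(cfg.groove_atom)
        if prof is None or rep.stem is None:
            continue
        for g in range(4):
            a = rep.stem.strands[g].direction
            b = rep.stem.strands[(g + 1) % 4].direction
            klass = _DIR_CLASS.get((a, b))
            w = prof.width[g]
            if klass and np.isfinite(w):
                rows.append({"label": rep.label, "groove": g + 1,
                             "class": klass, "width": w})
    table = pd.DataFrame(rows)
    by_class = (
        table.groupby("class")["width"].agg(["mean", "std", "count"])
        if len(table) else pd.DataFrame()
    )
    if len(table):
        n1 = by_class["count"] == 1
        by_class.loc[n1, "std"] = 0.0  # single observation: SD reported as 0, flagged
    histograms = {}
    if len(table):
        lo = np.floor(table["width"].min() / cfg.groove_bin) * cfg.groove_bin
        hi = np.ceil(table["width"].max() / cfg.groove_bin) * cfg.groove_bin
        edges = np.arange(lo, hi + cfg.groove_bin, cfg.groove_bin)
        for klass, sub in table.groupby("class"):
            counts, _ = np.histogram(sub["width"], bins=edges)
            histograms[klass] = pd.DataFrame({"left_edge": edges[:-1], "count": counts})

    sig_kept = [r for r in kept if r.label not in set(cfg.exclude_signature)]
    signature_table = pd.DataFrame([
        {
            "label": r.label,
            "topology": r.topology.name,
            "signature": r.grooves[cfg.groove_atom].signature,
            "signature_threshold": r.grooves[cfg.groove_atom].signature_threshold,
            "consistent": r.grooves[cfg.groove_atom].signature
            == r.grooves[cfg.groove_atom].signature_threshold,
        }
        for r in sig_kept if cfg.groove_atom in r.grooves
    ])

    perimeters = {}
    for kind in ("C5'", "C3'", "P"):
        vals = [r.grooves[kind].perimeter for r in kept
                if kind in r.grooves and np.isfinite(r.grooves[kind].perimeter)]
        if vals:
            perimeters[kind] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }

    audit = _audit(reports, cfg.exclude_grooves, "groove statistics") + _audit(
        reports, cfg.exclude_signature, "signature analysis")
    return {
        "by_class": by_class,
        "per_groove": table,
        "histograms": histograms,
        "signature_table": signature_table,
        "perimeter": perimeters,
        "excluded": audit,
        "n": len(kept),
    }


def _smoothed_mode(values: np.ndarray, bin_width: float, smooth: int = 5) -> float:
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    if smooth > 1 and len(counts) >= smooth:
        kernel = np.ones(smooth) / smooth
        counts = np.convolve(counts, kernel, mode="same")
    centers = edges[:-1] + bin_width / 2
    return float(centers[np.argmax(counts)])


def collect_steps(reports: Sequence[StructureReport], regular_only: bool = False,
                  exclude: Iterable[str] = ()) -> list[tuple[StructureReport, StackStep]]:
    out = []
    for rep in reports:
        if rep.label in set(exclude):
            continue
        if regular_only and not rep.is_regular:
            continue
        out.extend((rep, s) for s in rep.steps)
    return out


def psi_summary(reports: Sequence[StructureReport], cfg: CohortConfig | None = None) -> dict:
    """Counts, fractions, histograms and smoothed-mode peak per gc
    succession type (reading along the chain direction)."""
    cfg = cfg or CohortConfig()
    pairs = collect_steps(reports, exclude=cfg.exclude_psi)
    steps = [s for _, s in pairs if "?" not in s.succession]
    if not steps:
        raise ValueError("no stack steps")
    order = ["aa", "sa", "as", "ss"]
    label = {"aa": "anti-anti", "sa": "syn-anti", "as": "anti-syn", "ss": "syn-syn"}
    total = len(steps)
    out_rows, histograms, peaks = [], {}, {}
    for succ in order:
        vals = np.array([s.psi for s in steps if s.succession == succ])
        out_rows.append({
            "succession": label[succ],
            "count": len(vals),
            "fraction": len(vals) / total,
        })
        if len(vals):
            lo = np.floor(vals.min()) - 1
            hi = np.ceil(vals.max()) + 1
            edges = np.arange(lo, hi + cfg.psi_bin, cfg.psi_bin)
            counts, _ = np.histogram(vals, bins=edges)
            histograms[label[succ]] = pd.DataFrame(
                {"left_edge": edges[:-1], "count": counts})
            peaks[label[succ]] = _smoothed_mode(vals, cfg.psi_bin)
    return {
        "fractions": pd.DataFrame(out_rows),
        "histograms": histograms,
        "peaks": peaks,
        "n_steps": total,
        "excluded": _audit(reports, cfg.exclude_psi, "psi analysis"),
    }


def _step_min_distance(rep: StructureReport, step: StackStep) -> float:
    """Minimum groove distance paired with a stack step: the groove the
    strand delimits on its clockwise side, at the step's deeper tetrad."""
    deeper = max(step.tetrads)
    per_tetrad = rep.min_distances.get(step.strand, [])
    index = deeper - 2  # list starts at tetrad 2
    if 0 <= index < len(per_tetrad):
        return per_tetrad[index]
    return float("nan")


def angle_correlations(
    reports: Sequence[StructureReport],
    cfg: CohortConfig | None = None,
) -> list[CorrelationResult]:
    """Pearson correlations among twist, tilt, Psi and the minimum groove
    distances over all steps of the regular G4s."""
    cfg = cfg or CohortConfig()
    pairs = collect_steps(reports, regular_only=True)
    steps = [(rep, s) for rep, s in pairs if "?" not in s.succession]
    data = pd.DataFrame({
        "twist": [s.twist for _, s in steps],
        "tilt": [s.tilt for _, s in steps],
        "psi": [s.psi for _, s in steps],
        "min_d": [_step_min_distance(rep, s) for rep, s in steps],
    })
    wanted = [
        ("twist", "psi"), ("tilt", "psi"), ("twist", "tilt"),
        ("min_d", "tilt"), ("min_d", "twist"), ("min_d", "psi"),
    ]
    results = []
    for x, y in wanted:
        sub = data[[x, y]].dropna()
        if len(sub) < 3:
            continue  # skipped with note: too few paired observations
        r, p = stats.pearsonr(sub[x], sub[y])
        results.append(CorrelationResult(pair=f"{x}~{y}", r=float(r),
                                         p_value=float(p), n=len(sub)))
    return results


def table3_summary(reports: Sequence[StructureReport]) -> pd.DataFrame:
    """Mean +/- SD twist and tilt per gc succession type (regular G4s)."""
    pairs = collect_steps(reports, regular_only=True)
    steps = [s for _, s in pairs if "?" not in s.succession]
    label = {"aa": "anti-anti", "sa": "syn-anti", "as": "anti-syn", "ss": "syn-syn"}
    rows = []
    for succ in ("sa", "ss", "aa", "as"):
        vals_tw = [s.twist for s in steps if s.succession == succ]
        vals_ti = [s.tilt for s in steps if s.succession == succ]
        rows.append({
            "succession": label[succ],
            "n": len(vals_tw),
            "twist_mean": float(np.mean(vals_tw)) if vals_tw else float("nan"),
            "twist_sd": float(np.std(vals_tw, ddof=1)) if len(vals_tw) > 1 else 0.0,
            "tilt_mean": float(np.mean(vals_ti)) if vals_ti else float("nan"),
            "tilt_sd": float(np.std(vals_ti, ddof=1)) if len(vals_ti) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def write_cohort_tables(
    reports: Sequence[StructureReport],
    out_dir,
    cfg: CohortConfig | None = None,
) -> dict:
    """Write the cohort report directory (TSV tables + histogram CSVs)."""
    from pathlib import Path

    cfg = cfg or CohortConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    grooves = groove_summary(reports, cfg)
    grooves["by_class"].to_csv(out / "groove_classes.tsv", sep="\t")
    grooves["signature_table"].to_csv(out / "signatures.tsv", sep="\t", index=False)
    for klass, hist in grooves["histograms"].items():
        hist.to_csv(out / f"groove_hist_{klass}.csv", index=False)

    psi = psi_summary(reports, cfg)
    psi["fractions"].to_csv(out / "psi_fractions.tsv", sep="\t", index=False)
    for succ, hist in psi["histograms"].items():
        hist.to_csv(out / f"psi_hist_{succ}.csv", index=False)

    t3 = table3_summary(reports)
    t3.to_csv(out / "twist_tilt_by_succession.tsv", sep="\t", index=False)

    corr = angle_correlations(reports, cfg)
    pd.DataFrame([
        {"pair": c.pair, "r": round(c.r, 4), "p": c.p_text, "n": c.n} for c in corr
    ]).to_csv(out / "correlations.tsv", sep="\t", index=False)

    counts = pd.DataFrame([r.tsv_row() for r in reports])
    counts.groupby("topology").size().rename("count").to_csv(
        out / "topology_counts.tsv", sep="\t")
    counts.groupby("loops").size().rename("count").to_csv(
        out / "loop_combinations.tsv", sep="\t")
    audit = pd.DataFrame(grooves["excluded"] + psi["excluded"])
    if len(audit):
        audit.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    return {"grooves": grooves, "psi": psi, "table3": t3, "correlations": corr}
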