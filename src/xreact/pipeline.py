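"""End-to-end assay analysis: profile -> label -> join -> ROC -> report.

One call reproduces a full per-assay analysis from a library file and a
panel file: similarity of every library compound to the assay calibrator,
binary cross-reactivity labels, confusion tables at requested cutoffs,
ROC/AUC with the maximum-efficiency cutoff (when both classes have enough
compounds), and predicted labels for every untested compound. Each assay
is a configuration entry, not a code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diagnostics, panels as panels_mod
from .chem import CompoundLibrary, load_library
from .diagnostics import ClassSizeError, CutoffResult, RocCurve
from .fingerprints import PUBLIC_166, load_key_set
from .panels import AssayPanel, join, label_panel, load_panel
from .similarity import SimilarityProfile, profile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Per-assay analysis settings."""

    cutoffs: tuple[float, ...] = ()  # extra cutoffs to tabulate
    min_class_size: int = 5
    key_set: str = PUBLIC_166
    prediction_cutoff: float | None = None  # default: max-efficiency cutoff


@dataclass
class AnalysisReport:
    """Everything a per-assay run produces; recomputable from its inputs."""

    assay_name: str
    target_id: str
    key_set_id: str
    library_hash: str
    n_compounds: int
    category_summary: dict
    scored: pd.DataFrame
    predictions_input: pd.DataFrame
    confusion_rows: list[dict]
    roc: RocCurve | None
    best: CutoffResult | None
    roc_notice: str | None
    predictions: pd.DataFrame | None
    profile: SimilarityProfile

    def to_dict(self) -> dict:
        out = {
            "assay_name": self.assay_name,
            "target_id": self.target_id,
            "key_set_id": self.key_set_id,
            "library_hash": self.library_hash,
            "n_compounds": self.n_compounds,
            "n_tested": int(len(self.scored)),
            "n_untested": int(len(self.predictions_input)),
            "category_summary": self.category_summary,
            "confusion": self.confusion_rows,
        }
        if self.roc is not None:
            out["roc"] = {
                "auc": self.roc.auc,
                "max_efficiency": {
                    "cutoff": self.best.cutoff,
                    "efficiency": self.best.metrics.efficiency,
                    "sensitivity": self.best.metrics.sensitivity,
                    "specificity": self.best.metrics.specificity,
                },
            }
        else:
            out["roc"] = {"notice": self.roc_notice}
        return out

    def write(self, out_dir: str | Path) -> None:
        """Write the report bundle: report.json, table1.csv, roc_points.csv,
        predictions.csv, profile.csv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        pd.DataFrame(self.confusion_rows).to_csv(out_dir / "table1.csv", index=False)
        if self.roc is not None:
            pd.DataFrame(
                {"threshold": self.roc.thresholds, "fpr": self.roc.fpr, "tpr": self.roc.tpr}
            ).to_csv(out_dir / "roc_points.csv", index=False)
        if self.predictions is not None:
            self.predictions.to_csv(out_dir / "predictions.csv", index=False)
        self.profile.to_csv(out_dir / "profile.csv")


def _library_hash(library: CompoundLibrary) -> str:
    h = hashlib.sha256()
    for c in library:
        h.update(f"{c.id}\t{c.smiles}\n".encode())
    return h.hexdigest()[:16]


def analyze(
    library: CompoundLibrary,
    panel: AssayPanel,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """Run the full analysis on in-memory objects."""
    key_set = load_key_set(config.key_set)
    prof = profile(panel.calibrator_id, library, key_set)
    labels = label_panel(panel, known_ids=set(library.ids))
    scored, untested = join(prof, labels)

    confusion_rows = []
    for cutoff in config.cutoffs:
        counts = diagnostics.confusion_at_cutoff(scored, cutoff)
        m = diagnostics.metrics(counts)
        confusion_rows.append(
            {
                "assay": panel.assay_name,
                "cutoff": cutoff,
                "tp": counts.tp,
                "fp": counts.fp,
                "tn": counts.tn,
                "fn": counts.fn,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "efficiency": m.efficiency,
            }
        )

    roc = best = None
    notice = None
    try:
        roc = diagnostics.roc_curve(scored, min_class_size=config.min_class_size)
        best = diagnostics.max_efficiency_cutoff(scored, min_class_size=config.min_class_size)
    except ClassSizeError as exc:
        notice = (
            f"insufficient class size for ROC analysis: {exc.n_positive} cross-reactive "
            f"and {exc.n_negative} non-cross-reactive compounds "
            f"(need >= {exc.min_class_size} in each class)"
        )
        logger.info("%s: %s", panel.assay_name, notice)

    predictions = None
    pred_cutoff = config.prediction_cutoff
    if pred_cutoff is None and best is not None:
        pred_cutoff = min(max(best.cutoff, 0.0), 1.0)
    if pred_cutoff is not None and len(untested):
        predictions = diagnostics.predict(
            untested, pred_cutoff, assay_name=panel.assay_name, key_set_id=key_set.key_set_id
        )

    logger.info(
        "assay=%s key_set=%s library_hash=%s roc=%s",
        panel.assay_name, key_set.key_set_id, _library_hash(library),
        "ok" if roc else "refused",
    )
    return AnalysisReport(
        assay_name=panel.assay_name,
        target_id=panel.calibrator_id,
        key_set_id=key_set.key_set_id,
        library_hash=_library_hash(library),
        n_compounds=len(library),
        category_summary=prof.category_summary(),
        scored=scored,
        predictions_input=untested,
        confusion_rows=confusion_rows,
        roc=roc,
        best=best,
        roc_notice=notice,
        predictions=predictions,
        profile=prof,
    )


def run_assay_analysis(
    library_path: str | Path,
    panel_path: str | Path,
    config: AnalysisConfig = AnalysisConfig(),
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """File-based entry point: load the library and panel, analyze, and
    (optionally) write the report bundle."""
    library = load_library(library_path)
    panel = load_panel(panel_path)
    report = analyze(library, panel, config)
    if out_dir is not None:
        report.write(out_dir)
    return report
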