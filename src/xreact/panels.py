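"""Immunoassay cross-reactivity panels.

A panel records, for one named immunoassay, the percent cross-reactivity
of each tested compound relative to the assay calibrator (calibrator = 100).
Compounds never assayed are carried as *untested*; tested compounds are
labelled cross-reactive when their percent strictly exceeds the assay's
positivity threshold (the convention is "> 0.8%" for the amphetamine-type
ELISAs, "> 1%" for the cannabinoid assays), and are optionally assigned
ordinal bands ("≥25%", "1–24%", "<1%") whose lower edges are inclusive.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .similarity import SimilarityProfile

logger = logging.getLogger(__name__)

CROSS_REACTIVE = "cross-reactive"
NON_CROSS_REACTIVE = "non-cross-reactive"
UNTESTED = "untested"


class PanelError(ValueError):
    """A panel violates its contract (missing calibrator, unknown compound...)."""


@dataclass(frozen=True)
class CrossReactivityRecord:
    """Percent cross-reactivity of one compound, or an untested placeholder.

    ``percent`` is present iff ``tested``; qualitative "below detection"
    entries are encoded as tested with percent 0.
    """

    compound_id: str
    percent: float | None = None
    tested: bool = False

    def __post_init__(self) -> None:
        if self.tested and (self.percent is None or self.percent < 0):
            raise PanelError(
                f"{self.compound_id}: tested record needs percent >= 0, got {self.percent}"
            )
        if not self.tested and self.percent is not None:
            raise PanelError(f"{self.compound_id}: untested record cannot carry a percent")


@dataclass
class AssayPanel:
    """One immunoassay's cross-reactivity panel."""

    assay_name: str
    calibrator_id: str
    records: list[CrossReactivityRecord] = field(default_factory=list)
    positive_threshold_percent: float = 0.8
    band_edges: tuple[float, ...] = (1.0, 25.0)

    def __post_init__(self) -> None:
        if self.positive_threshold_percent <= 0:
            raise PanelError("positivity threshold must be > 0")
        if list(self.band_edges) != sorted(self.band_edges):
            raise PanelError("band edges must be ascending")
        cal = [r for r in self.records if r.compound_id == self.calibrator_id]
        if not cal:
            raise PanelError(f"calibrator {self.calibrator_id!r} missing from panel records")
        if not cal[0].tested or cal[0].percent != 100.0:
            raise PanelError(
                f"calibrator {self.calibrator_id!r} must be tested at percent 100"
            )

    def record(self, compound_id: str) -> CrossReactivityRecord:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)

    @property
    def tested_ids(self) -> list[str]:
        return [r.compound_id for r in self.records if r.tested]

    @property
    def untested_ids(self) -> list[str]:
        return [r.compound_id for r in self.records if not r.tested]


@dataclass(frozen=True)
class LabeledCompound:
    compound_id: str
    label: str  # cross-reactive | non-cross-reactive | untested
    band: str | None = None


def _band_name(edges: tuple[float, ...], i: int) -> str:
    """Human-readable band names: "<1%", "1-24%", ">=25%" for edges (1, 25)."""
    if i < 0:
        return f"<{edges[0]:g}%"
    if i == len(edges) - 1:
        return f">={edges[i]:g}%"
    upper = edges[i + 1]
    return f"{edges[i]:g}-{upper - 1:g}%" if upper == int(upper) else f"{edges[i]:g}-<{upper:g}%"


def assign_band(percent: float, edges: tuple[float, ...]) -> str:
    """Highest band whose (inclusive) lower edge the percent meets."""
    idx = -1
    for i, edge in enumerate(edges):
        if percent >= edge:
            idx = i
    return _band_name(edges, idx)


def label_panel(panel: AssayPanel, known_ids: set[str] | None = None) -> list[LabeledCompound]:
    """Binary labels (plus bands for tested compounds) for every panel record.

    A tested compound is cross-reactive iff its percent strictly exceeds
    the panel's positivity threshold; the calibrator (tested at 100) is
    always cross-reactive. Untested records pass through unlabelled.
    """
    if known_ids is not None:
        unknown = [r.compound_id for r in panel.records if r.compound_id not in known_ids]
        if unknown:
            raise PanelError(f"panel {panel.assay_name}: unknown compounds {unknown[:5]}")
    out = []
    for r in panel.records:
        if not r.tested:
            out.append(LabeledCompound(r.compound_id, UNTESTED))
            continue
        label = (
            CROSS_REACTIVE
            if r.percent > panel.positive_threshold_percent
            else NON_CROSS_REACTIVE
        )
        out.append(
            LabeledCompound(r.compound_id, label, band=assign_band(r.percent, panel.band_edges))
        )
    return out


def band_panel(panel: AssayPanel) -> dict[str, str]:
    """Ordinal band per tested compound."""
    return {
        r.compound_id: assign_band(r.percent, panel.band_edges)
        for r in panel.records
        if r.tested
    }


def join(profile: SimilarityProfile, labels: list[LabeledCompound]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join similarity scores with cross-reactivity labels.

    Returns ``(scored, predictions)``: one row per *tested* compound with
    its tanimoto score and binary label, and a separate table of untested
    compounds (score only) for downstream prediction. The calibrator /
    profile target is excluded — it has no score in its own profile.
    """
    scored_rows, pred_rows = [], []
    for lab in labels:
        if lab.compound_id == profile.target_id:
            continue
        try:
            score = profile.value(lab.compound_id)
        except KeyError:
            raise PanelError(
                f"compound {lab.compound_id!r} has a panel record but no similarity entry"
            ) from None
        if lab.label == UNTESTED:
            pred_rows.append({"compound_id": lab.compound_id, "score": score})
        else:
            scored_rows.append(
                {
                    "compound_id": lab.compound_id,
                    "score": score,
                    "label": lab.label,
                    "band": lab.band,
                }
            )
    scored = pd.DataFrame(scored_rows, columns=["compound_id", "score", "label", "band"])
    preds = pd.DataFrame(pred_rows, columns=["compound_id", "score"])
    if scored.empty:
        warnings.warn("no tested compounds after the join; scored table is empty")
    return scored, preds


def load_panel(path: str | Path) -> AssayPanel:
    """Read a panel CSV.

    Format: a header block of ``# key: value`` comment lines carrying
    ``assay_name``, ``calibrator_id``, ``positive_threshold_percent`` and
    ``band_edges`` (comma-separated), followed by a CSV table with columns
    ``compound_id,percent,tested`` (percent empty for untested rows).
    """
    meta: dict[str, str] = {}
    rows = []
    with open(path, newline="") as fh:
        lines = []
        for line in fh:
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
            else:
                lines.append(line)
        reader = csv.DictReader(lines)
        if reader.fieldnames is None or not {"compound_id", "tested"} <= set(reader.fieldnames):
            raise PanelError(f"{path}: need columns compound_id,percent,tested")
        for rec in reader:
            tested = rec["tested"].strip().lower() in {"1", "true", "yes"}
            percent = float(rec["percent"]) if tested and rec.get("percent", "").strip() else (0.0 if tested else None)
            rows.append(CrossReactivityRecord(rec["compound_id"].strip(), percent, tested))
    if "assay_name" not in meta or "calibrator_id" not in meta:
        raise PanelError(f"{path}: header must declare assay_name and calibrator_id")
    kwargs = {}
    if "positive_threshold_percent" in meta:
        kwargs["positive_threshold_percent"] = float(meta["positive_threshold_percent"])
    if "band_edges" in meta:
        kwargs["band_edges"] = tuple(float(x) for x in meta["band_edges"].split(","))
    return AssayPanel(meta["assay_name"], meta["calibrator_id"], rows, **kwargs)


def write_panel(panel: AssayPanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# assay_name: {panel.assay_name}\n")
        fh.write(f"# calibrator_id: {panel.calibrator_id}\n")
        fh.write(f"# positive_threshold_percent: {panel.positive_threshold_percent:g}\n")
        fh.write(f"# band_edges: {','.join(f'{e:g}' for e in panel.band_edges)}\n")
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "percent", "tested"])
        for r in panel.records:
            writer.writerow(
                [r.compound_id, f"{r.percent:.6g}" if r.tested else "", int(r.tested)]
            )
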