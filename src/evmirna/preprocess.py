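"""Detection-based filtering cascade and spike-in ΔCT normalization.

The filtering cascade mirrors the standard qPCR-array QC: of all target
assays on the card, keep those detected (CT < ceiling) in at least
``min_detected`` samples of *either* the pre or the post group.  Partially
detected miRNAs are retained on purpose — a species switched fully on or
off by the intervention is informative — and their imputed-at-ceiling
cells flow into the downstream statistics.

Normalization divides out per-sample technical yield via the exogenous
spike-in: expression = −ΔCT = −(CT_miRNA − CT_spike), a log2-scale
relative abundance under the efficiency-2 assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .qpcr import CtMatrix, QpcrFormatError

__all__ = ["FilterReport", "ExpressionMatrix", "filter_by_detection", "normalize_spike_in"]


@dataclass
class FilterReport:
    """Counts for the three-stage filtering cascade (spike-in excluded).

    ``n_assays_total`` → candidate miRNA assays on the array;
    ``n_detected_any`` → detected in ≥1 sample of either group;
    ``n_retained`` → detected in ≥ ``min_detected`` samples of either group.
    """

    n_assays_total: int
    n_detected_any: int
    n_retained: int
    min_detected: int
    dropped_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_retained <= self.n_detected_any <= self.n_assays_total
        assert len(self.dropped_ids) == self.n_assays_total - self.n_retained

    def to_dict(self) -> dict:
        return {
            "n_assays_total": self.n_assays_total,
            "n_detected_any": self.n_detected_any,
            "n_retained": self.n_retained,
            "min_detected": self.min_detected,
            "dropped_ids": [list(t) for t in self.dropped_ids],
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")
        return path


@dataclass
class ExpressionMatrix:
    """Retained miRNA × sample log2-scale expression (−ΔCT).

    ``expr`` index = miRNA assay ids (spike-in excluded), columns = sample
    ids; ``samples`` is the paired metadata frame from :class:`CtMatrix`.
    """

    expr: pd.DataFrame
    samples: pd.DataFrame

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)

    def samples_at(self, timepoint: str) -> list[str]:
        sub = self.samples[self.samples["timepoint"] == timepoint]
        return list(sub.sort_values("patient_id").index)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.expr.rename_axis("mirna").to_csv(path, sep="\t")
        return path


def filter_by_detection(
    ctm: CtMatrix, min_detected: int = 2
) -> tuple[CtMatrix, FilterReport]:
    """Apply the ≥``min_detected``-per-group detection rule.

    An assay is retained iff it is detected in at least ``min_detected``
    pre samples OR at least ``min_detected`` post samples.  The spike-in is
    never a candidate (it is exogenous) but is carried along in the
    returned matrix for normalization.
    """
    pre = ctm.samples_at("pre")
    post = ctm.samples_at("post")
    if min_detected > min(len(pre), len(post)):
        raise QpcrFormatError(
            f"min_detected={min_detected} exceeds group size "
            f"({len(pre)} pre / {len(post)} post)"
        )

    candidates = [a for a in ctm.assay_ids if a != ctm.spike_in]
    det = ctm.detected.loc[candidates]
    n_pre = det[pre].sum(axis=1)
    n_post = det[post].sum(axis=1)
    any_mask = (n_pre + n_post) >= 1
    keep_mask = (n_pre >= min_detected) | (n_post >= min_detected)

    dropped: list[tuple[str, str]] = []
    for a in candidates:
        if keep_mask[a]:
            continue
        reason = "below_min_detected" if any_mask[a] else "never_detected"
        dropped.append((a, reason))

    report = FilterReport(
        n_assays_total=len(candidates),
        n_detected_any=int(any_mask.sum()),
        n_retained=int(keep_mask.sum()),
        min_detected=min_detected,
        dropped_ids=dropped,
    )
    kept = [a for a in candidates if keep_mask[a]] + [ctm.spike_in]
    filtered = CtMatrix(
        ct=ctm.ct.loc[kept].copy(),
        detected=ctm.detected.loc[kept].copy(),
        samples=ctm.samples.copy(),
        spike_in=ctm.spike_in,
        ceiling=ctm.ceiling,
    )
    return filtered, report


def normalize_spike_in(ctm: CtMatrix) -> ExpressionMatrix:
    """Compute expression = −(CT_miRNA − CT_spike) per cell.

    Per-sample additive CT offsets (pipetting/yield artefacts hitting every
    assay of a sample equally) cancel exactly in the subtraction.  Fatal if
    the spike-in is not detected in some sample, which :class:`CtMatrix`
    already enforces.
    """
    spike = ctm.ct.loc[ctm.spike_in]
    mirnas = [a for a in ctm.assay_ids if a != ctm.spike_in]
    expr = -(ctm.ct.loc[mirnas] - spike)
    expr.index.name = "mirna"
    return ExpressionMatrix(expr=expr, samples=ctm.samples.copy())
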