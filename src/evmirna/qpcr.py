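"""qPCR array CT input/output and the limit-of-detection data model.

A miRNA array run yields one CT (cycle-threshold) value per assay per
sample; assays that never cross the fluorescence threshold are exported as
the literal token ``undetermined``.  Following the conservative
limit-of-detection convention, such cells — and any numeric CT at or above
the detection ceiling (default 40 cycles) — are imputed *at* the ceiling
and flagged not-detected.  The exogenous spike-in assay (cel-mir-39, added
before RNA extraction) must be detected in every sample because it is the
sole normalizer downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "QpcrFormatError",
    "read_ct_table",
    "write_ct_table",
]

#: Case-insensitive token the instrument emits for a non-detected assay.
UNDETERMINED_TOKEN = "undetermined"

#: Default limit-of-detection ceiling, in PCR cycles.
DEFAULT_CEILING = 40.0

VALID_TIMEPOINTS = ("pre", "post")


class QpcrFormatError(ValueError):
    """Raised when a CT export or its sample metadata violates the contract."""


@dataclass
class CtMatrix:
    """Assay × sample CT values with detection flags and paired metadata.

    Attributes
    ----------
    ct : pandas.DataFrame
        Float CT values (cycles), index = assay ids, columns = sample ids.
        Not-detected cells hold exactly ``ceiling``.
    detected : pandas.DataFrame
        Boolean, same shape/labels as ``ct``; True iff the source record
        carried a numeric CT strictly below ``ceiling``.
    samples : pandas.DataFrame
        Index = sample ids; columns ``patient_id`` and ``timepoint``
        (``pre``/``post``).  Each patient contributes exactly one sample
        per timepoint.
    spike_in : str
        Assay id of the exogenous normalizer; must be detected everywhere.
    ceiling : float
        Limit-of-detection CT, in cycles.
    """

    ct: pd.DataFrame
    detected: pd.DataFrame
    samples: pd.DataFrame
    spike_in: str
    ceiling: float = DEFAULT_CEILING

    def __post_init__(self) -> None:
        # canonical axis names so round-trips compare clean (rename_axis
        # copies the Index, which may be shared with samples.index)
        self.ct = self.ct.rename_axis(index="assay", columns=None)
        self.detected = self.detected.rename_axis(index="assay", columns=None)
        self.samples = self.samples.rename_axis(index="sample_id")
        self.validate()

    # -- structural checks ------------------------------------------------

    def validate(self) -> None:
        if self.ct.shape != self.detected.shape:
            raise QpcrFormatError(
                f"ct {self.ct.shape} and detected {self.detected.shape} "
                "matrices differ in shape"
            )
        if not self.ct.index.equals(self.detected.index) or not self.ct.columns.equals(
            self.detected.columns
        ):
            raise QpcrFormatError("ct and detected matrices have mismatched labels")
        if self.ct.index.has_duplicates:
            dups = self.ct.index[self.ct.index.duplicated()].unique().tolist()
            raise QpcrFormatError(f"duplicate assay ids: {dups}")
        if list(self.ct.columns) != list(self.samples.index):
            raise QpcrFormatError("sample columns do not match sample metadata index")
        if self.spike_in not in self.ct.index:
            raise QpcrFormatError(f"spike-in assay {self.spike_in!r} missing from table")

        bad_tp = set(self.samples["timepoint"]) - set(VALID_TIMEPOINTS)
        if bad_tp:
            raise QpcrFormatError(f"invalid timepoint labels: {sorted(bad_tp)}")
        counts = self.samples.groupby("patient_id")["timepoint"].value_counts().unstack(
            fill_value=0
        )
        for tp in VALID_TIMEPOINTS:
            if tp not in counts.columns:
                counts[tp] = 0
        broken = counts[(counts["pre"] != 1) | (counts["post"] != 1)]
        if len(broken):
            raise QpcrFormatError(
                "paired design violated; each patient needs exactly one pre and "
                f"one post sample, offenders: {broken.index.tolist()}"
            )

        det = self.detected.to_numpy()
        vals = self.ct.to_numpy(dtype=float)
        if np.any(det & (vals >= self.ceiling)):
            raise QpcrFormatError("detected cell holds a CT at/above the ceiling")
        if np.any(~det & (vals != self.ceiling)):
            raise QpcrFormatError("not-detected cell does not hold the ceiling value")
        spike_det = self.detected.loc[self.spike_in]
        if not bool(spike_det.all()):
            missing = spike_det.index[~spike_det].tolist()
            raise QpcrFormatError(
                f"spike-in {self.spike_in!r} not detected in samples {missing}; "
                "normalization is undefined"
            )

    # -- convenience ------------------------------------------------------

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_patients(self) -> int:
        return self.samples["patient_id"].nunique()

    def samples_at(self, timepoint: str) -> list[str]:
        """Sample ids at one timepoint, ordered by patient id."""
        sub = self.samples[self.samples["timepoint"] == timepoint]
        return list(sub.sort_values("patient_id").index)

    def to_long(self) -> pd.DataFrame:
        """Canonical long form: assay, sample, patient, timepoint, ct, detected."""
        long = (
            self.ct.stack()
            .rename("ct")
            .reset_index()
            .set_axis(["assay", "sample", "ct"], axis=1)
        )
        long["detected"] = self.detected.stack().to_numpy()
        long["patient"] = self.samples.loc[long["sample"], "patient_id"].to_numpy()
        long["timepoint"] = self.samples.loc[long["sample"], "timepoint"].to_numpy()
        return long[["assay", "sample", "patient", "timepoint", "ct", "detected"]]


# -- cell parsing ---------------------------------------------------------


def _parse_cell(raw: object, ceiling: float, context: str) -> tuple[float, bool]:
    """Parse one CT cell into (value, detected) under the ceiling policy."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ceiling, False
    text = str(raw).strip()
    if text == "" or text.lower() == UNDETERMINED_TOKEN:
        return ceiling, False
    try:
        value = float(text)
    except ValueError:
        raise QpcrFormatError(
            f"non-numeric CT value {text!r} at {context}"
        ) from None
    if np.isnan(value):
        return ceiling, False
    if value >= ceiling:
        return ceiling, False
    return value, True


def _resolve_sample_meta(
    sample_ids: list[str],
    sample_table: pd.DataFrame | str | Path | None,
    inline: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the sample metadata frame from a sidecar table, inline columns,
    or the ``<patient>_<timepoint>`` naming convention."""
    if sample_table is not None:
        if not isinstance(sample_table, pd.DataFrame):
            sample_table = pd.read_csv(sample_table, sep="\t", dtype=str)
        cols = {c.lower(): c for c in sample_table.columns}
        needed = {"sample", "patient", "timepoint"}
        if not needed <= set(cols):
            raise QpcrFormatError(
                f"sample table needs columns {sorted(needed)}, got "
                f"{list(sample_table.columns)}"
            )
        meta = pd.DataFrame(
            {
                "patient_id": sample_table[cols["patient"]].astype(str).to_numpy(),
                "timepoint": sample_table[cols["timepoint"]].astype(str).to_numpy(),
            },
            index=pd.Index(sample_table[cols["sample"]].astype(str), name="sample_id"),
        )
    elif inline is not None:
        meta = inline
    else:
        rows = {}
        for sid in sample_ids:
            head, sep, tail = sid.rpartition("_")
            if not sep or tail not in VALID_TIMEPOINTS:
                raise QpcrFormatError(
                    f"cannot infer patient/timepoint from sample id {sid!r}; "
                    "supply a sample table or use '<patient>_<pre|post>' ids"
                )
            rows[sid] = {"patient_id": head, "timepoint": tail}
        meta = pd.DataFrame.from_dict(rows, orient="index")
        meta.index.name = "sample_id"
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise QpcrFormatError(f"sample metadata missing for samples {missing}")
    return meta.loc[sample_ids]


def read_ct_table(
    path: str | Path | io.TextIOBase,
    format: str = "wide",
    *,
    spike_in: str,
    ceiling: float = DEFAULT_CEILING,
    sample_table: pd.DataFrame | str | Path | None = None,
) -> CtMatrix:
    """Read a CT export into a :class:`CtMatrix`, applying LOD imputation.

    Parameters
    ----------
    path
        CSV/TSV file (delimiter sniffed from the header line).  ``wide``
        dialect: first column assay id, one column per sample.  ``long``
        dialect: columns ``assay``, ``sample``, ``ct`` and optionally
        inline ``patient``/``timepoint`` columns.
    format
        ``"wide"`` or ``"long"``.
    spike_in
        Assay id of the exogenous normalizer; must be present and detected
        in every sample.
    ceiling
        Limit-of-detection CT.  Cells that are empty, ``undetermined``
        (case-insensitive) or numerically ≥ ceiling are imputed to the
        ceiling and flagged not-detected.
    sample_table
        Optional sidecar with columns ``sample``, ``patient``,
        ``timepoint``; otherwise metadata is taken from inline columns
        (long) or parsed from ``<patient>_<pre|post>`` sample ids.
    """
    if format not in ("wide", "long"):
        raise QpcrFormatError(f"unknown format {format!r}; use 'wide' or 'long'")

    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    if not text.strip():
        raise QpcrFormatError("empty CT table")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    raw = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)

    if format == "wide":
        assay_col = raw.columns[0]
        if raw[assay_col].duplicated().any():
            dups = raw[assay_col][raw[assay_col].duplicated()].tolist()
            raise QpcrFormatError(f"duplicate assay rows in wide table: {dups}")
        raw = raw.set_index(assay_col)
        sample_ids = list(raw.columns.astype(str))
        assay_ids = list(raw.index.astype(str))
        ct = np.empty(raw.shape, dtype=float)
        det = np.empty(raw.shape, dtype=bool)
        for i, a in enumerate(assay_ids):
            for j, s in enumerate(sample_ids):
                ct[i, j], det[i, j] = _parse_cell(
                    raw.iat[i, j], ceiling, f"assay {a!r}, sample {s!r}"
                )
        meta = _resolve_sample_meta(sample_ids, sample_table)
    else:
        cols = {c.lower(): c for c in raw.columns}
        if not {"assay", "sample", "ct"} <= set(cols):
            raise QpcrFormatError(
                f"long table needs columns assay, sample, ct; got {list(raw.columns)}"
            )
        recs = raw.rename(columns={cols[k]: k for k in cols})
        dup = recs.duplicated(subset=["assay", "sample"])
        if dup.any():
            first = recs.loc[dup, ["assay", "sample"]].iloc[0].tolist()
            raise QpcrFormatError(f"duplicate (assay, sample) record: {first}")
        assay_ids = list(pd.unique(recs["assay"]))
        sample_ids = list(pd.unique(recs["sample"]))
        ct_frame = pd.DataFrame(np.nan, index=assay_ids, columns=sample_ids)
        det_frame = pd.DataFrame(False, index=assay_ids, columns=sample_ids)
        for row in recs.itertuples(index=False):
            v, d = _parse_cell(
                row.ct, ceiling, f"assay {row.assay!r}, sample {row.sample!r}"
            )
            ct_frame.at[row.assay, row.sample] = v
            det_frame.at[row.assay, row.sample] = d
        if ct_frame.isna().any().any():
            # missing combination is treated like an empty cell
            det_frame = det_frame.where(~ct_frame.isna(), False)
            ct_frame = ct_frame.fillna(ceiling)
        ct, det = ct_frame.to_numpy(), det_frame.to_numpy()
        inline = None
        if {"patient", "timepoint"} <= set(cols):
            per_sample = recs.drop_duplicates("sample").set_index("sample")
            inline = pd.DataFrame(
                {
                    "patient_id": per_sample["patient"].astype(str),
                    "timepoint": per_sample["timepoint"].astype(str),
                }
            )
            inline.index.name = "sample_id"
        meta = _resolve_sample_meta(sample_ids, sample_table, inline)

    ct_df = pd.DataFrame(ct, index=pd.Index(assay_ids, name="assay"), columns=sample_ids)
    det_df = pd.DataFrame(det, index=ct_df.index, columns=sample_ids)
    return CtMatrix(ct=ct_df, detected=det_df, samples=meta, spike_in=spike_in, ceiling=ceiling)


def write_ct_table(ctm: CtMatrix, path: str | Path) -> Path:
    """Write the canonical long-format TSV (assay, sample, patient, timepoint,
    ct, detected).  Re-reading with ``format='long'`` round-trips exactly."""
    path = Path(path)
    long = ctm.to_long()
    # default float formatting is shortest-roundtrip repr, so values survive
    long.to_csv(path, sep="\t", index=False)
    return path
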