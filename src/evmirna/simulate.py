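"""Synthetic paired qPCR data with known ground truth.

The generator emulates the structure of a paired pre/post EV-miRNA array
study: five patients sampled at two timepoints, ~384 assays with heavy
censoring at the limit of detection, one exogenous spike-in per sample,
and a handful of planted post-intervention shifts of realistic magnitude
(3–7 cycles, i.e. |log2FC| 3–7 after the −ΔCT transform).

The CT model per miRNA i, patient j, timepoint t is

    ct[i,j,t] = b_i + a_j + eps[i,j,t] + shift_i * [t == post]

with b_i a between-miRNA baseline (a fraction of miRNAs sit in a high-CT
regime near the ceiling, which is what produces realistic non-detection),
a_j a patient offset shared by both timepoints (the pairing the paired
t-test exploits), and eps iid technical noise.  Censoring is hard
truncation: any ct ≥ ceiling is recorded as not-detected at the ceiling,
exactly the limit-of-detection semantics the imputation policy assumes.
A positive planted shift means a later CT post-intervention, i.e.
downregulation; the expected pipeline log2FC is minus the shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gsea import GeneSetCollection
from .qpcr import CtMatrix
from .targets import TargetMap

__all__ = ["SimConfig", "SimTruth", "simulate_ct", "simulate_targets_and_sets"]

SPIKE_IN_ID = "cel-miR-39-3p"


@dataclass
class SimConfig:
    """Generator parameters; defaults reflect the paired five-patient
    array design the pipeline targets (units: PCR cycles)."""

    n_patients: int = 5
    n_assays: int = 384
    spike_in_mean: float = 22.0
    spike_in_sd: float = 0.3
    baseline_ct_mean: float = 30.0
    baseline_ct_sd_between_mirna: float = 4.0
    noise_sd_within_patient: float = 1.0
    patient_offset_sd: float = 1.5
    ceiling: float = 40.0
    fraction_near_lod: float = 0.4
    near_lod_mean: float = 38.0
    near_lod_sd: float = 1.5
    #: optional right-truncation of the baseline distribution (cycles);
    #: emulates the detectability conditioning of an already-filtered,
    #: retained miRNA subset
    baseline_ct_max: float | None = None
    #: assay index -> ΔΔCT shift (cycles) added to post samples; positive
    #: shift = later CT = downregulation (expected log2FC = −shift)
    planted_effects: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_assays < 2:
            raise ValueError("need at least 2 patients and 2 assays")
        for sd in (
            self.spike_in_sd, self.baseline_ct_sd_between_mirna,
            self.noise_sd_within_patient, self.patient_offset_sd, self.near_lod_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")
        if not 0 <= self.fraction_near_lod <= 1:
            raise ValueError("fraction_near_lod must be in [0, 1]")
        bad = [i for i in self.planted_effects if not 0 <= i < self.n_assays]
        if bad:
            raise ValueError(f"planted assay indices out of range: {bad}")


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    planted_down_ids: list[str]  # positive ΔΔCT shift (downregulated post)
    planted_up_ids: list[str]
    shifts: dict[str, float]  # mirna id -> ΔΔCT cycles
    mirna_ids: list[str]  # all simulated candidate miRNA ids

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "planted_down_ids": self.planted_down_ids,
            "planted_up_ids": self.planted_up_ids,
            "shifts": self.shifts,
            "mirna_ids": self.mirna_ids,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return path


def _assay_id(i: int) -> str:
    return f"hsa-miR-s{i:04d}"


def simulate_ct(config: SimConfig) -> tuple[CtMatrix, SimTruth]:
    """Draw one paired CT matrix plus its ground truth, fully seeded."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, P = config.n_assays, config.n_patients

    mirna_ids = [_assay_id(i) for i in range(n)]
    patient_ids = [f"P{j+1:02d}" for j in range(P)]
    sample_ids = [f"{p}_{tp}" for p in patient_ids for tp in ("pre", "post")]
    samples = pd.DataFrame(
        {
            "patient_id": [p for p in patient_ids for _ in range(2)],
            "timepoint": ["pre", "post"] * P,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    near_lod = rng.random(n) < config.fraction_near_lod
    if config.baseline_ct_max is None:
        well_detected = rng.normal(
            config.baseline_ct_mean, config.baseline_ct_sd_between_mirna, size=n
        )
    else:
        # right-truncated normal via inverse-CDF sampling
        from scipy import stats as _stats

        mu, sd = config.baseline_ct_mean, config.baseline_ct_sd_between_mirna
        if sd > 0:
            upper = _stats.norm.cdf(config.baseline_ct_max, mu, sd)
            well_detected = _stats.norm.ppf(rng.random(n) * upper, mu, sd)
        else:
            well_detected = np.full(n, min(mu, config.baseline_ct_max))
    baselines = np.where(
        near_lod,
        rng.normal(config.near_lod_mean, config.near_lod_sd, size=n),
        well_detected,
    )
    offsets = rng.normal(0.0, config.patient_offset_sd, size=P)
    shifts = np.zeros(n)
    for idx, delta in config.planted_effects.items():
        shifts[idx] = delta

    ct = np.empty((n, 2 * P))
    for j in range(P):
        for k, tp in enumerate(("pre", "post")):
            col = 2 * j + k
            eps = rng.normal(0.0, config.noise_sd_within_patient, size=n)
            ct[:, col] = baselines + offsets[j] + eps
            if tp == "post":
                ct[:, col] += shifts

    detected = ct < config.ceiling
    ct = np.where(detected, ct, config.ceiling)

    spike = rng.normal(config.spike_in_mean, config.spike_in_sd, size=2 * P)
    spike = np.minimum(spike, config.ceiling - 1e-9)  # never censored

    ct_df = pd.DataFrame(
        np.vstack([ct, spike]),
        index=pd.Index(mirna_ids + [SPIKE_IN_ID], name="assay"),
        columns=sample_ids,
    )
    det_df = pd.DataFrame(
        np.vstack([detected, np.ones((1, 2 * P), dtype=bool)]),
        index=ct_df.index,
        columns=sample_ids,
    )
    ctm = CtMatrix(
        ct=ct_df, detected=det_df, samples=samples,
        spike_in=SPIKE_IN_ID, ceiling=config.ceiling,
    )
    truth = SimTruth(
        planted_down_ids=[_assay_id(i) for i, d in sorted(config.planted_effects.items()) if d > 0],
        planted_up_ids=[_assay_id(i) for i, d in sorted(config.planted_effects.items()) if d < 0],
        shifts={_assay_id(i): float(d) for i, d in sorted(config.planted_effects.items())},
        mirna_ids=mirna_ids,
    )
    return ctm, truth


def simulate_targets_and_sets(
    truth: SimTruth,
    n_genes: int = 500,
    targets_per_mirna: int = 20,
    n_random_sets: int = 20,
    set_size: int = 50,
    enriched_set_overlap: float = 0.8,
    seed: int = 0,
) -> tuple[TargetMap, GeneSetCollection, str]:
    """Random target map plus a gene-set collection with one planted positive.

    Every simulated miRNA receives ``targets_per_mirna`` random target
    genes.  The designated set ``PLANTED_TARGET_SET`` draws
    ``enriched_set_overlap`` of its members from the union of
    planted-down-miRNA targets (those genes carry large positive ranking
    metrics downstream), the rest — and all other sets — are uniform
    draws, so the designated set is the only true enrichment signal.
    """
    if targets_per_mirna > n_genes:
        raise ValueError("targets_per_mirna cannot exceed n_genes")
    if not 0 < enriched_set_overlap <= 1:
        raise ValueError("enriched_set_overlap must be in (0, 1]")
    if set_size > n_genes:
        raise ValueError("set_size cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = np.array([f"GENE{i:04d}" for i in range(n_genes)])

    from .targets import normalize_mirna_id

    entries: dict[str, frozenset[str]] = {}
    down_keys = {normalize_mirna_id(m).key for m in truth.planted_down_ids}
    down_target_union: set[str] = set()
    for mirna in truth.mirna_ids:
        key = normalize_mirna_id(mirna).key
        chosen = rng.choice(n_genes, size=targets_per_mirna, replace=False)
        tset = frozenset(genes[chosen])
        entries[key] = tset
        if key in down_keys:
            down_target_union |= tset

    n_from_union = round(enriched_set_overlap * set_size)
    if n_from_union > len(down_target_union):
        raise ValueError(
            f"cannot draw {n_from_union} genes from a planted-target union of "
            f"{len(down_target_union)}"
        )
    union_sorted = np.array(sorted(down_target_union))
    rest_pool = np.array(sorted(set(genes) - down_target_union))
    planted_members = set(
        union_sorted[rng.choice(len(union_sorted), size=n_from_union, replace=False)]
    )
    n_rest = set_size - n_from_union
    if n_rest > len(rest_pool):
        raise ValueError("set_size too large for the non-target gene pool")
    if n_rest:
        planted_members |= set(
            rest_pool[rng.choice(len(rest_pool), size=n_rest, replace=False)]
        )

    sets: dict[str, frozenset[str]] = {"PLANTED_TARGET_SET": frozenset(planted_members)}
    for s in range(n_random_sets):
        chosen = rng.choice(n_genes, size=set_size, replace=False)
        sets[f"RANDOM_SET_{s:02d}"] = frozenset(genes[chosen])

    collection = GeneSetCollection(
        sets=sets,
        descriptions={name: "synthetic" for name in sets},
        source="synthetic",
    )
    return TargetMap(entries=entries), collection, "PLANTED_TARGET_SET"
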