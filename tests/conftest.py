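"""Shared fixtures: small constructed CT matrices and simulation helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from evmirna.qpcr import CtMatrix
from evmirna.simulate import SimConfig


def make_samples(n_patients: int = 5) -> pd.DataFrame:
    pids = [f"P{j+1:02d}" for j in range(n_patients)]
    sids = [f"{p}_{tp}" for p in pids for tp in ("pre", "post")]
    return pd.DataFrame(
        {
            "patient_id": [p for p in pids for _ in range(2)],
            "timepoint": ["pre", "post"] * n_patients,
        },
        index=pd.Index(sids, name="sample_id"),
    )


def make_ct_matrix(
    ct: np.ndarray,
    assay_ids: list[str],
    n_patients: int = 5,
    spike_in: str = "cel-miR-39-3p",
    ceiling: float = 40.0,
) -> CtMatrix:
    """Wrap a raw assay × sample array (spike-in row included) applying the
    ceiling policy."""
    samples = make_samples(n_patients)
    detected = ct < ceiling
    ct = np.where(detected, ct, ceiling)
    ct_df = pd.DataFrame(ct, index=pd.Index(assay_ids, name="assay"), columns=samples.index)
    det_df = pd.DataFrame(detected, index=ct_df.index, columns=ct_df.columns)
    return CtMatrix(ct=ct_df, detected=det_df, samples=samples, spike_in=spike_in, ceiling=ceiling)


def dyadic(rng: np.random.Generator, low: float, high: float, size) -> np.ndarray:
    """Random values on a 1/64-cycle grid, so float additions stay exact."""
    return np.round(rng.uniform(low, high, size=size) * 64) / 64


@pytest.fixture
def five_patient_samples() -> pd.DataFrame:
    return make_samples(5)


@pytest.fixture
def recovery_config() -> SimConfig:
    """Study-scale retained-set simulation: 134 well-detected miRNAs with
    four planted post-intervention downregulation shifts."""
    return SimConfig(
        n_patients=5,
        n_assays=134,
        fraction_near_lod=0.0,
        baseline_ct_max=37.0,
        planted_effects={0: 3.0, 1: 4.0, 2: 5.0, 3: 7.0},
    )
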