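"""miRNA identifier normalization, validated-target maps, and gene ranking.

Array assay labels rarely match annotation databases verbatim
("HSA-MIR-505-3P_002089" vs "hsa-miR-505-3p"), so both sides are reduced
to a canonical lower-case key before joining against the miRNA→target
map.  The ranked gene list inverts regulation: each target gene receives
the *negative* log2FC of its most strongly regulated targeting miRNA,
reflecting the canonical inverse miRNA/target relationship — targets of a
strongly downregulated miRNA rise to the top of the list.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MirnaId",
    "TargetMap",
    "RankedGeneList",
    "normalize_mirna_id",
    "read_target_map",
    "build_ranked_list",
]


class MirnaId(NamedTuple):
    """Canonical matching key plus a human-readable display form."""

    key: str
    display: str


# species prefixes are 3-4 lowercase letters that are not themselves the
# mir/let family token
_FAMILY_TOKENS = ("mir", "let", "mirna")


def normalize_mirna_id(raw: str, default_species: str = "hsa") -> MirnaId:
    """Clean an assay label into a canonical miRNA key.

    Trims whitespace, drops assay-suffix decorations (anything after
    whitespace or an underscore), lowercases for the matching key, and
    prepends ``default_species`` when no species prefix is present:
    ``" HSA-MIR-505-3P "`` → key ``hsa-mir-505-3p``; ``"miR-21-5p"`` →
    key ``hsa-mir-21-5p``.
    """
    token = re.split(r"[\s_]+", raw.strip())[0].strip("-")
    if not token:
        raise ValueError(f"miRNA identifier empty after cleaning: {raw!r}")
    key = token.lower()
    head = key.split("-", 1)[0]
    if head in _FAMILY_TOKENS:
        key = f"{default_species.lower()}-{key}"
    parts = key.split("-")
    if len(parts) >= 2 and parts[1] == "mirna":
        parts[1] = "mir"
        key = "-".join(parts)
    # display form: species lowercase, mature "miR" capitalization, rest as-is
    dparts = key.split("-")
    if len(dparts) >= 2 and dparts[1] == "mir":
        dparts[1] = "miR"
    display = "-".join(dparts)
    return MirnaId(key=key, display=display)


@dataclass
class TargetMap:
    """Mapping canonical miRNA key → set of validated target gene symbols."""

    entries: dict[str, frozenset[str]]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        for k, genes in self.entries.items():
            if not genes:
                raise ValueError(f"empty target set stored for {k!r}")

    def targets_of(self, key: str) -> frozenset[str]:
        return self.entries.get(key, frozenset())

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.entries.values():
            out |= genes
        return out


def read_target_map(path: str | Path, default_species: str = "hsa") -> TargetMap:
    """Read a two-column (mirna, gene) TSV into a normalized TargetMap.

    Header row optional; duplicate pairs collapse; malformed rows (missing
    field, empty gene) are counted and logged, not fatal — but a file with
    zero valid rows is.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: target map needs two tab-separated columns")
    first = str(raw.iat[0, 0]).strip().lower()
    if first in {"mirna", "mir", "microrna", "mirna_id"}:
        raw = raw.iloc[1:]
    entries: dict[str, set[str]] = {}
    skipped = 0
    for _, row in raw.iterrows():
        mir, gene = row.iloc[0], row.iloc[1]
        if pd.isna(mir) or pd.isna(gene) or not str(gene).strip():
            skipped += 1
            continue
        try:
            key = normalize_mirna_id(str(mir), default_species).key
        except ValueError:
            skipped += 1
            continue
        entries.setdefault(key, set()).add(str(gene).strip().upper())
    if not entries:
        raise ValueError(f"{path}: no valid (mirna, gene) rows")
    if skipped:
        logger.warning("target map %s: skipped %d malformed rows", path, skipped)
    return TargetMap(
        entries={k: frozenset(v) for k, v in entries.items()}, n_skipped=skipped
    )


@dataclass
class RankedGeneList:
    """Unique target genes ordered by the inverse-regulation metric.

    ``frame`` columns: ``gene``, ``metric`` (= −log2FC of the provenance
    miRNA), ``provenance`` (canonical key of the miRNA that supplied the
    score); rows sorted by metric non-increasing, ties by gene id.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.frame["metric"].to_numpy()
        if np.any(np.diff(m) > 0):
            raise ValueError("ranked list metric must be non-increasing")
        if self.frame["gene"].duplicated().any():
            raise ValueError("ranked list genes must be unique")

    @property
    def genes(self) -> list[str]:
        return self.frame["gene"].tolist()

    @property
    def metric(self) -> np.ndarray:
        return self.frame["metric"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def write_rnk(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame[["gene", "metric"]].to_csv(path, sep="\t", index=False, header=False)
        return path

    def write_provenance(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path


def build_ranked_list(
    de: pd.DataFrame,
    targets: TargetMap,
    selection: str = "all_retained",
    strength: str = "magnitude",
    default_species: str = "hsa",
) -> RankedGeneList:
    """Rank unique target genes by −log2FC of their strongest regulator.

    For each gene targeted by at least one selected miRNA, the targeting
    miRNA with the largest |log2FC| supplies the score (``strength=
    "significance"`` prefers the smallest p instead); remaining ties break
    by smaller p, then lexicographic key.  ``selection="nominal_p"``
    restricts the contributing miRNAs to nominal p < 0.05; the default
    uses every retained miRNA so the ranked background stays dense.
    """
    if selection not in ("all_retained", "nominal_p"):
        raise ValueError(f"unknown selection {selection!r}")
    if strength not in ("magnitude", "significance"):
        raise ValueError(f"unknown strength {strength!r}")

    de = de.copy()
    de["norm_key"] = [normalize_mirna_id(m, default_species).key for m in de.index]
    if selection == "nominal_p":
        de = de[de["p_value"].notna() & (de["p_value"] < 0.05)]
    de = de[de["log2fc"].notna()]
    de = de[de["norm_key"].isin(targets.entries.keys())]
    if de.empty:
        raise ValueError(
            "no overlap between DE miRNAs and the target map; "
            f"map keys (sample): {sorted(targets.entries)[:5]}"
        )

    best: dict[str, tuple] = {}
    for row in de.itertuples():
        key = row.norm_key
        p = row.p_value if not pd.isna(row.p_value) else np.inf
        if strength == "magnitude":
            rank_key = (-abs(row.log2fc), p, key)
        else:
            rank_key = (p, -abs(row.log2fc), key)
        for gene in targets.targets_of(key):
            if gene not in best or rank_key < best[gene][0]:
                best[gene] = (rank_key, key, -row.log2fc)

    frame = pd.DataFrame(
        [(g, v[2], v[1]) for g, v in best.items()],
        columns=["gene", "metric", "provenance"],
    )
    frame = frame.sort_values(
        by=["metric", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return RankedGeneList(frame=frame)
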