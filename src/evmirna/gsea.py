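"""Preranked gene-set enrichment analysis, implemented from first principles.

The enrichment score (ES) is the classic weighted Kolmogorov–Smirnov
running statistic: walking the ranked gene list, a hit (set member)
increments the running sum by |metric|^weight normalized over all hits,
a miss decrements by 1/(N − n_hits); the ES is the signed maximum
deviation.  Significance comes from a gene-label permutation null —
same-size random draws from the ranked universe — which is the only
permutation scheme available for an externally ranked list.

Conventions follow the canonical GSEA tool: NES = ES divided by the mean
|null ES| of the matching sign; nominal p is the matching-sign tail
frequency with add-one smoothing so p is never exactly zero; the FDR q is
computed separately for the positive and negative NES tails as the ratio
of normalized-null to observed tail fractions, capped at 1 and made
monotone.  Leading-edge genes are the hits at or before the ES peak (at
or after it for negative ES), in rank order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .targets import RankedGeneList

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EsResult",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "prerank_gsea",
    "significant_pathways",
    "results_frame",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), symbols uppercase, no empty sets."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name  description  member...``.

    Duplicate member symbols collapse; a duplicate set name or a line with
    fewer than three fields is fatal (with its line number).
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            cleaned = frozenset(m.strip().upper() for m in members if m.strip())
            if not cleaned:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = cleaned
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    """Write a collection back to GMT with sorted members (deterministic)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
    return path


# -- enrichment score -----------------------------------------------------


@dataclass
class EsResult:
    es: float
    running_sum: np.ndarray
    peak_index: int  # 0-based position in the ranked list of the ES extremum


def _es_steps(metric_w: np.ndarray, hit: np.ndarray) -> np.ndarray:
    """Per-position running-sum increments for one hit mask."""
    n = metric_w.size
    n_hits = int(hit.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must be a non-empty proper subset of the ranked list")
    hit_total = metric_w[hit].sum()
    if hit_total > 0:
        inc = metric_w / hit_total
    else:
        # all hit metrics zero under weight > 0: fall back to uniform hits
        inc = np.full(n, 1.0 / n_hits)
    return np.where(hit, inc, -1.0 / (n - n_hits))


def enrichment_score(
    ranked: RankedGeneList, members: set[str] | frozenset[str], weight: float = 1.0
) -> EsResult:
    """Weighted running-sum enrichment score of ``members`` in ``ranked``.

    The running sum starts at 0, ends at 0 (to numerical precision), and
    the ES is its value at the point of maximum absolute deviation.
    """
    genes = ranked.genes
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    metric_w = np.abs(ranked.metric) ** weight
    steps = _es_steps(metric_w, hit)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return EsResult(es=float(running[peak]), running_sum=running, peak_index=peak)


def _es_batch(metric_w: np.ndarray, hit_matrix: np.ndarray) -> np.ndarray:
    """Vectorized ES for a (B, N) boolean hit matrix with a fixed ranking."""
    B, N = hit_matrix.shape
    n_hits = hit_matrix.sum(axis=1)
    hit_totals = (hit_matrix * metric_w).sum(axis=1)
    inc = np.where(
        hit_totals[:, None] > 0,
        metric_w[None, :] / np.where(hit_totals[:, None] > 0, hit_totals[:, None], 1.0),
        (1.0 / n_hits)[:, None],
    )
    steps = np.where(hit_matrix, inc, (-1.0 / (N - n_hits))[:, None])
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(B), idx]


# -- permutation GSEA -----------------------------------------------------


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    q_fdr: float
    leading_edge: list[str]
    n_hits: int


def _null_es(
    metric_w: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution for sets of ``size`` random genes."""
    N = metric_w.size
    hit_matrix = np.zeros((n_perm, N), dtype=bool)
    for b in range(n_perm):
        idx = rng.choice(N, size=size, replace=False)
        hit_matrix[b, idx] = True
    return _es_batch(metric_w, hit_matrix)


def _tail_stats(es: float, null: np.ndarray) -> tuple[float, float]:
    """(nominal p, NES) from the matching-sign side of one null sample."""
    if es >= 0:
        side = null[null >= 0]
        b = int((side >= es).sum())
    else:
        side = null[null < 0]
        b = int((side <= es).sum())
    p = (b + 1) / (side.size + 1)
    denom = np.abs(side).mean() if side.size else np.nan
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
    return p, nes


def prerank_gsea(
    ranked: RankedGeneList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """Permutation preranked GSEA over a gene-set collection.

    Size bounds apply to each set's intersection with the ranked universe;
    sets with an empty intersection, or covering the whole universe, are
    skipped with a log message.  Null ES distributions are shared across
    sets of equal intersection size (the null depends only on the size),
    drawn from a single seeded generator so results are reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    genes = ranked.genes
    universe = set(genes)
    metric_w = np.abs(ranked.metric) ** weight

    eligible: list[tuple[str, frozenset[str]]] = []
    sizes_seen: list[int] = []
    for name in collection.sets:
        inter = collection.sets[name] & universe
        if not inter:
            logger.info("set %s skipped: no overlap with ranked list", name)
            continue
        if len(inter) == len(universe):
            logger.info("set %s skipped: covers the entire ranked list", name)
            continue
        if not (min_size <= len(inter) <= max_size):
            logger.info(
                "set %s skipped: intersection size %d outside [%d, %d]",
                name, len(inter), min_size, max_size,
            )
            continue
        eligible.append((name, frozenset(inter)))
        sizes_seen.append(len(inter))
    if not eligible:
        raise ValueError(
            f"no eligible gene sets: {len(collection)} sets, size bounds "
            f"[{min_size}, {max_size}], universe {len(universe)} genes"
        )

    nulls: dict[int, np.ndarray] = {}
    for size in sorted(set(sizes_seen)):
        nulls[size] = _null_es(metric_w, size, n_perm, rng)

    results: list[EnrichmentResult] = []
    null_nes_pool: list[np.ndarray] = []
    for name, members in eligible:
        esr = enrichment_score(ranked, members, weight=weight)
        null = nulls[len(members)]
        p, nes = _tail_stats(esr.es, null)
        hit_positions = [i for i, g in enumerate(genes) if g in members]
        if esr.es >= 0:
            le = [genes[i] for i in hit_positions if i <= esr.peak_index]
        else:
            le = [genes[i] for i in hit_positions if i >= esr.peak_index]
        results.append(
            EnrichmentResult(
                set_name=name, es=esr.es, nes=nes, p_nominal=p, q_fdr=np.nan,
                leading_edge=le, n_hits=len(members),
            )
        )
        # normalize this set's null by its own tail means, for the FDR pool
        pos = null[null >= 0]
        neg = null[null < 0]
        parts = []
        if pos.size and pos.mean() > 0:
            parts.append(pos / pos.mean())
        if neg.size:
            parts.append(neg / np.abs(neg).mean())
        null_nes_pool.append(np.concatenate(parts) if parts else np.array([]))

    _assign_fdr(results, np.concatenate(null_nes_pool))
    return results


def _assign_fdr(results: list[EnrichmentResult], null_nes: np.ndarray) -> None:
    """Tail-wise GSEA FDR: ratio of null to observed NES tail fractions."""
    obs = np.array([r.nes for r in results])
    defined = np.isfinite(obs)
    pos_obs = obs[defined & (obs >= 0)]
    neg_obs = obs[defined & (obs < 0)]
    pos_null = null_nes[null_nes >= 0]
    neg_null = null_nes[null_nes < 0]

    raw: dict[int, float] = {}
    for i, r in enumerate(results):
        if not np.isfinite(r.nes):
            raw[i] = np.nan
            continue
        if r.nes >= 0:
            frac_null = (pos_null >= r.nes).mean() if pos_null.size else np.nan
            frac_obs = (pos_obs >= r.nes).mean() if pos_obs.size else np.nan
        else:
            frac_null = (neg_null <= r.nes).mean() if neg_null.size else np.nan
            frac_obs = (neg_obs <= r.nes).mean() if neg_obs.size else np.nan
        q = frac_null / frac_obs if frac_obs and np.isfinite(frac_obs) else np.nan
        raw[i] = min(q, 1.0) if np.isfinite(q) else np.nan

    # q-value monotonicity within each tail: q_i is the minimum estimated
    # FDR over thresholds no more extreme than NES_i (so a more extreme
    # NES never ends up with a larger q)
    for sign in (1, -1):
        idx = [
            i for i, r in enumerate(results)
            if np.isfinite(r.nes) and (r.nes >= 0) == (sign > 0)
        ]
        idx.sort(key=lambda i: abs(results[i].nes))  # least extreme first
        best = np.inf
        for i in idx:
            best = min(best, raw[i])
            raw[i] = best
    for i, r in enumerate(results):
        r.q_fdr = float(raw[i])


def significant_pathways(
    results: list[EnrichmentResult], q_threshold: float = 0.2
) -> list[EnrichmentResult]:
    """Strictly q < threshold, ordered by q ascending then |NES| descending."""
    kept = [r for r in results if np.isfinite(r.q_fdr) and r.q_fdr < q_threshold]
    return sorted(kept, key=lambda r: (r.q_fdr, -abs(r.nes), r.set_name))


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flat table of enrichment results (leading edge comma-joined)."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "q_fdr": [r.q_fdr for r in results],
            "n_hits": [r.n_hits for r in results],
            "n_leading_edge": [len(r.leading_edge) for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
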