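"""Paired differential expression, BH FDR, consistency calls, and PCA.

Each miRNA is tested with a paired two-tailed Student's t-test on the
per-patient post − pre expression differences.  The log2 fold change is
the mean post minus the mean pre expression (expression is already on the
−ΔCT log2 scale).  Records with zero variance of the paired differences —
the typical pathology when all cells sit at the imputation ceiling — are
flagged degenerate: their t and p are undefined, they are excluded from
the BH adjustment and can never be called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = [
    "paired_t_test",
    "benjamini_hochberg",
    "run_differential_expression",
    "top_k_by_p",
    "pca_scores",
    "PcaScores",
]


def paired_t_test(
    pre: np.ndarray, post: np.ndarray
) -> tuple[float, float, bool]:
    """Paired two-tailed t-test on aligned expression vectors.

    Returns ``(t, p, degenerate)``.  With ``d = post − pre``,
    ``t = mean(d) / (sd(d)/√n)`` using the sample sd (n−1 denominator) and
    ``p`` the two-sided tail of Student's t with n−1 df.  A zero sd makes
    the statistic undefined: ``(nan, nan, True)`` is returned rather than
    fabricating p = 0.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"length mismatch: pre {pre.shape} vs post {post.shape}")
    n = pre.size
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2 pairs, got {n}")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0.0:
        return float("nan"), float("nan"), True
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), False


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    Standard step-up: with p sorted ascending, q_(i) = min_{j>=i}
    (p_(j) · m / j), capped at 1, mapped back to the input order.
    Input entries must be defined and in [0, 1]; callers exclude
    undefined (degenerate) p-values beforehand.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be defined and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def run_differential_expression(
    em: ExpressionMatrix,
    q_threshold: float = 0.2,
    consistency_min: int = 3,
) -> pd.DataFrame:
    """Per-miRNA paired DE table with BH FDR and consistency calls.

    Returns a frame indexed by miRNA with columns ``log2fc``, ``t_stat``,
    ``p_value``, ``q_value``, ``n_down``, ``n_up``, ``n_zero``,
    ``consistent`` (``down``/``up``/``none``), ``significant`` (strict
    q < ``q_threshold``) and ``degenerate``.  A miRNA is consistently
    down/up when at least ``consistency_min`` patients moved in that
    direction; zero differences count toward neither.
    """
    pre_ids = em.samples_at("pre")
    post_ids = em.samples_at("post")
    pre = em.expr[pre_ids].to_numpy(dtype=float)
    post = em.expr[post_ids].to_numpy(dtype=float)
    n = len(pre_ids)
    if n < 2:
        raise ValueError(f"paired design needs >= 2 patients, got {n}")

    d = post - pre
    log2fc = post.mean(axis=1) - pre.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    t_stat = np.full(d.shape[0], np.nan)
    p_value = np.full(d.shape[0], np.nan)
    ok = ~degenerate
    t_stat[ok] = d[ok].mean(axis=1) / (sd[ok] / np.sqrt(n))
    p_value[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), df=n - 1)

    q_value = np.full(d.shape[0], np.nan)
    if ok.any():
        q_value[ok] = benjamini_hochberg(p_value[ok])

    n_down = (d < 0).sum(axis=1)
    n_up = (d > 0).sum(axis=1)
    n_zero = (d == 0).sum(axis=1)
    consistent = np.where(
        n_down >= consistency_min, "down", np.where(n_up >= consistency_min, "up", "none")
    )
    significant = ok & (q_value < q_threshold)

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "n_down": n_down.astype(int),
            "n_up": n_up.astype(int),
            "n_zero": n_zero.astype(int),
            "consistent": consistent,
            "significant": significant,
            "degenerate": degenerate,
        },
        index=pd.Index(em.mirna_ids, name="mirna"),
    )


def top_k_by_p(de: pd.DataFrame, k: int = 25) -> list[str]:
    """The k miRNAs with the smallest defined p-values, ascending.

    Ties are broken by |log2fc| descending, then lexicographic id, so the
    selection is deterministic.  ``k`` beyond the table size returns all
    defined records.
    """
    defined = de[de["p_value"].notna()].copy()
    defined["_abs_fc"] = defined["log2fc"].abs()
    defined = defined.rename_axis("mirna").reset_index()
    defined = defined.sort_values(
        by=["p_value", "_abs_fc", "mirna"], ascending=[True, False, True]
    )
    return defined["mirna"].head(k).tolist()


@dataclass
class PcaScores:
    """Sample scores of a centered PCA (samples = observations)."""

    scores: pd.DataFrame  # sample × component, columns PC1, PC2, ...
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # feature × component

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def write_tsv(self, path) -> None:
        out = self.scores.copy()
        out.to_csv(path, sep="\t")


def pca_scores(em: ExpressionMatrix, n_components: int = 2) -> PcaScores:
    """PCA of samples in miRNA-expression space via SVD.

    Features (miRNAs) are mean-centered but not scaled — all are already
    on the common −ΔCT log2 scale.  For reproducibility each component's
    sign is fixed so that its largest-|loading| feature loads positively.
    """
    X = em.expr.T.to_numpy(dtype=float)  # samples × features
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_rank = min(n_samples - 1, n_features)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds max rank {max_rank} "
            f"({n_samples} samples x {n_features} features)"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| feature positive per component
    for c in range(len(S)):
        jmax = np.argmax(np.abs(Vt[c]))
        if Vt[c, jmax] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    total_var = (S**2).sum()
    evr = (S**2 / total_var)[:n_components] if total_var > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * S[:n_components]
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PcaScores(
        scores=pd.DataFrame(scores, index=pd.Index(em.sample_ids, name="sample"), columns=cols),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(Vt[:n_components].T, index=em.expr.index, columns=cols),
    )
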