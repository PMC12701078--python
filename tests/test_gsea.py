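"""From-scratch preranked GSEA: running-sum ES, permutation null, FDR,
leading edge — checked against independent brute-force oracles and the
gseapy reference implementation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from evmirna.gsea import (
    GeneSetCollection,
    enrichment_score,
    prerank_gsea,
    read_gmt,
    significant_pathways,
    write_gmt,
)
from evmirna.targets import RankedGeneList


def make_ranked(genes: list[str], metrics: list[float]) -> RankedGeneList:
    return RankedGeneList(
        frame=pd.DataFrame(
            {"gene": genes, "metric": metrics, "provenance": ""}
        )
    )


def oracle_es(metrics, hit_flags, weight=1.0):
    """Independent brute-force running sum: explicit loop, no shortcuts."""
    total = sum(abs(m) ** weight for m, h in zip(metrics, hit_flags) if h)
    n_hits = sum(hit_flags)
    n_miss = len(metrics) - n_hits
    running, best, best_pos = 0.0, 0.0, 0
    track = []
    for pos, (m, h) in enumerate(zip(metrics, hit_flags)):
        if h:
            running += (abs(m) ** weight / total) if total > 0 else 1.0 / n_hits
        else:
            running -= 1.0 / n_miss
        track.append(running)
        if abs(running) > abs(best):
            best, best_pos = running, pos
    return best, track, best_pos


RANKED10 = make_ranked(
    [f"g{i}" for i in range(1, 11)],
    [9.0, 7.5, 5.0, 3.5, 2.0, 1.0, 0.5, -1.0, -2.5, -4.0],
)


class TestGmtIo:
    def test_duplicate_members_collapse(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("S1\tdesc\tA\tB\tA\n")
        coll = read_gmt(f)
        assert coll.sets["S1"] == {"A", "B"}

    def test_short_line_fatal_with_lineno(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("S1\tdesc\tA\nS2\tonlydesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(f)

    def test_duplicate_set_name_fatal(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("S1\td\tA\tB\nS1\td\tC\tD\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(f)

    def test_empty_file_fatal(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("")
        with pytest.raises(ValueError, match="no gene sets"):
            read_gmt(f)

    def test_round_trip_fifty_sets(self, tmp_path):
        rng = np.random.default_rng(13)
        genes = [f"G{i:03d}" for i in range(200)]
        sets = {
            f"HALLMARK_LIKE_{s:02d}": frozenset(
                genes[i] for i in rng.choice(200, size=25, replace=False)
            )
            for s in range(50)
        }
        coll = GeneSetCollection(sets=sets, descriptions={k: "d" for k in sets})
        p1 = tmp_path / "a.gmt"
        write_gmt(coll, p1)
        back = read_gmt(p1)
        assert back.sets == coll.sets
        p2 = tmp_path / "b.gmt"
        write_gmt(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestEnrichmentScore:
    def test_top_gene_singleton_extreme(self):
        ranked = make_ranked(list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0])
        res = enrichment_score(ranked, {"a"})
        assert res.es == pytest.approx(1.0)
        assert res.peak_index == 0

    def test_bottom_gene_singleton_negative(self):
        ranked = make_ranked(list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0])
        res = enrichment_score(ranked, {"e"})
        assert res.es == pytest.approx(-1.0)
        assert res.peak_index == 3  # just before the final hit

    def test_weight_zero_ignores_metrics(self):
        ranked = make_ranked(list("abcde"), [100.0, 4.0, 3.0, 2.0, 1.0])
        r0 = enrichment_score(ranked, {"a", "c"}, weight=0.0)
        uniform = make_ranked(list("abcde"), [1.0, 1.0, 1.0, 1.0, 1.0])
        r1 = enrichment_score(uniform, {"a", "c"}, weight=1.0)
        assert r0.es == pytest.approx(r1.es)

    def test_zero_metric_hits_fall_back_to_uniform(self):
        ranked = make_ranked(list("abcde"), [5.0, 4.0, 0.0, 0.0, -1.0])
        res = enrichment_score(ranked, {"c", "d"}, weight=1.0)
        assert np.isfinite(res.es)
        assert abs(res.es) <= 1.0

    def test_running_sum_starts_and_ends_near_zero(self):
        rng = np.random.default_rng(3)
        metrics = np.sort(rng.normal(scale=3, size=60))[::-1]
        ranked = make_ranked([f"g{i}" for i in range(60)], list(metrics))
        members = {f"g{i}" for i in rng.choice(60, size=12, replace=False)}
        res = enrichment_score(ranked, members)
        assert abs(res.running_sum[-1]) < 1e-9

    def test_es_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            metrics = np.sort(rng.normal(scale=2, size=30))[::-1]
            ranked = make_ranked([f"g{i}" for i in range(30)], list(metrics))
            k = int(rng.integers(1, 29))
            members = {f"g{i}" for i in rng.choice(30, size=k, replace=False)}
            assert -1.0 <= enrichment_score(ranked, members).es <= 1.0

    def test_improper_subset_rejected(self):
        ranked = make_ranked(list("abc"), [3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"a", "b", "c"})
        with pytest.raises(ValueError):
            enrichment_score(ranked, set())

    def test_exhaustive_oracle_equivalence_sizes_1_to_4(self):
        genes = RANKED10.genes
        metrics = RANKED10.metric
        checked = 0
        for size in (1, 2, 3, 4):
            for combo in itertools.combinations(range(10), size):
                members = {genes[i] for i in combo}
                hits = [i in combo for i in range(10)]
                exp_es, exp_track, exp_pos = oracle_es(metrics, hits)
                res = enrichment_score(RANKED10, members)
                assert res.es == exp_es
                assert res.peak_index == exp_pos
                assert np.allclose(res.running_sum, exp_track, atol=1e-12)
                checked += 1
        assert checked == 385

    def test_reversed_ranking_negates_es_weight_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            metrics = np.sort(rng.normal(size=20))[::-1]
            genes = [f"g{i}" for i in range(20)]
            ranked = make_ranked(genes, list(metrics))
            rev = make_ranked(genes[::-1], list(metrics[::-1] * -1))
            k = int(rng.integers(1, 19))
            members = {f"g{i}" for i in rng.choice(20, size=k, replace=False)}
            ra = enrichment_score(ranked, members, weight=0.0)
            rb = enrichment_score(rev, members, weight=0.0)
            assert abs(ra.es) == pytest.approx(abs(rb.es), abs=1e-12)
            # when the peak magnitude is attained with one sign only, the
            # signed ES must flip; with a +/- tie either sign is legitimate
            track = ra.running_sum
            if not np.isclose(track.max(), -track.min(), atol=1e-12):
                assert ra.es == pytest.approx(-rb.es, abs=1e-12)


def random_universe(n=120, seed=0):
    rng = np.random.default_rng(seed)
    metrics = np.sort(rng.normal(scale=2, size=n))[::-1]
    return make_ranked([f"g{i:03d}" for i in range(n)], list(metrics))


class TestPrerankGsea:
    def test_seed_reproducibility(self):
        ranked = random_universe()
        rng = np.random.default_rng(1)
        sets = {
            f"S{j}": frozenset(
                f"g{i:03d}" for i in rng.choice(120, size=15, replace=False)
            )
            for j in range(5)
        }
        coll = GeneSetCollection(sets=sets)
        r1 = prerank_gsea(ranked, coll, n_perm=100, min_size=5, seed=42)
        r2 = prerank_gsea(ranked, coll, n_perm=100, min_size=5, seed=42)
        for a, b in zip(r1, r2):
            assert (a.es, a.nes, a.p_nominal, a.q_fdr, a.leading_edge) == (
                b.es, b.nes, b.p_nominal, b.q_fdr, b.leading_edge
            )

    def test_top_block_set_is_extreme(self):
        ranked = random_universe(n=500, seed=7)
        top = frozenset(ranked.genes[:50])
        rng = np.random.default_rng(2)
        sets = {"TOP": top}
        for j in range(10):
            sets[f"R{j}"] = frozenset(
                ranked.genes[i] for i in rng.choice(500, size=50, replace=False)
            )
        res = prerank_gsea(
            ranked, GeneSetCollection(sets=sets), n_perm=1000, min_size=5, seed=3
        )
        by_name = {r.set_name: r for r in res}
        top_r = by_name["TOP"]
        assert top_r.es > 0 and top_r.nes > 0
        assert top_r.p_nominal < 0.01
        assert top_r.q_fdr < 0.2
        sig = significant_pathways(res)
        assert sig and sig[0].set_name == "TOP"

    def test_leading_edge_contains_top_hits(self):
        ranked = random_universe(n=100, seed=9)
        members = frozenset(ranked.genes[:10])
        res = prerank_gsea(
            ranked,
            GeneSetCollection(sets={"S": members}),
            n_perm=50, min_size=5, seed=0,
        )[0]
        assert res.es > 0
        assert set(res.leading_edge) <= set(members)
        assert ranked.genes[0] in res.leading_edge
        # rank order preserved
        pos = [ranked.genes.index(g) for g in res.leading_edge]
        assert pos == sorted(pos)

    def test_nominal_p_roughly_uniform_for_random_sets(self):
        from scipy import stats as spstats

        ranked = random_universe(n=200, seed=11)
        rng = np.random.default_rng(4)
        sets = {
            f"S{j:03d}": frozenset(
                ranked.genes[i] for i in rng.choice(200, size=20, replace=False)
            )
            for j in range(150)
        }
        res = prerank_gsea(
            ranked, GeneSetCollection(sets=sets), n_perm=200, min_size=5, seed=8
        )
        pvals = np.array([r.p_nominal for r in res])
        frac = (pvals < 0.05).mean()
        assert 0.0 <= frac <= 0.12
        assert spstats.kstest(pvals, "uniform").pvalue > 0.01

    def test_size_bounds_and_no_eligible_fatal(self):
        ranked = random_universe(n=50, seed=1)
        coll = GeneSetCollection(sets={"TINY": frozenset(ranked.genes[:3])})
        with pytest.raises(ValueError, match="no eligible"):
            prerank_gsea(ranked, coll, n_perm=10, min_size=15, seed=0)

    def test_q_threshold_strict(self):
        from evmirna.gsea import EnrichmentResult

        results = [
            EnrichmentResult("A", 0.5, 1.5, 0.01, 0.2, [], 10),
            EnrichmentResult("B", 0.5, 1.5, 0.01, 0.19, [], 10),
        ]
        kept = significant_pathways(results, q_threshold=0.2)
        assert [r.set_name for r in kept] == ["B"]


class TestGseapyCrossValidation:
    def test_es_matches_reference_tool(self):
        gseapy = pytest.importorskip("gseapy")
        ranked = random_universe(n=100, seed=17)
        rng = np.random.default_rng(6)
        sets = {
            f"S{j}": sorted(
                ranked.genes[i] for i in rng.choice(100, size=20, replace=False)
            )
            for j in range(5)
        }
        rnk = pd.DataFrame({"gene": ranked.genes, "score": ranked.metric})
        ref = gseapy.prerank(
            rnk=rnk, gene_sets=sets, permutation_num=10, min_size=2,
            max_size=500, seed=1, outdir=None, no_plot=True, weight=1.0,
        ).res2d.set_index("Term")
        ours = prerank_gsea(
            ranked,
            GeneSetCollection(sets={k: frozenset(v) for k, v in sets.items()}),
            n_perm=10, min_size=2, seed=1,
        )
        for r in ours:
            assert r.es == pytest.approx(float(ref.loc[r.set_name, "ES"]), abs=1e-6)
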