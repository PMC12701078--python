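"""End-to-end orchestration: read → filter → normalize → DE → rank → GSEA
→ network, with a deterministic manifest.

All randomness (simulation, permutation null) flows from one root seed
through :class:`numpy.random.SeedSequence` children, so a fixed config
plus seed reproduces every output file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .diffexpr import pca_scores, run_differential_expression
from .gsea import prerank_gsea, read_gmt, results_frame
from .network import build_network, degree_summary, export_network
from .preprocess import filter_by_detection, normalize_spike_in
from .qpcr import read_ct_table, write_ct_table
from .simulate import SimConfig, simulate_ct, simulate_targets_and_sets
from .targets import build_ranked_list, read_target_map

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of (``ct_table`` + ``target_map`` + ``gmt``) or
    ``simulate`` must be provided.
    """

    out_dir: str | Path = "evmirna_run"
    seed: int = 0
    # input files
    ct_table: str | Path | None = None
    ct_format: str = "wide"
    spike_in: str | None = None
    sample_table: str | Path | None = None
    target_map: str | Path | None = None
    gmt: str | Path | None = None
    # or simulation
    simulate: SimConfig | None = None
    sim_n_genes: int = 500
    sim_targets_per_mirna: int = 20
    sim_n_random_sets: int = 20
    sim_set_size: int = 50
    sim_enriched_overlap: float = 0.8
    # thresholds
    ceiling: float = 40.0
    min_detected: int = 2
    q_de: float = 0.2
    consistency_min: int = 3
    p_network: float = 0.05
    q_pathway: float = 0.2
    # GSEA parameters
    n_perm: int = 1000
    gsea_weight: float = 1.0
    min_size: int = 15
    max_size: int = 500

    def validate(self) -> None:
        has_files = self.ct_table is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise ValueError("provide either input files or a simulate block, not both")
        if has_files and (self.target_map is None or self.gmt is None or not self.spike_in):
            raise ValueError("file mode needs ct_table, target_map, gmt and spike_in")
        for name in ("q_de", "p_network", "q_pathway"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"threshold {name}={v} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            planted = {int(k): float(v) for k, v in (sim.pop("planted_effects", {}) or {}).items()}
            cfg.simulate = SimConfig(planted_effects=planted, **sim)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the manifest (also written to
    ``manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    sim_seed, sets_seed, gsea_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )
    manifest: dict = {
        "package": "evmirna",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }
    files: list[Path] = []

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    # --- inputs ---------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        sim.seed = sim_seed
        ctm, truth = simulate_ct(sim)
        tmap, collection, planted_set = simulate_targets_and_sets(
            truth,
            n_genes=config.sim_n_genes,
            targets_per_mirna=config.sim_targets_per_mirna,
            n_random_sets=config.sim_n_random_sets,
            set_size=config.sim_set_size,
            enriched_set_overlap=config.sim_enriched_overlap,
            seed=sets_seed,
        )
        files.append(write_ct_table(ctm, out / "ct_table.tsv"))
        files.append(truth.write_json(out / "sim_truth.json"))
        stage(
            "simulate",
            n_assays=sim.n_assays,
            n_patients=sim.n_patients,
            n_planted=len(sim.planted_effects),
            planted_set=planted_set,
        )
    else:
        ctm = read_ct_table(
            config.ct_table,
            format=config.ct_format,
            spike_in=config.spike_in,
            ceiling=config.ceiling,
            sample_table=config.sample_table,
        )
        tmap = read_target_map(config.target_map)
        collection = read_gmt(config.gmt)
        stage(
            "read",
            n_assays=len(ctm.assay_ids),
            n_samples=len(ctm.sample_ids),
            n_map_mirnas=len(tmap.entries),
            n_sets=len(collection),
        )

    # --- preprocess -----------------------------------------------------
    filtered, report = filter_by_detection(ctm, min_detected=config.min_detected)
    files.append(report.write_json(out / "filter_report.json"))
    stage(
        "filter",
        n_assays_total=report.n_assays_total,
        n_detected_any=report.n_detected_any,
        n_retained=report.n_retained,
    )
    em = normalize_spike_in(filtered)
    files.append(em.write_tsv(out / "expression.tsv"))

    # --- differential expression ----------------------------------------
    de = run_differential_expression(
        em, q_threshold=config.q_de, consistency_min=config.consistency_min
    )
    de_path = out / "de_table.tsv"
    de.to_csv(de_path, sep="\t")
    files.append(de_path)
    stage(
        "diffexpr",
        n_tested=int(de["p_value"].notna().sum()),
        n_degenerate=int(de["degenerate"].sum()),
        n_significant=int(de["significant"].sum()),
        n_consistent_down=int((de["consistent"] == "down").sum()),
    )
    if len(em.sample_ids) >= 3:
        pcs = pca_scores(em, n_components=2)
        pcs.write_tsv(out / "pca_scores.tsv")
        files.append(out / "pca_scores.tsv")

    # --- ranking and GSEA -----------------------------------------------
    ranked = build_ranked_list(de, tmap)
    files.append(ranked.write_rnk(out / "ranked_genes.rnk"))
    files.append(ranked.write_provenance(out / "ranked_provenance.tsv"))
    stage("rank", n_genes=len(ranked))

    results = prerank_gsea(
        ranked,
        collection,
        n_perm=config.n_perm,
        weight=config.gsea_weight,
        min_size=config.min_size,
        max_size=config.max_size,
        seed=gsea_seed,
    )
    enr = results_frame(results).sort_values(
        by=["q_fdr", "p_nominal", "set_name"]
    ).reset_index(drop=True)
    enr_path = out / "enrichment.tsv"
    enr.to_csv(enr_path, sep="\t", index=False)
    files.append(enr_path)
    stage(
        "gsea",
        n_sets_tested=len(results),
        n_significant=int((enr["q_fdr"] < config.q_pathway).sum()),
    )

    # --- network ----------------------------------------------------------
    net = build_network(
        de, tmap, results, mirna_p=config.p_network, pathway_q=config.q_pathway
    )
    files.append(export_network(net, out / "network.graphml", format="graphml"))
    files.append(export_network(net, out / "network_edges.tsv", format="edge_tsv"))
    deg = degree_summary(net)
    deg_path = out / "network_degrees.tsv"
    deg.to_csv(deg_path, sep="\t", index=False)
    files.append(deg_path)
    stage("network", n_nodes=net.n_nodes, n_edges=net.n_edges)

    for f in files:
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
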