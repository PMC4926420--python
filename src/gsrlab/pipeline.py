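"""End-to-end orchestration: template -> score -> test -> rank/venn/progressive ->
classify/cluster -> network.

Each stage writes its artifacts once and records them in ``manifest.json`` together with
SHA-256 hashes of its inputs and a hash of its parameters.  Re-running with an identical
configuration is a no-op for completed stages; a corrupted intermediate (hash mismatch)
causes that stage and everything downstream of it to be re-executed.  Stage-level logging
reports the counts (sets scored and skipped, samples per group) that make the filtering
rules auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import classify as clf
from . import core, deregulation, network
from .io import read_expression, read_gmt, read_phenotype

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_config_file"]


@dataclass
class PipelineConfig:
    expr_path: str
    pheno_path: str
    gmt_path: str
    out_dir: str
    expr_dialect: str = "tsv"
    control_label: str = "control"
    stage_labels: tuple[str, ...] | None = None  # derived from phenotypes when None
    alpha: float = 0.05
    top_k: int = 200
    max_final_rank: int = 200
    min_rank_drop: int = 15
    drop_mode: str = "every"
    n_folds: int = 5
    n_repeats: int = 10
    svm_c: float = 1.0
    knn_k: int = 3
    tau: float = 1.0
    min_network_sets: int = 5
    seed: int = 0

    def params_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.stages: dict[str, dict] = {}
        if path.exists():
            self.stages = json.loads(path.read_text())

    def save(self) -> None:
        self.path.write_text(json.dumps(self.stages, indent=2, sort_keys=True))

    def is_current(self, stage: str, params_hash: str, inputs: list[Path]) -> bool:
        entry = self.stages.get(stage)
        if entry is None or entry["params"] != params_hash:
            return False
        recorded_inputs = entry["inputs"]
        if set(recorded_inputs) != {str(p) for p in inputs}:
            return False
        for p in inputs:
            if not p.exists() or _sha256(p) != recorded_inputs[str(p)]:
                return False
        for out_path, digest in entry["outputs"].items():
            p = Path(out_path)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, params_hash: str, inputs: list[Path], outputs: list[Path]):
        self.stages[stage] = {
            "params": params_hash,
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        self.save()


def read_config_file(path: str | Path) -> dict:
    """Parse a ``key = value`` config file mirroring the CLI flags."""
    values: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        values[key] = value
    return values


def run_pipeline(config: PipelineConfig) -> dict[str, list[str]]:
    """Execute all stages in dependency order; returns {stage: [output paths]}."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    ph = config.params_hash()
    produced: dict[str, list[str]] = {}

    expr_path = Path(config.expr_path)
    pheno_path = Path(config.pheno_path)
    gmt_path = Path(config.gmt_path)
    for p in (expr_path, pheno_path, gmt_path):
        if not p.exists():
            raise FileNotFoundError(p)

    phenotypes = read_phenotype(pheno_path)
    stages = (
        list(config.stage_labels)
        if config.stage_labels
        else [g for g in phenotypes.labels if g != config.control_label]
    )

    # -- score -------------------------------------------------------------
    templates_path = out / "templates.tsv"
    gsr_path = out / "gsr.tsv"
    score_inputs = [expr_path, pheno_path, gmt_path]
    if manifest.is_current("score", ph, score_inputs):
        logger.info("score: up to date")
        gsr = core.read_gsr(gsr_path)
    else:
        expr = read_expression(expr_path, dialect=config.expr_dialect)
        collection = read_gmt(gmt_path)
        templates, skipped = core.build_templates(
            expr, phenotypes, collection, config.control_label
        )
        gsr = core.score_samples(templates, expr, template_provenance=expr.dataset_id)
        gsr.skipped_sets = skipped + gsr.skipped_sets
        core.write_templates(templates, templates_path)
        core.write_gsr(gsr, gsr_path)
        logger.info(
            "score: %d sets scored, %d skipped, %d samples",
            len(gsr.set_names), len(gsr.skipped_sets), len(gsr.sample_ids),
        )
        manifest.record("score", ph, score_inputs, [templates_path, gsr_path])
    produced["score"] = [str(templates_path), str(gsr_path)]

    # -- deregulation ------------------------------------------------------
    dereg_paths = {s: out / f"dereg_{s}.tsv" for s in stages}
    if manifest.is_current("test", ph, [gsr_path]):
        logger.info("test: up to date")
        records_by_stage = {
            s: [
                deregulation.DeregulationRecord(
                    set_name=row["set"], stage_label=s,
                    p_value=row["p"], q_value=row["q"], rank=int(row["rank"]),
                )
                for _, row in pd.read_csv(dereg_paths[s], sep="\t").iterrows()
            ]
            for s in stages
        }
    else:
        records_by_stage = {}
        for s in stages:
            records = deregulation.test_deregulation(
                gsr, phenotypes, s, config.control_label
            )
            records_by_stage[s] = records
            deregulation.records_to_frame(records).to_csv(
                dereg_paths[s], sep="\t", index=False
            )
        manifest.record("test", ph, [gsr_path], list(dereg_paths.values()))
    produced["test"] = [str(p) for p in dereg_paths.values()]

    # -- set analysis ------------------------------------------------------
    venn_path = out / "venn.tsv"
    common_path = out / "common_sets.txt"
    test_outputs = sorted(dereg_paths.values())
    k = min(config.top_k, len(gsr.set_names))
    if manifest.is_current("venn", ph, test_outputs):
        logger.info("venn: up to date")
        common_members = common_path.read_text().split()
    else:
        venn = deregulation.top_k_set_analysis(records_by_stage, k=k)
        pd.DataFrame(
            sorted(venn.region_counts.items()), columns=["region", "count"]
        ).to_csv(venn_path, sep="\t", index=False)
        common_path.write_text("\n".join(venn.common_members) + "\n")
        common_members = venn.common_members
        manifest.record("venn", ph, test_outputs, [venn_path, common_path])
    produced["venn"] = [str(venn_path), str(common_path)]

    # -- progressive ranking ----------------------------------------------
    progressive_path = out / "progressive.tsv"
    if manifest.is_current("progressive", ph, test_outputs):
        logger.info("progressive: up to date")
    else:
        criteria = deregulation.ProgressiveCriteria(
            alpha=config.alpha,
            max_final_rank=config.max_final_rank,
            min_rank_drop=config.min_rank_drop,
        )
        selected = deregulation.select_progressive(
            records_by_stage, criteria, drop_mode=config.drop_mode
        )
        rows = [
            {"set": r.set_name,
             **{f"rank_{s}": rk for s, rk in zip(stages, r.ranks)}}
            for r in selected
        ]
        pd.DataFrame(rows, columns=["set", *(f"rank_{s}" for s in stages)]).to_csv(
            progressive_path, sep="\t", index=False
        )
        manifest.record("progressive", ph, test_outputs, [progressive_path])
    produced["progressive"] = [str(progressive_path)]

    # -- classification + clustering --------------------------------------
    report_path = out / "report.tsv"
    cluster_path = out / "cluster.tsv"
    if manifest.is_current("classify", ph, [gsr_path]):
        logger.info("classify: up to date")
    else:
        frames = []
        for s in stages:
            rep = clf.svm_cv(
                gsr, phenotypes, [s, config.control_label],
                n_folds=config.n_folds, n_repeats=config.n_repeats,
                C=config.svm_c, seed=config.seed,
            )
            frame = rep.to_frame()
            frame.insert(0, "comparison", f"{s}_vs_{config.control_label}")
            frames.append(frame)
        if len(stages) > 1:
            rep = clf.svm_cv(
                gsr, phenotypes, stages,
                n_folds=config.n_folds, n_repeats=config.n_repeats,
                C=config.svm_c, seed=config.seed,
            )
            frame = rep.to_frame()
            frame.insert(0, "comparison", "multiclass_" + "_".join(stages))
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(report_path, sep="\t", index=False)
        cluster = clf.cluster_group_means(
            gsr, phenotypes, groups=[config.control_label, *stages]
        )
        with cluster_path.open("w") as fh:
            fh.write("leaf_order\t" + ",".join(cluster.leaf_order) + "\n")
            for a, b, height in cluster.merge_sequence:
                fh.write(f"merge\t{','.join(a)}\t{','.join(b)}\t{height:.6g}\n")
        manifest.record("classify", ph, [gsr_path], [report_path, cluster_path])
    produced["classify"] = [str(report_path), str(cluster_path)]

    # -- network -----------------------------------------------------------
    net_path = out / "net.gml"
    if manifest.is_current("network", ph, [gsr_path, common_path]):
        logger.info("network: up to date")
    else:
        selected_sets = list(common_members)
        if len(selected_sets) < config.min_network_sets:
            # fall back to the final stage's top-k list
            final = deregulation.records_to_frame(records_by_stage[stages[-1]])
            selected_sets = final["set"].head(k).tolist()
        profiles = gsr.data.loc[sorted(selected_sets)]
        mim = network.mi_matrix(profiles, k=config.knn_k)
        edges = network.aracne_prune(
            mim, network.NetworkConfig(k=config.knn_k, tau=config.tau)
        )
        component = network.largest_component(edges)
        component.to_gml(net_path)
        logger.info(
            "network: %d sets, %d edges after pruning, largest component %d nodes",
            len(selected_sets), len(edges), len(component.nodes),
        )
        manifest.record("network", ph, [gsr_path, common_path], [net_path])
    produced["network"] = [str(net_path)]

    return produced
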