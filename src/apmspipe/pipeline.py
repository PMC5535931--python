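"""End-to-end pipeline orchestration.

``run_full_pipeline`` executes the stages in dependency order —
interactome -> differential -> methylproteome -> network — on a set of
input tables, writes one TSV per result type plus a JSON run report
carrying the resolved configuration and SHA-256 checksums of every input,
and guarantees bit-identical outputs for identical inputs and config.
Optional stages (methyl evidence, annotations) are skipped with a logged
notice when their inputs are absent; a stage error aborts the run, names
the stage, and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .design_io import (
    ValidationError,
    read_contaminant_profile,
    read_count_matrix,
    read_gmt,
    read_manifest,
    read_peptide_evidence,
    write_table,
)
from .differential import DifferentialRecord, differential_cascade
from .interactome import EnrichmentRecord, ScoreModel, Verdict, build_interactome
from .methylproteome import (
    CandidateTarget,
    MethylSite,
    call_methyl_sites,
    format_occupancy,
    panmethyl_enrichment,
    triangulate_targets,
)
from .network import TermEnrichment, mcl_cluster, term_enrichment

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline", "load_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold of the analysis in one auditable place."""

    floor: float = 0.1
    interactome_fc: float = 2.0
    differential_igg_fc: float = 1.5
    condition_fc: float = 2.0
    score_threshold: float = 0.8
    q_threshold: float = 0.05
    prior_true: float = 0.5
    contaminant_max_frequency: float = 0.5
    protein_prob_min: float = 0.999
    peptide_prob_min: float = 0.80
    panmethyl_ratio: float = 1.5
    mcl_inflation: float = 2.0
    dead_zone_low: float = 0.83
    dead_zone_high: float = 1.2
    min_coip_experiments: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "floor",
            "interactome_fc",
            "differential_igg_fc",
            "condition_fc",
            "score_threshold",
            "panmethyl_ratio",
            "mcl_inflation",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("protein_prob_min", "peptide_prob_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1]")


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Built-in defaults < config file < explicit overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, Mapping):
            raise ValidationError("config file must hold a mapping")
        unknown = set(loaded) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(
    config: PipelineConfig,
    manifest_path: str | Path,
    counts_path: str | Path,
    out_dir: str | Path,
    evidence_path: str | Path | None = None,
    contaminants_path: str | Path | None = None,
    annotations_path: str | Path | None = None,
    reference_path: str | Path | None = None,
) -> dict:
    """Run every applicable stage and write results under ``out_dir``.

    Returns the run report (also written as ``run_report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        "manifest": Path(manifest_path),
        "counts": Path(counts_path),
    }
    for name, p in (
        ("evidence", evidence_path),
        ("contaminants", contaminants_path),
        ("annotations", annotations_path),
        ("reference", reference_path),
    ):
        if p is not None:
            inputs[name] = Path(p)

    report: dict = {
        "pipeline_version": __version__,
        "config": asdict(config),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "stages": {},
        "outputs": [],
    }
    written: list[Path] = []

    def emit(records, name: str, cls=None) -> None:
        path = out / name
        write_table(records, path, cls=cls)
        written.append(path)
        report["outputs"].append(name)

    stage = "load"
    try:
        manifest = read_manifest(inputs["manifest"])
        matrix = read_count_matrix(inputs["counts"], manifest)
        profile = (
            read_contaminant_profile(inputs["contaminants"])
            if "contaminants" in inputs
            else None
        )
        reference = (
            set(Path(inputs["reference"]).read_text().split())
            if "reference" in inputs
            else None
        )

        stage = "interactome"
        logger.info("[interactome] %d proteins, %d samples", len(matrix.proteins), len(matrix.samples))
        records = build_interactome(
            matrix,
            manifest,
            model=ScoreModel(prior_true=config.prior_true, count_floor=config.floor),
            profile=profile,
            fc_threshold=config.interactome_fc,
            score_threshold=config.score_threshold,
            reference=reference,
            floor=config.floor,
            contaminant_max_frequency=config.contaminant_max_frequency,
            q_threshold=config.q_threshold,
        )
        emit(records, "interactome.tsv", cls=EnrichmentRecord)
        hc = [r.protein_id for r in records if r.verdict is Verdict.HIGH_CONFIDENCE]
        report["stages"]["interactome"] = {
            "status": "completed",
            "n_high_confidence": len(hc),
        }

        stage = "differential"
        diff = differential_cascade(
            matrix,
            manifest,
            floor=config.floor,
            igg_fc=config.differential_igg_fc,
            ratio_fc=config.condition_fc,
            dead_zone=(config.dead_zone_low, config.dead_zone_high),
        )
        emit(diff, "differential.tsv", cls=DifferentialRecord)
        report["stages"]["differential"] = {
            "status": "completed",
            "n_selective": sum(1 for d in diff if d.verdict.value == "selective"),
        }

        stage = "methylproteome"
        if "evidence" in inputs:
            evidence = read_peptide_evidence(inputs["evidence"])
            sites = call_methyl_sites(
                evidence,
                manifest,
                protein_prob_min=config.protein_prob_min,
                peptide_prob_min=config.peptide_prob_min,
            )
            emit(sites, "methyl_sites.tsv", cls=MethylSite)
            if manifest.pan_methyl_samples():
                pan = panmethyl_enrichment(
                    matrix, manifest, ratio_min=config.panmethyl_ratio, floor=config.floor
                )
            else:
                logger.warning("[methylproteome] no pan_methyl sample; enrichment skipped")
                pan = set()
            targets = triangulate_targets(
                sites, pan, matrix, manifest, min_experiments=config.min_coip_experiments
            )
            emit(targets, "candidate_targets.tsv", cls=CandidateTarget)
            report["stages"]["methylproteome"] = {
                "status": "completed",
                "n_sites": len(sites),
                "n_panmethyl_enriched": len(pan),
                "n_direct_candidates": sum(1 for t in targets if t.is_direct_candidate),
            }
        else:
            logger.warning("[methylproteome] no evidence table; stage skipped")
            report["stages"]["methylproteome"] = {"status": "skipped"}

        stage = "network"
        import networkx as nx

        hc_set = set(hc)
        if hc_set:
            # co-purification graph over high-confidence preys: edge weight =
            # number of bait samples detecting both preys
            baits = manifest.bait_samples()
            sub = (matrix.subset(baits).loc[sorted(hc_set)] > 0).to_numpy()
            ids = sorted(hc_set)
            g = nx.Graph()
            g.add_nodes_from(ids)
            co = sub @ sub.T
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if co[i, j] > 0:
                        g.add_edge(ids[i], ids[j], weight=float(co[i, j]))
            clusters = mcl_cluster(g, inflation=config.mcl_inflation)
            cluster_rows = [
                {"cluster": f"c{k + 1}", "protein_id": pid}
                for k, cl in enumerate(clusters)
                for pid in sorted(cl)
            ]
            import pandas as pd

            pd.DataFrame(cluster_rows, columns=["cluster", "protein_id"]).to_csv(
                out / "clusters.tsv", sep="\t", index=False
            )
            written.append(out / "clusters.tsv")
            report["outputs"].append("clusters.tsv")
            report["stages"]["network"] = {
                "status": "completed",
                "n_clusters": len(clusters),
            }
            if "annotations" in inputs:
                annotations = read_gmt(inputs["annotations"])
                enr: list[TermEnrichment] = []
                for cl in clusters:
                    enr.extend(term_enrichment(set(cl), annotations, hc_set))
                emit(enr, "term_enrichment.tsv", cls=TermEnrichment)
                report["stages"]["network"]["n_terms_tested"] = len(enr)
        else:
            logger.warning("[network] empty high-confidence set; stage skipped")
            report["stages"]["network"] = {"status": "skipped"}

    except Exception as exc:  # noqa: BLE001 - partial outputs must not survive
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, ValidationError):
            raise PipelineError(stage, exc) from exc
        raise PipelineError(stage, exc) from exc

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
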