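"""End-to-end orchestration: config validation, staged runs, manifest.

A single JSON run config drives the chem -> space -> cpa -> cluster stages in
order. Every stage writes its tables under the configured output directory;
outputs are written to ``<name>.partial`` first and renamed on stage success,
so an aborted run leaves only clearly marked partial files. The manifest
records package/library versions, the seed, every threshold, and SHA-256
digests of inputs and outputs; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io import read_compounds, read_feature_table, write_feature_table  # noqa: F401
from . import descriptors as desc
from . import chemspace
from . import profiles as prof
from . import clusters as clu

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_json``)."""

    output_dir: Path
    seed: int = 42
    compounds_path: Path | None = None
    compounds_format: str = "csv"
    plate_path: Path | None = None
    cluster_model_path: Path | None = None
    analysis: prof.AnalysisConfig = field(default_factory=prof.AnalysisConfig)
    descriptor_names: list[str] | None = None
    pca_components: int = 2
    umap_neighbors: int = 10
    enrichment_smarts: str = chemspace.AOHI_SMARTS

    def __post_init__(self) -> None:
        for label, p in (
            ("compounds", self.compounds_path),
            ("plate", self.plate_path),
            ("cluster_model", self.cluster_model_path),
        ):
            if p is not None and not Path(p).exists():
                raise ValueError(f"{label} path does not exist: {p}")
        if self.compounds_path is None and self.plate_path is None:
            raise ValueError("config must reference at least a compound set or a plate")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        analysis = prof.AnalysisConfig(**raw.get("analysis", {}))
        return cls(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 42)),
            compounds_path=Path(raw["compounds"]["path"]) if "compounds" in raw else None,
            compounds_format=raw.get("compounds", {}).get("format", "csv"),
            plate_path=Path(raw["plate"]["path"]) if "plate" in raw else None,
            cluster_model_path=(
                Path(raw["cluster_model"]["path"]) if "cluster_model" in raw else None
            ),
            analysis=analysis,
            descriptor_names=raw.get("descriptors"),
            pca_components=int(raw.get("pca", {}).get("k", 2)),
            umap_neighbors=int(raw.get("umap", {}).get("n_neighbors", 10)),
            enrichment_smarts=raw.get("enrichment_smarts", chemspace.AOHI_SMARTS),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageWriter:
    """Writes stage outputs via .partial files, renamed on stage success."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.pending: list[Path] = []
        self.finalized: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / f"{name}.partial"
        self.pending.append(p)
        return p

    def finish_stage(self) -> None:
        for p in self.pending:
            final = p.with_suffix("")
            p.rename(final)
            self.finalized.append(final)
        self.pending = []


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages and return the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    writer = _StageWriter(outdir)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "feature_significance_threshold": config.analysis.feature_significance_threshold,
            "activity_threshold_pct": config.analysis.activity_threshold,
            "similarity_threshold_pct": config.analysis.similarity_threshold,
            "robust_scale_constant": config.analysis.robust_scale_constant,
        },
        "inputs": {},
        "stages": [],
        "outputs": {},
    }
    for label, p in (
        ("compounds", config.compounds_path),
        ("plate", config.plate_path),
        ("cluster_model", config.cluster_model_path),
    ):
        if p is not None:
            manifest["inputs"][label] = {"path": Path(p).name, "sha256": _sha256(Path(p))}

    stage = "chem"
    try:
        compounds = None
        if config.compounds_path is not None:
            compounds = read_compounds(config.compounds_path, config.compounds_format)
            table = desc.descriptor_table(compounds, config.descriptor_names)
            table.values.to_csv(writer.path("descriptors.csv"))
            scores = pd.DataFrame(
                {
                    "compound_id": [r.compound_id for r in compounds],
                    "class_label": [r.class_label for r in compounds],
                    "qed": [desc.qed(r.structure) for r in compounds],
                    "sps": [desc.sps(r.structure) for r in compounds],
                    "nsps": [desc.nsps(r.structure) for r in compounds],
                }
            )
            scores.to_csv(writer.path("chem_scores.csv"), index=False)
            if len(compounds) >= 2:
                desc.tanimoto_matrix(compounds).values.to_csv(writer.path("tanimoto.csv"))
            writer.finish_stage()
            manifest["stages"].append(stage)

            stage = "space"
            pca = chemspace.pca_embed(table, config.pca_components)
            out = pca.coordinates.copy()
            out.to_csv(writer.path("pca.csv"))
            manifest["pca_explained_variance_pct"] = pca.explained_variance_pct
            if table.values.shape[0] > config.umap_neighbors:
                chemspace.umap_embed(
                    table, n_neighbors=config.umap_neighbors, seed=config.seed, normalize=True
                ).coordinates.to_csv(writer.path("chemspace_umap.csv"))
            enrich = chemspace.enrichment(compounds, config.enrichment_smarts)
            pd.DataFrame(
                [
                    {
                        "class_label": e.class_label,
                        "n_total": e.n_total,
                        "n_matching": e.n_matching,
                        "fraction": e.fraction,
                    }
                    for e in enrich
                ]
            ).to_csv(writer.path("enrichment.csv"), index=False)
            writer.finish_stage()
            manifest["stages"].append(stage)

        stage = "cpa"
        profiles = None
        if config.plate_path is not None:
            plate = read_feature_table(config.plate_path)
            profiles = prof.zscore_profiles(plate, config.analysis)
            prof.profiles_to_frame(profiles).to_csv(writer.path("profiles.csv"), index=False)
            if len(profiles) >= 2:
                prof.biosim_matrix(profiles, config.analysis).values.to_csv(
                    writer.path("biosim_matrix.csv")
                )
            writer.finish_stage()
            manifest["stages"].append(stage)

        stage = "cluster"
        if profiles is not None and config.cluster_model_path is not None:
            model = clu.ClusterModel.from_json(config.cluster_model_path)
            assignments = clu.assign_clusters(profiles, model, config.analysis)
            clu.assignments_to_frame(assignments).to_csv(writer.path("cluster_assignments.csv"))
            if len(profiles) > config.umap_neighbors:
                clu.profile_umap(
                    profiles, n_neighbors=config.umap_neighbors, seed=config.seed
                ).coordinates.to_csv(writer.path("profile_umap.csv"))
            writer.finish_stage()
            manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    for p in writer.finalized:
        manifest["outputs"][p.name] = _sha256(p)
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
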