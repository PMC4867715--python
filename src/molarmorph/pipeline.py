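"""End-to-end orchestration: io -> GPA -> PCA -> LDA -> report bundle.

The replication run reads per-tooth coordinate files plus a taxonomy table,
standardizes scale and side, superimposes everything jointly (fossils
included), fits the PCA, runs the discriminant analyses at all four
grouping levels with fossil posterior classification, and writes a CSV/YAML
report bundle. The synthetic benchmark sweeps the group-effect-to-noise
ratio and scores classification against the generating truth.
"""

from __future__ import annotations

import hashlib
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discriminant import GROUPING_LEVELS, run_all_ldas, summary_table
from .error_assessment import run_error_study
from .landmark_io import (
    ShapeDataset,
    assemble_dataset,
    read_coordinates_csv,
    read_taxonomy_csv,
    read_tps,
    standardize_dataset,
    write_coordinates_csv,
)
from .shape_pca import fit_pca, project
from .superimposition import gpa, project_new, tangent_project
from .synthetic_data import SynthSpec, generate, generate_repetition_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run (serialized into outputs)."""

    coordinates: dict = field(default_factory=dict)  # tooth -> path (tps or csv)
    taxonomy: str | None = None
    output_dir: str = "molarmorph_output"
    pca_scope: str = "all"            # or "extant_project_fossils"
    n_pcs: int | None = None          # None: auto (condition-number rule)
    priors: str = "equal"
    allow_reflection: bool = False
    flip_y: bool = False
    n_perm: int = 999
    seed: int = 0
    crossval: bool = True

    def __post_init__(self) -> None:
        if self.pca_scope not in ("all", "extant_project_fossils"):
            raise ValueError(f"unknown pca_scope {self.pca_scope!r}")
        if self.priors not in ("equal", "proportional"):
            raise ValueError(f"unknown priors {self.priors!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_tooth_dataset(config: RunConfig, tooth: str) -> ShapeDataset:
    path = Path(config.coordinates[tooth])
    if not path.exists():
        raise FileNotFoundError(f"coordinate file for {tooth} not found: {path}")
    if path.suffix.lower() == ".csv":
        configs = read_coordinates_csv(path)
    else:
        configs = read_tps(path, tooth)
    configs = standardize_dataset(configs, flip_y=config.flip_y)
    taxonomy = read_taxonomy_csv(config.taxonomy)
    return assemble_dataset(configs, taxonomy, tooth)


@dataclass
class ToothAnalysis:
    """All per-tooth intermediate results of a replication run."""

    tooth: str
    dataset: ShapeDataset
    aligned: "object"
    pca: "object"
    lda_results: dict
    fossil_scores: pd.DataFrame


def analyse_tooth(dataset: ShapeDataset, config: RunConfig) -> ToothAnalysis:
    """GPA (fossils included), PCA per ``pca_scope``, four LDAs with fossil
    posteriors."""
    ids = dataset.specimen_ids
    aligned = tangent_project(
        gpa(dataset.coords(ids), ids=ids, allow_reflection=config.allow_reflection)
    )
    extant = dataset.extant_ids
    fossils = dataset.fossil_ids

    include = ids if config.pca_scope == "all" else extant
    pca = fit_pca(aligned, include=include)

    tang = aligned.tangent_frame()
    extant_scores = project(pca, tang[[aligned.index_of(i) for i in extant]])
    fossil_scores = pd.DataFrame(
        project(pca, tang[[aligned.index_of(i) for i in fossils]]) if fossils else
        np.empty((0, pca.scores.shape[1])),
        index=fossils,
        columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
    )
    labels = {lvl: dataset.labels(lvl, extant) for lvl in GROUPING_LEVELS}
    lda_results = run_all_ldas(
        extant_scores,
        labels,
        unknown_scores=fossil_scores if len(fossil_scores) else None,
        n_components_in=config.n_pcs,
        priors=config.priors,
        crossval=config.crossval,
    )
    return ToothAnalysis(
        tooth=dataset.tooth,
        dataset=dataset,
        aligned=aligned,
        pca=pca,
        lda_results=lda_results,
        fossil_scores=fossil_scores,
    )


def write_tooth_reports(analysis: ToothAnalysis, outdir: Path) -> list[Path]:
    t = analysis.tooth
    written = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        p = outdir / name
        df.to_csv(p, index=index)
        written.append(p)

    save(analysis.pca.variance_frame(), f"variance_{t}.csv", index=False)
    save(analysis.pca.scores_frame(), f"scores_{t}.csv")
    save(
        pd.DataFrame(
            analysis.pca.loadings,
            index=[f"PC{i + 1}" for i in range(analysis.pca.loadings.shape[0])],
        ),
        f"loadings_{t}.csv",
    )
    cons = pd.DataFrame(analysis.aligned.consensus, columns=["x", "y"])
    cons.index = np.arange(1, len(cons) + 1)
    cons.index.name = "landmark"
    save(cons, f"consensus_{t}.csv")
    save(summary_table(analysis.lda_results), f"lda_summary_{t}.csv")
    for factor, res in analysis.lda_results.items():
        if res.posteriors is not None:
            post = res.posteriors.copy()
            post["predicted"] = res.predicted
            save(post, f"fossil_posteriors_{t}_{factor}.csv")
    return written


def run_replication(config: RunConfig) -> dict[str, ToothAnalysis]:
    """Full replication bundle over every tooth in ``config.coordinates``.

    On any stage failure the partially written output directory is removed
    and the stage-named error re-raised.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    analyses: dict[str, ToothAnalysis] = {}
    try:
        for tooth in sorted(config.coordinates):
            logger.info("processing %s", tooth)
            dataset = load_tooth_dataset(config, tooth)
            analysis = analyse_tooth(dataset, config)
            write_tooth_reports(analysis, outdir)
            write_coordinates_csv(
                dataset.configurations, outdir / f"standardized_coordinates_{tooth}.csv"
            )
            analyses[tooth] = analysis
        metadata = {
            "molarmorph_version": __version__,
            "config": asdict(config),
            "config_hash": config.digest(),
            "n_pcs_used": {
                t: {f: r.model.n_components_in for f, r in a.lda_results.items()}
                for t, a in analyses.items()
            },
            "n_specimens": {t: len(a.dataset.configurations) for t, a in analyses.items()},
        }
        with open(outdir / "run_metadata.yaml", "w") as fh:
            yaml.safe_dump(metadata, fh, sort_keys=False)
        config.to_yaml(outdir / "config.yaml")
    except Exception as exc:
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"replication run failed: {exc}") from exc
    return analyses


def analyse_synthetic(
    spec: SynthSpec, config: RunConfig | None = None
) -> tuple[ToothAnalysis, "object"]:
    """Generate a synthetic dataset and run the full per-tooth analysis,
    including the scale/side standardization a file-based run would get."""
    config = config or RunConfig(seed=spec.seed)
    dataset, truth = generate(spec)
    dataset = ShapeDataset(
        configurations=standardize_dataset(dataset.configurations, flip_y=config.flip_y),
        taxonomy=dataset.taxonomy,
        tooth=dataset.tooth,
    )
    return analyse_tooth(dataset, config), truth


def run_synthetic_benchmark(
    deltas: np.ndarray | list[float],
    within_sigma: float = 0.10,
    n_per_group: int = 20,
    n_replicates: int = 1,
    factor: str = "family",
    seed: int = 0,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross-validated pcc as a function of the group-effect / noise ratio.

    A reduced three-family design (``counts`` defaults to 3 one-species
    families of ``n_per_group`` specimens) keeps each grid point cheap.
    Returns one row per (delta, replicate) with pcc scored against the
    generating labels.
    """
    if counts is None:
        counts = pd.DataFrame(
            {
                "genus": ["GenA", "GenB", "GenC"],
                "species": ["GenA sp", "GenB sp", "GenC sp"],
                "n": [n_per_group] * 3,
                "subfamily_G": ["Cebinae", "Pitheciinae", "Atelinae"],
                "subfamily_R": ["Cebinae", "Pitheciinae", "Atelinae"],
                "family": ["Cebidae", "Pitheciidae", "Atelidae"],
            }
        )
    rows = []
    rng = np.random.default_rng(seed)
    for delta in deltas:
        for rep in range(n_replicates):
            spec = SynthSpec(
                taxonomy_counts=counts,
                group_effect=float(delta),
                within_sigma=within_sigma,
                n_fossils=0,
                seed=int(rng.integers(2**31 - 1)),
            )
            analysis, _ = analyse_synthetic(spec, RunConfig(crossval=True))
            res = analysis.lda_results[factor]
            rows.append(
                {
                    "delta": float(delta),
                    "sigma": within_sigma,
                    "delta_over_sigma": float(delta) / within_sigma if within_sigma else np.inf,
                    "replicate": rep,
                    "pcc_original": res.pcc_original,
                    "pcc_crossval": res.pcc_crossval,
                }
            )
    return pd.DataFrame(rows)


def run_error_study_pipeline(
    digit_sigma: float = 0.02,
    n_specimens: int = 5,
    n_rep: int = 9,
    n_perm: int = 999,
    seed: int = 0,
    group_by: str = "repetition",
):
    """Synthetic repeated-digitization study on distinct species means."""
    spec = SynthSpec(seed=seed)
    _, truth = generate(
        SynthSpec(taxonomy_counts=spec.counts().iloc[:n_specimens].assign(n=1), seed=seed)
    )
    bases = {s: m for s, m in list(truth.group_means.items())[:n_specimens]}
    study = generate_repetition_study(
        bases, n_rep=n_rep, digit_sigma=digit_sigma, seed=seed + 1
    )
    return run_error_study(study, n_perm=n_perm, seed=seed + 2, group_by=group_by)
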