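"""End-to-end driver: CFAB scoring -> DE -> association -> enrichment.

Runs one contrast (reference vs one aged group, within that group's
sequencing run), writes every stage's table under an output directory,
and records a manifest with input/config/output checksums so a rerun
with the same config is verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, cfab, diffexpr, enrichment
from . import io as ftx_io
from .errors import ConfigError, DomainError, PipelineError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    counts_path: str
    metadata_path: str
    gmt_path: str | None = None
    contrast: str = "6m:28m"
    reference_group: str = "6m"
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    r_moderate: float = 0.50
    r_strong: float = 0.70
    gsea_fdr: float = 0.25
    overrep_q: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    outdir: str = "ftx_out"

    def validate(self) -> None:
        for name in ("alpha", "lfc_threshold", "r_moderate", "r_strong", "gsea_fdr", "overrep_q"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not self.r_moderate < self.r_strong <= 1.0:
            raise ConfigError(
                f"need r_moderate < r_strong <= 1, got {self.r_moderate}, {self.r_strong}"
            )
        parts = self.contrast.split(":")
        if len(parts) != 2 or parts[0] != self.reference_group:
            raise ConfigError(f"contrast must be '{self.reference_group}:<old group>', got {self.contrast!r}")

    @property
    def old_group(self) -> str:
        return self.contrast.split(":")[1]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    cfab_scores: pd.DataFrame
    anova: cfab.AnovaResult
    de: pd.DataFrame
    normalized: pd.DataFrame
    associations: pd.DataFrame | None
    crosstab: pd.DataFrame | None
    overrep: pd.DataFrame | None
    gsea: pd.DataFrame | None
    intersection: list[str] = field(default_factory=list)
    outputs: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return decorator


def select_contrast_samples(meta: pd.DataFrame, reference: str, old: str) -> pd.DataFrame:
    """Samples of the two contrast groups, restricted to the old group's run.

    With re-prepared reference libraries (one per run), the contrast is
    analyzed within the run that carries the aged group, so each animal
    contributes exactly the libraries sequenced alongside that group.
    """
    in_groups = meta[meta["age_group"].isin([reference, old])]
    if in_groups.empty:
        raise DomainError(f"no samples in groups {reference!r}/{old!r}")
    old_runs = set(in_groups.loc[in_groups["age_group"] == old, "run"])
    if len(old_runs) == 1:
        run = next(iter(old_runs))
        selected = in_groups[in_groups["run"] == run]
        if set(selected["age_group"]) == {reference, old}:
            return selected
    return in_groups


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    counts_all = ftx_io.read_counts_tsv(config.counts_path)
    meta_all = ftx_io.read_metadata_tsv(config.metadata_path)
    missing = set(meta_all.index) - set(counts_all.sample_ids)
    if missing:
        raise DomainError(f"metadata samples absent from counts: {sorted(missing)[:5]}")

    result = PipelineResult(
        cfab_scores=None, anova=None, de=None, normalized=None,  # type: ignore[arg-type]
        associations=None, crosstab=None, overrep=None, gsea=None,
    )

    # --- CFAB scoring (all animals, reference-group standardization) ---
    scores, anova = _run_cfab(meta_all, config)
    result.cfab_scores, result.anova = scores, anova
    _write(scores, outdir / "cfab_scores.csv", outputs, index_label="animal_id")
    _write(anova.lsd.assign(F=anova.f, anova_pval=anova.pval), outdir / "cfab_anova_lsd.csv", outputs)

    # --- differential expression within the contrast ---
    meta = select_contrast_samples(meta_all, config.reference_group, config.old_group)
    counts = counts_all.subset_samples(meta.index)
    de, norm = _run_de(counts, meta, config)
    result.de, result.normalized = de, norm
    _write(de, outdir / "de_results.csv", outputs, index_label="gene_id")
    _write(norm, outdir / "normalized_log2.csv", outputs, index_label="gene_id")

    pca, pct = diffexpr.pca_scores(norm, n_components=min(2, len(meta) - 1))
    pca.attrs["percent_variance"] = list(pct)
    _write(pca, outdir / "pca_scores.csv", outputs, index_label="sample_id")

    degs = de.index[de["is_deg"]]
    if len(degs) > 0:
        # --- association screen on DEGs ---
        phenos = _phenotypes(meta, scores, config)
        assoc, crosstab = association.screen(
            norm.loc[degs],
            phenos,
            de["log2fc"],
            r_moderate=config.r_moderate,
            r_strong=config.r_strong,
        )
        assoc = assoc.merge(de[["padj"]], left_on="gene_id", right_index=True)
        result.associations, result.crosstab = assoc, crosstab
        _write(assoc, outdir / "associations.csv", outputs)
        _write(crosstab, outdir / "association_crosstab.csv", outputs)

    # --- enrichment + intersection ---
    if config.gmt_path and len(degs) > 0:
        collection = ftx_io.read_gmt(config.gmt_path)
        tested = de.index[np.isfinite(de["pval"])]
        overrep = enrichment.hypergeometric_enrichment(set(degs), set(tested), collection)
        ranked = de.loc[tested, "wald"].dropna()
        gsea = enrichment.gsea_preranked(
            ranked, collection, n_perm=config.n_perm, seed=config.seed, fdr_threshold=config.gsea_fdr
        )
        result.overrep, result.gsea = overrep, gsea
        overrep_genes = enrichment.enriched_term_genes(overrep, collection, config.overrep_q)
        gsea_genes = enrichment.gsea_leading_edge_genes(gsea, config.gsea_fdr)
        result.intersection = enrichment.intersect_methods(overrep_genes, gsea_genes, set(degs))
        _write(overrep, outdir / "overrep_enrichment.csv", outputs)
        _write(gsea, outdir / "gsea_results.csv", outputs)
        _write(
            pd.DataFrame({"gene_id": result.intersection}), outdir / "intersection_genes.csv", outputs
        )

    _write_manifest(config, outputs, outdir)
    result.outputs = outputs
    return result


@_stage("cfab")
def _run_cfab(meta_all: pd.DataFrame, config: PipelineConfig):
    records = cfab.records_from_frame(meta_all.reset_index())
    scores = cfab.score_cohort(records, reference_group=config.reference_group)
    anova = cfab.group_anova_lsd(scores["cfab"].to_numpy(), scores["age_group"].to_numpy())
    return scores, anova


@_stage("diffexpr")
def _run_de(counts, meta, config: PipelineConfig):
    factors = diffexpr.size_factors(counts)
    disp = diffexpr.estimate_dispersions(counts, factors, meta["age_group"].to_numpy())
    de = diffexpr.wald_test(
        counts,
        factors,
        disp,
        meta["age_group"].to_numpy(),
        reference=config.reference_group,
        alpha=config.alpha,
        lfc_threshold=config.lfc_threshold,
    )
    norm = diffexpr.normalized_log2(counts, factors)
    return de, norm


@_stage("association")
def _phenotypes(meta: pd.DataFrame, scores: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Per-sample phenotype columns: cfab, determinant z-scores, TA mass.

    Technical-replicate libraries reuse their animal's single phenotype
    values (libraries are kept separate, never averaged).
    """
    cols = {"cfab": scores["cfab"]}
    for name in cfab.DETERMINANTS:
        cols[name] = scores[f"z_{name}"]
    table = pd.DataFrame(cols)
    phenos = table.loc[meta["animal_id"]].set_axis(meta.index)
    if "ta_mass_mg" in meta.columns:
        phenos["ta_mass_mg"] = meta["ta_mass_mg"]
    return phenos


def _write(frame: pd.DataFrame, path: Path, outputs: dict, *, index_label=None) -> None:
    frame.to_csv(path, index=index_label is not None, index_label=index_label)
    outputs[path.name] = path


def _write_manifest(config: PipelineConfig, outputs: dict[str, Path], outdir: Path) -> None:
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("counts", config.counts_path),
                ("metadata", config.metadata_path),
                ("gmt", config.gmt_path),
            )
            if p
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    outputs["manifest.json"] = path


def verify_manifest(outdir) -> bool:
    """Re-hash every listed output and compare with the manifest."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json", encoding="utf-8") as handle:
        manifest = json.load(handle)
    return all(
        _sha256(outdir / name) == digest for name, digest in manifest["outputs"].items()
    )
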