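"""End-to-end orchestration: simulate -> quant -> groupstats -> geneassoc
-> exprcorr -> enrich, driven by one config, with a provenance manifest.

Every stage records its parameters and a SHA-256 checksum of each output
file in ``manifest.json``, so a run is self-describing and reruns under
the same seed can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import enrich as enrich_mod
from . import exprcorr, geneassoc, groupstats, p9quant, synth
from .sites import read_site_table

log = logging.getLogger("mtp9.pipeline")

STAGES = ("simulate", "quant", "groupstats", "geneassoc", "exprcorr", "enrich")


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serialisable).

    ``stages`` toggles each stage; ``input_dir`` points at an existing
    cohort directory when the simulate stage is off.
    """

    outdir: str = "mtp9_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    input_dir: str | None = None
    sim: dict[str, Any] = field(default_factory=dict)
    quant: dict[str, Any] = field(
        default_factory=lambda: {"min_baseq": 20, "min_depth": 10}
    )
    geneassoc: dict[str, Any] = field(
        default_factory=lambda: {
            "site": 585, "window": 10_000, "k_eigenvectors": 10,
            "prune_window": 50, "prune_step": 5, "prune_r2": 0.2,
            "method": "minp-perm", "n_perm": 10_000,
        }
    )
    exprcorr: dict[str, Any] = field(
        default_factory=lambda: {"site": 585, "top_n": 1000}
    )
    enrich: dict[str, Any] = field(
        default_factory=lambda: {"min_fold": 2.0, "max_q": 0.05,
                                 "alternative": "two-sided"}
    )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        cfg = cls()
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(val, Mapping):
                current.update(val)
            else:
                setattr(cfg, key, val)
        unknown = set(cfg.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) in config: {sorted(unknown)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict[str, Any]:
        return {
            "outdir": self.outdir, "seed": self.seed, "stages": dict(self.stages),
            "input_dir": self.input_dir, "sim": dict(self.sim),
            "quant": dict(self.quant), "geneassoc": dict(self.geneassoc),
            "exprcorr": dict(self.exprcorr), "enrich": dict(self.enrich),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str, what: str) -> Path:
    if not path.exists():
        raise PipelineError(stage, f"missing upstream input: {what} ({path})")
    return path


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": config.to_dict(), "stages": {}}

    def record(stage: str, params: Mapping[str, Any], files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "params": dict(params),
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in sorted(files)},
        }

    sim_dir = out / "sim"
    if config.stages.get("simulate", True):
        try:
            cfg = synth.SimConfig(**config.sim, seed=config.seed)
            synth.simulate_cohort(cfg, sim_dir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        files = [p for p in sim_dir.rglob("*") if p.is_file()]
        record("simulate", config.sim | {"seed": config.seed}, files)
        data_dir = sim_dir
    else:
        if config.input_dir is None:
            raise PipelineError("simulate", "stage disabled but no input_dir given")
        data_dir = Path(config.input_dir)

    quant_dir = out / "quant"
    if config.stages.get("quant", True):
        try:
            sites = read_site_table(_require(data_dir / "sites.tsv", "quant", "site table"))
            _require(data_dir / "pileups", "quant", "pileup directory")
            matrix, long = p9quant.quantify_directory(
                data_dir / "pileups", sites, **config.quant
            )
            quant_dir.mkdir(exist_ok=True)
            p9quant.write_profile_matrix(matrix, quant_dir / "matrix.tsv")
            long.to_csv(quant_dir / "long.tsv", sep="\t", index=False,
                        float_format="%.10g")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("quant", str(exc)) from exc
        record("quant", config.quant, [quant_dir / "matrix.tsv", quant_dir / "long.tsv"])

    def load_matrix() -> pd.DataFrame:
        return p9quant.read_profile_matrix(
            _require(quant_dir / "matrix.tsv", "groupstats", "AAF matrix")
        )

    def load_meta() -> pd.DataFrame:
        return pd.read_csv(
            _require(data_dir / "metadata.tsv", "groupstats", "metadata"),
            sep="\t", index_col=0,
        )

    if config.stages.get("groupstats", True):
        try:
            matrix, meta = load_matrix(), load_meta()
            gdir = out / "groupstats"
            gdir.mkdir(exist_ok=True)
            table = groupstats.table_by_site(matrix, meta)
            table.to_csv(gdir / "table_by_site.tsv", sep="\t", float_format="%.6g")
            rho, pval = groupstats.spearman_matrix(matrix)
            rho.to_csv(gdir / "spearman_rho.tsv", sep="\t", float_format="%.6g")
            pval.to_csv(gdir / "spearman_p.tsv", sep="\t", float_format="%.6g")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("groupstats", str(exc)) from exc
        record("groupstats", {}, list(gdir.glob("*.tsv")))

    if config.stages.get("geneassoc", True):
        try:
            ga = config.geneassoc
            matrix, meta = load_matrix(), load_meta()
            geno = geneassoc.GenotypeMatrix.from_tsv(
                _require(data_dir / "genotypes.tsv", "geneassoc", "genotype table")
            )
            annot = pd.read_csv(
                _require(data_dir / "genes.tsv", "geneassoc", "gene annotation"),
                sep="\t", index_col=0,
            )
            kept = geneassoc.ld_prune(
                geno, window=ga["prune_window"], step=ga["prune_step"],
                r2_max=ga["prune_r2"],
            )
            pruned = geneassoc.GenotypeMatrix(
                snps=geno.snps.loc[kept], dosage=geno.dosage[kept]
            )
            k = min(ga["k_eigenvectors"], len(meta) - 2)
            ev, _ = geneassoc.pca_eigenvectors(pruned, k=k)
            pheno = geneassoc.log10_phenotype(matrix[ga["site"]])
            covs = pd.concat(
                [meta[["age"]].astype(float),
                 (meta["sex"] == "F").astype(float).rename("sex"), ev],
                axis=1,
            )
            snp_res = geneassoc.snp_assoc(pruned.dosage, pheno, covs)
            mapping = geneassoc.map_snps_to_genes(
                pruned.snps, annot, window=ga["window"]
            )
            genes = geneassoc.gene_p(
                snp_res, mapping, method=ga["method"], n_perm=ga["n_perm"],
                seed=config.seed, dosage=pruned.dosage, phenotype=pheno,
                covariates=covs,
            )
            adir = out / "geneassoc"
            adir.mkdir(exist_ok=True)
            snp_res.to_csv(adir / "snp_assoc.tsv", sep="\t", float_format="%.6g")
            genes.to_csv(adir / "gene_assoc.tsv", sep="\t", float_format="%.6g")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("geneassoc", str(exc)) from exc
        record(
            "geneassoc",
            ga | {"n_snps_kept": len(kept), "threshold": genes.attrs["threshold"]},
            list(adir.glob("*.tsv")),
        )

    top_genes: list[str] = []
    if config.stages.get("exprcorr", True):
        try:
            ec = config.exprcorr
            matrix = load_matrix()
            counts = pd.read_csv(
                _require(data_dir / "counts.tsv", "exprcorr", "count matrix"),
                sep="\t", index_col=0,
            )
            t2g = pd.read_csv(
                _require(data_dir / "t2g.tsv", "exprcorr", "transcript-gene map"),
                sep="\t", index_col=0,
            )
            factors = exprcorr.tmm_factors(counts)
            norm = exprcorr.cpm(counts, factors, log=True)
            corr = exprcorr.correlate_with_methylation(norm, matrix[ec["site"]])
            top_t, top_genes = exprcorr.select_top(corr, n=ec["top_n"], t2g=t2g)
            edir = out / "exprcorr"
            edir.mkdir(exist_ok=True)
            factors.to_frame().to_csv(edir / "tmm_factors.tsv", sep="\t",
                                      float_format="%.10g")
            corr.to_csv(edir / "correlations.tsv", sep="\t", float_format="%.6g")
            (edir / "top_transcripts.txt").write_text("\n".join(top_t) + "\n")
            (edir / "top_genes.txt").write_text("\n".join(top_genes) + "\n")
            sub = norm.loc[top_t]
            structure = exprcorr.heatmap_structure(sub)
            (edir / "row_dendrogram.nwk").write_text(
                exprcorr.linkage_to_newick(
                    structure["row_linkage"], list(structure["scaled"].index)
                ) + "\n"
            )
            (edir / "col_dendrogram.nwk").write_text(
                exprcorr.linkage_to_newick(
                    structure["col_linkage"], list(structure["scaled"].columns)
                ) + "\n"
            )
            scores, var = exprcorr.pca_samples(structure["scaled"])
            scores.to_csv(edir / "pca_scores.tsv", sep="\t", float_format="%.6g")
            pd.Series(var, index=scores.columns, name="var_explained").to_csv(
                edir / "pca_variance.tsv", sep="\t", float_format="%.6g"
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("exprcorr", str(exc)) from exc
        record("exprcorr", ec, [p for p in edir.glob("*") if p.is_file()])

    if config.stages.get("enrich", True):
        try:
            en = config.enrich
            if not top_genes:
                top_path = _require(
                    out / "exprcorr" / "top_genes.txt", "enrich", "top gene list"
                )
                top_genes = top_path.read_text().split()
            t2g = pd.read_csv(
                _require(data_dir / "t2g.tsv", "enrich", "transcript-gene map"),
                sep="\t", index_col=0,
            )
            terms = enrich_mod.load_gmt(
                _require(data_dir / "genesets.gmt", "enrich", "GMT file")
            )
            background = list(dict.fromkeys(t2g["gene"]))
            rows = enrich_mod.overrepresentation(
                top_genes, terms, background, alternative=en["alternative"]
            )
            filtered = enrich_mod.filter_fold(
                rows, min_fold=en["min_fold"], max_q=en["max_q"]
            )
            ndir = out / "enrich"
            ndir.mkdir(exist_ok=True)
            rows.to_csv(ndir / "enrichment.tsv", sep="\t", float_format="%.6g")
            filtered.to_csv(ndir / "enrichment_filtered.tsv", sep="\t",
                            float_format="%.6g")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc
        record("enrich", en, list(ndir.glob("*.tsv")))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
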