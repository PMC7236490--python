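"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a post-mortem brain RNA-seq study of
mitochondrial tRNA p9 methylation in four diagnosis groups (normal control
NC, Alzheimer's disease AD, progressive supranuclear palsy PSP, pathological
aging PA):

* per-sample, per-site methylation fractions drawn from Beta distributions,
  with an additive mean shift in the AD and PSP groups (the tauopathy
  hypermethylation contrast);
* RNA-seq pileups at the 11 p9 sites where a methylated template produces a
  non-reference base call with probability ``rho_misincorp`` and every base
  carries a sequencing-error floor ``eps_err``, so the per-read probability
  of an alternative call is

      p_alt = m * rho * (1 - eps) + (1 - m * rho) * eps;

* one causal nuclear SNP with an additive effect ``causal_beta`` on
  log10 methylation at site 585, placed inside an annotated gene;
* negative-binomial transcript counts with heterogeneous library sizes,
  where a known subset of transcripts is driven by site-585 methylation;
* a GMT file whose planted term collects the genes of those driven
  transcripts.

Everything is reproducible from ``SimConfig.seed``; two runs with the same
seed write byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sites import P9Site, P9_POSITIONS, sites_from_reference, write_site_table

GROUPS = ("NC", "AD", "PSP", "PA")
SHIFTED_GROUPS = frozenset({"AD", "PSP"})

#: Table-1-like age distributions (mean, sd) per diagnosis, truncated [55, 100].
AGE_PARAMS: dict[str, tuple[float, float]] = {
    "NC": (82.9, 7.8),
    "AD": (82.6, 7.6),
    "PSP": (74.0, 6.6),
    "PA": (84.5, 4.3),
}

#: Group sizes of the real cohort (266 subjects total).
STUDY_GROUP_SIZES: dict[str, int] = {"NC": 74, "AD": 82, "PSP": 83, "PA": 27}

_BASES = np.array(list("ACGT"))
_Q_HIGH, _Q_LOW = chr(33 + 30), chr(33 + 10)  # two-spike base qualities Q30 / Q10
_P_HIGH_QUAL = 0.85


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``n_per_group`` may be a single count applied to every group or a
    mapping group -> count. Methylation per sample and site is
    Beta(mean * beta_conc, (1 - mean) * beta_conc) with mean
    ``methyl_base`` in NC/PA and ``methyl_base + methyl_shift`` in AD/PSP.
    """

    n_per_group: int | Mapping[str, int] = 40
    depth_mean: float = 1000.0
    methyl_base: float = 0.10
    methyl_shift: float = 0.05
    beta_conc: float = 50.0
    rho_misincorp: float = 1.0
    eps_err: float = 0.001
    n_snps: int = 200
    snps_per_gene: int = 10
    causal_beta: float = 0.12
    n_transcripts: int = 2000
    n_linked: int = 100
    link_beta: float = 1.0
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def group_sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_group, Mapping):
            return {g: int(self.n_per_group[g]) for g in GROUPS}
        return {g: int(self.n_per_group) for g in GROUPS}

    def validate(self) -> None:
        for name in ("methyl_base", "rho_misincorp", "eps_err"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.methyl_base + self.methyl_shift <= 1.0:
            raise ValueError("methyl_base + methyl_shift must stay in [0, 1]")
        if self.rho_misincorp < self.eps_err:
            raise ValueError("rho_misincorp must be >= eps_err")
        if any(n <= 0 for n in self.group_sizes().values()):
            raise ValueError("group sizes must be positive")
        for name in ("depth_mean", "beta_conc", "n_snps", "n_transcripts", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_linked > self.n_transcripts:
            raise ValueError("n_linked cannot exceed n_transcripts")
        lo, hi = self.libsize_range
        if not 0 < lo <= hi:
            raise ValueError("libsize_range must be 0 < lo <= hi")


def study_sizes(**overrides) -> SimConfig:
    """SimConfig preset with the study's group sizes (74/82/83/27)."""
    return SimConfig(n_per_group=dict(STUDY_GROUP_SIZES), **overrides)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    methyl_true: pd.DataFrame            # sample x site fractions
    causal_snp_id: str
    causal_gene: str
    linked_transcripts: list[str]
    group_of: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "methyl_true": {
                s: {str(p): round(float(v), 10) for p, v in row.items()}
                for s, row in self.methyl_true.iterrows()
            },
            "causal_snp_id": self.causal_snp_id,
            "causal_gene": self.causal_gene,
            "linked_transcripts": list(self.linked_transcripts),
            "group_of": dict(self.group_of),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        mt = pd.DataFrame.from_dict(d["methyl_true"], orient="index")
        mt.columns = [int(c) for c in mt.columns]
        mt = mt[sorted(mt.columns)]
        mt.index.name = "sample"
        return cls(
            methyl_true=mt,
            causal_snp_id=d["causal_snp_id"],
            causal_gene=d["causal_gene"],
            linked_transcripts=list(d["linked_transcripts"]),
            group_of=dict(d["group_of"]),
        )


# ---------------------------------------------------------------------------
# reference & pileups

def simulate_reference(
    length: int = 16569, seed: int = 0
) -> tuple[str, list[P9Site]]:
    """Random A/C/G/T mitochondrial reference plus the 11-site p9 table.

    ``length`` must cover the largest p9 coordinate (14,734).
    """
    max_pos = max(P9_POSITIONS)
    if length < max_pos:
        raise ValueError(
            f"reference length {length} is below the largest p9 position {max_pos}"
        )
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(_BASES, size=length))
    return seq, sites_from_reference(seq)


def write_fasta(sequence: str, path: str | Path, name: str = "chrM") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def alt_call_probability(m: float, rho: float, eps: float) -> float:
    """Per-read probability of a non-reference call at methylation m."""
    return m * rho * (1.0 - eps) + (1.0 - m * rho) * eps


def simulate_site_pileup(
    depth: int,
    m: float,
    rho: float,
    eps: float,
    ref_base: str,
    seed: int | np.random.Generator = 0,
):
    """Simulate quality-agnostic allele counts at one site.

    Non-reference calls are Binomial(depth, p_alt) and split uniformly over
    the three non-reference bases; strands are assigned 50/50. Returns a
    :class:`~mtp9.p9quant.SiteAlleleCounts` with position 0 placeholder.
    """
    from .p9quant import SiteAlleleCounts

    for name, v in (("m", m), ("rho", rho), ("eps", eps)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_alt = alt_call_probability(m, rho, eps)
    n_alt = rng.binomial(depth, p_alt)
    alt_bases = [b for b in "ACGT" if b != ref_base]
    alt_counts = rng.multinomial(n_alt, [1 / 3] * 3)
    counts = {b: 0 for b in "ACGT"}
    counts[ref_base] = depth - n_alt
    for b, c in zip(alt_bases, alt_counts):
        counts[b] = int(c)
    fwd = {b: int(rng.binomial(c, 0.5)) for b, c in counts.items()}
    rev = {b: counts[b] - fwd[b] for b in counts}
    return SiteAlleleCounts(
        sample_id="", position=0, counts=counts, fwd_counts=fwd, rev_counts=rev,
        depth_kept=depth, depth_raw=depth,
    )


def _pileup_line(
    position: int, ref_base: str, counts: Mapping[str, int],
    fwd: Mapping[str, int], rng: np.random.Generator,
) -> str:
    """Render one mpileup line with two-spike base qualities and read marks."""
    tokens: list[str] = []
    for b in "ACGT":
        nf = fwd[b]
        nr = counts[b] - nf
        if b == ref_base:
            tokens += ["."] * nf + [","] * nr
        else:
            tokens += [b] * nf + [b.lower()] * nr
    order = rng.permutation(len(tokens))
    tokens = [tokens[i] for i in order]
    quals = np.where(rng.random(len(tokens)) < _P_HIGH_QUAL, _Q_HIGH, _Q_LOW)
    if tokens:
        tokens[0] = "^]" + tokens[0]       # read-start mark exercises the parser
        tokens[-1] = tokens[-1] + "$"
    return "\t".join(
        ["chrM", str(position), ref_base, str(len(order)), "".join(tokens), "".join(quals)]
    )


# ---------------------------------------------------------------------------
# in-memory cohort pieces

def _sample_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for g in GROUPS:
        n = cfg.group_sizes()[g]
        mu, sd = AGE_PARAMS[g]
        ages = np.empty(n)
        filled = 0
        while filled < n:             # truncated normal [55, 100] by rejection
            draw = rng.normal(mu, sd, size=n - filled)
            ok = draw[(draw >= 55) & (draw <= 100)]
            ages[filled : filled + len(ok)] = ok
            filled += len(ok)
        for i in range(n):
            rows.append((f"{g}{i + 1:03d}", g, round(float(ages[i]), 1), "F" if i % 2 else "M"))
    return pd.DataFrame(rows, columns=["sample", "diagnosis", "age", "sex"]).set_index("sample")


def simulate_methylation(
    cfg: SimConfig, rng: np.random.Generator, meta: pd.DataFrame
) -> pd.DataFrame:
    """Draw true methylation fractions (sample x 11 sites) from the group Betas."""
    n = len(meta)
    means = np.where(
        meta["diagnosis"].isin(SHIFTED_GROUPS).to_numpy()[:, None],
        cfg.methyl_base + cfg.methyl_shift,
        cfg.methyl_base,
    )
    a = means * cfg.beta_conc
    b = (1.0 - means) * cfg.beta_conc
    m = rng.beta(np.broadcast_to(a, (n, 11)), np.broadcast_to(b, (n, 11)))
    return pd.DataFrame(m, index=meta.index, columns=list(P9_POSITIONS))


def _apply_causal_effect(
    methyl: pd.DataFrame, dosage: np.ndarray, beta: float, site: int = 585
) -> None:
    """Additive effect of the causal SNP on log10 methylation at one site."""
    m = methyl[site].to_numpy() * np.power(10.0, beta * dosage)
    methyl[site] = np.clip(m, 1e-4, 0.999)


def _simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator, samples: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, str, str]:
    """Independent SNPs on one nuclear chromosome, tiled into genes.

    Returns (snp table, dosage sample x snp, gene annotation, causal snp id,
    causal gene id).
    """
    n_snps, per_gene = cfg.n_snps, cfg.snps_per_gene
    mafs = rng.uniform(0.1, 0.5, size=n_snps)
    n_genes_total = n_snps // per_gene
    causal_gene_idx = int(rng.integers(n_genes_total))
    causal_snp_idx = causal_gene_idx * per_gene + per_gene // 2
    mafs[causal_snp_idx] = 0.3  # common causal variant: fixed MAF keeps power analytic
    pos = 10_000 + 5_000 * np.arange(n_snps)
    snp_ids = [f"rs{i + 1:05d}" for i in range(n_snps)]
    snps = pd.DataFrame({"snp": snp_ids, "chrom": "1", "pos": pos}).set_index("snp")
    dosage = pd.DataFrame(
        rng.binomial(2, mafs, size=(len(samples), n_snps)),
        index=pd.Index(samples, name="sample"), columns=snp_ids,
    )
    n_genes = n_snps // per_gene
    genes = []
    for j in range(n_genes):
        lo, hi = j * per_gene, (j + 1) * per_gene - 1
        genes.append((f"G{j + 1:03d}", "1", int(pos[lo]) - 2_000, int(pos[hi]) + 2_000))
    gene_df = pd.DataFrame(genes, columns=["gene", "chrom", "start", "end"]).set_index("gene")
    return snps, dosage, gene_df, snp_ids[causal_snp_idx], gene_df.index[causal_gene_idx]


def _simulate_expression(
    cfg: SimConfig, rng: np.random.Generator, meta: pd.DataFrame, m585: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """NB counts (transcript x sample) with a methylation-driven subset."""
    n_t, n_s = cfg.n_transcripts, len(meta)
    t_ids = [f"T{i + 1:05d}" for i in range(n_t)]
    g_ids = [f"EG{i // 2 + 1:05d}" for i in range(n_t)]  # two transcripts per gene
    t2g = pd.DataFrame({"transcript": t_ids, "gene": g_ids}).set_index("transcript")
    log_mu0 = rng.normal(4.0, 1.0, size=n_t)
    libfac = rng.uniform(*cfg.libsize_range, size=n_s)
    linked_idx = rng.choice(n_t, size=cfg.n_linked, replace=False)
    z = (m585 - m585.mean()) / m585.std(ddof=0)
    log_mu = np.tile(log_mu0[:, None], (1, n_s))
    signs = np.where(rng.random(cfg.n_linked) < 0.5, -1.0, 1.0)
    log_mu[linked_idx] += cfg.link_beta * signs[:, None] * z[None, :]
    mu = np.exp(log_mu) * libfac[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(t_ids, name="transcript"), columns=meta.index)
    linked = [t_ids[i] for i in sorted(linked_idx)]
    return counts_df, t2g, linked


def _write_gmt(
    path: Path, linked_genes: list[str], background: list[str], rng: np.random.Generator
) -> None:
    planted = sorted(set(linked_genes))[:60]
    lines = ["\t".join(["PLANTED_LINKED", "genes of methylation-driven transcripts"] + planted)]
    others = sorted(set(background) - set(planted))
    for k in range(19):
        size = min(int(rng.integers(20, 60)), len(others))
        if size == 0:
            break
        members = sorted(rng.choice(others, size=size, replace=False))
        lines.append("\t".join([f"RANDOM_{k + 1:02d}", "random background term"] + list(members)))
    path.write_text("\n".join(lines) + "\n")


def simulate_aaf(
    cfg: SimConfig, seed: int | None = None, with_genotypes: bool = False
):
    """Fast in-memory cohort: metadata, true methylation, observed AAF.

    Skips pileup text entirely: the observed AAF at each site is
    Binomial(depth, p_alt)/depth with depth ~ Poisson(depth_mean). When
    ``with_genotypes`` the causal-SNP effect on site 585 is applied and the
    dosage tables are returned too. Used by repeated-simulation studies
    where file round-trips would dominate runtime.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    meta = _sample_table(cfg, rng)
    methyl = simulate_methylation(cfg, rng, meta)
    geno = None
    if with_genotypes:
        snps, dosage, gene_df, causal_snp, causal_gene = _simulate_genotypes(
            cfg, rng, list(meta.index)
        )
        _apply_causal_effect(methyl, dosage[causal_snp].to_numpy(float), cfg.causal_beta)
        geno = {
            "snps": snps, "dosage": dosage, "genes": gene_df,
            "causal_snp_id": causal_snp, "causal_gene": causal_gene,
        }
    depth = rng.poisson(cfg.depth_mean, size=methyl.shape)
    p_alt = alt_call_probability(methyl.to_numpy(), cfg.rho_misincorp, cfg.eps_err)
    alt = rng.binomial(depth, p_alt)
    with np.errstate(invalid="ignore"):
        aaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    aaf = pd.DataFrame(aaf, index=meta.index, columns=methyl.columns)
    if with_genotypes:
        return meta, methyl, aaf, geno
    return meta, methyl, aaf


def simulate_cohort(cfg: SimConfig, outdir: str | Path) -> SimulationTruth:
    """Write a full synthetic cohort to ``outdir`` and return its truth.

    Files written: ``reference.fa``, ``sites.tsv``, ``pileups/<sample>.pileup``,
    ``metadata.tsv``, ``genotypes.tsv``, ``genes.tsv``, ``counts.tsv``,
    ``t2g.tsv``, ``genesets.gmt``, ``truth.json``. Byte-identical across
    runs with equal seeds.
    """
    cfg.validate()
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "pileups").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    rng = np.random.default_rng(cfg.seed)
    sequence, sites = simulate_reference(seed=int(rng.integers(2**31)))
    write_fasta(sequence, outdir / "reference.fa")
    write_site_table(sites, outdir / "sites.tsv")

    meta = _sample_table(cfg, rng)
    meta.to_csv(outdir / "metadata.tsv", sep="\t")

    methyl = simulate_methylation(cfg, rng, meta)
    snps, dosage, gene_df, causal_snp, causal_gene = _simulate_genotypes(
        cfg, rng, list(meta.index)
    )
    _apply_causal_effect(methyl, dosage[causal_snp].to_numpy(float), cfg.causal_beta)

    geno_out = snps.copy()
    geno_out = pd.concat([geno_out, dosage.T], axis=1)
    geno_out.to_csv(outdir / "genotypes.tsv", sep="\t")
    gene_df.to_csv(outdir / "genes.tsv", sep="\t")

    ref_by_pos = {s.position: s.ref_base for s in sites}
    for sample in meta.index:
        lines = []
        for pos in P9_POSITIONS:
            depth = int(rng.poisson(cfg.depth_mean))
            sc = simulate_site_pileup(
                depth, float(methyl.at[sample, pos]), cfg.rho_misincorp,
                cfg.eps_err, ref_by_pos[pos], rng,
            )
            lines.append(_pileup_line(pos, ref_by_pos[pos], sc.counts, sc.fwd_counts, rng))
        (outdir / "pileups" / f"{sample}.pileup").write_text("\n".join(lines) + "\n")

    counts_df, t2g, linked = _simulate_expression(
        cfg, rng, meta, methyl[585].to_numpy()
    )
    counts_df.to_csv(outdir / "counts.tsv", sep="\t")
    t2g.to_csv(outdir / "t2g.tsv", sep="\t")
    linked_genes = sorted(t2g.loc[linked, "gene"].unique())
    _write_gmt(outdir / "genesets.gmt", linked_genes, list(t2g["gene"].unique()), rng)

    truth = SimulationTruth(
        methyl_true=methyl,
        causal_snp_id=causal_snp,
        causal_gene=causal_gene,
        linked_transcripts=linked,
        group_of=dict(meta["diagnosis"]),
    )
    truth.to_json(outdir / "truth.json")
    return truth
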