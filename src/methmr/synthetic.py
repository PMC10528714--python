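"""Synthetic study generator with known causal ground truth.

Emulates, at desk scale, the statistical structure of the data the
screen consumes: a block-LD genotype reference panel, an EWAS-style
candidate CpG list, two mQTL cohorts (discovery and replication, shared
truth, independent sampling noise), an eQTL cohort, GWAS traits with
polygenic background, and gene sets.

Every CpG carries one causal topology:

* ``mediation``  — SNPs -> CpG -> gene -> trait (the signal the screen
  should recover),
* ``pleiotropy`` — the CpG has several cis mQTLs, one of which also hits
  the trait directly (exposure <- SNP -> outcome),
* ``linkage``    — one SNP drives the CpG, a *different* SNP in LD drives
  the trait,
* ``reverse``    — SNPs drive the trait and the trait drives the CpG,
* ``null``       — SNPs drive the CpG only.

Summary statistics are produced by explicit per-individual simulation and
per-SNP least-squares regression (never by sampling Z-scores directly),
so allele frequencies, LD and delta-method behaviour are internally
consistent.  Phenotype effects are expressed per standard deviation of
genotype using the *theoretical* dosage SD sqrt(2f(1-f)), keeping betas
comparable across cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .ld import LdPanel
from .sumstats_io import (
    GeneSet,
    QtlProbeSet,
    SumStatRecord,
    write_gmt,
    write_gwas_ma,
    write_qtl_table,
)

log = logging.getLogger(__name__)

Topology = Literal["mediation", "pleiotropy", "linkage", "reverse", "null"]

_NONPAL_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PAL_PAIRS = [("A", "T"), ("C", "G")]


class ScenarioSpec(BaseModel):
    """Study-design parameters; defaults are the package's reference study.

    Sample sizes mirror the source cohorts at desk scale: ~2,000 per mQTL
    cohort (methylation panels of that order), 5,000 for the eQTL cohort
    and 20,000 for each GWAS trait (consortium GWAS scaled down so a full
    run stays in CPU-minutes).
    """

    seed: int = 0

    # cohort sizes
    n_ref: int = 500
    n_mqtl_disc: int = 2000
    n_mqtl_repl: int = 2000
    n_eqtl: int = 5000
    n_gwas: int = 20000

    # CpG topology census (total = number of candidate CpGs)
    n_mediation: int = 5
    n_pleiotropy: int = 10
    n_linkage: int = 10
    n_reverse: int = 10
    n_null: int = 65

    n_traits: int = 3
    causal_genes_per_trait: int = 4   # standalone genes driving the trait
    decoy_genes_per_trait: int = 4    # standalone genes with eQTLs only
    background_blocks_per_trait: int = 6

    # LD structure: one block per CpG / standalone gene / background locus;
    # rho is the AR(1) latent correlation between adjacent SNPs
    snps_per_block: int = 25
    rho_cpg_block: float = 0.90       # causal SNPs 8 apart stay clump-separable
    rho_linkage_block: float = 0.986  # dosage r2 ~0.5 at the 12-SNP offset
    rho_gene_block: float = 0.55      # eQTLs 6 apart are near linkage equilibrium
    rho_background_block: float = 0.90
    maf_min: float = 0.05
    maf_max: float = 0.5
    frac_palindromic: float = 0.1

    # effect sizes (variance fractions on the standardized scale)
    mediation_h2: tuple[float, float, float] = (0.15, 0.10, 0.06)
    b_cpg_gene: float = 0.6
    b_gene_trait: float = 0.35        # sign alternates across mediation CpGs
    pleiotropy_trait_h2: float = 0.004
    linkage_cpg_h2: float = 0.15
    linkage_trait_h2: float = 0.01
    reverse_trait_h2: tuple[float, float] = (0.03, 0.02)
    b_trait_cpg: float = 0.9
    background_h2: float = 0.004
    pathway_eqtl_h2: tuple[float, ...] = (0.02, 0.05, 0.09, 0.14)
    b_pathway_gene_trait: float = 0.2
    trait_noise_var: float = 0.5

    # smoking as the upstream exposure behind the candidate list
    simulate_smoking: bool = True
    smoking_prevalence: float = 0.25
    b_smoking: float = 0.15

    # which trans records each probe/gene set carries besides its cis block
    gwas_sig_p: float = 5e-8
    flip_fraction: float = 0.3        # per-dataset allele-orientation jitter

    @property
    def n_cpgs(self) -> int:
        return (self.n_mediation + self.n_pleiotropy + self.n_linkage
                + self.n_reverse + self.n_null)

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.trait_noise_var):
            raise ValueError("trait_noise_var must be > 0")
        for name in ("rho_cpg_block", "rho_linkage_block", "rho_gene_block",
                     "rho_background_block"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} outside [0,1)")
        if sum(self.mediation_h2) >= 1:
            raise ValueError("mediation per-CpG h2 exceeds 1")
        return self


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Block:
    kind: str                      # cpg | gene | background
    owner: str                     # cpg id, gene id or trait id
    rho: float
    snp_slice: slice
    chrom: str
    base_bp: int


@dataclasses.dataclass
class _CpgInfo:
    cpg_id: str
    topology: Topology
    trait: str
    block: int
    causal_local: list[int]        # within-block SNP offsets driving the CpG
    cpg_h2: list[float]
    trait_local: list[int]         # within-block SNP offsets driving the trait
    trait_h2: list[float]
    gene: str | None
    ewas_direction: int


@dataclasses.dataclass
class _GeneInfo:
    gene_id: str
    role: str                      # mediator | pathway-causal | decoy
    trait: str | None
    block: int
    eqtl_local: list[int]
    eqtl_h2: list[float]
    b_gene_trait: float


@dataclasses.dataclass
class Layout:
    spec: ScenarioSpec
    blocks: list[_Block]
    cpgs: list[_CpgInfo]
    genes: list[_GeneInfo]
    snp_ids: list[str]
    chrom: list[str]
    bp: list[int]
    a1: list[str]
    a2: list[str]
    mafs: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def traits(self) -> list[str]:
        return [f"trait{t}" for t in range(self.spec.n_traits)]


def build_layout(spec: ScenarioSpec) -> Layout:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    blocks: list[_Block] = []
    cpgs: list[_CpgInfo] = []
    genes: list[_GeneInfo] = []
    snp_ids: list[str] = []
    chrom: list[str] = []
    bp: list[int] = []
    mafs: list[float] = []

    m = spec.snps_per_block

    def add_block(kind: str, owner: str, rho: float) -> int:
        b = len(blocks)
        c = str(b % 22 + 1)
        base = 1 + (b // 22) * 30_000_000
        start = len(snp_ids)
        for j in range(m):
            snp_ids.append(f"rs{start + j + 1}")
            chrom.append(c)
            bp.append(base + j * 1000)
        blocks.append(_Block(kind, owner, rho, slice(start, start + m), c, base))
        mafs.extend(rng.uniform(spec.maf_min, spec.maf_max, size=m).tolist())
        return b

    topo_census: list[Topology] = (
        ["mediation"] * spec.n_mediation + ["pleiotropy"] * spec.n_pleiotropy
        + ["linkage"] * spec.n_linkage + ["reverse"] * spec.n_reverse
        + ["null"] * spec.n_null
    )
    tri = list(spec.mediation_h2)
    med_count = 0
    for i, topo in enumerate(topo_census):
        cpg_id = f"cg{i:08d}"
        trait = f"trait{i % spec.n_traits}"
        rho = spec.rho_linkage_block if topo == "linkage" else spec.rho_cpg_block
        b = add_block("cpg", cpg_id, rho)
        gene = None
        if topo == "mediation":
            gene = f"MEDG{med_count + 1}"
            sign = 1.0 if med_count % 2 == 0 else -1.0
            genes.append(_GeneInfo(
                gene_id=gene, role="mediator", trait=trait, block=b,
                eqtl_local=[], eqtl_h2=[],
                b_gene_trait=sign * spec.b_gene_trait,
            ))
            med_count += 1
            info = _CpgInfo(cpg_id, topo, trait, b, [0, 8, 16], tri, [], [],
                            gene, -1 if i % 2 == 0 else 1)
        elif topo == "pleiotropy":
            info = _CpgInfo(cpg_id, topo, trait, b, [0, 8, 16], tri,
                            [8], [spec.pleiotropy_trait_h2], None,
                            -1 if i % 2 == 0 else 1)
        elif topo == "linkage":
            info = _CpgInfo(cpg_id, topo, trait, b, [0], [spec.linkage_cpg_h2],
                            [12], [spec.linkage_trait_h2], None,
                            -1 if i % 2 == 0 else 1)
        elif topo == "reverse":
            info = _CpgInfo(cpg_id, topo, trait, b, [], [],
                            [0, 12], list(spec.reverse_trait_h2), None,
                            -1 if i % 2 == 0 else 1)
        else:
            info = _CpgInfo(cpg_id, topo, trait, b, [0, 8, 16], tri, [], [],
                            None, -1 if i % 2 == 0 else 1)
        cpgs.append(info)

    # standalone genes: pathway-causal then decoys, per trait
    local = [0, 6, 12, 18][: len(spec.pathway_eqtl_h2)]
    for t in range(spec.n_traits):
        for k in range(spec.causal_genes_per_trait):
            gid = f"PWG{t}_{k + 1}"
            b = add_block("gene", gid, spec.rho_gene_block)
            scale = rng.uniform(0.7, 1.3)
            genes.append(_GeneInfo(
                gene_id=gid, role="pathway-causal", trait=f"trait{t}", block=b,
                eqtl_local=list(local),
                eqtl_h2=[h * scale for h in spec.pathway_eqtl_h2],
                b_gene_trait=spec.b_pathway_gene_trait,
            ))
        for k in range(spec.decoy_genes_per_trait):
            gid = f"DECOY{t}_{k + 1}"
            b = add_block("gene", gid, spec.rho_gene_block)
            scale = rng.uniform(0.7, 1.3)
            genes.append(_GeneInfo(
                gene_id=gid, role="decoy", trait=None, block=b,
                eqtl_local=list(local),
                eqtl_h2=[h * scale for h in spec.pathway_eqtl_h2],
                b_gene_trait=0.0,
            ))

    for t in range(spec.n_traits):
        for k in range(spec.background_blocks_per_trait):
            add_block("background", f"trait{t}", spec.rho_background_block)

    a1: list[str] = []
    a2: list[str] = []
    for _ in snp_ids:
        if rng.random() < spec.frac_palindromic:
            pair = _PAL_PAIRS[rng.integers(len(_PAL_PAIRS))]
        else:
            pair = _NONPAL_PAIRS[rng.integers(len(_NONPAL_PAIRS))]
        a1.append(pair[0])
        a2.append(pair[1])

    maf_arr = np.array(mafs)
    # palindromic SNPs must stay below the harmonization ambiguity limit,
    # otherwise they would be excluded from every analysis
    pal = np.array([is_pal for is_pal in
                    ((x, y) in _PAL_PAIRS or (y, x) in _PAL_PAIRS
                     for x, y in zip(a1, a2))])
    maf_arr[pal] = np.minimum(maf_arr[pal], 0.35)

    return Layout(spec=spec, blocks=blocks, cpgs=cpgs, genes=genes,
                  snp_ids=snp_ids, chrom=chrom, bp=bp, a1=a1, a2=a2,
                  mafs=maf_arr)


# ---------------------------------------------------------------------------
# genotypes and phenotypes
# ---------------------------------------------------------------------------

def _block_dosages(rng: np.random.Generator, n: int, mafs: np.ndarray,
                   rho: float) -> np.ndarray:
    """Hardy-Weinberg dosages with AR(1) latent-Gaussian block LD.

    Adjacent SNPs have latent correlation ``rho``, decaying as
    ``rho**distance`` along the block — the distance decay real haplotype
    LD shows, which is what makes p-value clumping retain only a handful
    of index SNPs per locus.  Each haplotype carries the alternate allele
    when its latent Gaussian falls below the allele-frequency quantile;
    dosage = sum of two haplotypes.  (Thresholding attenuates the dosage
    correlation to roughly 0.85x the latent one.)
    """
    m = len(mafs)
    thr = stats.norm.ppf(mafs).astype(np.float32)
    dos = np.zeros((n, m), dtype=np.int8)
    r = np.float32(rho)
    a = np.float32(np.sqrt(max(0.0, 1.0 - rho * rho)))
    for _hap in range(2):
        z = rng.standard_normal((n, m), dtype=np.float32)
        for j in range(1, m):
            z[:, j] = r * z[:, j - 1] + a * z[:, j]
        dos += (z < thr[None, :]).astype(np.int8)
    return dos


def simulate_genotypes(layout: Layout, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    G = np.empty((n, layout.n_snps), dtype=np.int8)
    for blk in layout.blocks:
        G[:, blk.snp_slice] = _block_dosages(
            rng, n, layout.mafs[blk.snp_slice], blk.rho
        )
    return G


def simulate_panel(spec: ScenarioSpec, layout: Layout | None = None) -> LdPanel:
    layout = layout or build_layout(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    G = simulate_genotypes(layout, spec.n_ref, rng).astype(np.float64)
    return LdPanel(snp_ids=layout.snp_ids, chrom=layout.chrom, bp=layout.bp,
                   a1=layout.a1, a2=layout.a2, genotypes=G)


def _std_cols(G: np.ndarray, idx: Sequence[int], mafs: np.ndarray) -> np.ndarray:
    """Genotype columns standardized by theoretical mean/SD."""
    f = mafs[list(idx)]
    sd = np.sqrt(2.0 * f * (1.0 - f))
    return (G[:, list(idx)].astype(np.float64) - 2.0 * f) / sd


def simulate_individuals(layout: Layout, G: np.ndarray,
                         rng: np.random.Generator) -> dict:
    """Latent phenotypes for one cohort: CpGs, gene expression, traits.

    Topology semantics: mediation CpGs transmit to the trait only through
    their gene; pleiotropy SNPs hit CpG and trait separately; linkage
    splits CpG- and trait-driving SNPs within one LD block; reverse CpGs
    are computed *after* the traits they listen to.  Noise is Gaussian and
    cohort-independent.
    """
    spec = layout.spec
    n = G.shape[0]
    out: dict = {}

    smoke = rng.binomial(1, spec.smoking_prevalence, size=n).astype(np.float64)
    sp = spec.smoking_prevalence
    smoke_std = (smoke - sp) / np.sqrt(sp * (1 - sp))
    out["smoking"] = smoke

    cpg = {}
    for info in layout.cpgs:
        if info.topology == "reverse":
            continue  # needs the trait; filled in below
        blk = layout.blocks[info.block]
        idx = [blk.snp_slice.start + j for j in info.causal_local]
        gen = np.zeros(n)
        h2_tot = 0.0
        if idx:
            X = _std_cols(G, idx, layout.mafs)
            w = np.sqrt(np.array(info.cpg_h2))
            gen = X @ w
            h2_tot = float(np.sum(info.cpg_h2))
        smoke_term = 0.0
        smoke_var = 0.0
        if spec.simulate_smoking:
            smoke_term = info.ewas_direction * spec.b_smoking * smoke_std
            smoke_var = spec.b_smoking**2
        noise_var = max(0.05, 1.0 - h2_tot - smoke_var)
        cpg[info.cpg_id] = gen + smoke_term + np.sqrt(noise_var) * rng.standard_normal(n)

    expr = {}
    for g in layout.genes:
        if g.role == "mediator":
            continue
        blk = layout.blocks[g.block]
        idx = [blk.snp_slice.start + j for j in g.eqtl_local]
        X = _std_cols(G, idx, layout.mafs)
        w = np.sqrt(np.array(g.eqtl_h2))
        h2_tot = float(np.sum(g.eqtl_h2))
        noise_var = max(0.05, 1.0 - h2_tot)
        expr[g.gene_id] = X @ w + np.sqrt(noise_var) * rng.standard_normal(n)

    # mediator genes listen to their CpG
    cpg_by_gene = {info.gene: info.cpg_id for info in layout.cpgs if info.gene}
    for g in layout.genes:
        if g.role != "mediator":
            continue
        src = cpg[cpg_by_gene[g.gene_id]]
        noise_var = max(0.05, 1.0 - spec.b_cpg_gene**2)
        expr[g.gene_id] = spec.b_cpg_gene * src + np.sqrt(noise_var) * rng.standard_normal(n)

    traits = {t: np.sqrt(spec.trait_noise_var) * rng.standard_normal(n)
              for t in layout.traits()}
    for g in layout.genes:
        if g.trait is not None and g.b_gene_trait != 0.0:
            traits[g.trait] = traits[g.trait] + g.b_gene_trait * expr[g.gene_id]
    for info in layout.cpgs:
        if not info.trait_local:
            continue
        blk = layout.blocks[info.block]
        idx = [blk.snp_slice.start + j for j in info.trait_local]
        X = _std_cols(G, idx, layout.mafs)
        w = np.sqrt(np.array(info.trait_h2))
        traits[info.trait] = traits[info.trait] + X @ w
    for blk in layout.blocks:
        if blk.kind != "background":
            continue
        X = _std_cols(G, [blk.snp_slice.start], layout.mafs)
        traits[blk.owner] = traits[blk.owner] + np.sqrt(spec.background_h2) * X[:, 0]

    for info in layout.cpgs:
        if info.topology != "reverse":
            continue
        src = traits[info.trait]
        cpg[info.cpg_id] = (spec.b_trait_cpg * src
                            + np.sqrt(0.3) * rng.standard_normal(n))

    out["cpg"] = cpg
    out["expr"] = expr
    out["trait"] = traits
    return out


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def regress_columns(G: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP simple linear regression of each phenotype on each dosage.

    Returns ``(beta, se, p, keep)`` with shape ``(n_snps, n_phenos)``;
    ``keep`` marks non-monomorphic SNPs (others get nan).
    """
    n = G.shape[0]
    if n < 30:
        raise ValueError("need n >= 30 individuals for summary statistics")
    # float32 suffices: relative error ~1e-7 is far below sampling noise
    Gf = np.asarray(G, dtype=np.float32)
    Gc = Gf - Gf.mean(axis=0, dtype=np.float64).astype(np.float32)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float32).T).T
    Yc = Y - Y.mean(axis=0, dtype=np.float64).astype(np.float32)
    sxx = np.einsum("ij,ij->j", Gc, Gc, dtype=np.float64)
    syy = np.einsum("ij,ij->j", Yc, Yc, dtype=np.float64)
    keep = sxx > 0
    sxx_safe = np.where(keep, sxx, 1.0)
    cross = (Gc.T @ Yc).astype(np.float64)
    beta = cross / sxx_safe[:, None]
    dof = n - 2
    sigma2 = (syy[None, :] - beta**2 * sxx_safe[:, None]) / dof
    sigma2 = np.clip(sigma2, 1e-300, None)
    se = np.sqrt(sigma2 / sxx_safe[:, None])
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    p = np.clip(p, 1e-300, 1.0)
    beta[~keep] = np.nan
    se[~keep] = np.nan
    p[~keep] = np.nan
    return beta, se, p, keep


def summarize(G: np.ndarray, phenotype: np.ndarray, layout: Layout,
              n: int | None = None,
              snp_indices: Sequence[int] | None = None,
              flip: np.ndarray | None = None) -> list[SumStatRecord]:
    """Summary-statistic records for one phenotype over chosen SNPs.

    ``flip`` optionally swaps the reported allele orientation per SNP (the
    record's effect allele becomes the panel's other allele), which the
    pipeline must undo via harmonization.  Monomorphic SNPs are skipped
    with a warning.
    """
    idx = np.arange(G.shape[1]) if snp_indices is None else np.asarray(snp_indices)
    sub = G[:, idx]
    beta, se, p, keep = regress_columns(sub, phenotype[:, None])
    nn = n if n is not None else G.shape[0]
    freq = sub.mean(axis=0, dtype=np.float64) / 2.0
    records: list[SumStatRecord] = []
    for k, j in enumerate(idx):
        if not keep[k]:
            log.warning("summarize: %s monomorphic; skipped", layout.snp_ids[j])
            continue
        b, s, pv, f = float(beta[k, 0]), float(se[k, 0]), float(p[k, 0]), float(freq[k])
        a1, a2 = layout.a1[j], layout.a2[j]
        if flip is not None and flip[j]:
            a1, a2 = a2, a1
            b = -b
            f = 1.0 - f
        records.append(SumStatRecord(
            snp_id=layout.snp_ids[j], a1=a1, a2=a2, freq=f, beta=b, se=s,
            p=pv, n=nn, chrom=layout.chrom[j], bp=int(layout.bp[j]),
        ))
    return records


# ---------------------------------------------------------------------------
# the study bundle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StudyBundle:
    spec: ScenarioSpec
    layout: Layout
    panel: LdPanel
    mqtl_disc: list[QtlProbeSet]
    mqtl_repl: list[QtlProbeSet]
    eqtl: list[QtlProbeSet]
    gwas: dict[str, list[SumStatRecord]]
    candidates: pd.DataFrame
    gene_sets: list[GeneSet]
    manifest: dict

    def mqtl_disc_by_probe(self) -> dict[str, QtlProbeSet]:
        return {p.probe_id: p for p in self.mqtl_disc}

    def mqtl_repl_by_probe(self) -> dict[str, QtlProbeSet]:
        return {p.probe_id: p for p in self.mqtl_repl}

    def eqtl_by_gene(self) -> dict[str, QtlProbeSet]:
        return {p.gene_name: p for p in self.eqtl}


def _probe_sets_for_cohort(
    layout: Layout, G: np.ndarray, phen: dict, kind: str,
    sig_trans: np.ndarray, rng: np.random.Generator,
) -> list[QtlProbeSet]:
    """mQTL or eQTL probe sets: cis block + trans records at GWAS-significant
    SNPs (the targeted trans lookup the pipeline's reverse test queries)."""
    spec = layout.spec
    flip = rng.random(layout.n_snps) < spec.flip_fraction
    out: list[QtlProbeSet] = []
    if kind == "mqtl":
        entities = [(c.cpg_id, c.block, "", phen["cpg"][c.cpg_id])
                    for c in layout.cpgs]
    else:
        entities = [(g.gene_id, g.block if g.role != "mediator"
                     else next(c.block for c in layout.cpgs if c.gene == g.gene_id),
                     g.gene_id, phen["expr"][g.gene_id])
                    for g in layout.genes]
    for ent_id, block, gene_name, y in entities:
        blk = layout.blocks[block]
        cis = np.arange(blk.snp_slice.start, blk.snp_slice.stop)
        idx = np.union1d(cis, np.flatnonzero(sig_trans))
        recs = summarize(G, y, layout, snp_indices=idx, flip=flip)
        mid = blk.base_bp + 12_500
        out.append(QtlProbeSet(
            probe_id=ent_id, probe_chrom=blk.chrom, probe_bp=mid,
            gene_name=gene_name, records=recs,
        ))
    return out


def simulate_study(spec: ScenarioSpec) -> StudyBundle:
    """Simulate the full study bundle in memory (see module docstring)."""
    layout = build_layout(spec)
    ss = np.random.SeedSequence([spec.seed, 303])
    (s_panel, s_gwas, s_disc, s_repl, s_eqtl,
     s_flip_g, s_flip_d, s_flip_r, s_flip_e) = [
        np.random.default_rng(c) for c in ss.spawn(9)
    ]

    panel = simulate_panel(spec, layout)

    # GWAS cohort: traits over all SNPs
    Gg = simulate_genotypes(layout, spec.n_gwas, s_gwas)
    ph_g = simulate_individuals(layout, Gg, s_gwas)
    traits = layout.traits()
    Y = np.column_stack([ph_g["trait"][t] for t in traits])
    beta, se, p, keep = regress_columns(Gg, Y)
    flip_g = s_flip_g.random(layout.n_snps) < spec.flip_fraction
    freq = Gg.mean(axis=0, dtype=np.float64) / 2.0
    gwas: dict[str, list[SumStatRecord]] = {}
    for ti, t in enumerate(traits):
        recs = []
        for j in range(layout.n_snps):
            if not keep[j]:
                continue
            b, f = float(beta[j, ti]), float(freq[j])
            a1, a2 = layout.a1[j], layout.a2[j]
            if flip_g[j]:
                a1, a2 = a2, a1
                b = -b
                f = 1.0 - f
            recs.append(SumStatRecord(
                snp_id=layout.snp_ids[j], a1=a1, a2=a2, freq=f, beta=b,
                se=float(se[j, ti]), p=float(p[j, ti]), n=spec.n_gwas,
                chrom=layout.chrom[j], bp=int(layout.bp[j]),
            ))
        gwas[t] = recs
    sig_trans = (p < spec.gwas_sig_p).any(axis=1) & keep
    del Gg

    Gd = simulate_genotypes(layout, spec.n_mqtl_disc, s_disc)
    ph_d = simulate_individuals(layout, Gd, s_disc)
    mqtl_disc = _probe_sets_for_cohort(layout, Gd, ph_d, "mqtl", sig_trans, s_flip_d)
    del Gd

    Gr = simulate_genotypes(layout, spec.n_mqtl_repl, s_repl)
    ph_r = simulate_individuals(layout, Gr, s_repl)
    mqtl_repl = _probe_sets_for_cohort(layout, Gr, ph_r, "mqtl", sig_trans, s_flip_r)
    del Gr

    Ge = simulate_genotypes(layout, spec.n_eqtl, s_eqtl)
    ph_e = simulate_individuals(layout, Ge, s_eqtl)
    eqtl = _probe_sets_for_cohort(layout, Ge, ph_e, "eqtl", sig_trans, s_flip_e)
    del Ge

    candidates = pd.DataFrame({
        "cpg_id": [c.cpg_id for c in layout.cpgs],
        "chrom": [layout.blocks[c.block].chrom for c in layout.cpgs],
        "bp": [layout.blocks[c.block].base_bp + 12_500 for c in layout.cpgs],
        "ewas_direction": ["hypo" if c.ewas_direction < 0 else "hyper"
                           for c in layout.cpgs],
    })

    gene_sets: list[GeneSet] = []
    for t in range(spec.n_traits):
        tid = f"trait{t}"
        med = [g.gene_id for g in layout.genes
               if g.role == "mediator" and g.trait == tid]
        causal = [g.gene_id for g in layout.genes
                  if g.role == "pathway-causal" and g.trait == tid]
        decoys = [g.gene_id for g in layout.genes if g.role == "decoy"
                  and g.gene_id.startswith(f"DECOY{t}_")]
        gene_sets.append(GeneSet(f"SET_CAUSAL_T{t}",
                                 f"genes driving {tid}", med + causal))
        gene_sets.append(GeneSet(f"SET_DECOY_T{t}",
                                 f"expressed genes unrelated to {tid}",
                                 med + decoys))

    manifest = {
        "spec": spec.model_dump(),
        "cpgs": {
            c.cpg_id: {
                "topology": c.topology, "trait": c.trait, "gene": c.gene,
                "cpg_h2": c.cpg_h2, "trait_h2": c.trait_h2,
            } for c in layout.cpgs
        },
        "genes": {
            g.gene_id: {"role": g.role, "trait": g.trait,
                        "b_gene_trait": g.b_gene_trait}
            for g in layout.genes
        },
        "true_pairs": [[c.cpg_id, c.trait] for c in layout.cpgs
                       if c.topology == "mediation"],
        "topology_counts": {
            "mediation": spec.n_mediation, "pleiotropy": spec.n_pleiotropy,
            "linkage": spec.n_linkage, "reverse": spec.n_reverse,
            "null": spec.n_null,
        },
    }

    return StudyBundle(
        spec=spec, layout=layout, panel=panel, mqtl_disc=mqtl_disc,
        mqtl_repl=mqtl_repl, eqtl=eqtl, gwas=gwas, candidates=candidates,
        gene_sets=gene_sets, manifest=manifest,
    )


def emit_study(spec: ScenarioSpec, outdir, force: bool = False) -> StudyBundle:
    """Write the full bundle to ``outdir`` as flat files + manifest JSON."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty; pass force=True")
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_study(spec)
    bundle.panel.to_tsv(outdir / "panel_genotypes.tsv", outdir / "panel_sites.tsv")
    write_qtl_table(bundle.mqtl_disc, outdir / "mqtl_discovery.tsv")
    write_qtl_table(bundle.mqtl_repl, outdir / "mqtl_replication.tsv")
    write_qtl_table(bundle.eqtl, outdir / "eqtl.tsv")
    for trait, recs in bundle.gwas.items():
        write_gwas_ma(recs, outdir / f"gwas_{trait}.ma")
    bundle.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
    return bundle


# ---------------------------------------------------------------------------
# focused generators for operating-characteristic studies
# ---------------------------------------------------------------------------

def _binomial_dosages(rng, n, mafs) -> np.ndarray:
    return rng.binomial(2, mafs[None, :], size=(n, len(mafs))).astype(np.int8)


def _mini_layout(snp_ids, chrom, bp, mafs) -> Layout:
    """Minimal layout shim so :func:`summarize` can be reused."""
    spec = ScenarioSpec()
    return Layout(spec=spec, blocks=[], cpgs=[], genes=[], snp_ids=list(snp_ids),
                  chrom=list(chrom), bp=list(bp), a1=["A"] * len(snp_ids),
                  a2=["G"] * len(snp_ids), mafs=np.asarray(mafs))


def simulate_heidi_dataset(
    kind: Literal["pleiotropy", "linkage"],
    seed: int,
    *,
    n_snps: int = 25,
    rho: float | None = None,
    n_qtl: int = 8000,
    n_gwas: int = 20000,
    n_ref: int = 500,
    h2_qtl: float = 0.15,
    h2_trait: float | None = None,
) -> tuple[QtlProbeSet, list[SumStatRecord], LdPanel]:
    """One LD block; either a shared causal variant or two distinct ones.

    ``pleiotropy``: SNP 0 drives both the molecular trait and the complex
    trait (HEIDI's null).  ``linkage``: SNP 0 drives the molecular trait,
    SNP 12 (in LD) drives the complex trait.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    if h2_trait is None:
        h2_trait = 0.004 if kind == "pleiotropy" else 0.01
    if rho is None:
        # AR(1): pleiotropy wants a spread of r2 to the top SNP inside the
        # HEIDI window; linkage wants dosage r2 ~0.5 at the causal offset
        rho = 0.94 if kind == "pleiotropy" else 0.986
    mafs = rng.uniform(0.15, 0.5, size=n_snps)
    ids = [f"rs{i+1}" for i in range(n_snps)]
    bp = [1000 * (i + 1) for i in range(n_snps)]
    layout = _mini_layout(ids, ["1"] * n_snps, bp, mafs)

    Gp = _block_dosages(rng, n_ref, mafs, rho).astype(np.float64)
    panel = LdPanel(ids, ["1"] * n_snps, bp, ["A"] * n_snps, Gp,
                    a2=["G"] * n_snps)

    causal_q = 0
    causal_t = 0 if kind == "pleiotropy" else 12

    Gq = _block_dosages(rng, n_qtl, mafs, rho)
    xq = _std_cols(Gq, [causal_q], mafs)[:, 0]
    mol = np.sqrt(h2_qtl) * xq + np.sqrt(1 - h2_qtl) * rng.standard_normal(n_qtl)
    qtl_recs = summarize(Gq, mol, layout)

    Gg = _block_dosages(rng, n_gwas, mafs, rho)
    xt = _std_cols(Gg, [causal_t], mafs)[:, 0]
    trait = np.sqrt(h2_trait) * xt + np.sqrt(1 - h2_trait) * rng.standard_normal(n_gwas)
    gwas_recs = summarize(Gg, trait, layout)

    probe = QtlProbeSet(probe_id="probe", probe_chrom="1", probe_bp=12_500,
                        gene_name="", records=qtl_recs)
    return probe, gwas_recs, panel


def simulate_instrument_dataset(
    seed: int,
    *,
    n_instruments: int = 20,
    b_xy: float = 0.3,
    h2_per_instrument: float = 0.005,
    n_exposure: int = 20000,
    n_outcome: int = 20000,
    n_ref: int = 500,
    outlier_index: int | None = None,
    outlier_effect: float = 0.19,
) -> tuple[QtlProbeSet, list[SumStatRecord], LdPanel]:
    """Independent instruments for a scalar exposure -> outcome effect.

    Two non-overlapping cohorts; optionally SNP ``outlier_index`` gains a
    direct (pleiotropic) outcome effect of ``outlier_effect`` per genotype
    SD on top of the mediated path.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    m = n_instruments
    mafs = rng.uniform(0.1, 0.5, size=m)
    ids = [f"rs{i+1}" for i in range(m)]
    bp = [10_000_000 * (i + 1) for i in range(m)]
    chrom = [str(i % 22 + 1) for i in range(m)]
    layout = _mini_layout(ids, chrom, bp, mafs)
    w = np.full(m, np.sqrt(h2_per_instrument))
    h2_tot = h2_per_instrument * m

    Gp = _binomial_dosages(rng, n_ref, mafs).astype(np.float64)
    panel = LdPanel(ids, chrom, bp, ["A"] * m, Gp, a2=["G"] * m)

    def expo(G):
        X = _std_cols(G, range(m), mafs)
        return X @ w + np.sqrt(1 - h2_tot) * rng.standard_normal(G.shape[0]), X

    Ge = _binomial_dosages(rng, n_exposure, mafs)
    exp_phen, _ = expo(Ge)
    exp_recs = summarize(Ge, exp_phen, layout)

    Go = _binomial_dosages(rng, n_outcome, mafs)
    exp_o, Xo = expo(Go)
    noise_var = max(0.05, 1.0 - b_xy**2 * 1.0)
    out_phen = b_xy * exp_o + np.sqrt(noise_var) * rng.standard_normal(n_outcome)
    if outlier_index is not None:
        out_phen = out_phen + outlier_effect * Xo[:, outlier_index]
    out_recs = summarize(Go, out_phen, layout)

    probe = QtlProbeSet(probe_id="exposure", probe_chrom="1", probe_bp=1,
                        gene_name="", records=exp_recs)
    return probe, out_recs, panel


def simulate_pathway_dataset(
    kind: Literal["causal", "decoy"],
    seed: int,
    *,
    n_genes: int = 13,
    snps_per_gene: int = 4,
    n_eqtl: int = 5000,
    n_gwas: int = 20000,
    n_ref: int = 500,
    b_gene_trait: float = 0.2,
) -> tuple[dict[str, QtlProbeSet], list[SumStatRecord], LdPanel, GeneSet]:
    """Independent-SNP pathway: genes with eQTLs, trait driven (or not) by
    the genes' expression, with per-SNP effect sizes spread so the |Z|
    correlation has signal under the causal condition."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    m = n_genes * snps_per_gene
    mafs = rng.uniform(0.1, 0.5, size=m)
    ids = [f"rs{i+1}" for i in range(m)]
    bp = [5_000_000 * (i + 1) for i in range(m)]
    chrom = [str(i % 22 + 1) for i in range(m)]
    layout = _mini_layout(ids, chrom, bp, mafs)
    base = np.array([0.02, 0.05, 0.09, 0.14][:snps_per_gene])
    h2 = np.concatenate([base * rng.uniform(0.7, 1.3) for _ in range(n_genes)])
    gene_of_snp = np.repeat(np.arange(n_genes), snps_per_gene)
    genes = [f"G{i+1}" for i in range(n_genes)]

    Gp = _binomial_dosages(rng, n_ref, mafs).astype(np.float64)
    panel = LdPanel(ids, chrom, bp, ["A"] * m, Gp, a2=["G"] * m)

    def expressions(G):
        X = _std_cols(G, range(m), mafs)
        E = np.zeros((G.shape[0], n_genes))
        for g in range(n_genes):
            sel = gene_of_snp == g
            tot = float(h2[sel].sum())
            E[:, g] = X[:, sel] @ np.sqrt(h2[sel]) + np.sqrt(
                max(0.05, 1 - tot)) * rng.standard_normal(G.shape[0])
        return E

    Ge = _binomial_dosages(rng, n_eqtl, mafs)
    E = expressions(Ge)
    store: dict[str, QtlProbeSet] = {}
    for g, gid in enumerate(genes):
        recs = summarize(Ge, E[:, g], layout)
        store[gid] = QtlProbeSet(probe_id=gid, probe_chrom="1", probe_bp=1,
                                 gene_name=gid, records=recs)

    Gg = _binomial_dosages(rng, n_gwas, mafs)
    Eg = expressions(Gg)
    bt = b_gene_trait if kind == "causal" else 0.0
    trait = Eg @ np.full(n_genes, bt) + rng.standard_normal(n_gwas)
    gwas_recs = summarize(Gg, trait, layout)
    gs = GeneSet(set_id=f"SET_{kind.upper()}", description=f"{kind} pathway",
                 genes=list(genes))
    return store, gwas_recs, panel, gs
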