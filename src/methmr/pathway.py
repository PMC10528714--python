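"""Pathway-level |Z| rank correlation between eQTL and GWAS signals.

For each gene set containing a gene of interest, pool the significant
eQTLs of the set's member genes, prune them to near-linkage-equilibrium,
and ask whether SNPs that perturb the pathway's expression (large |z_eqtl|)
also perturb the trait (large |z_gwas|), via Spearman rank correlation of
the absolute Z-scores.  Absolute values are used because member genes may
act in either direction (inhibitory or activatory).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import ld as ldmod
from .ld import LdPanel
from .sumstats_io import GeneSet, P_FLOOR, QtlProbeSet, SumStatRecord

log = logging.getLogger(__name__)


@dataclasses.dataclass(slots=True)
class PathwayConfig:
    p_eqtl: float = 5e-8            #: eQTL significance for panel membership
    r2_pathway: float = 0.05        #: pruning ceiling (near linkage equilibrium)
    prune_window_kb: float = 250.0
    min_snps: int = 10              #: below this a set is not reported
    permutation_below_n: int = 30   #: exact permutation p when n < this
    n_permutations: int = 10_000
    permutation_seed: int = 20230719


@dataclasses.dataclass(slots=True)
class PathwayResult:
    set_id: str
    description: str
    gene_indicator: str
    trait_id: str
    n_snps: int
    rho: float
    p: float
    p_method: str
    q: float | None = None


class InsufficientSnps(ValueError):
    pass


def pathway_snp_panel(
    genes: Sequence[str],
    eqtl_store: Mapping[str, QtlProbeSet],
    panel: LdPanel,
    config: PathwayConfig | None = None,
) -> list[tuple[str, float]]:
    """Pooled, pruned eQTL SNPs for a pathway with their |z_eqtl|.

    Significant eQTL records (p <= ``p_eqtl``) of all member genes are
    pooled; a SNP that is an eQTL for several member genes keeps its
    largest |z|.  The pool is clumped at ``r2_pathway`` (index p = the
    pooled eQTL p) so retained SNPs are in near-linkage equilibrium.
    """
    cfg = config or PathwayConfig()
    best: dict[str, SumStatRecord] = {}
    for gene in genes:
        ps = eqtl_store.get(gene)
        if ps is None:
            continue
        for rec in ps.records:
            if rec.p > cfg.p_eqtl:
                continue
            prev = best.get(rec.snp_id)
            if prev is None or abs(rec.z) > abs(prev.z):
                best[rec.snp_id] = rec
    if not best:
        return []
    pooled = sorted(best.values(), key=lambda r: (r.p, r.bp, r.snp_id))
    kept = ldmod.clump(
        pooled, panel, p_index=cfg.p_eqtl, r2_max=cfg.r2_pathway,
        window_kb=cfg.prune_window_kb,
    )
    return [(s, abs(best[s].z)) for s in kept]


def _spearman_perm_p(x: np.ndarray, y: np.ndarray, rho: float,
                     n_perm: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean())
    ry = (ry - ry.mean())
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    obs = abs(rx @ ry / denom)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry)
        if abs(rx @ perm / denom) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def pathway_trait_correlation(
    snp_panel: Sequence[tuple[str, float]],
    gwas: Sequence[SumStatRecord],
    *,
    set_id: str = "",
    description: str = "",
    gene_indicator: str = "",
    trait_id: str = "",
    config: PathwayConfig | None = None,
) -> PathwayResult:
    """Spearman correlation of |z_eqtl| with |z_gwas| over the SNP panel.

    Ties get average ranks.  The p-value uses the two-sided t
    approximation for n >= ``permutation_below_n`` and an exact (seeded)
    permutation test below that.  Raises :class:`InsufficientSnps` when
    fewer than ``min_snps`` SNPs are present in both the panel and the
    GWAS.
    """
    cfg = config or PathwayConfig()
    gwas_by_snp = {r.snp_id: r for r in gwas}
    pairs = [
        (ze, abs(gwas_by_snp[s].z)) for s, ze in snp_panel if s in gwas_by_snp
    ]
    n = len(pairs)
    if n < cfg.min_snps:
        raise InsufficientSnps(
            f"{set_id or 'panel'}: {n} SNPs shared with GWAS; need {cfg.min_snps}"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    rho = float(stats.spearmanr(x, y).statistic)
    if n < cfg.permutation_below_n:
        p = _spearman_perm_p(x, y, rho, cfg.n_permutations, cfg.permutation_seed)
        method = "permutation"
    else:
        # two-sided t approximation on rho
        if abs(rho) >= 1.0:
            p = P_FLOOR
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = max(float(2.0 * stats.t.sf(abs(t), df=n - 2)), P_FLOOR)
        method = "t-approx"
    return PathwayResult(
        set_id=set_id, description=description, gene_indicator=gene_indicator,
        trait_id=trait_id, n_snps=n, rho=rho, p=float(p), p_method=method,
    )


def pathway_scan(
    gene_indicator: str,
    gene_sets: Sequence[GeneSet],
    eqtl_store: Mapping[str, QtlProbeSet],
    gwas: Sequence[SumStatRecord],
    panel: LdPanel,
    trait_id: str = "trait",
    config: PathwayConfig | None = None,
) -> list[PathwayResult]:
    """Test every gene set containing the indicator gene against a trait.

    Results are sorted by ascending p; a Benjamini-Hochberg q-value across
    the tested sets is attached (an addition over reporting raw p only).
    Sets with too few usable SNPs are skipped with a log entry.
    """
    cfg = config or PathwayConfig()
    results: list[PathwayResult] = []
    for gs in gene_sets:
        if gene_indicator not in gs.genes:
            continue
        snps = pathway_snp_panel(gs.genes, eqtl_store, panel, cfg)
        if not snps:
            log.info("pathway %s skipped: no qualifying eQTLs", gs.set_id)
            continue
        try:
            res = pathway_trait_correlation(
                snps, gwas, set_id=gs.set_id, description=gs.description,
                gene_indicator=gene_indicator, trait_id=trait_id, config=cfg,
            )
        except InsufficientSnps as exc:
            log.info("pathway %s skipped: %s", gs.set_id, exc)
            continue
        results.append(res)
    results.sort(key=lambda r: (r.p, r.set_id))
    if results:
        q = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q = float(qv)
    return results
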