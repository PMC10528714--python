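"""SMR co-localization test and the HEIDI pleiotropy-vs-linkage test.

SMR asks whether a molecular trait (here CpG methylation, or gene
expression) and a complex trait share an associated variant, by combining
the two Z-scores at the strongest QTL SNP:

    T_SMR = z_gwas^2 z_qtl^2 / (z_gwas^2 + z_qtl^2)  ~  chi2(1 df)

with the Wald ratio b_smr = b_gwas / b_qtl and its delta-method SE.  A
small p_smr is consistent with either a single shared causal variant
(pleiotropy, which here includes a genuine causal chain) or two distinct
variants in LD (linkage).  HEIDI separates the two: under the
single-shared-variant null, the ratio b_xy(i) = b_gwas(i)/b_qtl(i) is the
same at every SNP in LD with the top SNP; heterogeneity across such SNPs
indicates linkage.  The HEIDI statistic is the sum of squared standardized
differences d_i = b_xy(i) - b_xy(top), referred to the distribution of a
quadratic form in correlated normals (weighted chi-square mixture over the
eigenvalues of the correlation matrix of the d_i).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .ld import LdPanel
from .sumstats_io import P_FLOOR, QtlProbeSet, SumStatRecord, harmonize_many

log = logging.getLogger(__name__)


@dataclasses.dataclass(slots=True)
class HeidiConfig:
    """SNP-selection and evaluation constants for HEIDI.

    The selection rules follow common SMR-tool practice; every constant is
    configurable because no single published value is canonical.
    """

    snp_p: float = 1.6e-3        #: QTL p-value ceiling for contributing SNPs
    r2_min: float = 0.05         #: min r2 with the top SNP
    r2_max: float = 0.9          #: max r2 with the top SNP (collinearity guard)
    max_snps: int = 20           #: cap, strongest QTL p first
    min_snps: int = 3            #: below this, p_heidi is undefined
    ridge: float = 1e-8          #: diagonal regularization of the d covariance


@dataclasses.dataclass(slots=True)
class SmrResult:
    probe_id: str
    trait_id: str
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    n_heidi_snps: int
    p_heidi: float | None
    pass_smr: bool
    pass_heidi: bool
    heidi_method: str = ""


class SmrError(ValueError):
    pass


def smr_test(qtl: SumStatRecord, gwas: SumStatRecord) -> tuple[float, float, float]:
    """SMR test at a single (top) QTL SNP.

    Both records must already be harmonized to the same effect allele.
    Returns ``(b_smr, se_smr, p_smr)``.
    """
    if qtl.beta == 0:
        raise SmrError(f"{qtl.snp_id}: QTL beta is zero; Wald ratio undefined")
    z_q = qtl.z
    z_g = gwas.z
    denom = z_g * z_g + z_q * z_q
    t_smr = 0.0 if denom == 0 else (z_g * z_g * z_q * z_q) / denom
    p_smr = max(float(stats.chi2.sf(t_smr, df=1)), P_FLOOR)
    b_smr = gwas.beta / qtl.beta
    if gwas.beta != 0:
        se_smr = abs(b_smr) * float(
            np.sqrt(gwas.se**2 / gwas.beta**2 + qtl.se**2 / qtl.beta**2)
        )
    else:  # ratio is exactly 0; only the numerator contributes variance
        se_smr = float(np.sqrt(gwas.se**2 / qtl.beta**2))
    return b_smr, se_smr, p_smr


# ---------------------------------------------------------------------------
# quadratic forms in correlated normals
# ---------------------------------------------------------------------------

def quadform_sf(q: float, weights: np.ndarray) -> tuple[float, str]:
    """Upper tail P(sum_i w_i X_i > q), X_i iid chi-square(1).

    Exact evaluation by Imhof's numerical inversion of the characteristic
    function; closed forms for the one-weight and equal-weight cases; a
    Satterthwaite two-moment chi-square approximation as fallback.  Returns
    ``(p, method)``.
    """
    w = np.asarray(weights, dtype=float)
    w = w[w > 1e-12]
    if w.size == 0:
        return 1.0, "degenerate"
    if q <= 0:
        return 1.0, "degenerate"
    if w.size == 1 or np.allclose(w, w[0], rtol=1e-12):
        p = float(stats.chi2.sf(q / w[0], df=w.size))
        return max(p, P_FLOOR), "exact-chi2"

    def integrand(u: float) -> float:
        lu = w * u
        theta = 0.5 * np.sum(np.arctan(lu)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p(lu * lu)))
        return float(np.sin(theta) / (u * rho))

    try:
        with warnings.catch_warnings():
            # the Imhof integrand oscillates with a slowly decaying envelope;
            # quad's subdivision-limit warning is expected and harmless as
            # long as the returned error estimate is small (checked below)
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(
                integrand, 0.0, np.inf, limit=800, epsabs=1e-11, epsrel=1e-9
            )
        p = 0.5 + val / np.pi
        if np.isfinite(p) and err < 1e-4:
            return min(1.0, max(p, P_FLOOR)), "imhof"
    except Exception:  # pragma: no cover - scipy integration failure
        pass
    c = float(np.sum(w**2) / np.sum(w))
    d = float(np.sum(w) ** 2 / np.sum(w**2))
    p = float(stats.chi2.sf(q / c, df=d))
    return max(p, P_FLOOR), "satterthwaite"


# ---------------------------------------------------------------------------
# HEIDI
# ---------------------------------------------------------------------------

def _bxy_cov(
    qtl: Sequence[SumStatRecord],
    gwas: Sequence[SumStatRecord],
    R: np.ndarray,
) -> np.ndarray:
    """Delta-method covariance of the per-SNP Wald ratios b_xy(i).

    Treats the QTL and GWAS estimates as independent of each other, with
    cross-SNP correlation r_ij within each study (both cohorts share the
    population LD structure).
    """
    bq = np.array([r.beta for r in qtl])
    sq = np.array([r.se for r in qtl])
    bg = np.array([r.beta for r in gwas])
    sg = np.array([r.se for r in gwas])
    # cov from the GWAS numerators + cov propagated from the QTL denominators
    cov_num = R * np.outer(sg, sg) / np.outer(bq, bq)
    cov_den = R * np.outer(sq, sq) * np.outer(bg, bg) / np.outer(bq**2, bq**2)
    return cov_num + cov_den


def heidi_test(
    qtl_set: QtlProbeSet,
    gwas: Sequence[SumStatRecord],
    panel: LdPanel,
    config: HeidiConfig | None = None,
    top_snp: str | None = None,
) -> tuple[float | None, int, str]:
    """HEIDI test for one probe against one trait.

    Records are assumed harmonized to the panel's allele orientation.
    Returns ``(p_heidi, n_heidi_snps, method)``; ``p_heidi`` is ``None``
    when fewer than ``config.min_snps`` SNPs qualify.
    """
    cfg = config or HeidiConfig()
    gwas_by_snp = {r.snp_id: r for r in gwas}
    qtl_by_snp = qtl_set.by_snp()

    usable = [
        r for r in qtl_set.records
        if r.snp_id in gwas_by_snp and r.snp_id in panel
        and not panel.monomorphic[panel.index(r.snp_id)]
    ]
    if not usable:
        return None, 0, "no-snps"
    if top_snp is None:
        top = min(usable, key=lambda r: (r.p, r.bp, r.snp_id))
    else:
        if top_snp not in qtl_by_snp or top_snp not in gwas_by_snp:
            return None, 0, "no-snps"
        top = qtl_by_snp[top_snp]

    others = [r for r in usable if r.snp_id != top.snp_id and r.p < cfg.snp_p]
    if others:
        rvec = panel.corr_vector(top.snp_id, [r.snp_id for r in others])
        others = [
            r for r, rr in zip(others, rvec)
            if cfg.r2_min <= rr * rr <= cfg.r2_max
        ]
    others.sort(key=lambda r: (r.p, r.bp, r.snp_id))
    others = others[: cfg.max_snps]
    n_sel = len(others)
    if n_sel < cfg.min_snps:
        return None, n_sel, "too-few-snps"

    ids = [top.snp_id] + [r.snp_id for r in others]
    qtl_recs = [top] + others
    gwas_recs = [gwas_by_snp[s] for s in ids]
    if any(r.beta == 0 for r in qtl_recs):
        return None, n_sel, "zero-qtl-beta"
    R = panel.corr_matrix(ids)

    cov_b = _bxy_cov(qtl_recs, gwas_recs, R)
    bxy = np.array([g.beta / q.beta for q, g in zip(qtl_recs, gwas_recs)])
    d = bxy[1:] - bxy[0]
    # cov(d_i, d_j) = cov(b_i,b_j) - cov(b_i,b_top) - cov(b_j,b_top) + var(b_top)
    cov_d = (
        cov_b[1:, 1:] - cov_b[1:, [0]] - cov_b[[0], 1:] + cov_b[0, 0]
    )
    diag = np.diag(cov_d).copy()
    bad = diag <= 0
    if bad.any():
        log.warning("heidi: non-positive d variance; ridge applied")
    diag = np.maximum(diag, cfg.ridge)
    cov_d = cov_d + np.eye(n_sel) * cfg.ridge
    sd = np.sqrt(diag)
    z_d = d / sd
    stat = float(np.sum(z_d**2))
    if stat == 0.0:
        return 1.0, n_sel, "degenerate"
    C = cov_d / np.outer(sd, sd)
    eig = np.linalg.eigvalsh((C + C.T) / 2.0)
    eig = np.clip(eig, 0.0, None)
    p, method = quadform_sf(stat, eig)
    return p, n_sel, method


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen_probe(
    probe: QtlProbeSet,
    trait_id: str,
    gwas: Sequence[SumStatRecord],
    panel: LdPanel,
    *,
    p_instrument: float = 5e-8,
    p_colocalization: float = 5e-8,
    heidi_keep_p: float = 0.01,
    undefined_heidi_pass: bool = True,
    heidi_config: HeidiConfig | None = None,
    heidi_only_if_smr: bool = True,
    palindrome_maf_limit: float = 0.4,
) -> tuple[SmrResult | None, str]:
    """SMR + HEIDI for one probe/trait pair.

    Harmonizes both studies to the panel orientation, runs the SMR test at
    the top QTL SNP (requires top QTL ``p <= p_instrument``), then HEIDI.
    Returns ``(result, reason)``; ``result`` is ``None`` when the pair is
    not testable, with ``reason`` in ``{"no-overlap", "no-instrument"}``.
    """
    probe_snps = {r.snp_id for r in probe.records}
    refs = panel.reference_records(
        [r.snp_id for r in probe.records if r.snp_id in panel]
    )
    qtl_h, _ = harmonize_many(refs, [r for r in probe.records if r.snp_id in panel],
                              palindrome_maf_limit=palindrome_maf_limit)
    gwas_sub = [r for r in gwas if r.snp_id in probe_snps and r.snp_id in panel]
    grefs = panel.reference_records([r.snp_id for r in gwas_sub])
    gwas_h, _ = harmonize_many(grefs, gwas_sub,
                               palindrome_maf_limit=palindrome_maf_limit)
    gwas_by_snp = {r.snp_id: r for r in gwas_h}
    overlap = [r for r in qtl_h if r.snp_id in gwas_by_snp]
    if not overlap:
        return None, "no-overlap"
    top = min(overlap, key=lambda r: (r.p, r.bp, r.snp_id))
    if top.p > p_instrument:
        return None, "no-instrument"
    b_smr, se_smr, p_smr = smr_test(top, gwas_by_snp[top.snp_id])
    pass_smr = p_smr < p_colocalization

    p_heidi: float | None = None
    n_heidi = 0
    method = "not-evaluated"
    if pass_smr or not heidi_only_if_smr:
        qset = QtlProbeSet(
            probe_id=probe.probe_id, probe_chrom=probe.probe_chrom,
            probe_bp=probe.probe_bp, gene_name=probe.gene_name, records=qtl_h,
        )
        p_heidi, n_heidi, method = heidi_test(
            qset, gwas_h, panel, heidi_config, top_snp=top.snp_id
        )
    if p_heidi is None:
        pass_heidi = undefined_heidi_pass
    else:
        pass_heidi = p_heidi >= heidi_keep_p
    return (
        SmrResult(
            probe_id=probe.probe_id, trait_id=trait_id, top_snp=top.snp_id,
            b_smr=b_smr, se_smr=se_smr, p_smr=p_smr,
            n_heidi_snps=n_heidi, p_heidi=p_heidi,
            pass_smr=pass_smr, pass_heidi=pass_heidi, heidi_method=method,
        ),
        "ok",
    )


def colocalization_screen(
    probes: Sequence[QtlProbeSet],
    trait_id: str,
    gwas: Sequence[SumStatRecord],
    panel: LdPanel,
    **kwargs,
) -> list[SmrResult]:
    """Run :func:`screen_probe` over many probes; untestable probes logged."""
    out: list[SmrResult] = []
    for probe in probes:
        res, reason = screen_probe(probe, trait_id, gwas, panel, **kwargs)
        if res is None:
            log.info("screen: %s x %s skipped (%s)", probe.probe_id, trait_id, reason)
            continue
        out.append(res)
    return out
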