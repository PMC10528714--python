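"""Multi-instrument summary-based MR with LD-aware GLS and outlier removal.

Instruments are SNPs strongly associated with the exposure (p below the
genome-wide threshold), mutually near-independent (pairwise r2 below a
clumping threshold), and non-pleiotropic (SNPs whose per-SNP Wald ratio is
heterogeneous against the consensus are removed, mirroring the
HEIDI-outlier step of GSMR).  The causal effect combines per-SNP Wald
ratios b_xy(i) = b_out(i)/b_exp(i) by generalized least squares:

    b_xy = (1' V^-1 b) / (1' V^-1 1),   var(b_xy) = 1 / (1' V^-1 1)

where V_ij = r_ij sqrt(var_i var_j) uses the signed LD correlation r_ij
between instruments and delta-method per-SNP variances.  With independent
instruments this reduces to the inverse-variance-weighted mean; with one
instrument it is the Wald ratio with its delta-method SE.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats

from . import ld as ldmod
from .ld import LdPanel
from .sumstats_io import P_FLOOR, QtlProbeSet, SumStatRecord, harmonize_many

log = logging.getLogger(__name__)


@dataclasses.dataclass(slots=True)
class GsmrConfig:
    p_exposure: float = 5e-8          #: instrument significance on the exposure
    r2_instruments: float = 0.2       #: clumping ceiling among instruments
    clump_window_kb: float = 10_000.0
    p_heidi_outlier: float = 0.01     #: per-SNP heterogeneity removal threshold
    min_instruments_for_filter: int = 3
    max_filter_iter: int = 10
    ridge: float = 1e-6               #: ridge on the correlation factor of V
    cond_max: float = 1e8
    palindrome_maf_limit: float = 0.4


@dataclasses.dataclass(slots=True)
class InstrumentSet:
    exposure_id: str
    outcome_id: str
    snps: list[tuple[SumStatRecord, SumStatRecord]]  #: (exposure, outcome) pairs
    ld_corr: np.ndarray
    dropped: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    @property
    def n_instruments(self) -> int:
        return len(self.snps)

    def ratios(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP Wald ratios and their delta-method variances."""
        be = np.array([e.beta for e, _ in self.snps])
        se_e = np.array([e.se for e, _ in self.snps])
        bo = np.array([o.beta for _, o in self.snps])
        se_o = np.array([o.se for _, o in self.snps])
        b = bo / be
        var = se_o**2 / be**2 + bo**2 * se_e**2 / be**4
        return b, var


@dataclasses.dataclass(slots=True)
class MrResult:
    exposure_id: str
    outcome_id: str
    direction: str                    #: "forward" or "reverse"
    b_xy: float | None
    se_xy: float | None
    p_xy: float | None
    n_instruments: int
    removed_snps: list[tuple[str, str]]
    testable: bool
    reason: str = ""


def _not_testable(exposure_id, outcome_id, direction, reason,
                  removed=None) -> MrResult:
    return MrResult(
        exposure_id=exposure_id, outcome_id=outcome_id, direction=direction,
        b_xy=None, se_xy=None, p_xy=None, n_instruments=0,
        removed_snps=list(removed or []), testable=False, reason=reason,
    )


def select_instruments(
    exposure: QtlProbeSet,
    outcome: Sequence[SumStatRecord],
    panel: LdPanel,
    config: GsmrConfig | None = None,
    outcome_id: str = "outcome",
) -> InstrumentSet:
    """Harmonize, threshold, clump, and pair exposure/outcome records.

    Exposure and outcome are both re-expressed on the panel's counted
    allele so betas and signed LD share one convention.  Exclusions (allele
    mismatches, missing outcome records, clumped SNPs) are recorded with
    reason codes on the returned set.
    """
    cfg = config or GsmrConfig()
    dropped: list[tuple[str, str]] = []

    in_panel = [r for r in exposure.records if r.snp_id in panel]
    dropped += [(r.snp_id, "not-in-panel") for r in exposure.records
                if r.snp_id not in panel]
    refs = panel.reference_records([r.snp_id for r in in_panel])
    exp_h, excl = harmonize_many(refs, in_panel,
                                 palindrome_maf_limit=cfg.palindrome_maf_limit)
    dropped += excl

    sig = [r for r in exp_h if r.p <= cfg.p_exposure]
    dropped += [(r.snp_id, "exposure-not-significant") for r in exp_h
                if r.p > cfg.p_exposure]

    out_in_panel = [r for r in outcome if r.snp_id in panel]
    orefs = panel.reference_records([r.snp_id for r in out_in_panel])
    out_h, _ = harmonize_many(orefs, out_in_panel,
                              palindrome_maf_limit=cfg.palindrome_maf_limit)
    out_by_snp = {r.snp_id: r for r in out_h}

    paired = [r for r in sig if r.snp_id in out_by_snp]
    dropped += [(r.snp_id, "no-outcome-record") for r in sig
                if r.snp_id not in out_by_snp]

    kept_ids = ldmod.clump(
        paired, panel, p_index=cfg.p_exposure, r2_max=cfg.r2_instruments,
        window_kb=cfg.clump_window_kb,
    )
    kept_set = set(kept_ids)
    dropped += [(r.snp_id, "clumped") for r in paired if r.snp_id not in kept_set]
    exp_by_snp = {r.snp_id: r for r in paired}
    pairs = [(exp_by_snp[s], out_by_snp[s]) for s in kept_ids]
    R = panel.corr_matrix(kept_ids) if kept_ids else np.zeros((0, 0))
    return InstrumentSet(
        exposure_id=exposure.probe_id, outcome_id=outcome_id,
        snps=pairs, ld_corr=R, dropped=dropped,
    )


def heidi_outlier_filter(
    inst: InstrumentSet, config: GsmrConfig | None = None
) -> InstrumentSet:
    """Iteratively remove instruments with heterogeneous Wald ratios.

    A provisional global effect (median of per-SNP ratios, for robustness)
    anchors a per-SNP z_d test; SNPs with heterogeneity p below
    ``p_heidi_outlier`` are removed and the provisional effect
    re-estimated, to a fixed point or ``max_filter_iter`` iterations.
    Skipped (with a warning) below ``min_instruments_for_filter``
    instruments.
    """
    cfg = config or GsmrConfig()
    if inst.n_instruments < cfg.min_instruments_for_filter:
        log.warning(
            "outlier filter skipped for %s->%s: only %d instruments",
            inst.exposure_id, inst.outcome_id, inst.n_instruments,
        )
        return inst
    keep = np.arange(inst.n_instruments)
    removed: list[tuple[str, str]] = []
    b_all, var_all = inst.ratios()
    for _ in range(cfg.max_filter_iter):
        if keep.size == 0:
            break
        b = b_all[keep]
        var = var_all[keep]
        med = float(np.median(b))
        # SE of d_i = b_i - median includes the median's own sampling
        # variance (~ pi/2 times that of the mean for Gaussian ratios)
        var_med = (np.pi / 2.0) * float(np.mean(var)) / keep.size
        z_d = (b - med) / np.sqrt(var + var_med)
        p = 2.0 * stats.norm.sf(np.abs(z_d))
        bad = p < cfg.p_heidi_outlier
        if not bad.any():
            break
        for i in keep[bad]:
            removed.append((inst.snps[i][0].snp_id, "heidi-outlier"))
        keep = keep[~bad]
    pairs = [inst.snps[i] for i in keep]
    R = inst.ld_corr[np.ix_(keep, keep)]
    return InstrumentSet(
        exposure_id=inst.exposure_id, outcome_id=inst.outcome_id,
        snps=pairs, ld_corr=R, dropped=inst.dropped + removed,
    )


def fit(
    inst: InstrumentSet,
    config: GsmrConfig | None = None,
    direction: str = "forward",
) -> MrResult:
    """GLS-combined causal estimate from an instrument set."""
    cfg = config or GsmrConfig()
    removed = [d for d in inst.dropped if d[1] == "heidi-outlier"]
    if inst.n_instruments == 0:
        return _not_testable(inst.exposure_id, inst.outcome_id, direction,
                             "no-instruments", removed)
    b, var = inst.ratios()
    R = np.array(inst.ld_corr, dtype=float)
    if np.linalg.cond(R) > cfg.cond_max:
        R = (R + cfg.ridge * np.eye(len(b))) / (1.0 + cfg.ridge)
        log.warning("fit: ill-conditioned LD correlation; ridge applied")
    # exact delta-method covariance of the Wald ratios; keeps the beta signs
    # so the estimate is invariant to per-SNP allele relabeling (it reduces
    # to r_ij * sqrt(var_i var_j) when all orientations agree)
    be = np.array([e.beta for e, _ in inst.snps])
    se_e = np.array([e.se for e, _ in inst.snps])
    bo = np.array([o.beta for _, o in inst.snps])
    se_o = np.array([o.se for _, o in inst.snps])
    V = R * (np.outer(se_o, se_o) / np.outer(be, be)
             + np.outer(bo * se_e, bo * se_e) / np.outer(be**2, be**2))
    try:
        w = np.linalg.solve(V, np.ones_like(b))
    except np.linalg.LinAlgError:
        V = V + cfg.ridge * np.diag(var)
        try:
            w = np.linalg.solve(V, np.ones_like(b))
        except np.linalg.LinAlgError:
            return _not_testable(inst.exposure_id, inst.outcome_id, direction,
                                 "singular-covariance", removed)
    denom = float(w.sum())
    if denom <= 0:
        return _not_testable(inst.exposure_id, inst.outcome_id, direction,
                             "singular-covariance", removed)
    b_xy = float(w @ b) / denom
    se_xy = float(np.sqrt(1.0 / denom))
    p_xy = max(float(2.0 * stats.norm.sf(abs(b_xy) / se_xy)), P_FLOOR)
    return MrResult(
        exposure_id=inst.exposure_id, outcome_id=inst.outcome_id,
        direction=direction, b_xy=b_xy, se_xy=se_xy, p_xy=p_xy,
        n_instruments=inst.n_instruments, removed_snps=removed, testable=True,
        reason="ok",
    )


def mr_forward(
    exposure: QtlProbeSet,
    outcome: Sequence[SumStatRecord],
    panel: LdPanel,
    config: GsmrConfig | None = None,
    outcome_id: str = "outcome",
    direction: str = "forward",
) -> MrResult:
    """Instrument selection + outlier removal + GLS fit in one call."""
    inst = select_instruments(exposure, outcome, panel, config, outcome_id)
    if inst.n_instruments == 0:
        return _not_testable(exposure.probe_id, outcome_id, direction,
                             "no-instruments")
    inst = heidi_outlier_filter(inst, config)
    return fit(inst, config, direction)


def bidirectional(
    exposure_qtl: QtlProbeSet,
    outcome_records: Sequence[SumStatRecord],
    panel: LdPanel,
    config: GsmrConfig | None = None,
    outcome_id: str = "outcome",
    p_reverse: float = 0.05,
) -> tuple[MrResult, MrResult, bool]:
    """Forward (exposure -> outcome) and reverse (outcome -> exposure) MR.

    The reverse direction instruments on outcome-associated SNPs (same
    significance threshold) and uses the exposure's QTL records as outcome
    statistics.  ``reverse_ok`` is true when the reverse test is either not
    testable (no significant, paired outcome instruments) or yields
    ``p >= p_reverse``; the pipeline excludes pairs with reverse evidence.
    """
    forward = mr_forward(exposure_qtl, outcome_records, panel, config,
                         outcome_id=outcome_id, direction="forward")
    pseudo = QtlProbeSet(
        probe_id=outcome_id, probe_chrom="", probe_bp=-1, gene_name="",
        records=list(outcome_records),
    )
    reverse = mr_forward(pseudo, exposure_qtl.records, panel, config,
                         outcome_id=exposure_qtl.probe_id, direction="reverse")
    reverse_ok = (not reverse.testable) or (reverse.p_xy >= p_reverse)
    return forward, reverse, reverse_ok
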