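"""End-to-end orchestration: co-localization -> bidirectional MR ->
replication -> expression mediation, with per-pair reason codes.

Stage ordering is enforced and audited: no MR without a co-localization
pass, no replication without a discovery pass, no expression mediation
without a final pass.  Every threshold lives in :class:`PipelineConfig`;
the defaults are the screen's canonical operating point (genome-wide
5e-8 at each MR stage, reverse-causation exclusion at 0.05, instrument
LD below r2 0.2, HEIDI retention at 0.01).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .gsmr import GsmrConfig, MrResult, bidirectional, mr_forward
from .ld import LdPanel
from .smr import HeidiConfig, SmrResult, screen_probe
from .sumstats_io import QtlProbeSet, SumStatRecord

log = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Every threshold the screen applies, in one validated object."""

    p_colocalization: float = 5e-8   #: SMR pass threshold
    p_instrument: float = 5e-8       #: exposure-side instrument significance
    p_mr: float = 5e-8               #: causal-contribution threshold (all MR stages)
    p_reverse: float = 0.05          #: reverse-causation exclusion threshold
    r2_instruments: float = 0.2      #: LD ceiling among MR instruments
    p_heidi_outlier: float = 0.01    #: per-SNP pleiotropy removal inside GSMR
    heidi_keep_p: float = 0.01       #: probe-level HEIDI retention threshold
    heidi_gate: bool = True          #: drop HEIDI-rejected pairs before MR
    undefined_heidi_pass: bool = True
    r2_pathway: float = 0.05
    p_eqtl: float = 5e-8
    cis_window_kb: float = 1000.0    #: locus definition for gene mediation
    clump_window_kb: float = 10_000.0
    palindrome_maf_limit: float = 0.4
    heidi: HeidiConfig = Field(default_factory=HeidiConfig)

    model_config = {"arbitrary_types_allowed": True}

    @model_validator(mode="after")
    def _check(self):
        for name in ("p_colocalization", "p_instrument", "p_mr", "p_reverse",
                     "p_heidi_outlier", "heidi_keep_p", "p_eqtl"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("r2_instruments", "r2_pathway"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        return self

    def gsmr_config(self) -> GsmrConfig:
        return GsmrConfig(
            p_exposure=self.p_instrument, r2_instruments=self.r2_instruments,
            clump_window_kb=self.clump_window_kb,
            p_heidi_outlier=self.p_heidi_outlier,
            palindrome_maf_limit=self.palindrome_maf_limit,
        )


@dataclasses.dataclass
class GeneLink:
    gene_id: str
    cpg_to_gene: MrResult
    gene_to_trait: MrResult
    sign_consistent: bool


@dataclasses.dataclass
class MediationRecord:
    cpg_id: str
    trait_id: str
    smr: SmrResult | None = None
    discovery: MrResult | None = None
    reverse: MrResult | None = None
    reverse_ok: bool = True
    replication: MrResult | None = None
    gene_links: list[GeneLink] = dataclasses.field(default_factory=list)
    final_pass: bool = False
    sign_discordant: bool = False
    reasons: list[str] = dataclasses.field(default_factory=list)
    stage_log: list[str] = dataclasses.field(default_factory=list)

    @property
    def discovery_pass(self) -> bool:
        return bool(
            self.smr is not None and self.smr.pass_smr
            and self.discovery is not None and self.discovery.testable
            and self.discovery.p_xy is not None
        )


def run_discovery(
    candidate_cpgs: Sequence[QtlProbeSet],
    traits: Mapping[str, Sequence[SumStatRecord]],
    panel: LdPanel,
    config: PipelineConfig | None = None,
) -> list[MediationRecord]:
    """Stage 1+2: SMR/HEIDI screen, then bidirectional MR on passing pairs.

    Every CpG x trait pair yields a record; untestable or failing pairs
    carry reason codes and never abort the run.
    """
    cfg = config or PipelineConfig()
    gcfg = cfg.gsmr_config()
    out: list[MediationRecord] = []
    for probe in candidate_cpgs:
        for trait_id, gwas in traits.items():
            rec = MediationRecord(cpg_id=probe.probe_id, trait_id=trait_id)
            rec.stage_log.append("screen")
            smr_res, reason = screen_probe(
                probe, trait_id, gwas, panel,
                p_instrument=cfg.p_instrument,
                p_colocalization=cfg.p_colocalization,
                heidi_keep_p=cfg.heidi_keep_p,
                undefined_heidi_pass=cfg.undefined_heidi_pass,
                heidi_config=cfg.heidi,
                palindrome_maf_limit=cfg.palindrome_maf_limit,
            )
            if smr_res is None:
                rec.reasons.append(reason)
                out.append(rec)
                continue
            rec.smr = smr_res
            if not smr_res.pass_smr:
                rec.reasons.append("smr-fail")
                out.append(rec)
                continue
            if cfg.heidi_gate and not smr_res.pass_heidi:
                rec.reasons.append("heidi-fail")
                out.append(rec)
                continue
            rec.stage_log.append("mr")
            fwd, rev, rev_ok = bidirectional(
                probe, gwas, panel, gcfg, outcome_id=trait_id,
                p_reverse=cfg.p_reverse,
            )
            rec.discovery, rec.reverse, rec.reverse_ok = fwd, rev, rev_ok
            if not fwd.testable:
                rec.reasons.append(f"forward-{fwd.reason}")
            elif fwd.p_xy >= cfg.p_mr:
                rec.reasons.append("discovery-not-significant")
            if not rev_ok:
                rec.reasons.append("reverse-causation")
            out.append(rec)
    return out


def run_replication(
    records: Sequence[MediationRecord],
    replication_mqtl: Mapping[str, QtlProbeSet],
    traits: Mapping[str, Sequence[SumStatRecord]],
    panel: LdPanel,
    config: PipelineConfig | None = None,
) -> list[MediationRecord]:
    """Stage 3: forward MR in the replication cohort; sets ``final_pass``.

    ``final_pass`` requires discovery p < p_mr, replication p < p_mr, no
    reverse-causation evidence in discovery, and (when the HEIDI gate is
    active) a HEIDI pass.  Replication filters on p only; a significant
    but sign-flipped replication passes with a ``sign-discordant`` flag.
    """
    cfg = config or PipelineConfig()
    gcfg = cfg.gsmr_config()
    for rec in records:
        eligible = (
            rec.discovery_pass and rec.discovery.p_xy < cfg.p_mr and rec.reverse_ok
            and (rec.smr.pass_heidi or not cfg.heidi_gate)
        )
        if not eligible:
            continue
        probe = replication_mqtl.get(rec.cpg_id)
        if probe is None:
            rec.reasons.append("not-in-replication")
            continue
        rec.stage_log.append("replication")
        rep = mr_forward(probe, traits[rec.trait_id], panel, gcfg,
                         outcome_id=rec.trait_id)
        rec.replication = rep
        if not rep.testable:
            rec.reasons.append(f"replication-{rep.reason}")
            continue
        if rep.p_xy < cfg.p_mr:
            rec.final_pass = True
            if rep.b_xy * rec.discovery.b_xy < 0:
                rec.sign_discordant = True
                rec.reasons.append("sign-discordant")
        else:
            rec.reasons.append("replication-not-significant")
    return list(records)


def mediate_expression(
    record: MediationRecord,
    mqtl: QtlProbeSet,
    eqtl_sets: Sequence[QtlProbeSet],
    gwas: Sequence[SumStatRecord],
    panel: LdPanel,
    config: PipelineConfig | None = None,
) -> MediationRecord:
    """Stage 4: chain CpG -> gene expression -> trait for a passing pair.

    Genes are in the locus when their top eQTL SNP lies within
    ``cis_window_kb`` of the CpG.  A gene link is reported when both MR
    legs are significant at ``p_mr``; the product of the two effect signs
    must match the direct CpG -> trait sign, else the link is flagged.
    """
    cfg = config or PipelineConfig()
    if not record.final_pass:
        raise ValueError("mediation requested for a pair without final_pass")
    gcfg = cfg.gsmr_config()
    record.stage_log.append("mediation")
    window = cfg.cis_window_kb * 1000.0
    for gene_set in eqtl_sets:
        top = gene_set.top_snp()
        chrom, bp = (top.chrom, top.bp)
        if top.snp_id in panel and (top.bp < 0 or not top.chrom):
            chrom, bp = panel.position(top.snp_id)
        if chrom != mqtl.probe_chrom or abs(bp - mqtl.probe_bp) > window:
            continue
        c2g = mr_forward(mqtl, gene_set.records, panel, gcfg,
                         outcome_id=gene_set.gene_name or gene_set.probe_id)
        if not c2g.testable or c2g.p_xy >= cfg.p_mr:
            continue
        g2t = mr_forward(gene_set, gwas, panel, gcfg, outcome_id=record.trait_id)
        if not g2t.testable or g2t.p_xy >= cfg.p_mr:
            continue
        sign_ok = (c2g.b_xy * g2t.b_xy) * record.discovery.b_xy > 0
        if not sign_ok:
            record.reasons.append(
                f"sign-inconsistent-chain:{gene_set.gene_name or gene_set.probe_id}"
            )
        record.gene_links.append(GeneLink(
            gene_id=gene_set.gene_name or gene_set.probe_id,
            cpg_to_gene=c2g, gene_to_trait=g2t, sign_consistent=sign_ok,
        ))
    return record


def run_all(
    candidate_cpgs: Sequence[QtlProbeSet],
    traits: Mapping[str, Sequence[SumStatRecord]],
    replication_mqtl: Mapping[str, QtlProbeSet],
    eqtl_sets: Sequence[QtlProbeSet],
    panel: LdPanel,
    config: PipelineConfig | None = None,
) -> list[MediationRecord]:
    """Discovery -> replication -> expression mediation, in order."""
    cfg = config or PipelineConfig()
    records = run_discovery(candidate_cpgs, traits, panel, cfg)
    records = run_replication(records, replication_mqtl, traits, panel, cfg)
    mqtl_by_probe = {p.probe_id: p for p in candidate_cpgs}
    for rec in records:
        if rec.final_pass:
            mediate_expression(rec, mqtl_by_probe[rec.cpg_id], eqtl_sets,
                               traits[rec.trait_id], panel, cfg)
    return records


# ---------------------------------------------------------------------------
# export and scoring
# ---------------------------------------------------------------------------

_EXPORT_COLUMNS = [
    "trait_id", "cpg_id", "top_snp", "b_smr", "se_smr", "p_smr", "p_heidi",
    "n_heidi_snps", "pass_smr", "pass_heidi",
    "b_discovery", "se_discovery", "p_discovery", "n_instruments_discovery",
    "reverse_ok", "p_reverse",
    "b_replication", "se_replication", "p_replication",
    "final_pass", "sign_discordant", "genes", "reasons",
    "p_discovery_bonferroni", "b_discovery_display", "b_replication_display",
]


def export_results(records: Sequence[MediationRecord], path) -> pd.DataFrame:
    """Deterministic results table, ordered by (trait, cpg).

    Betas/SEs are written at full precision; ``*_display`` columns carry
    rounded copies for human reading.  Re-reading the TSV reproduces the
    pass flags.
    """
    rows = []
    for r in sorted(records, key=lambda r: (r.trait_id, r.cpg_id)):
        def mr_fields(m: MrResult | None):
            if m is None or not m.testable:
                return None, None, None, 0
            return m.b_xy, m.se_xy, m.p_xy, m.n_instruments

        bd, sed, pdisc, nd = mr_fields(r.discovery)
        br, ser, prep, _ = mr_fields(r.replication)
        rows.append({
            "trait_id": r.trait_id, "cpg_id": r.cpg_id,
            "top_snp": r.smr.top_snp if r.smr else "",
            "b_smr": r.smr.b_smr if r.smr else None,
            "se_smr": r.smr.se_smr if r.smr else None,
            "p_smr": r.smr.p_smr if r.smr else None,
            "p_heidi": r.smr.p_heidi if r.smr else None,
            "n_heidi_snps": r.smr.n_heidi_snps if r.smr else 0,
            "pass_smr": bool(r.smr.pass_smr) if r.smr else False,
            "pass_heidi": bool(r.smr.pass_heidi) if r.smr else False,
            "b_discovery": bd, "se_discovery": sed, "p_discovery": pdisc,
            "n_instruments_discovery": nd,
            "reverse_ok": bool(r.reverse_ok),
            "p_reverse": (r.reverse.p_xy if r.reverse is not None
                          and r.reverse.testable else None),
            "b_replication": br, "se_replication": ser, "p_replication": prep,
            "final_pass": bool(r.final_pass),
            "sign_discordant": bool(r.sign_discordant),
            "genes": ";".join(g.gene_id for g in r.gene_links),
            "reasons": ";".join(r.reasons),
            # report-only multiplicity column; the screen itself applies the
            # fixed per-stage threshold, not an across-pairs correction
            "p_discovery_bonferroni": (None if pdisc is None
                                       else min(1.0, pdisc * len(records))),
            "b_discovery_display": None if bd is None else round(bd, 3),
            "b_replication_display": None if br is None else round(br, 3),
        })
    df = pd.DataFrame(rows, columns=_EXPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def score_against_manifest(records: Sequence[MediationRecord],
                           manifest: dict) -> dict:
    """TP/FP/flagging summary of a pipeline run against simulation truth.

    A true positive is a final-pass record matching a planted
    (mediation CpG, trait) pair; any other final-pass record is a false
    positive.  For linkage/reverse CpGs the summary also reports how often
    pairs that cleared the SMR stage were flagged by HEIDI or the
    reverse-causation filter ("caught").
    """
    true_pairs = {tuple(p) for p in manifest["true_pairs"]}
    topo = {c: info["topology"] for c, info in manifest["cpgs"].items()}
    tp = fp = 0
    confound_passed_smr = 0
    confound_caught = 0
    for rec in records:
        if rec.final_pass:
            if (rec.cpg_id, rec.trait_id) in true_pairs:
                tp += 1
            else:
                fp += 1
        if topo.get(rec.cpg_id) in ("linkage", "reverse"):
            if rec.smr is not None and rec.smr.pass_smr:
                confound_passed_smr += 1
                heidi_flag = not rec.smr.pass_heidi
                reverse_flag = not rec.reverse_ok
                if heidi_flag or reverse_flag:
                    confound_caught += 1
    return {
        "n_true_pairs": len(true_pairs),
        "tp": tp,
        "fp": fp,
        "tpr": tp / len(true_pairs) if true_pairs else float("nan"),
        "confound_passed_smr": confound_passed_smr,
        "confound_caught": confound_caught,
        "confound_caught_rate": (confound_caught / confound_passed_smr
                                 if confound_passed_smr else float("nan")),
    }
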