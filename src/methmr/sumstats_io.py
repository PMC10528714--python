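"""Readers, writers and allele-aware record semantics for summary statistics.

The pipeline consumes three flat-file dialects:

* GWAS associations in the COJO ``.ma`` layout
  (``SNP A1 A2 freq b se p N``, whitespace separated),
* cis-QTL tables for methylation probes or genes in a long TSV layout
  (one row per probe x SNP), and
* gene sets in GMT (set id, description, then member gene symbols).

All readers transparently accept gzip-compressed files.  Records are
validated against the invariants that make two-sample MR meaningful
(positive SEs, alleles distinct, p consistent with beta/se), and
:func:`harmonize` re-expresses one record on another record's effect
allele, the step every two-cohort comparison in the pipeline starts with.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Smallest p-value ever emitted; avoids 0 from extreme-tail underflow.
P_FLOOR = 1e-300


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclasses.dataclass(slots=True)
class SumStatRecord:
    """One SNP's association with one entity (trait, CpG or gene).

    ``beta`` is the effect per copy of ``a1`` (the effect allele); ``freq``
    is the frequency of ``a1``.  ``chrom``/``bp`` may be unknown (empty / -1)
    for GWAS dialects that omit positions; they are then filled from the LD
    panel's SNP map.
    """

    snp_id: str
    a1: str
    a2: str
    freq: float
    beta: float
    se: float
    p: float
    n: float
    chrom: str = ""
    bp: int = -1

    @property
    def z(self) -> float:
        return self.beta / self.se

    def validate(self, p_z_rel_tol: float = 10.0, warn: bool = True) -> None:
        """Raise ``ValueError`` on a broken invariant.

        The p vs |z| consistency check only warns by default because
        published files round p-values; ``p_z_rel_tol`` is the tolerated
        multiplicative discrepancy between the stated p and
        ``2 * Phi(-|beta/se|)``.
        """
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.snp_id}: se must be > 0 (got {self.se})")
        if not (0.0 <= self.freq <= 1.0):
            raise ValueError(f"{self.snp_id}: freq outside [0,1] (got {self.freq})")
        if self.a1 == self.a2:
            raise ValueError(f"{self.snp_id}: a1 == a2 ({self.a1})")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: non-finite beta")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.snp_id}: p outside (0,1] (got {self.p})")
        if self.n < 1:
            raise ValueError(f"{self.snp_id}: n < 1 (got {self.n})")
        if warn and not self.p_consistent(p_z_rel_tol):
            log.warning(
                "%s: stated p=%.3g inconsistent with z=%.3f beyond %gx",
                self.snp_id, self.p, self.z, p_z_rel_tol,
            )

    def p_consistent(self, rel_tol: float = 10.0) -> bool:
        p_from_z = max(float(2.0 * stats.norm.sf(abs(self.z))), P_FLOOR)
        if max(self.p, p_from_z) < 1e-20:
            # deep in the tail the normal approximation and the (often
            # t-based) stated p legitimately diverge by orders of magnitude
            return True
        lo, hi = p_from_z / rel_tol, min(1.0, p_from_z * rel_tol)
        return lo <= self.p <= hi


@dataclasses.dataclass(slots=True)
class QtlProbeSet:
    """All available SNP records for one methylation probe or gene."""

    probe_id: str
    probe_chrom: str
    probe_bp: int
    gene_name: str
    records: list[SumStatRecord]

    def validate(self) -> None:
        if not self.records:
            raise ValueError(f"{self.probe_id}: empty record set")
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.probe_id}: duplicate snp_id in probe set")

    def top_snp(self) -> SumStatRecord:
        """Record with the smallest QTL p-value (ties: smallest bp, then id)."""
        return min(self.records, key=lambda r: (r.p, r.bp, r.snp_id))

    def by_snp(self) -> dict[str, SumStatRecord]:
        return {r.snp_id: r for r in self.records}


@dataclasses.dataclass(slots=True)
class GeneSet:
    set_id: str
    description: str
    genes: list[str]


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


_MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


def read_gwas_ma(
    path,
    *,
    drop_invalid: bool = False,
    snp_map: dict[str, tuple[str, int]] | None = None,
    p_z_rel_tol: float = 10.0,
) -> list[SumStatRecord]:
    """Read a COJO ``.ma`` summary-statistics file.

    Parameters
    ----------
    drop_invalid
        When true, rows violating record invariants are dropped with a
        logged warning instead of raising.
    snp_map
        Optional ``snp_id -> (chrom, bp)`` filled into records (the ``.ma``
        dialect carries no positions).
    """
    records: list[SumStatRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().split()
        lower = [h.lower() for h in header]
        for col in _MA_COLUMNS:
            if col.lower() not in lower:
                raise FormatError(f"{path}: missing required column '{col}'")
        idx = {col: lower.index(col.lower()) for col in _MA_COLUMNS}
        extra = [h for h in header if h.lower() not in {c.lower() for c in _MA_COLUMNS}]
        if extra:
            log.warning("%s: ignoring extra columns %s", path, extra)
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            try:
                rec = SumStatRecord(
                    snp_id=fields[idx["SNP"]],
                    a1=fields[idx["A1"]].upper(),
                    a2=fields[idx["A2"]].upper(),
                    freq=float(fields[idx["freq"]]),
                    beta=float(fields[idx["b"]]),
                    se=float(fields[idx["se"]]),
                    p=float(fields[idx["p"]]),
                    n=float(fields[idx["N"]]),
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: unparseable row ({exc})") from exc
            if snp_map is not None and rec.snp_id in snp_map:
                rec.chrom, rec.bp = snp_map[rec.snp_id]
            try:
                rec.validate(p_z_rel_tol=p_z_rel_tol)
            except ValueError as exc:
                if drop_invalid:
                    log.warning("%s:%d: dropping invalid row: %s", path, lineno, exc)
                    continue
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_gwas_ma(records: Iterable[SumStatRecord], path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(_MA_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.snp_id}\t{r.a1}\t{r.a2}\t{r.freq:.10g}\t{r.beta:.10g}\t"
                f"{r.se:.10g}\t{r.p:.10g}\t{r.n:.10g}\n"
            )


_QTL_COLUMNS = [
    "probe_id", "probe_chrom", "probe_bp", "gene", "snp_id", "chrom", "bp",
    "a1", "a2", "freq", "beta", "se", "p", "n",
]


def read_qtl_table(path, *, drop_invalid: bool = False) -> list[QtlProbeSet]:
    """Read a long-format QTL TSV, grouping rows by ``probe_id`` in file order.

    A BESD-derived text export (SMR's ``--query`` output) maps onto this
    schema directly: Probe/Chr/bp/Gene annotate the probe; the remaining
    columns are the per-SNP association fields.
    """
    order: list[str] = []
    sets: dict[str, QtlProbeSet] = {}
    seen: set[tuple[str, str]] = set()
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_QTL_COLUMNS)] != _QTL_COLUMNS:
            raise FormatError(
                f"{path}: expected columns {_QTL_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                probe_id = f[0]
                rec = SumStatRecord(
                    snp_id=f[4], a1=f[7].upper(), a2=f[8].upper(),
                    freq=float(f[9]), beta=float(f[10]), se=float(f[11]),
                    p=float(f[12]), n=float(f[13]), chrom=f[5], bp=int(f[6]),
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: unparseable row ({exc})") from exc
            key = (probe_id, rec.snp_id)
            if key in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate (probe_id, snp_id) pair {key}"
                )
            seen.add(key)
            try:
                rec.validate()
            except ValueError as exc:
                if drop_invalid:
                    log.warning("%s:%d: dropping invalid row: %s", path, lineno, exc)
                    continue
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if probe_id not in sets:
                order.append(probe_id)
                sets[probe_id] = QtlProbeSet(
                    probe_id=probe_id, probe_chrom=f[1], probe_bp=int(f[2]),
                    gene_name=f[3], records=[],
                )
            sets[probe_id].records.append(rec)
    return [sets[p] for p in order]


def write_qtl_table(probe_sets: Iterable[QtlProbeSet], path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(_QTL_COLUMNS) + "\n")
        for ps in probe_sets:
            for r in ps.records:
                fh.write(
                    f"{ps.probe_id}\t{ps.probe_chrom}\t{ps.probe_bp}\t{ps.gene_name}\t"
                    f"{r.snp_id}\t{r.chrom}\t{r.bp}\t{r.a1}\t{r.a2}\t{r.freq:.10g}\t"
                    f"{r.beta:.10g}\t{r.se:.10g}\t{r.p:.10g}\t{r.n:.10g}\n"
                )


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set file (name, description, member genes per line)."""
    out: list[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            genes: list[str] = []
            for g in fields[2:]:
                if not g:
                    continue
                if g in genes:
                    log.warning(
                        "%s:%d: duplicate gene %s in set %s", path, lineno, g, fields[0]
                    )
                    continue
                genes.append(g)
            out.append(GeneSet(set_id=fields[0], description=fields[1], genes=genes))
    return out


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "wt") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G SNPs cannot be strand-resolved from alleles alone."""
    return _COMPLEMENT.get(a1) == a2


def _complement_alleles(a1: str, a2: str) -> tuple[str, str] | None:
    try:
        return _COMPLEMENT[a1], _COMPLEMENT[a2]
    except KeyError:
        return None


def harmonize(
    reference: SumStatRecord,
    other: SumStatRecord,
    *,
    palindrome_maf_limit: float = 0.4,
) -> tuple[SumStatRecord | None, str]:
    """Express ``other`` on ``reference``'s effect allele.

    Returns ``(record, reason)``; ``record`` is ``None`` when the SNP must be
    excluded, with ``reason`` one of ``"palindromic-ambiguous"`` or
    ``"allele-mismatch"``.  Successful reasons are ``"ok"`` (identical
    orientation), ``"allele-swap"``, ``"strand-flip"``,
    ``"strand-flip-swap"`` or ``"palindromic-freq-aligned"``.

    Palindromic (A/T, C/G) SNPs are aligned by allele-frequency concordance
    and excluded as ambiguous when either record's minor-allele frequency
    exceeds ``palindrome_maf_limit`` (common SNPs carry no orientation
    information).  Harmonization never changes ``|beta|``, ``se``, ``p`` or
    ``n``.
    """
    if reference.snp_id != other.snp_id:
        raise ValueError(
            f"harmonize called on different SNPs: {reference.snp_id} vs {other.snp_id}"
        )
    ra = (reference.a1, reference.a2)

    def _flipped(rec: SumStatRecord) -> SumStatRecord:
        return dataclasses.replace(
            rec, a1=reference.a1, a2=reference.a2,
            beta=-rec.beta, freq=1.0 - rec.freq,
        )

    def _same(rec: SumStatRecord) -> SumStatRecord:
        return dataclasses.replace(rec, a1=reference.a1, a2=reference.a2)

    if is_palindromic(other.a1, other.a2):
        if {other.a1, other.a2} != {reference.a1, reference.a2}:
            return None, "allele-mismatch"
        maf = min(other.freq, 1.0 - other.freq)
        ref_maf = min(reference.freq, 1.0 - reference.freq)
        if maf > palindrome_maf_limit or ref_maf > palindrome_maf_limit:
            return None, "palindromic-ambiguous"
        # normalize labels, then strand-correct so the a1 frequency falls on
        # the same side of 0.5 as the reference's
        out = _same(other) if (other.a1, other.a2) == ra else _flipped(other)
        if (out.freq - 0.5) * (reference.freq - 0.5) < 0:
            out = dataclasses.replace(out, beta=-out.beta, freq=1.0 - out.freq)
        unchanged = (out.beta == other.beta and out.freq == other.freq
                     and (other.a1, other.a2) == ra)
        return out, "ok" if unchanged else "palindromic-freq-aligned"

    if (other.a1, other.a2) == ra:
        return _same(other), "ok"
    if (other.a2, other.a1) == ra:
        return _flipped(other), "allele-swap"
    comp = _complement_alleles(other.a1, other.a2)
    if comp is not None:
        if comp == ra:
            return _same(other), "strand-flip"
        if (comp[1], comp[0]) == ra:
            return _flipped(other), "strand-flip-swap"
    return None, "allele-mismatch"


def harmonize_many(
    reference_by_snp: dict[str, SumStatRecord],
    records: Sequence[SumStatRecord],
    *,
    palindrome_maf_limit: float = 0.4,
) -> tuple[list[SumStatRecord], list[tuple[str, str]]]:
    """Harmonize a record list against a reference map; exclusions logged.

    Records without a reference entry are excluded with reason
    ``"no-reference-record"``.
    """
    kept: list[SumStatRecord] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        ref = reference_by_snp.get(rec.snp_id)
        if ref is None:
            excluded.append((rec.snp_id, "no-reference-record"))
            continue
        out, reason = harmonize(ref, rec, palindrome_maf_limit=palindrome_maf_limit)
        if out is None:
            excluded.append((rec.snp_id, reason))
        else:
            kept.append(out)
    return kept, excluded
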