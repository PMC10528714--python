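"""LD reference panel: pairwise r2 queries and greedy p-value clumping.

The panel is an individual-level genotype matrix (dosage 0/1/2, missing
allowed) over a set of SNPs.  All LD here is the squared (or signed)
Pearson correlation of dosages over pairwise-complete individuals, the
quantity PLINK's ``--clump`` step operates on; phase-aware measures (D')
are out of scope.

Sign convention: correlations are between counted-allele (``a1``) dosages
as stored in the panel.  Summary records must be harmonized to the panel's
``a1`` (see :func:`methmr.sumstats_io.harmonize_many` with
:meth:`LdPanel.reference_records`) before their betas are combined with
signed LD.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats_io import SumStatRecord

log = logging.getLogger(__name__)


class LdError(ValueError):
    """Undefined LD (monomorphic SNP, too few pairwise-complete samples)."""


class LdPanel:
    """Genotype reference supporting pairwise r2 queries.

    Parameters
    ----------
    snp_ids, chrom, bp, a1
        Per-SNP metadata; ``a1`` is the counted allele (dosage = copies of
        a1).  ``a2`` defaults to ``"N"`` when the source format lacks it.
    genotypes
        ``n_individuals x n_snps`` float array with ``nan`` for missing.
    """

    def __init__(
        self,
        snp_ids: Sequence[str],
        chrom: Sequence[str],
        bp: Sequence[int],
        a1: Sequence[str],
        genotypes: np.ndarray,
        a2: Sequence[str] | None = None,
    ):
        self.snp_ids = list(snp_ids)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_ids in panel")
        self.chrom = list(chrom)
        self.bp = [int(b) for b in bp]
        self.a1 = list(a1)
        self.a2 = list(a2) if a2 is not None else ["N"] * len(self.snp_ids)
        G = np.asarray(genotypes, dtype=np.float64)
        if G.ndim != 2 or G.shape[1] != len(self.snp_ids):
            raise ValueError("genotype matrix shape does not match snp_ids")
        self._G = G
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        self._missing = np.isnan(G)
        self._has_missing = bool(self._missing.any())
        mean = np.nanmean(G, axis=0)
        self._freq = mean / 2.0
        Gc = G - mean
        Gc[self._missing] = 0.0
        self._Gc = Gc
        self._norm = np.sqrt((Gc**2).sum(axis=0))
        # monomorphic: fewer than 2 distinct observed dosage values
        self.monomorphic = np.array(
            [len(np.unique(G[~self._missing[:, j], j])) < 2 for j in range(G.shape[1])]
        )

    @property
    def n_individuals(self) -> int:
        return self._G.shape[0]

    @property
    def n_snps(self) -> int:
        return self._G.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise LdError(f"unknown SNP id: {snp_id}") from None

    def freq(self, snp_id: str) -> float:
        return float(self._freq[self.index(snp_id)])

    def position(self, snp_id: str) -> tuple[str, int]:
        i = self.index(snp_id)
        return self.chrom[i], self.bp[i]

    def snp_map(self) -> dict[str, tuple[str, int]]:
        return {s: (self.chrom[i], self.bp[i]) for i, s in enumerate(self.snp_ids)}

    def reference_records(self, snp_ids: Iterable[str] | None = None) -> dict[str, SumStatRecord]:
        """Pseudo-records carrying the panel's allele orientation and frequency.

        Used as the harmonization reference so that betas and signed LD
        share an allele convention (beta/se/p fields are placeholders).
        """
        ids = self.snp_ids if snp_ids is None else snp_ids
        out = {}
        for s in ids:
            i = self.index(s)
            out[s] = SumStatRecord(
                snp_id=s, a1=self.a1[i], a2=self.a2[i],
                freq=float(self._freq[i]), beta=0.0, se=1.0, p=1.0,
                n=self.n_individuals, chrom=self.chrom[i], bp=self.bp[i],
            )
        return out

    # -- correlations ------------------------------------------------------

    def _check_informative(self, i: int) -> None:
        if self.monomorphic[i]:
            raise LdError(f"SNP {self.snp_ids[i]} is monomorphic; LD undefined")

    def corr(self, snp_a: str, snp_b: str) -> float:
        """Signed Pearson correlation of dosages (pairwise-complete)."""
        ia, ib = self.index(snp_a), self.index(snp_b)
        self._check_informative(ia)
        self._check_informative(ib)
        if not self._has_missing:
            denom = self._norm[ia] * self._norm[ib]
            return float(self._Gc[:, ia] @ self._Gc[:, ib] / denom)
        ok = ~(self._missing[:, ia] | self._missing[:, ib])
        if ok.sum() < 3:
            raise LdError(
                f"fewer than 3 pairwise-complete individuals for "
                f"{snp_a}/{snp_b}"
            )
        xa = self._G[ok, ia]
        xb = self._G[ok, ib]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            raise LdError(f"no variation in pairwise-complete subset {snp_a}/{snp_b}")
        return float(np.corrcoef(xa, xb)[0, 1])

    def r2(self, snp_a: str, snp_b: str) -> float:
        """Squared dosage correlation in [0, 1]."""
        return min(1.0, self.corr(snp_a, snp_b) ** 2)

    def corr_vector(self, target: str, snp_ids: Sequence[str]) -> np.ndarray:
        """Signed correlation of ``target`` against each of ``snp_ids``."""
        if not self._has_missing:
            it = self.index(target)
            self._check_informative(it)
            idx = np.array([self.index(s) for s in snp_ids])
            for i in idx:
                self._check_informative(int(i))
            denom = self._norm[it] * self._norm[idx]
            return (self._Gc[:, idx].T @ self._Gc[:, it]) / denom
        return np.array([self.corr(target, s) for s in snp_ids])

    def corr_matrix(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Signed correlation matrix over ``snp_ids`` (unit diagonal)."""
        if not self._has_missing:
            idx = np.array([self.index(s) for s in snp_ids])
            for i in idx:
                self._check_informative(int(i))
            sub = self._Gc[:, idx]
            denom = np.outer(self._norm[idx], self._norm[idx])
            R = (sub.T @ sub) / denom
        else:
            m = len(snp_ids)
            R = np.eye(m)
            for i in range(m):
                for j in range(i + 1, m):
                    R[i, j] = R[j, i] = self.corr(snp_ids[i], snp_ids[j])
        np.fill_diagonal(R, 1.0)
        return np.clip(R, -1.0, 1.0)

    # -- constructors / writers -------------------------------------------

    @classmethod
    def from_tsv(cls, genotype_path, sites_path) -> "LdPanel":
        """Plain-text panel: genotype matrix TSV (rows = individuals,
        columns = SNPs, header = ids) plus a sidecar TSV with columns
        ``snp_id chrom bp a1`` (optional ``a2``)."""
        G = pd.read_csv(genotype_path, sep="\t")
        sites = pd.read_csv(sites_path, sep="\t", dtype={"chrom": str})
        for col in ("snp_id", "chrom", "bp", "a1"):
            if col not in sites.columns:
                raise ValueError(f"{sites_path}: missing column '{col}'")
        order = list(G.columns)
        sites = sites.set_index("snp_id").loc[order]
        return cls(
            snp_ids=order,
            chrom=sites["chrom"].tolist(),
            bp=sites["bp"].tolist(),
            a1=sites["a1"].tolist(),
            a2=sites["a2"].tolist() if "a2" in sites.columns else None,
            genotypes=G.to_numpy(dtype=np.float64),
        )

    def to_tsv(self, genotype_path, sites_path) -> None:
        gdf = pd.DataFrame(self._G, columns=self.snp_ids)
        # keep integer dosages readable; missing stays empty
        gdf.to_csv(genotype_path, sep="\t", index=False, float_format="%g")
        pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "bp": self.bp,
             "a1": self.a1, "a2": self.a2}
        ).to_csv(sites_path, sep="\t", index=False)

    @classmethod
    def from_plink(cls, prefix) -> "LdPanel":
        """Read a PLINK 1 binary fileset (``prefix``.bed/.bim/.fam).

        SNP-major .bed only.  Dosage counts the .bim A1 allele; the 2-bit
        codes are 00 = hom A1 (2), 10 = het (1), 11 = hom A2 (0),
        01 = missing.
        """
        prefix = str(prefix)
        bim = pd.read_csv(
            prefix + ".bim", sep=r"\s+", header=None,
            names=["chrom", "snp_id", "cm", "bp", "a1", "a2"], dtype={"chrom": str},
        )
        with open(prefix + ".fam") as fh:
            n_ind = sum(1 for line in fh if line.strip())
        with open(prefix + ".bed", "rb") as fh:
            magic = fh.read(3)
            if magic[:2] != b"\x6c\x1b":
                raise ValueError(f"{prefix}.bed: bad magic bytes")
            if magic[2] != 1:
                raise ValueError(f"{prefix}.bed: not SNP-major")
            data = np.frombuffer(fh.read(), dtype=np.uint8)
        n_snps = len(bim)
        bytes_per_snp = (n_ind + 3) // 4
        if len(data) != n_snps * bytes_per_snp:
            raise ValueError(f"{prefix}.bed: size inconsistent with .bim/.fam")
        data = data.reshape(n_snps, bytes_per_snp)
        # unpack 2-bit genotype codes, individual-fastest within byte
        shifts = np.arange(4) * 2
        codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
        codes = codes.reshape(n_snps, -1)[:, :n_ind]
        dosage = np.empty(codes.shape, dtype=np.float64)
        dosage[codes == 0] = 2.0
        dosage[codes == 2] = 1.0
        dosage[codes == 3] = 0.0
        dosage[codes == 1] = np.nan
        return cls(
            snp_ids=bim["snp_id"].tolist(), chrom=bim["chrom"].tolist(),
            bp=bim["bp"].tolist(), a1=bim["a1"].tolist(), a2=bim["a2"].tolist(),
            genotypes=dosage.T,
        )


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def clump(
    records: Sequence[SumStatRecord],
    panel: LdPanel,
    p_index: float,
    r2_max: float,
    window_kb: float,
) -> list[str]:
    """Greedy p-value clumping with the PLINK ``--clump`` semantics.

    Candidates are records with ``p <= p_index`` present in the panel
    (absent SNPs dropped with a warning).  Repeatedly take the remaining
    candidate with the smallest p (ties: ascending bp, then snp_id) as an
    index SNP and discard every remaining candidate on the same chromosome
    within ``window_kb`` kilobases whose r2 with it is ``>= r2_max``.
    Returns index SNP ids in selection order.
    """
    cand: list[tuple[float, int, str]] = []
    for rec in records:
        if rec.p > p_index:
            continue
        if rec.snp_id not in panel:
            log.warning("clump: %s absent from LD panel; dropped", rec.snp_id)
            continue
        chrom, bp = panel.position(rec.snp_id)
        if rec.bp >= 0 and rec.chrom:
            chrom, bp = rec.chrom, rec.bp
        cand.append((rec.p, bp, rec.snp_id, chrom))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    kept: list[str] = []
    window_bp = window_kb * 1000.0
    alive = list(cand)
    while alive:
        p0, bp0, snp0, chrom0 = alive.pop(0)
        kept.append(snp0)
        survivors = []
        near = [t for t in alive if t[3] == chrom0 and abs(t[1] - bp0) <= window_bp]
        if near:
            rvec = panel.corr_vector(snp0, [t[2] for t in near])
            doomed = {t[2] for t, r in zip(near, rvec) if r * r >= r2_max}
        else:
            doomed = set()
        for t in alive:
            if t[2] not in doomed:
                survivors.append(t)
        alive = survivors
    return kept
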