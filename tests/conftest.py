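import logging

import numpy as np
import pytest

from methmr.ld import LdPanel
from methmr.pipeline import run_all
from methmr.sumstats_io import SumStatRecord
from methmr.synthetic import ScenarioSpec, simulate_study

logging.getLogger("methmr").setLevel(logging.ERROR)


def make_record(snp_id="rs1", a1="A", a2="G", freq=0.3, beta=0.1, se=0.02,
                p=None, n=10_000, chrom="1", bp=100):
    """Record factory with a p-value consistent with beta/se by default."""
    if p is None:
        from scipy import stats
        p = float(2 * stats.norm.sf(abs(beta / se)))
        p = max(p, 1e-300)
    return SumStatRecord(snp_id=snp_id, a1=a1, a2=a2, freq=freq, beta=beta,
                         se=se, p=p, n=n, chrom=chrom, bp=bp)


def make_panel(G, chrom=None, bp=None, a1=None, a2=None):
    """LdPanel from a raw dosage matrix with generated metadata."""
    m = G.shape[1]
    ids = [f"rs{i+1}" for i in range(m)]
    return LdPanel(
        snp_ids=ids,
        chrom=chrom or ["1"] * m,
        bp=bp or [1000 * (i + 1) for i in range(m)],
        a1=a1 or ["A"] * m,
        a2=a2 or ["G"] * m,
        genotypes=np.asarray(G, dtype=float),
    )


def random_panel(rng, n=60, m=20, maf_range=(0.2, 0.5), chrom=None, bp=None):
    mafs = rng.uniform(*maf_range, size=m)
    G = rng.binomial(2, mafs[None, :], size=(n, m))
    return make_panel(G, chrom=chrom, bp=bp)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced study for fast pipeline-level tests."""
    return ScenarioSpec(
        seed=11, n_mqtl_disc=1200, n_mqtl_repl=1200, n_eqtl=2500,
        n_gwas=8000, n_ref=400,
        n_mediation=3, n_pleiotropy=4, n_linkage=4, n_reverse=4, n_null=15,
        causal_genes_per_trait=4, decoy_genes_per_trait=2,
        background_blocks_per_trait=4,
    )


@pytest.fixture(scope="session")
def study_bundle():
    """One full-size default study, shared across tests."""
    return simulate_study(ScenarioSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_records(study_bundle):
    b = study_bundle
    return run_all(b.mqtl_disc, b.gwas, b.mqtl_repl_by_probe(), b.eqtl, b.panel)
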