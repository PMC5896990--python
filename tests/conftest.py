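import numpy as np
import pytest

from lipidmr import HarmonizedInstrument, SNPAssociation


def make_assoc(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.02,
    eaf=0.3,
    pvalue=None,
    n=10_000,
) -> SNPAssociation:
    """SNPAssociation with a Wald-consistent p-value filled in by default."""
    from scipy.stats import norm

    if pvalue is None and se > 0:
        pvalue = max(2 * norm.sf(abs(beta) / se), 1e-300)
    return SNPAssociation(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def make_instruments(beta_exp, beta_out, se_exp=None, se_out=None):
    """HarmonizedInstrument list from parallel arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    k = len(beta_exp)
    se_exp = np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, dtype=float)
    se_out = np.full(k, 0.05) if se_out is None else np.asarray(se_out, dtype=float)
    return [
        HarmonizedInstrument(
            variant_id=f"rs{i + 1}",
            effect_allele="A",
            beta_exp=float(beta_exp[i]),
            se_exp=float(se_exp[i]),
            beta_out=float(beta_out[i]),
            se_out=float(se_out[i]),
        )
        for i in range(k)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20180412)


@pytest.fixture
def simulated_instruments(rng):
    """50 instruments around a true causal log-OR of 0.4, modest noise."""
    k = 50
    bx = rng.uniform(0.03, 0.12, k) * rng.choice([-1, 1], k)
    sx = np.full(k, 0.004)
    sy = rng.uniform(0.05, 0.12, k)
    by = 0.4 * bx + rng.normal(0, sy)
    return make_instruments(bx, by, sx, sy)
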