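import numpy as np
import pytest

from micromr.sumstats import HarmonizedPair, VariantAssociation


def make_assoc(**kwargs) -> VariantAssociation:
    defaults = dict(
        variant_id="rs1",
        chromosome="1",
        position=1_000_000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.2,
        se=0.04,
        pvalue=1e-6,
        n=2223,
        trait_id="trait",
        trait_type="continuous",
    )
    defaults.update(kwargs)
    return VariantAssociation(**defaults)


def make_pair(bx=0.5, sx=0.05, by=0.1, sy=0.02, vid="rs1", action="kept") -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=vid,
        effect_allele="A",
        other_allele="G",
        exposure_beta=bx,
        exposure_se=sx,
        exposure_eaf=0.3,
        outcome_beta=by,
        outcome_se=sy,
        outcome_eaf=0.3,
        action=action,
    )


def random_pairs(rng: np.random.Generator, n: int) -> list[HarmonizedPair]:
    return [
        make_pair(
            bx=rng.uniform(0.1, 1.0),
            sx=rng.uniform(0.01, 0.1),
            by=rng.normal(0, 0.3),
            sy=rng.uniform(0.01, 0.2),
            vid=f"rs{i + 1}",
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
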