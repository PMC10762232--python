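import numpy as np
import pytest

from imaps.simulate import SimConfig, gen_reference


@pytest.fixture(scope="session")
def ref():
    """Shared toy genome (seed-fixed)."""
    return gen_reference(SimConfig(seed=5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_variant_rows(rng, n, with_cpg_meth=True):
    """Random (window11, derived, meth, dnase, h3k9me3) rows for context tests."""
    bases = np.array(list("ACGT"))
    rows = []
    for _ in range(n):
        w = "".join(bases[rng.integers(0, 4, 11)])
        anc = w[5]
        der = str(rng.choice([b for b in "ACGT" if b != anc]))
        cpg = (anc == "C" and der == "T" and w[6] == "G") or (
            anc == "G" and der == "A" and w[4] == "C"
        )
        meth = float(rng.uniform(0, 100)) if (cpg and with_cpg_meth) else np.nan
        rows.append(
            dict(
                window11=w,
                derived=der,
                meth=meth,
                dnase=bool(rng.random() < 0.3),
                h3k9me3=bool(rng.random() < 0.1),
            )
        )
    return rows
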