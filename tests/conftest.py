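import numpy as np
import pandas as pd
import pytest

from prspipe.io import GenotypeMatrix, SummaryStatSet
from prspipe.qc import Harmonized


def make_sumstats(
    ids, effect, other, weight, p, freq=None, chrom=None, pos=None, trait="toy"
) -> SummaryStatSet:
    n = len(ids)
    table = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom if chrom is not None else ["1"] * n,
            "pos": pos if pos is not None else np.arange(1, n + 1) * 100,
            "effect_allele": effect,
            "other_allele": other,
            "weight": np.asarray(weight, dtype=float),
            "p_value": np.asarray(p, dtype=float),
        }
    )
    if freq is not None:
        table["effect_allele_freq"] = np.asarray(freq, dtype=float)
    return SummaryStatSet(trait_label=trait, table=table)


def make_matrix(dosage, ids=None, ref=None, alt=None, maf=None, info=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = ids if ids is not None else [f"v{j}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["G"] * m,
            "info_score": info if info is not None else [1.0] * m,
        }
    )
    if maf is not None:
        variants["maf"] = maf
    else:
        from prspipe.io import _maf_from_dosage

        variants["maf"] = _maf_from_dosage(dosage)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)], variants=variants, dosage=dosage
    )


def make_harmonized(dosage, weight, p=None, ids=None, trait="toy") -> Harmonized:
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = ids if ids is not None else [f"v{j}" for j in range(m)]
    table = pd.DataFrame(
        {
            "id": ids,
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "effect_allele": ["G"] * m,
            "other_allele": ["A"] * m,
            "weight": np.asarray(weight, dtype=float),
            "p_value": np.asarray(p, dtype=float) if p is not None else np.full(m, 0.5),
        }
    )
    return Harmonized(
        trait_label=trait,
        sample_ids=[f"s{i}" for i in range(n)],
        table=table,
        dosage=dosage,
    )


@pytest.fixture
def toy_harmonized():
    rng = np.random.default_rng(0)
    return make_harmonized(
        rng.integers(0, 3, size=(5, 4)).astype(float),
        weight=[0.3, -0.1, 0.5, 0.2],
        p=[0.0005, 0.002, 0.5, 0.9],
    )
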