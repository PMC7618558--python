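import numpy as np
import pandas as pd
import pytest

from mrforge.sumstats_io import CANONICAL_COLUMNS, HarmonizedSet


def make_sumstats(
    variant_ids,
    beta,
    se,
    chrom="1",
    pos=None,
    eaf=0.3,
    effect_allele="A",
    other_allele="G",
    n=100_000.0,
    n_case=None,
    n_control=None,
    pval=None,
) -> pd.DataFrame:
    """Build a canonical summary-statistics frame from effect arrays."""
    from scipy import stats

    k = len(variant_ids)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)

    def _col(x, default=None):
        if x is None:
            return [default] * k if default is not None else [np.nan] * k
        if np.isscalar(x) or isinstance(x, str):
            return [x] * k
        return list(x)

    if pval is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1)
        pval = np.nan_to_num(pval, nan=1.0)
    df = pd.DataFrame({
        "variant_id": list(variant_ids),
        "chrom": _col(chrom),
        "pos": pos if pos is not None else np.arange(1, k + 1) * 1000,
        "effect_allele": _col(effect_allele),
        "other_allele": _col(other_allele),
        "eaf": _col(eaf),
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": _col(n),
        "n_case": _col(n_case),
        "n_control": _col(n_control),
    })
    return df[CANONICAL_COLUMNS]


def make_harmonized(beta_exp, beta_out, se_out, se_exp=None, n_exp=100_000.0,
                    n_out=100_000.0) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays."""
    from scipy import stats

    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    se_out = np.asarray(se_out, float) * np.ones_like(beta_out)
    se_exp = (np.asarray(se_exp, float) * np.ones_like(beta_exp)
              if se_exp is not None else 0.01 * np.ones_like(beta_exp))
    L = len(beta_exp)
    df = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(L)],
        "chrom": "1",
        "pos": np.arange(1, L + 1) * 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "beta_exp": beta_exp,
        "se_exp": se_exp,
        "pval_exp": np.clip(2 * stats.norm.sf(np.abs(beta_exp / se_exp)),
                            np.finfo(float).tiny, 1),
        "beta_out": beta_out,
        "se_out": se_out,
        "pval_out": np.clip(2 * stats.norm.sf(np.abs(beta_out / se_out)),
                            np.finfo(float).tiny, 1),
        "eaf": 0.3,
        "n_exp": float(n_exp),
        "n_out": float(n_out),
        "palindromic_flag": False,
        "flipped_flag": False,
    })
    return HarmonizedSet(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
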