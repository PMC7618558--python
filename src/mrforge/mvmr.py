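"""Multivariable IVW Mendelian randomization.

Estimates the direct effect of each exposure on the outcome by weighted
least squares of the outcome effects on the matrix of exposure effects with
no intercept, weights 1 / se_out^2.  Standard errors are inflated by the
multiplicative random-effects factor ``max(1, sqrt(Q / (L - k)))`` as in the
univariable case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import DEFAULT_WINDOW_BP, LDMatrix, ld_clump
from .mr_core import Z95, _normal_p

_COND_LIMIT = 1e8


@dataclass
class MVHarmonizedSet:
    """Per-variant effects on k exposures and one outcome, common effect allele.

    ``df`` columns: ``variant_id``, ``beta_exp1..beta_expk``,
    ``se_exp1..se_expk``, ``beta_out``, ``se_out``.
    """

    df: pd.DataFrame
    exposure_labels: tuple[str, ...]
    outcome_label: str = "outcome"

    def __len__(self) -> int:
        return len(self.df)

    @property
    def k(self) -> int:
        return len(self.exposure_labels)

    def exposure_matrix(self) -> np.ndarray:
        cols = [f"beta_exp{i + 1}" for i in range(self.k)]
        return self.df[cols].to_numpy(float)

    def swap_exposures(self) -> "MVHarmonizedSet":
        """Exchange the order of two exposures (k = 2 only)."""
        if self.k != 2:
            raise ValueError("swap_exposures supports exactly two exposures")
        df = self.df.rename(columns={
            "beta_exp1": "beta_exp2", "beta_exp2": "beta_exp1",
            "se_exp1": "se_exp2", "se_exp2": "se_exp1",
        })
        return MVHarmonizedSet(df, (self.exposure_labels[1], self.exposure_labels[0]),
                               self.outcome_label)


@dataclass
class MVMRResult:
    """Direct-effect estimates, one per exposure, plus strength diagnostics."""

    exposure_labels: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pval: np.ndarray
    n_variants: int
    conditional_F: np.ndarray
    Q: float
    Q_pval: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.exposure_labels,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "conditional_F": self.conditional_F,
        })


def mv_instrument_union(
    exp1: pd.DataFrame,
    exp2: pd.DataFrame,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[str]:
    """Instruments significant in either exposure, jointly clumped.

    A variant enters the union if it passes ``p_threshold`` in either
    exposure GWAS; joint clumping ranks variants by the smaller of their two
    p-values.
    """
    if exp1.empty or exp2.empty:
        raise ValueError("both exposure collections must be non-empty")
    merged = exp1.merge(exp2, on="variant_id", how="outer", suffixes=("_1", "_2"))
    p = merged[["pval_1", "pval_2"]].min(axis=1)
    sig = merged[p <= p_threshold].copy()
    if sig.empty:
        raise ValueError(f"no variant reaches p <= {p_threshold:g} in either exposure")
    sig["pval"] = p[p <= p_threshold]
    sig["chrom"] = sig["chrom_1"].fillna(sig["chrom_2"])
    sig["pos"] = sig["pos_1"].fillna(sig["pos_2"])
    clumped = ld_clump(
        sig[["variant_id", "chrom", "pos", "pval"]], ld, r2_threshold, window_bp
    )
    return list(clumped["variant_id"])


def harmonize_mv(
    exposures: list[pd.DataFrame],
    outcome: pd.DataFrame,
    variant_ids: list[str] | None = None,
    exposure_labels: tuple[str, ...] | None = None,
    outcome_label: str = "outcome",
) -> MVHarmonizedSet:
    """Align several exposures and an outcome to the first exposure's alleles.

    Assumes all inputs are canonical summary-statistics frames; variants are
    intersected (optionally restricted to ``variant_ids``) and effects whose
    allele pair is swapped relative to the first exposure are sign-flipped.
    """
    from .sumstats_io import harmonize_pair

    base = exposures[0]
    if variant_ids is not None:
        base = base[base["variant_id"].isin(variant_ids)]
    out_cols: dict[str, pd.Series] = {}
    current_ids = None
    for i, exp in enumerate(exposures[1:], start=2):
        h = harmonize_pair(base, exp)
        out_cols[f"beta_exp{i}"] = h.df.set_index("variant_id")["beta_out"]
        out_cols[f"se_exp{i}"] = h.df.set_index("variant_id")["se_out"]
        ids = set(h.df["variant_id"])
        current_ids = ids if current_ids is None else current_ids & ids
    h_out = harmonize_pair(base, outcome)
    out_cols["beta_out"] = h_out.df.set_index("variant_id")["beta_out"]
    out_cols["se_out"] = h_out.df.set_index("variant_id")["se_out"]
    ids = set(h_out.df["variant_id"])
    current_ids = ids if current_ids is None else current_ids & ids

    base = base[base["variant_id"].isin(current_ids)].reset_index(drop=True)
    df = pd.DataFrame({
        "variant_id": base["variant_id"],
        "beta_exp1": base["beta"].to_numpy(),
        "se_exp1": base["se"].to_numpy(),
    })
    for name, series in out_cols.items():
        df[name] = series.reindex(base["variant_id"]).to_numpy()
    labels = exposure_labels or tuple(f"exposure{i + 1}" for i in range(len(exposures)))
    return MVHarmonizedSet(df, labels, outcome_label)


def mvmr_ivw(m: MVHarmonizedSet) -> MVMRResult:
    """Multivariable IVW: origin-constrained WLS of beta_out on all exposures."""
    L, k = len(m), m.k
    if L < k + 1:
        raise ValueError(f"need at least {k + 1} variants for {k} exposures")
    X = m.exposure_matrix()
    y = m.df["beta_out"].to_numpy(float)
    sy = m.df["se_out"].to_numpy(float)
    w = 1.0 / sy**2
    Xw = X * np.sqrt(w)[:, None]
    cond = np.linalg.cond(Xw)
    if cond > _COND_LIMIT:
        raise ValueError(
            f"rank-deficient design: exposure effects are collinear "
            f"(condition number {cond:.3g})"
        )
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    q = float(np.sum(w * resid**2))
    q_p = float(stats.chi2.sf(q, L - k))
    phi = max(1.0, np.sqrt(q / (L - k)))
    cov = np.linalg.inv(xtwx)
    se = phi * np.sqrt(np.diag(cov))
    pvals = np.array([_normal_p(b / s) for b, s in zip(beta, se)])

    # conditional instrument strength: how much exposure-i signal remains
    # after projecting out the other exposures (regression heuristic)
    cond_f = np.empty(k)
    for i in range(k):
        xi = X[:, i]
        others = np.delete(X, i, axis=1)
        se_i = m.df[f"se_exp{i + 1}"].to_numpy(float)
        wi = 1.0 / se_i**2
        if others.shape[1]:
            coef = np.linalg.lstsq(others * np.sqrt(wi)[:, None],
                                   xi * np.sqrt(wi), rcond=None)[0]
            r = xi - others @ coef
        else:
            r = xi
        cond_f[i] = float(np.mean((r / se_i) ** 2))

    return MVMRResult(
        exposure_labels=m.exposure_labels,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=pvals,
        n_variants=L,
        conditional_F=cond_f,
        Q=q,
        Q_pval=q_p,
    )
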