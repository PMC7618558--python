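"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly on the summary-statistic scale (no
individual-level genotypes): true per-allele effects are drawn from the
model, sampling noise is added with the analytic binary-trait standard-error
approximation ``se ~ sqrt(n / (2 maf (1 - maf) n_case n_control))``, and LD
enters as AR(1) blocks through which causal z-scores propagate
(z_marginal = r * z_causal).  Defaults emulate the scale of a biobank
exposure GWAS (~21k cases / ~391k controls) paired with a consortium
outcome GWAS (~3k cases / ~995k controls) and 35 genome-wide-significant
instruments of strength F ~ 100.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import RegionalPair
from .instruments import LDMatrix
from .sumstats_io import CANONICAL_COLUMNS, HarmonizedSet, harmonize_pair

#: Two-sided genome-wide significance on the z scale (p = 5e-8).
GWS_Z = float(stats.norm.isf(2.5e-8))

#: Margin added to the significance threshold when resampling true effects,
#: so that observed (noisy) effects still pass the threshold almost surely.
_RESAMPLE_MARGIN = 1.0


@dataclass(frozen=True)
class ColliderSpec:
    """Parameters of a conditional (index-event) GWAS scenario.

    ``b`` is the collider-induced slope linking incidence effects to spurious
    progression effects.  ``frac_progression`` of the panel carries genuine
    direct progression effects (the free mixture component); the rest form
    the incidence-only cluster.  Optional exposure instruments (``L_instruments``
    with exposure->incidence effect ``kappa`` and exposure->progression
    effect ``theta``) let downstream MR quantify collider-induced bias.
    """

    b: float = -0.4
    n_variants: int = 500
    frac_progression: float = 0.3
    incidence_sd: float = 0.1
    progression_sd: float = 0.1
    L_instruments: int = 0
    kappa: float = 0.0
    theta: float = 0.0


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of a synthetic two-sample MR dataset.

    ``theta`` is the true causal log-odds effect of the exposure on the
    outcome; ``L`` the number of instruments with true exposure effects
    gamma ~ N(0, gamma_sd^2) (resampled until they clear genome-wide
    significance at the exposure sample size); ``pleiotropy`` the mean and SD
    of direct variant->outcome effects (InSIDE holds unless
    ``alpha_gamma_corr`` is non-zero); ``n_exp``/``n_out`` the case/control
    sizes of the two GWAS; ``ld_rho`` the AR(1) correlation of the LD block
    around each instrument; ``overlap_rho`` correlates the two traits'
    sampling noise to emulate sample overlap.
    """

    theta: float = 0.19
    L: int = 35
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.125
    pleiotropy: tuple[float, float] = (0.0, 0.005)
    n_exp: tuple[int, int] = (21_021, 391_160)
    n_out: tuple[int, int] = (3_018, 994_582)
    ld_rho: float = 0.9
    n_null_variants: int = 200
    companions_per_instrument: int = 3
    overlap_rho: float = 0.0
    alpha_gamma_corr: float = 0.0
    n_outcome_specific: int = 2
    outcome_gamma_sd: float = 0.3
    reverse_effect: float = 0.0
    collider: ColliderSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimOutput:
    """Simulated exposure/outcome summary statistics with their ground truth."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    truth: SimTruth


@dataclass
class ConditionalSimOutput:
    """Simulated incidence and conditional progression GWAS."""

    incidence: pd.DataFrame
    progression: pd.DataFrame
    exposure: pd.DataFrame | None
    is_instrument: np.ndarray
    has_progression_effect: np.ndarray
    truth: SimTruth


def binary_trait_se(maf, n_case: float, n_control: float) -> np.ndarray:
    """Analytic SE of a per-allele log-odds estimate at the given frequency."""
    maf = np.asarray(maf, float)
    n = n_case + n_control
    return np.sqrt(n / (2 * maf * (1 - maf) * n_case * n_control))


def _resample_above(rng, sd: float, threshold: np.ndarray, size: int) -> np.ndarray:
    """Draw N(0, sd^2) truncated to |x| >= threshold, elementwise."""
    if np.any(stats.norm.sf(threshold / sd) < 5e-5):
        raise ValueError(
            "infeasible configuration: true effects cannot reach significance; "
            "increase sample size or gamma_sd"
        )
    x = rng.normal(0, sd, size)
    for _ in range(1000):
        bad = np.abs(x) < threshold
        if not bad.any():
            return x
        x[bad] = rng.normal(0, sd, int(bad.sum()))
    raise ValueError("resampling failed to produce significant instruments")


def _sumstats_frame(ids, chrom, pos, eaf, beta, se, n, n_case, n_control) -> pd.DataFrame:
    z = beta / se
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    k = len(ids)
    return pd.DataFrame({
        "variant_id": ids,
        "chrom": np.asarray(chrom, dtype=str),
        "pos": np.asarray(pos, dtype=int),
        "effect_allele": ["A"] * k,
        "other_allele": ["G"] * k,
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": float(n),
        "n_case": float(n_case),
        "n_control": float(n_control),
    })[CANONICAL_COLUMNS]


def simulate_pair(truth: SimTruth) -> SimOutput:
    """Generate exposure and outcome GWAS summary statistics.

    Each of the L instruments leads an AR(1) LD block of
    ``companions_per_instrument`` null neighbours whose marginal effects are
    the causal z-score attenuated by the signed correlation; the remaining
    ``n_null_variants`` background variants are independent with zero effect.
    Observed effects are truth plus normal noise at the analytic SE; the
    exposure and outcome noise draws share correlation ``overlap_rho``.
    """
    rng = np.random.default_rng(truth.seed)
    L = truth.L
    n_comp = truth.companions_per_instrument
    n_free = truth.n_null_variants
    mu_a, sd_a = truth.pleiotropy

    maf_inst = rng.uniform(*truth.maf_range, L)
    se_exp_inst = binary_trait_se(maf_inst, *truth.n_exp)
    gamma = _resample_above(rng, truth.gamma_sd, (GWS_Z + _RESAMPLE_MARGIN) * se_exp_inst, L)

    # directional pleiotropy is defined on the exposure-increasing allele
    # (the orientation MR software works in), so the mean pleiotropic effect
    # carries the sign of gamma; the noise part is independent of gamma
    # unless alpha_gamma_corr breaks the InSIDE assumption deliberately
    alpha_noise = rng.normal(0, 1, L)
    if sd_a > 0 and truth.alpha_gamma_corr != 0:
        g_std = (np.abs(gamma) - np.abs(gamma).mean()) / max(np.abs(gamma).std(), 1e-12)
        c = truth.alpha_gamma_corr
        noise = c * g_std + np.sqrt(1 - c**2) * alpha_noise
    else:
        noise = alpha_noise
    alpha = np.sign(gamma) * mu_a + sd_a * noise
    Gamma = truth.theta * gamma + alpha

    ids, chroms, poss, mafs = [], [], [], []
    true_exp, true_out = [], []
    blocks: list[tuple[int, int]] = []  # (offset, size) of each LD block
    offset = 0
    for j in range(L):
        size = 1 + n_comp
        blocks.append((offset, size))
        for k in range(size):
            ids.append(f"rs{j}_{k}" if k else f"rs{j}")
            chroms.append("1")
            poss.append(1_000_000 + j * 25_000_000 + k * 1_000)
            mafs.append(maf_inst[j])
            r = truth.ld_rho**k
            true_exp.append(r * gamma[j])
            true_out.append(r * Gamma[j])
        offset += size
    for m in range(n_free):
        ids.append(f"null{m}")
        chroms.append("2")
        poss.append(1_000_000 + m * 25_000_000)
        mafs.append(rng.uniform(*truth.maf_range))
        true_exp.append(0.0)
        true_out.append(0.0)

    # outcome-specific variants: genome-wide-significant for the outcome,
    # affecting the exposure only through an optional reverse effect
    if truth.n_outcome_specific:
        maf_os = rng.uniform(*truth.maf_range, truth.n_outcome_specific)
        se_out_os = binary_trait_se(maf_os, *truth.n_out)
        gamma_os = _resample_above(
            rng, truth.outcome_gamma_sd, (GWS_Z + _RESAMPLE_MARGIN) * se_out_os,
            truth.n_outcome_specific,
        )
        for m in range(truth.n_outcome_specific):
            ids.append(f"os{m}")
            chroms.append("4")
            poss.append(1_000_000 + m * 25_000_000)
            mafs.append(maf_os[m])
            true_exp.append(truth.reverse_effect * gamma_os[m])
            true_out.append(gamma_os[m])

    mafs = np.asarray(mafs)
    true_exp = np.asarray(true_exp)
    true_out = np.asarray(true_out)
    se_exp = binary_trait_se(mafs, *truth.n_exp)
    se_out = binary_trait_se(mafs, *truth.n_out)

    k_total = len(ids)
    eps_e = rng.normal(0, 1, k_total)
    eps_o_ind = rng.normal(0, 1, k_total)
    rho = truth.overlap_rho
    eps_o = rho * eps_e + np.sqrt(1 - rho**2) * eps_o_ind

    exposure = _sumstats_frame(
        ids, chroms, poss, mafs, true_exp + se_exp * eps_e, se_exp,
        sum(truth.n_exp), *truth.n_exp,
    )
    outcome = _sumstats_frame(
        ids, chroms, poss, mafs, true_out + se_out * eps_o, se_out,
        sum(truth.n_out), *truth.n_out,
    )

    r = np.eye(k_total)
    for off, size in blocks:
        idx = np.arange(off, off + size)
        r[np.ix_(idx, idx)] = truth.ld_rho ** np.abs(idx[:, None] - idx[None, :])
    ld = LDMatrix(ids, r)
    return SimOutput(exposure, outcome, ld, truth)


def instrument_harmonized_set(sim: SimOutput) -> HarmonizedSet:
    """Harmonized exposure/outcome pairs restricted to the true instruments.

    Bypasses significance selection and clumping; used when an experiment
    needs the planted instruments exactly.
    """
    inst = [f"rs{j}" for j in range(sim.truth.L)]
    exp = sim.exposure[sim.exposure["variant_id"].isin(inst)]
    out = sim.outcome[sim.outcome["variant_id"].isin(inst)]
    return harmonize_pair(exp, out, exposure_label="sim_exposure", outcome_label="sim_outcome")


def simulate_conditional(truth: SimTruth) -> ConditionalSimOutput:
    """Generate paired incidence and conditional (progression) GWAS.

    Incidence effects delta are drawn for every panel variant (resampled to
    clear genome-wide significance, emulating pre-selection of
    incidence-associated variants).  The progression GWAS conditions on the
    index event, inducing observed effects
    beta_P = true_progression + b * delta + noise; variants without a true
    progression effect form the incidence-only cluster.  When the collider
    spec requests instruments, L extra variants carry exposure effects gamma
    with delta = kappa * gamma and true progression effect theta * gamma.
    """
    if truth.collider is None:
        raise ValueError("truth.collider must be set for simulate_conditional")
    cs = truth.collider
    if not np.isfinite(cs.b):
        raise ValueError("collider slope b must be finite")
    rng = np.random.default_rng(truth.seed)

    M = cs.n_variants
    maf = rng.uniform(*truth.maf_range, M)
    se_inc = binary_trait_se(maf, *truth.n_exp)
    delta = _resample_above(rng, cs.incidence_sd, (GWS_Z + _RESAMPLE_MARGIN) * se_inc, M)
    has_prog = rng.uniform(size=M) < cs.frac_progression
    prog_true = np.where(has_prog, rng.normal(0, cs.progression_sd, M), 0.0)
    is_inst = np.zeros(M, dtype=bool)
    gamma_full = np.zeros(M)

    if cs.L_instruments:
        Li = cs.L_instruments
        maf_i = rng.uniform(*truth.maf_range, Li)
        se_exp_i = binary_trait_se(maf_i, *truth.n_exp)
        gamma = _resample_above(
            rng, truth.gamma_sd, (GWS_Z + _RESAMPLE_MARGIN) * se_exp_i, Li
        )
        maf = np.concatenate([maf, maf_i])
        delta = np.concatenate([delta, cs.kappa * gamma])
        prog_true = np.concatenate([prog_true, cs.theta * gamma])
        has_prog = np.concatenate([has_prog, np.ones(Li, dtype=bool)])
        is_inst = np.concatenate([is_inst, np.ones(Li, dtype=bool)])
        gamma_full = np.concatenate([gamma_full, gamma])
        M += Li

    se_inc = binary_trait_se(maf, *truth.n_exp)
    se_prog = binary_trait_se(maf, *truth.n_out)
    ids = [f"rs{j}" if is_inst[j] else f"cv{j}" for j in range(M)]
    pos = 1_000_000 + 25_000_000 * np.arange(M)
    chrom = ["3"] * M

    beta_inc_obs = delta + se_inc * rng.normal(0, 1, M)
    beta_prog_obs = prog_true + cs.b * delta + se_prog * rng.normal(0, 1, M)

    incidence = _sumstats_frame(ids, chrom, pos, maf, beta_inc_obs, se_inc,
                                sum(truth.n_exp), *truth.n_exp)
    progression = _sumstats_frame(ids, chrom, pos, maf, beta_prog_obs, se_prog,
                                  sum(truth.n_out), *truth.n_out)
    exposure = None
    if cs.L_instruments:
        se_exp = binary_trait_se(maf, *truth.n_exp)
        beta_exp_obs = gamma_full + se_exp * rng.normal(0, 1, M)
        exposure = _sumstats_frame(ids, chrom, pos, maf, beta_exp_obs, se_exp,
                                   sum(truth.n_exp), *truth.n_exp)
    return ConditionalSimOutput(incidence, progression, exposure,
                                is_inst, has_prog, truth)


def simulate_region(
    shared: bool,
    n_variants: int = 200,
    ld_rho: float = 0.9,
    z_causal: float = 8.0,
    seed: int = 0,
    n_samples: int = 50_000,
    maf: float = 0.3,
    **regional_kwargs,
) -> RegionalPair:
    """Simulate a regional association pair for colocalization.

    One causal variant per trait (the same index when ``shared``, otherwise
    two indices far enough apart that their AR(1) correlation is negligible).
    Marginal z-scores follow the standard summary-statistic model
    z ~ N(R mu, R) with R the AR(1) LD matrix; betas are z * se at the
    analytic SE for ``n_samples`` individuals.
    """
    if n_variants < 2:
        raise ValueError("n_variants must be >= 2")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_variants)
    R = ld_rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(n_variants))

    c1 = n_variants // 2
    c2 = c1 if shared else (n_variants // 4 if n_variants >= 8 else 0)
    if not shared and n_variants >= 8:
        c1 = 3 * n_variants // 4

    se = float(binary_trait_se(maf, n_samples / 2, n_samples / 2))
    betas = []
    for c in (c1, c2):
        mu = np.zeros(n_variants)
        if z_causal != 0:
            mu[c] = z_causal
        z = R @ mu + chol @ rng.normal(0, 1, n_variants)
        betas.append(z * se)

    df = pd.DataFrame({
        "variant_id": [f"v{i}" for i in idx],
        "beta_t1": betas[0],
        "se_t1": se,
        "beta_t2": betas[1],
        "se_t2": se,
    })
    return RegionalPair(df, **regional_kwargs)


def _child_seeds(seed: int, reps: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(reps)]


def recovery_experiment(
    truth: SimTruth,
    reps: int,
    estimators: list[str] = ("ivw", "egger", "weighted_median", "weighted_mode"),
    boot_reps: int = 400,
    use_planted_instruments: bool = True,
) -> pd.DataFrame:
    """Repeated simulate-and-estimate runs summarized per estimator.

    Returns one row per estimator with mean bias, RMSE, empirical 95% CI
    coverage of the true ``theta``, and mean CI width.  ``wald`` uses only
    the first planted instrument; ``dispatch`` applies the variant-count
    rule.  With ``use_planted_instruments`` the planted instruments are used
    directly; otherwise each replicate reruns significance selection and LD
    clumping.
    """
    from . import mr_core
    from .instruments import select_instruments

    if reps < 2:
        raise ValueError("reps must be >= 2")
    seeds = _child_seeds(truth.seed, reps)
    rows = {name: {"est": [], "lo": [], "hi": []} for name in estimators}
    for i in range(reps):
        sim = simulate_pair(replace(truth, seed=seeds[i]))
        if use_planted_instruments:
            h = instrument_harmonized_set(sim)
        else:
            inst = select_instruments(sim.exposure, sim.ld)
            h = harmonize_pair(inst.variants, sim.outcome)
        for name in estimators:
            if name == "wald":
                res = mr_core.wald_ratio(h.subset(h.df.index == 0))
            elif name == "ivw":
                res = mr_core.ivw(h, "multiplicative_random")
            elif name == "ivw_fixed":
                res = mr_core.ivw(h, "fixed")
            elif name == "egger":
                res = mr_core.mr_egger(h)
            elif name == "weighted_median":
                res = mr_core.weighted_median(h, reps=boot_reps, seed=seeds[i])
            elif name == "weighted_mode":
                res = mr_core.weighted_mode(h, reps=boot_reps, seed=seeds[i])
            elif name == "dispatch":
                res = mr_core.dispatch_mr(h)
            else:
                raise ValueError(f"unknown estimator {name!r}")
            rows[name]["est"].append(res.beta)
            rows[name]["lo"].append(res.ci_low)
            rows[name]["hi"].append(res.ci_high)

    out = []
    for name, r in rows.items():
        est = np.asarray(r["est"])
        lo = np.asarray(r["lo"])
        hi = np.asarray(r["hi"])
        covered = (lo <= truth.theta) & (truth.theta <= hi)
        out.append({
            "estimator": name,
            "mean_bias": float(np.mean(est - truth.theta)),
            "rmse": float(np.sqrt(np.mean((est - truth.theta) ** 2))),
            "coverage": float(np.mean(covered)),
            "mean_ci_width": float(np.mean(hi - lo)),
            "n_reps": reps,
        })
    return pd.DataFrame(out)
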