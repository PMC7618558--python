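"""Reading, validation, harmonization, and writing of GWAS summary statistics.

Summary statistics are carried as :class:`pandas.DataFrame` objects with the
canonical columns listed in :data:`CANONICAL_COLUMNS`.  Effects on binary
traits are log odds ratios; effects on quantitative traits are in SD units.
Harmonization aligns exposure and outcome effects to the same effect allele,
resolving strand flips where possible and dropping strand-ambiguous
(palindromic) variants whose allele frequency is too close to 0.5 to orient.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistics tables.
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_case", "n_control",
]

#: Columns that must be present (directly or through a column map).
MANDATORY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default frequency band treated as strand-unresolvable for palindromic
#: variants: effect-allele frequencies in (0.42, 0.58) on either trait drop
#: the variant.
DEFAULT_PALINDROME_EAF_LIMIT = 0.42


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association with one trait.

    ``beta`` is log odds for binary traits (SD units for quantitative ones),
    ``eaf`` the effect-allele frequency, ``n`` the total sample size with an
    optional case/control split for binary traits.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    n_case: float | None = None
    n_control: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.variant_id}: eaf must lie in [0, 1]")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: alleles must differ")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.variant_id}: pval must lie in (0, 1]")
        if (
            self.n_case is not None
            and self.n_control is not None
            and not math.isclose(self.n_case + self.n_control, self.n)
        ):
            raise ValueError(f"{self.variant_id}: n_case + n_control != n")


def variants_to_frame(records: Iterable[VariantAssoc]) -> pd.DataFrame:
    """Convert ``VariantAssoc`` records into a canonical DataFrame."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.reindex(columns=CANONICAL_COLUMNS)


def _revcomp(allele: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError as exc:  # non-ACGT character
        raise ValueError(f"allele {allele!r} is not over {{A,C,G,T}}") from exc


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True if the allele pair is its own reverse complement (e.g. A/T, C/G)."""
    return other_allele == _revcomp(effect_allele)


def _valid_allele(a: object) -> bool:
    return isinstance(a, str) and len(a) > 0 and all(b in _COMPLEMENT for b in a)


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating per-variant invariants; return (clean, drop counts)."""
    counts: dict[str, int] = {}
    mask = pd.Series(True, index=df.index)

    def _flag(name: str, bad: pd.Series) -> None:
        bad = bad & mask
        counts[name] = int(bad.sum())
        mask[bad] = False

    _flag("nonpositive_se", ~(df["se"] > 0))
    _flag("eaf_out_of_range", ~((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    _flag("pval_out_of_range", ~((df["pval"] > 0) & (df["pval"] <= 1)))
    _flag("identical_alleles", df["effect_allele"] == df["other_allele"])
    _flag(
        "invalid_alleles",
        ~(df["effect_allele"].map(_valid_allele) & df["other_allele"].map(_valid_allele)),
    )
    if "n_case" in df.columns and "n_control" in df.columns:
        both = df["n_case"].notna() & df["n_control"].notna()
        _flag("case_control_mismatch",
              both & ~np.isclose(df["n_case"].fillna(0) + df["n_control"].fillna(0), df["n"]))
    _flag("duplicate_variant_id", df["variant_id"].duplicated(keep="first"))

    dropped = {k: v for k, v in counts.items() if v}
    if dropped:
        logger.warning("validate_sumstats dropped rows: %s", dropped)
    return df[mask].reset_index(drop=True), dropped


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file into canonical form.

    Parameters
    ----------
    path:
        Tab-delimited file with a header row.
    column_map:
        Optional mapping of file headers to canonical field names, e.g.
        ``{"EA": "effect_allele"}``.

    Rows violating per-variant invariants (non-positive SE, out-of-range
    frequency or p-value, identical alleles, inconsistent case/control split)
    are dropped with a logged count; the file is rejected outright only when
    a mandatory column is missing or no valid rows remain.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in ("n_case", "n_control"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]
    df, _ = validate_sumstats(df)
    if df.empty:
        raise ValueError(f"{path}: no valid rows after validation")
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical summary-statistics table as TSV (full precision)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def or_ci_to_beta_se(
    or_point: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """Convert an odds ratio with a Wald confidence interval to (beta, se).

    beta = ln(OR); se = (ln(hi) - ln(lo)) / (2 z), with z the standard-normal
    quantile at (1 + level) / 2.
    """
    if min(or_point, ci_low, ci_high) <= 0:
        raise ValueError("odds ratio and CI bounds must be positive")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if not ci_low < or_point < ci_high:
        raise ValueError("require ci_low < or_point < ci_high")
    z = stats.norm.ppf((1 + level) / 2)
    return math.log(or_point), (math.log(ci_high) - math.log(ci_low)) / (2 * z)


@dataclass
class HarmonizedSet:
    """Paired exposure/outcome effects aligned to a common effect allele.

    ``df`` holds one row per retained variant with columns
    ``variant_id, chrom, pos, beta_exp, se_exp, pval_exp, beta_out, se_out,
    pval_out, eaf, n_exp, n_out, palindromic_flag, flipped_flag``.
    """

    df: pd.DataFrame
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0

    def __len__(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        if self.df["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_id in harmonized set")
        if not ((self.df["se_exp"] > 0).all() and (self.df["se_out"] > 0).all()):
            raise ValueError("all standard errors must be > 0")

    def subset(self, mask) -> "HarmonizedSet":
        return HarmonizedSet(
            self.df[mask].reset_index(drop=True),
            self.exposure_label,
            self.outcome_label,
        )


def harmonize_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Variants are intersected on ``variant_id``.  Outcome effects whose allele
    pair is the swap (or reverse-complement swap) of the exposure's are
    sign-flipped with ``eaf -> 1 - eaf``.  Palindromic variants are retained
    only when the effect-allele frequency is outside
    ``(palindrome_eaf_limit, 1 - palindrome_eaf_limit)`` on both traits and
    the minor allele is on the same side; otherwise they are dropped.
    Variants with incompatible allele pairs are dropped.
    """
    if exposure.empty or outcome.empty:
        raise ValueError("exposure and outcome collections must be non-empty")
    if not 0 < palindrome_eaf_limit < 0.5:
        raise ValueError("palindrome_eaf_limit must lie in (0, 0.5)")

    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("_exp", "_out"), how="inner"
    )
    if merged.empty:
        raise ValueError("no variants shared between exposure and outcome")

    rows = []
    n_pal = n_bad = 0
    for rec in merged.itertuples(index=False):
        ea_e, oa_e = rec.effect_allele_exp, rec.other_allele_exp
        ea_o, oa_o = rec.effect_allele_out, rec.other_allele_out
        beta_out, eaf_out, flipped = rec.beta_out, rec.eaf_out, False

        if is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                n_bad += 1
                continue
            if ea_o != ea_e:  # nominal swap before the frequency check
                beta_out, eaf_out, flipped = -beta_out, 1 - eaf_out, True
            lo, hi = palindrome_eaf_limit, 1 - palindrome_eaf_limit
            resolvable = not (lo < rec.eaf_exp < hi) and not (lo < eaf_out < hi)
            oriented = (rec.eaf_exp < 0.5) == (eaf_out < 0.5)
            if not (resolvable and oriented):
                n_pal += 1
                continue
            palindromic = True
        else:
            palindromic = False
            if (ea_o, oa_o) == (ea_e, oa_e):
                pass
            elif (ea_o, oa_o) == (oa_e, ea_e):
                beta_out, eaf_out, flipped = -beta_out, 1 - eaf_out, True
            elif (ea_o, oa_o) == (_revcomp(ea_e), _revcomp(oa_e)):
                pass  # pure strand flip
            elif (ea_o, oa_o) == (_revcomp(oa_e), _revcomp(ea_e)):
                beta_out, eaf_out, flipped = -beta_out, 1 - eaf_out, True
            else:
                n_bad += 1
                continue

        rows.append({
            "variant_id": rec.variant_id,
            "chrom": rec.chrom_exp,
            "pos": rec.pos_exp,
            "effect_allele": ea_e,
            "other_allele": oa_e,
            "beta_exp": rec.beta_exp,
            "se_exp": rec.se_exp,
            "pval_exp": rec.pval_exp,
            "beta_out": beta_out,
            "se_out": rec.se_out,
            "pval_out": rec.pval_out,
            "eaf": rec.eaf_exp,
            "n_exp": rec.n_exp,
            "n_out": rec.n_out,
            "palindromic_flag": palindromic,
            "flipped_flag": flipped,
        })

    if n_pal:
        logger.info("harmonize_pair dropped %d unresolvable palindromic variants", n_pal)
    if n_bad:
        logger.info("harmonize_pair dropped %d allele-incompatible variants", n_bad)
    if not rows:
        raise ValueError("harmonization left zero variants")
    return HarmonizedSet(
        pd.DataFrame(rows), exposure_label, outcome_label,
        n_dropped_palindromic=n_pal, n_dropped_incompatible=n_bad,
    )


def _to_serializable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {k: _to_serializable(v) for k, v in dataclasses.asdict(obj).items()}
        # causal-estimate results also export the odds-ratio scale
        if "beta" in out and "ci_low" in out and "method" in out:
            out["odds_ratio"] = math.exp(out["beta"])
            out["or_ci_low"] = math.exp(out["ci_low"])
            out["or_ci_high"] = math.exp(out["ci_high"])
        return out
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {k: _to_serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_serializable(v) for v in obj]
    return obj


def write_results(results, path: str | Path, format: str = "tsv") -> None:
    """Write analysis results (dataclasses, mappings, or DataFrames).

    ``tsv`` flattens each result to one row; ``json`` nests them.  Floats are
    written with 12 significant digits so a read round-trips to printed
    precision.
    """
    path = Path(path)
    serializable = _to_serializable(results)
    if format == "json":
        path.write_text(json.dumps(serializable, indent=2, allow_nan=True) + "\n")
    elif format == "tsv":
        if isinstance(serializable, Mapping):
            serializable = [serializable]
        df = pd.json_normalize(serializable)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path, format: str = "tsv"):
    """Read back a file written by :func:`write_results`."""
    if format == "json":
        return json.loads(Path(path).read_text())
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    raise ValueError(f"unknown format {format!r}")
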