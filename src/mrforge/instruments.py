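"""Instrument selection: MAF filtering, greedy LD clumping, instrument
strength, and gene-specific cis instruments with tiered significance fallback.

Clumping follows the standard greedy index-variant algorithm: variants are
ranked by p-value and the best remaining variant repeatedly claims (removes)
every weaker variant on the same chromosome within the window whose squared
correlation with it reaches the threshold.  Ties on p-value are broken by
(chrom, pos, variant_id) so the output is independent of input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default clumping window (10 Mb) and tiered cis p-value thresholds.
DEFAULT_WINDOW_BP = 10_000_000
DEFAULT_CIS_TIERS = (5e-8, 5e-6, 5e-4)
DEFAULT_CIS_FLANK_BP = 200_000


@dataclass
class LDMatrix:
    """Square signed-correlation matrix over an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix dimensions do not match variant list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def index_of(self, variant_id: str) -> int | None:
        return self._index.get(variant_id)

    def r2(self, id1: str, id2: str) -> float:
        """Squared correlation; 0 for variants absent from the matrix."""
        i, j = self._index.get(id1), self._index.get(id2)
        if i is None or j is None:
            return 0.0
        return float(self.r[i, j] ** 2)

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)))

    @classmethod
    def from_long(cls, pairs: pd.DataFrame, variant_ids: Sequence[str] | None = None) -> "LDMatrix":
        """Build from a long-format table with columns (id1, id2, r)."""
        ids = list(variant_ids) if variant_ids is not None else sorted(
            set(pairs["id1"]) | set(pairs["id2"])
        )
        idx = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        for rec in pairs.itertuples(index=False):
            i, j = idx[rec.id1], idx[rec.id2]
            r[i, j] = r[j, i] = rec.r
        return cls(ids, r)

    @classmethod
    def read(cls, matrix_path: str | Path, variants_path: str | Path | None = None) -> "LDMatrix":
        """Read either a long TSV (id1, id2, r) or a dense matrix + sidecar list."""
        matrix_path = Path(matrix_path)
        with open(matrix_path) as fh:
            header = fh.readline().split()
        if header[:3] == ["id1", "id2", "r"]:
            return cls.from_long(pd.read_csv(matrix_path, sep="\t"))
        if variants_path is None:
            raise ValueError("dense LD matrix requires a sidecar variant list")
        ids = Path(variants_path).read_text().split()
        return cls(ids, np.loadtxt(matrix_path))

    def write(self, matrix_path: str | Path) -> None:
        """Write in long format (upper triangle of non-zero correlations)."""
        rows = []
        k = len(self.variant_ids)
        for i in range(k):
            for j in range(i + 1, k):
                if self.r[i, j] != 0.0:
                    rows.append((self.variant_ids[i], self.variant_ids[j], self.r[i, j]))
        pd.DataFrame(rows, columns=["id1", "id2", "r"]).to_csv(
            matrix_path, sep="\t", index=False, float_format="%.12g"
        )


@dataclass
class InstrumentSet:
    """Clumped exposure associations with per-variant and mean F statistics."""

    variants: pd.DataFrame
    p_threshold: float
    r2_threshold: float
    clump_window_bp: int
    per_variant_F: np.ndarray
    mean_F: float
    tier_used: float | None = None
    gene_label: str | None = None

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])


@dataclass(frozen=True)
class NoCisInstrument:
    """Typed outcome for a gene with no cis variant at any significance tier."""

    gene_label: str
    most_lenient_p: float
    reason: str = "no cis variant below the most lenient tier"


@dataclass
class CisSpec:
    """Cis-window definition for a gene-specific instrument.

    The window is gene body +/- ``flank_bp`` (gene body only when
    ``intragenic_only``).  ``tier_thresholds`` are tried strictest first;
    the first tier yielding at least one clumped variant defines the
    instrument.
    """

    gene_label: str
    chrom: str
    gene_start: int
    gene_end: int
    flank_bp: int = DEFAULT_CIS_FLANK_BP
    intragenic_only: bool = False
    tier_thresholds: tuple[float, ...] = DEFAULT_CIS_TIERS

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError("gene_start must be <= gene_end")
        # thresholds increase in leniency: 5e-8 first, then 5e-6, 5e-4, ...
        if any(a >= b for a, b in zip(self.tier_thresholds, self.tier_thresholds[1:])):
            raise ValueError("tier_thresholds must be strictly increasing (strictest first)")

    @property
    def window(self) -> tuple[int, int]:
        if self.intragenic_only:
            return self.gene_start, self.gene_end
        return self.gene_start - self.flank_bp, self.gene_end + self.flank_bp


def maf_filter(records: pd.DataFrame, maf_min: float) -> pd.DataFrame:
    """Retain variants whose minor-allele frequency is at least ``maf_min``."""
    if records["eaf"].isna().any():
        raise ValueError("maf_filter requires eaf for all records")
    maf = np.minimum(records["eaf"], 1 - records["eaf"])
    return records[maf >= maf_min].reset_index(drop=True)


def _clump_order(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)


def ld_clump(
    records: pd.DataFrame,
    ld: LDMatrix,
    r2_threshold: float,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy LD clumping of ``records`` (one row per variant).

    Variants absent from the LD matrix are treated as uncorrelated with all
    others (a warning is emitted once per call).
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must lie in (0, 1]")
    if records.empty:
        return records.copy()

    df = _clump_order(records)
    missing = [v for v in df["variant_id"] if ld.index_of(v) is None]
    if missing:
        logger.warning(
            "%d variant(s) absent from the LD matrix; assuming r2 = 0", len(missing)
        )

    alive = np.ones(len(df), dtype=bool)
    accepted: list[int] = []
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    ids = df["variant_id"].to_numpy()
    for i in range(len(df)):
        if not alive[i]:
            continue
        accepted.append(i)
        in_window = (
            alive
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        in_window[: i + 1] = False  # only weaker (later-ranked) variants drop
        for j in np.nonzero(in_window)[0]:
            if ld.r2(ids[i], ids[j]) >= r2_threshold:
                alive[j] = False
    return df.iloc[accepted].reset_index(drop=True)


def _f_stats(df: pd.DataFrame) -> np.ndarray:
    return (df["beta"].to_numpy() / df["se"].to_numpy()) ** 2


def select_instruments(
    exposure: pd.DataFrame,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> InstrumentSet:
    """Select instruments at ``p_threshold`` then clump; attach F statistics.

    The per-variant F statistic is the squared Wald z (beta/se)^2; ``mean_F``
    is their arithmetic mean.
    """
    if exposure.empty:
        raise ValueError("exposure collection is empty")
    sig = exposure[exposure["pval"] <= p_threshold]
    if sig.empty:
        raise ValueError(
            f"no variant reaches p <= {p_threshold:g}; consider a more lenient tier"
        )
    clumped = ld_clump(sig, ld, r2_threshold, window_bp)
    f = _f_stats(clumped)
    return InstrumentSet(
        variants=clumped,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        clump_window_bp=window_bp,
        per_variant_F=f,
        mean_F=float(f.mean()),
    )


def cis_instruments(
    exposure: pd.DataFrame,
    ld: LDMatrix,
    spec: CisSpec,
    r2_threshold: float = 0.001,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> InstrumentSet | NoCisInstrument:
    """Build a gene-specific cis instrument with tiered significance fallback.

    Restricts to the cis window, then tries each tier in ``spec`` strictest
    first; the first tier with at least one variant surviving clumping
    defines the instrument (recorded in ``tier_used``).
    """
    lo, hi = spec.window
    window = exposure[
        (exposure["chrom"].astype(str) == str(spec.chrom))
        & (exposure["pos"] >= lo)
        & (exposure["pos"] <= hi)
    ]
    for tier in spec.tier_thresholds:
        sig = window[window["pval"] <= tier]
        if sig.empty:
            continue
        clumped = ld_clump(sig, ld, r2_threshold, window_bp)
        if not clumped.empty:
            f = _f_stats(clumped)
            return InstrumentSet(
                variants=clumped,
                p_threshold=tier,
                r2_threshold=r2_threshold,
                clump_window_bp=window_bp,
                per_variant_F=f,
                mean_F=float(f.mean()),
                tier_used=tier,
                gene_label=spec.gene_label,
            )
    return NoCisInstrument(spec.gene_label, spec.tier_thresholds[-1])


def group_loci(
    gene_instruments: Mapping[str, InstrumentSet],
) -> dict[str, InstrumentSet]:
    """Merge genes whose instruments contain identical variant sets.

    Neighbouring genes often share the same clumped cis variants; such genes
    are reported as one locus with a joined label.  Partially overlapping
    (non-identical) variant sets are kept separate.
    """
    by_set: dict[frozenset[str], list[str]] = {}
    for gene, inst in gene_instruments.items():
        by_set.setdefault(frozenset(inst.variant_ids), []).append(gene)
    out: dict[str, InstrumentSet] = {}
    for genes in by_set.values():
        label = "/".join(sorted(genes))
        out[label] = gene_instruments[genes[0]]
    return out
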