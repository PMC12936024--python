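"""Differential-expression screening and intersection with a core gene set.

The screen works on a raw gene x sample count matrix with a two-group design
(disease group AG vs control group BG).  Counts are normalised to log2
counts-per-million with a pseudocount, tested per gene with a Welch
two-sample t-test (a documented stand-in for a negative-binomial Wald test;
the thresholding and gene-set intersection logic downstream is what this
module exists for), FDR-adjusted by Benjamini-Hochberg, and thresholded at
|log2FC| >= 1.5 and FDR < 0.01.  Genes passing the screen that also belong
to the inflammation-related core gene set are flagged as irDEGs
(inflammation-related differentially expressed genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUPS = ("AG", "BG")


@dataclass(frozen=True)
class ScreenConfig:
    """Screening thresholds: |log2FC| >= lfc (inclusive), FDR < fdr (strict)."""

    lfc_threshold: float = 1.5
    fdr_threshold: float = 0.01
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) with an AG/BG group label per sample."""

    counts: pd.DataFrame  # index = gene symbols, columns = sample IDs
    group: Mapping[str, str]  # sample -> "AG" | "BG"

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene symbols in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        labels = {self.group.get(s) for s in self.counts.columns}
        if labels - set(GROUPS) or not labels >= set(GROUPS):
            raise ValueError("every sample needs a group label and both AG and BG must be non-empty")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group[s] == group]


def normalize_log2cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + pseudocount) / libsize * 1e6).

    Library size is the raw column sum.  Scale-invariant: doubling all counts
    and library sizes leaves values unchanged.  All-zero samples are rejected.
    """
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return np.log2((counts + pseudocount).div(lib, axis=1) * 1e6)


def test_de(normalized: pd.DataFrame, group: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene Welch t-test of AG vs BG on normalised expression.

    Returns a DataFrame indexed by gene with ``log2fc`` (mean AG - mean BG)
    and two-sided ``p`` with Satterthwaite degrees of freedom.  Genes with
    zero variance in both groups and equal means get p = 1 by convention.
    """
    ag = [s for s in normalized.columns if group[s] == "AG"]
    bg = [s for s in normalized.columns if group[s] == "BG"]
    if len(ag) < 2 or len(bg) < 2:
        raise ValueError("need >= 2 samples per group")
    a = normalized[ag].to_numpy()
    b = normalized[bg].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=normalized.index)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not p.size:
        return p
    return multipletests(p, method="fdr_bh")[1]


def screen_irdegs(
    records: pd.DataFrame,
    core_gene_set: Iterable[str],
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Apply DE thresholds and intersect with the core gene set.

    ``records`` must be indexed by gene and carry ``log2fc`` and ``p``; an
    ``fdr`` column is added (BH) if absent.  Output adds ``direction``
    (up/down/none by the sign of log2fc for DEGs), ``is_deg`` (|log2fc| >=
    lfc_threshold and fdr < fdr_threshold, boundary log2fc retained, boundary
    fdr excluded) and ``is_irdeg`` (DEG and symbol in the core set,
    case-insensitive after whitespace strip).
    """
    core = {g.strip().upper() for g in core_gene_set if g.strip()}
    if not core:
        raise ValueError("core gene set is empty")
    out = records.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    is_deg = (out["log2fc"].abs() >= config.lfc_threshold) & (out["fdr"] < config.fdr_threshold)
    out["is_deg"] = is_deg
    out["direction"] = np.where(~is_deg, "none", np.where(out["log2fc"] > 0, "up", "down"))
    out["is_irdeg"] = is_deg & out.index.str.strip().str.upper().isin(core)
    if not out["is_irdeg"].any():
        logger.warning("no DEG intersects the core gene set")
    return out


def run_screen(
    matrix: ExpressionMatrix,
    core_gene_set: Iterable[str],
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Full screen: normalise, Welch-test, BH-adjust, threshold, intersect."""
    normalized = normalize_log2cpm(matrix.counts, config.pseudocount)
    records = test_de(normalized, matrix.group)
    return screen_irdegs(records, core_gene_set, config)
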