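"""Normalization and differential-expression calling for count matrices.

Every treatment cell (strain x genistein) is contrasted against the
wild-type no-genistein baseline.  Libraries are normalized with the
median-of-ratios size-factor estimator; significance comes from an exact
conditioned-binomial count test (a Poisson-rate comparison conditioned on
the total): with replicates pooled within sides, the treatment total given
the grand total N is Binomial(N, q) under the null, where q is the
treatment share of the summed size factors.  The two-sided p-value sums the
probabilities of all outcomes no more likely than the observed one.

DEG thresholding follows the |FC| >= 3, p < 0.05 rule; down-regulation is
reported as a fold-change <= 1/3 (printed as a negative fold-change in the
field's convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STRAINS = ("WT", "nodD1", "ttsI")
BASELINE = ("WT", False)


@dataclass
class CountMatrix:
    """Genes x libraries integer counts plus the library design.

    ``design`` is indexed by library id with columns ``strain``,
    ``genistein`` (bool), ``replicate`` and optionally ``depth_factor``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate library ids")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"libraries missing from design: {missing}")

    def libraries_for(self, strain: str, genistein: bool) -> list[str]:
        d = self.design
        sel = d[(d["strain"] == strain) & (d["genistein"] == genistein)]
        libs = [l for l in self.counts.columns if l in sel.index]
        return libs


@dataclass(frozen=True)
class Contrast:
    """One strain x genistein cell versus the WT no-genistein baseline."""

    strain: str
    genistein: bool
    treatment_libs: tuple[str, ...]
    baseline_libs: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"{self.strain}{'+' if self.genistein else '-'}gen"


def standard_contrasts(cm: CountMatrix) -> list[Contrast]:
    """All non-baseline cells of the 3x2 design versus WT-gen."""
    base = tuple(cm.libraries_for(*BASELINE))
    if not base:
        raise ValueError("no wild-type no-genistein baseline libraries")
    out = []
    for strain in STRAINS:
        for gen in (True, False):
            if (strain, gen) == BASELINE:
                continue
            libs = tuple(cm.libraries_for(strain, gen))
            if libs:
                out.append(Contrast(strain, gen, libs, base))
    return out


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Uses genes positive in every library; if none exist, falls back to
    total-count scaling with a warning.
    """
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("a library has no nonzero counts")
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        logger.warning("no gene positive in all libraries; "
                       "falling back to total-count scaling")
        totals = counts.sum(axis=0).astype(float)
        factors = totals
    else:
        logc = np.log(positive.values.astype(float))
        loggeo = logc.mean(axis=1, keepdims=True)
        factors = pd.Series(
            np.exp(np.median(logc - loggeo, axis=0)), index=counts.columns)
    factors = factors / np.exp(np.log(factors).mean())
    return factors


# ---------------------------------------------------------------------------
# Fold change and exact test
# ---------------------------------------------------------------------------

def fold_change(cm: CountMatrix, gene: str, contrast: Contrast,
                factors: pd.Series, pseudocount: float = 0.5
                ) -> tuple[float, float]:
    """(FC, log2FC) of normalized replicate means, pseudocount-guarded."""
    row = cm.counts.loc[gene]
    norm = row / factors
    mt = norm[list(contrast.treatment_libs)].mean()
    mb = norm[list(contrast.baseline_libs)].mean()
    fc = (mt + pseudocount) / (mb + pseudocount)
    return float(fc), float(np.log2(fc))


def exact_count_test(cm: CountMatrix, gene: str, contrast: Contrast,
                     factors: pd.Series) -> float:
    """Two-sided exact conditioned-binomial p-value for one gene.

    Raw counts are pooled within sides; size factors enter only through the
    null split probability q = sum(sf_treatment) / sum(sf_both sides).
    N = 0 yields p = 1.
    """
    kt = int(cm.counts.loc[gene, list(contrast.treatment_libs)].sum())
    kb = int(cm.counts.loc[gene, list(contrast.baseline_libs)].sum())
    n = kt + kb
    if n == 0:
        return 1.0
    st = factors[list(contrast.treatment_libs)].sum()
    sb = factors[list(contrast.baseline_libs)].sum()
    q = float(st / (st + sb))
    return float(stats.binomtest(kt, n, q).pvalue)


# ---------------------------------------------------------------------------
# Per-contrast tables and DEG calls
# ---------------------------------------------------------------------------

def contrast_table(cm: CountMatrix, contrast: Contrast, factors: pd.Series,
                   pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene FC/log2FC/p/mean-normalized-count table for one contrast."""
    norm = cm.counts.div(factors, axis=1)
    mt = norm[list(contrast.treatment_libs)].mean(axis=1)
    mb = norm[list(contrast.baseline_libs)].mean(axis=1)
    fc = (mt + pseudocount) / (mb + pseudocount)

    kt = cm.counts[list(contrast.treatment_libs)].sum(axis=1).astype(int)
    kb = cm.counts[list(contrast.baseline_libs)].sum(axis=1).astype(int)
    st = factors[list(contrast.treatment_libs)].sum()
    sb = factors[list(contrast.baseline_libs)].sum()
    q = float(st / (st + sb))
    pvals = np.ones(len(cm.counts))
    for i, (a, b) in enumerate(zip(kt.values, kb.values)):
        n = int(a + b)
        if n > 0:
            pvals[i] = stats.binomtest(int(a), n, q).pvalue
    return pd.DataFrame({
        "fc": fc, "log2fc": np.log2(fc), "p": pvals,
        "mean_norm_treatment": mt, "mean_norm_baseline": mb,
    }, index=cm.counts.index)


def call_degs(table: pd.DataFrame, fc_threshold: float = 3.0,
              alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
    """Add boolean ``call`` and ``direction`` columns to a contrast table.

    A gene passes when FC >= threshold or FC <= 1/threshold AND p < alpha
    (the numeric log2 cutoff equals log2(threshold)).  Optional
    Benjamini-Hochberg correction replaces raw p with adjusted q.
    """
    out = table.copy()
    p = out["p"].values
    if bh:
        p = _bh_adjust(p)
        out["q"] = p
    fc = out["fc"].values
    passes_fc = (fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)
    out["call"] = passes_fc & (p < alpha)
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    cummin = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        cummin = min(cummin, p[i] * n / (rank_idx + 1))
        adj[i] = cummin
    return adj


def run_de(cm: CountMatrix, fc_threshold: float = 3.0, alpha: float = 0.05,
           pseudocount: float = 0.5, bh: bool = False,
           factors: pd.Series | None = None
           ) -> dict[tuple[str, bool], pd.DataFrame]:
    """Full DE pass: size factors, then one called table per contrast.

    Returns a dict keyed by (strain, genistein).
    """
    if factors is None:
        factors = size_factors(cm.counts)
    results = {}
    for contrast in standard_contrasts(cm):
        tab = contrast_table(cm, contrast, factors, pseudocount)
        results[(contrast.strain, contrast.genistein)] = call_degs(
            tab, fc_threshold, alpha, bh)
    return results


def deg_sets(results: dict[tuple[str, bool], pd.DataFrame],
             genistein: bool = True) -> dict[str, set[str]]:
    """Per-strain DEG id sets for the genistein (or no-genistein) cells."""
    out = {}
    for (strain, gen), tab in results.items():
        if gen == genistein:
            out[strain] = set(tab.index[tab["call"]])
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(counts_path: str | Path, design_path: str | Path
                ) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    design = pd.read_csv(design_path, sep="\t", index_col=0, comment="#")
    design["genistein"] = design["genistein"].astype(bool)
    return CountMatrix(counts=counts, design=design)


def write_contrast_tables(results: dict[tuple[str, bool], pd.DataFrame],
                          outdir: str | Path, header: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (strain, gen), tab in results.items():
        name = f"de_{strain}_{'gen' if gen else 'nogen'}.tsv"
        with open(outdir / name, "w") as fh:
            if header:
                fh.write(header)
            tab.to_csv(fh, sep="\t", index_label="gene")


def read_contrast_tables(dedir: str | Path
                         ) -> dict[tuple[str, bool], pd.DataFrame]:
    results = {}
    for path in sorted(Path(dedir).glob("de_*.tsv")):
        stem = path.stem  # de_<strain>_<gen|nogen>
        _, strain, cond = stem.split("_")
        tab = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        results[(strain, cond == "gen")] = tab
    return results
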