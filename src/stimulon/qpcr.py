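"""Relative qPCR quantification (ddCt) and RNA-seq concordance.

Fold changes are computed against a reference gene (16S rRNA in the
bacterial setting) with the classic ddCt method under the assumption of
perfect amplification efficiency (doubling per cycle):

    dCt   = Ct_target - Ct_reference        (per condition)
    ddCt  = dCt_treated - dCt_control
    FC    = 2 ** (-ddCt)

Technical replicates are averaged within each biological replicate before
biological replicates are averaged; the reported spread is the range of
per-biological-replicate fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("gene", "condition", "bio_rep", "tech_rep", "ct_target",
              "ct_ref")


@dataclass(frozen=True)
class FoldChangeEstimate:
    """ddCt fold change for one gene, with replicate spread."""

    gene: str
    fold_change: float
    spread: float             # range of per-biological-replicate FCs
    n_bio_treated: int
    n_bio_control: int

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CT_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return tab


def _delta_ct_per_bio(records: pd.DataFrame) -> pd.Series:
    """dCt per biological replicate, technical replicates averaged first."""
    if records["ct_target"].isna().any() or records["ct_ref"].isna().any():
        raise ValueError("missing Ct value (target or reference)")
    if len(records) == 0:
        raise ValueError("no Ct records for this condition")
    grouped = records.groupby("bio_rep")
    return grouped["ct_target"].mean() - grouped["ct_ref"].mean()


def ddct_fold_change(treated: pd.DataFrame,
                     control: pd.DataFrame) -> FoldChangeEstimate:
    """ddCt fold change of one gene, treated versus control condition.

    Each frame holds the Ct records of one condition (columns ``bio_rep``,
    ``tech_rep``, ``ct_target``, ``ct_ref``).
    """
    genes = set(treated.get("gene", pd.Series(["?"]))) | \
        set(control.get("gene", pd.Series(["?"])))
    if len(genes) > 1:
        raise ValueError(f"records mix genes: {sorted(genes)}")
    gene = next(iter(genes))

    dct_t = _delta_ct_per_bio(treated)
    dct_c = _delta_ct_per_bio(control)
    ddct = dct_t.mean() - dct_c.mean()
    fc = float(2.0 ** (-ddct))
    per_bio_fc = 2.0 ** (-(dct_t - dct_c.mean()))
    spread = float(per_bio_fc.max() - per_bio_fc.min()) if len(dct_t) > 1 \
        else 0.0
    return FoldChangeEstimate(gene=str(gene), fold_change=fc, spread=spread,
                              n_bio_treated=len(dct_t),
                              n_bio_control=len(dct_c))


def fold_changes_from_table(table: pd.DataFrame, treated: str,
                            control: str) -> pd.DataFrame:
    """Per-gene ddCt fold changes between two condition labels."""
    rows = []
    for gene, sub in table.groupby("gene"):
        t = sub[sub["condition"] == treated]
        c = sub[sub["condition"] == control]
        if len(t) == 0 or len(c) == 0:
            continue
        est = ddct_fold_change(t, c)
        rows.append({"gene": gene, "fold_change": est.fold_change,
                     "spread": est.spread})
    return pd.DataFrame(rows).set_index("gene")


def concordance(qpcr: pd.DataFrame, rnaseq: pd.DataFrame
                ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation (log2 scale) of qPCR vs RNA-seq fold changes.

    ``qpcr`` needs a ``fold_change`` column; ``rnaseq`` a ``log2fc`` column;
    both indexed by gene.  Genes whose fold changes disagree in sign are
    flagged discordant.  Requires >= 3 shared genes.
    """
    shared = sorted(set(qpcr.index) & set(rnaseq.index))
    if len(shared) < 3:
        raise ValueError(
            f"concordance needs >= 3 shared genes, got {len(shared)}")
    q = np.log2(qpcr.loc[shared, "fold_change"].astype(float))
    r = rnaseq.loc[shared, "log2fc"].astype(float)
    coef = float(stats.pearsonr(q, r).statistic)
    table = pd.DataFrame({
        "log2fc_qpcr": q, "log2fc_rnaseq": r,
        "discordant": np.sign(q) != np.sign(r)})
    return coef, table
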