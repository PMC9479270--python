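"""Relative quantification of qPCR data by the Livak 2^-ddCt method.

Each gene's cycle-threshold (Ct) value is first normalized to a reference
gene measured in the same sample (dCt = Ct_gene - Ct_reference; U6 is the
conventional reference for small RNAs), then centered on the calibrator
group (ddCt = dCt - mean calibrator dCt), and expressed as a fold change
2^-ddCt. Amplification efficiency is fixed at 2 per cycle (no efficiency
correction). Centering uses the arithmetic mean of the calibrator-group
dCt values, the standard Livak formulation, so the geometric mean of the
calibrator-group folds is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from lncnet.exceptions import DataError, DesignError, ParameterError

logger = logging.getLogger(__name__)

CT_COLUMNS = ("sample_id", "group", "gene", "ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns sample_id, group, gene, ct (+ optional replicate)."""
    table = pd.read_csv(path, sep="\t")
    validate_ct_table(table)
    return table


def validate_ct_table(table: pd.DataFrame) -> None:
    for col in CT_COLUMNS:
        if col not in table.columns:
            raise DataError(f"Ct table is missing column {col!r}")
    if not np.issubdtype(table["ct"].to_numpy().dtype, np.number):
        raise DataError("ct values must be numeric")
    if (table["ct"] <= 0).any():
        bad = table.loc[table["ct"] <= 0].iloc[0]
        raise DataError(f"non-positive Ct for sample {bad['sample_id']!r}, "
                        f"gene {bad['gene']!r}")


def ddct(table: pd.DataFrame, reference_gene: str,
         calibrator_group: str) -> pd.DataFrame:
    """Per sample and gene: dCt, ddCt and fold = 2^-ddCt.

    Technical replicates (repeated sample/gene rows) are averaged first.
    The reference gene must be measured in every sample; it is consumed for
    normalization and excluded from the output. Returns columns
    ``sample_id, group, gene, delta_ct, delta_delta_ct, fold``.
    """
    validate_ct_table(table)
    mean_ct = (table.groupby(["sample_id", "group", "gene"], sort=True)["ct"]
               .mean().reset_index())
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = mean_ct[mean_ct["gene"] != reference_gene].copy()
    if targets.empty:
        raise ParameterError("no target genes besides the reference")
    missing = set(targets["sample_id"]) - set(ref.index)
    if missing:
        raise DataError(f"sample {sorted(missing)[0]!r} lacks the reference "
                        f"gene {reference_gene!r}")
    if calibrator_group not in set(mean_ct["group"]):
        raise ParameterError(f"calibrator group {calibrator_group!r} not present")

    targets["delta_ct"] = targets["ct"].to_numpy() - ref.loc[targets["sample_id"]].to_numpy()
    calib = targets[targets["group"] == calibrator_group]
    calib_mean = calib.groupby("gene")["delta_ct"].mean()
    absent = set(targets["gene"]) - set(calib_mean.index)
    if absent:
        raise DataError(f"gene {sorted(absent)[0]!r} has no calibrator-group "
                        "measurement")
    targets["delta_delta_ct"] = (targets["delta_ct"].to_numpy()
                                 - calib_mean.loc[targets["gene"]].to_numpy())
    targets["fold"] = np.exp2(-targets["delta_delta_ct"])
    out = targets[["sample_id", "group", "gene", "delta_ct", "delta_delta_ct",
                   "fold"]].reset_index(drop=True)
    return out


@dataclass(frozen=True)
class GroupComparison:
    gene: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    difference: float
    p_value: float


def group_compare(rel: pd.DataFrame, group_a: str, group_b: str,
                  gene: str | None = None, value: str = "fold",
                  equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample t-test between two groups' relative expression.

    Compares ``fold`` values by default (``value="delta_delta_ct"`` compares
    on the Ct scale). ``gene`` may be omitted when the table holds a single
    gene. The independent Student's t-test (pooled variance) is the default,
    matching common qPCR practice; set ``equal_var=False`` for Welch.
    """
    if value not in ("fold", "delta_delta_ct"):
        raise ParameterError(f"unknown value column {value!r}")
    genes = sorted(set(rel["gene"]))
    if gene is None:
        if len(genes) != 1:
            raise ParameterError("gene must be named when the table holds "
                                 f"{len(genes)} genes")
        gene = genes[0]
    sub = rel[rel["gene"] == gene]
    a = sub.loc[sub["group"] == group_a, value].to_numpy(dtype=float)
    b = sub.loc[sub["group"] == group_b, value].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DesignError("each compared group needs at least 2 samples")
    if np.allclose(a.var(), 0.0) and np.allclose(b.var(), 0.0):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return GroupComparison(gene=gene, group_a=group_a, group_b=group_b,
                           mean_a=float(a.mean()), mean_b=float(b.mean()),
                           difference=float(a.mean() - b.mean()), p_value=p)
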