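"""Per-contrast differential expression and microarray-style filtering.

Fold changes are ratios of linear-scale group means, reported as a
magnitude >= 1 with a separate Up/Down direction (Up when the numerator
group mean exceeds the denominator's). P-values come from a two-sided
two-sample t-test on log2 intensities — Welch (unequal variances) by
default, pooled-variance as an option. No multiplicity correction is
applied to the filter (the screening convention this pipeline models filters
on raw p), but Benjamini-Hochberg q-values are reported alongside.

The expression filter retains a transcript when all four criteria hold:
fold-change magnitude at least ``min_fc`` (2 by default; a strict > mode is
available), p below ``max_p`` (0.05), mean raw intensity above
``min_raw_intensity`` (200) in at least one of the two compared groups, and
annotated transcript length below ``max_length_nt`` (3 kb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncnet.exceptions import DataError, DesignError, ParameterError
from lncnet.synthetic import DOWN, UP, ExpressionStudy

logger = logging.getLogger(__name__)

#: column order of a contrast-result table
RESULT_COLUMNS = ["transcript_id", "fc_magnitude", "direction", "p_value",
                  "q_bh", "mean_numerator", "mean_denominator"]


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison, e.g. Contrast("CIA vs Control", "CIA", "Control")."""

    name: str
    numerator_group: str
    denominator_group: str

    def __post_init__(self) -> None:
        if self.numerator_group == self.denominator_group:
            raise ParameterError("contrast numerator and denominator must differ")

    def swapped(self) -> "Contrast":
        return Contrast(f"{self.denominator_group} vs {self.numerator_group}",
                        self.denominator_group, self.numerator_group)


@dataclass(frozen=True)
class DEThresholds:
    """Filter criteria for calling a transcript differentially expressed."""

    min_fc: float = 2.0
    max_p: float = 0.05
    min_raw_intensity: float = 200.0
    max_length_nt: int = 3000
    strict_fc: bool = False  # True: fc > min_fc; False: fc >= min_fc

    def __post_init__(self) -> None:
        if self.min_fc < 1.0:
            raise ParameterError(f"min_fc must be >= 1, got {self.min_fc}")
        if not 0.0 < self.max_p <= 1.0:
            raise ParameterError(f"max_p must be in (0, 1], got {self.max_p}")


def welch_ttest_log2(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> np.ndarray:
    """Row-wise two-sided t-test p-values on log2 intensities.

    ``a`` and ``b`` are (transcripts x replicates) linear-scale blocks.
    Degenerate rows (zero variance in both groups) get p = 1 when the means
    are equal and p = 0 otherwise.
    """
    la, lb = np.log2(a), np.log2(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p[bad & equal] = 1.0
        p[bad & ~equal] = 0.0
    return p


def contrast_statistics(study: ExpressionStudy, contrast: Contrast,
                        equal_var: bool = False) -> pd.DataFrame:
    """Fold change, direction, and t-test p-value for every transcript.

    Returns one row per transcript, ordered by transcript_id, with columns
    ``transcript_id, fc_magnitude, direction, p_value, q_bh,
    mean_numerator, mean_denominator``. Means are linear-scale group means;
    q_bh is the Benjamini-Hochberg adjustment across all transcripts of the
    contrast.
    """
    for g in (contrast.numerator_group, contrast.denominator_group):
        if g not in study.group_order:
            raise DesignError(f"group {g!r} not present in the study")
        if len(study.samples_of(g)) < 2:
            raise DesignError(f"group {g!r} has fewer than 2 replicates")
    num = study.matrix[study.samples_of(contrast.numerator_group)].to_numpy(dtype=float)
    den = study.matrix[study.samples_of(contrast.denominator_group)].to_numpy(dtype=float)
    if np.any(num <= 0) or np.any(den <= 0):
        raise DataError("intensities must be strictly positive")

    mean_num = num.mean(axis=1)
    mean_den = den.mean(axis=1)
    ratio = mean_num / mean_den
    fc = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(mean_num > mean_den, UP,
                         np.where(mean_num < mean_den, DOWN, None))
    p = welch_ttest_log2(num, den, equal_var=equal_var)
    q = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame({
        "transcript_id": study.matrix.index,
        "fc_magnitude": fc,
        "direction": direction,
        "p_value": p,
        "q_bh": q,
        "mean_numerator": mean_num,
        "mean_denominator": mean_den,
    })
    return out.sort_values("transcript_id", kind="stable", ignore_index=True)


def filter_de(results: pd.DataFrame, study: ExpressionStudy,
              thresholds: DEThresholds | None = None,
              biotype: str | None = None) -> dict[str, str]:
    """Apply the four-part expression filter; return retained id -> direction.

    ``results`` is a contrast-result table from :func:`contrast_statistics`
    computed on ``study``. The raw-intensity criterion uses the larger of
    the two linear-scale group means; the length criterion uses the study's
    annotation. ``biotype`` optionally restricts the filter to one biotype
    universe (lncRNA or mRNA).
    """
    if thresholds is None:
        thresholds = DEThresholds()
    if len(results) == 0:
        return {}
    missing = set(results["transcript_id"]) - set(study.annotation.index)
    if missing:
        raise DataError(f"transcript {sorted(missing)[0]!r} missing annotation")
    ann = study.annotation.loc[results["transcript_id"]]

    fc = results["fc_magnitude"].to_numpy(dtype=float)
    fc_ok = fc > thresholds.min_fc if thresholds.strict_fc else fc >= thresholds.min_fc
    p_ok = results["p_value"].to_numpy(dtype=float) < thresholds.max_p
    raw = np.maximum(results["mean_numerator"].to_numpy(dtype=float),
                     results["mean_denominator"].to_numpy(dtype=float))
    raw_ok = raw > thresholds.min_raw_intensity
    len_ok = ann["length_nt"].to_numpy() < thresholds.max_length_nt
    keep = fc_ok & p_ok & raw_ok & len_ok
    directed = results["direction"].notna().to_numpy()
    keep &= directed
    if biotype is not None:
        keep &= (ann["biotype"] == biotype).to_numpy()

    retained = results.loc[keep]
    return dict(zip(retained["transcript_id"], retained["direction"]))
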