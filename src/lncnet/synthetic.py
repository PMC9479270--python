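"""Synthetic three-group expression studies with planted ground truth.

The generator emulates a one-color microarray experiment with three groups
(healthy control, disease model, treated disease) and a small number of
replicates per group, the design used for treatment-reversal screens. It
plants three kinds of structure and records them in a :class:`PlantedTruth`
so that every downstream stage (differential expression, reversal
intersection, co-expression network, sub-network extraction) can be tested
for exact or statistical recovery:

* **Reversal lncRNAs** ("key" lncRNAs): the disease group mean is shifted by
  a factor drawn from ``planted_fc_range`` and the treated group mean is
  shifted past baseline in the opposite direction, so the regulation
  direction flips between the disease-vs-control and treated-vs-disease
  contrasts.
* **Coupled target mRNAs**: each key lncRNA shares one latent per-sample
  profile with ``targets_per_lncrna`` mRNAs (plus independent noise of sd
  ``coupling_sd``), so each pair's Pearson correlation across all samples is
  close to +/-1. Because the shared profile carries the reversal pattern,
  every coupled target is itself a reversal mRNA.
* **Standalone reversal mRNAs**: ``n_reversal_mrna`` additional mRNAs carry
  their own reversal pattern but no coupling, contributing to the reversal
  intersection without adding network edges.

Intensities are generated on the log2 scale (Normal baseline + planted
effects + noise) and exponentiated, the standard log-normal microarray
intensity model; fold changes are therefore multiplicative. The latent
per-sample variation of a planted profile is centered within each group so
that the planted fold change equals the realized group-mean ratio exactly;
see docs/methods.md for the rationale. Unplanted transcripts are independent
draws from one global null distribution, keeping the null of the correlation
test clean.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lncnet.exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

LNCRNA = "lncRNA"
MRNA = "mRNA"
UP = "Up"
DOWN = "Down"

_CHROMOSOMES = [f"chr{i}" for i in range(1, 21)] + ["chrX"]
_RELATIONSHIPS = [
    "Intergenic",
    "Intronic antisense",
    "Exon sense-overlapping",
    "Intron sense-overlapping",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated three-group expression study.

    Defaults emulate a rat lncRNA/mRNA array of ~10^4 lncRNA and ~2x10^4
    mRNA probes hybridized for 3 groups x 4 replicates (12 arrays), with
    9 planted key lncRNAs at fold change 4, 15 coupled target mRNAs each,
    and 25 additional standalone reversal mRNAs.
    """

    n_lncrna: int = 10_000
    n_mrna: int = 20_000
    n_replicates: int = 4
    groups: tuple[str, str, str] = ("Control", "CIA", "BZXD")
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.0
    noise_log2_sd: float = 0.1
    n_reversal_lncrna: int = 9
    n_reversal_mrna: int = 25
    planted_fc_range: tuple[float, float] = (4.0, 4.0)
    targets_per_lncrna: int = 15
    coupling_sd: float = 0.05
    latent_sd: float = 0.6
    low_intensity_fraction: float = 0.05
    low_intensity_log2_mean: float = 6.0
    negative_coupling_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lncrna", "n_mrna", "n_replicates", "n_reversal_lncrna",
                     "n_reversal_mrna", "targets_per_lncrna"):
            if int(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2 for group statistics")
        if len(self.groups) != 3 or len(set(self.groups)) != 3:
            raise ConfigurationError("groups must be three distinct labels "
                                     "(control, disease, treated)")
        for name in ("baseline_log2_sd", "noise_log2_sd", "coupling_sd",
                     "latent_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.planted_fc_range
        if lo < 1.0:
            raise ConfigurationError(
                f"planted_fc_range lower bound must be >= 1, got {lo}")
        if hi < lo:
            raise ConfigurationError("planted_fc_range must be (low, high) with low <= high")
        if not 0.0 <= self.low_intensity_fraction < 1.0:
            raise ConfigurationError("low_intensity_fraction must be in [0, 1)")
        if not 0.0 <= self.negative_coupling_fraction <= 1.0:
            raise ConfigurationError("negative_coupling_fraction must be in [0, 1]")
        if self.n_reversal_lncrna > self.n_lncrna:
            raise ConfigurationError("n_reversal_lncrna cannot exceed n_lncrna")
        needed = self.n_reversal_lncrna * self.targets_per_lncrna + self.n_reversal_mrna
        if needed > self.n_mrna:
            raise ConfigurationError(
                f"n_mrna={self.n_mrna} too small for "
                f"{self.n_reversal_lncrna} x {self.targets_per_lncrna} coupled targets "
                f"plus {self.n_reversal_mrna} standalone reversal mRNAs")

    @property
    def control_group(self) -> str:
        return self.groups[0]

    @property
    def disease_group(self) -> str:
        return self.groups[1]

    @property
    def treated_group(self) -> str:
        return self.groups[2]


@dataclass
class ExpressionStudy:
    """A transcript-by-sample expression matrix with sample and transcript metadata.

    ``matrix`` holds strictly positive linear-scale intensities indexed by
    transcript id, columns ordered as in ``samples``. ``samples`` has columns
    ``sample_id, group, replicate``; ``annotation`` is indexed by transcript
    id with columns ``biotype, chromosome, strand, length_nt, relationship``.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataError(f"duplicate sample_id {dup!r}")
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise DataError(f"duplicate transcript_id {dup!r}")
        if list(self.matrix.columns) != list(self.samples["sample_id"]):
            raise DataError("matrix columns must match sample metadata order")
        missing = self.matrix.index.difference(self.annotation.index)
        if len(missing):
            raise DataError(f"transcript {missing[0]!r} missing from annotation")
        values = self.matrix.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("matrix contains non-numeric values")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise DataError("intensities must be strictly positive and finite")
        unknown = set(self.samples["group"]) - set(self.group_order)
        if unknown:
            raise DataError(f"unknown group {sorted(unknown)[0]!r}")
        counts = self.samples["group"].value_counts()
        for g in self.group_order:
            if counts.get(g, 0) < 2:
                raise DataError(f"group {g!r} has fewer than 2 replicates")
        if (self.annotation.loc[self.matrix.index, "length_nt"] <= 0).any():
            raise DataError("annotation length_nt must be positive")

    def samples_of(self, group: str) -> list[str]:
        if group not in self.group_order:
            raise DataError(f"unknown group {group!r}")
        mask = self.samples["group"] == group
        return list(self.samples.loc[mask, "sample_id"])

    def transcripts_of(self, biotype: str) -> pd.Index:
        ann = self.annotation.loc[self.matrix.index]
        return ann.index[ann["biotype"] == biotype]

    def log2_matrix(self) -> pd.DataFrame:
        return np.log2(self.matrix)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted structure of one simulated study.

    ``de_disease`` / ``de_treated`` map each planted transcript to its
    regulation direction in the disease-vs-control and treated-vs-disease
    contrasts. ``planted_edges`` holds (lncrna_id, mrna_id, sign) for every
    coupled pair; sign is +1 for positive and -1 for negative coupling.
    """

    de_disease: dict[str, str]
    de_treated: dict[str, str]
    reversal_lncrna: frozenset[str]
    reversal_mrna: frozenset[str]
    planted_edges: frozenset[tuple[str, str, int]]


def _centered_wiggle(rng: np.random.Generator, sd: float, n_groups: int,
                     n_rep: int) -> np.ndarray:
    """Per-sample latent variation, mean-centered within each group.

    Centering keeps planted group means exact while still giving each
    planted profile sample-level individuality that decorrelates unrelated
    planted families.
    """
    z = rng.normal(0.0, sd, size=(n_groups, n_rep))
    z -= z.mean(axis=1, keepdims=True)
    return z.ravel()


def simulate_study(cfg: SimulationConfig) -> tuple[ExpressionStudy, PlantedTruth]:
    """Simulate one three-group expression study with planted structure.

    Returns the study and the planted ground truth. Identical ``cfg``
    (including ``seed``) reproduces the identical study bit-for-bit.
    """
    rng = np.random.default_rng(cfg.seed)
    n_rep, n_groups = cfg.n_replicates, 3
    n_samples = n_groups * n_rep
    group_of_sample = np.repeat(np.arange(n_groups), n_rep)

    lnc_ids = np.array([f"LNC{i:06d}" for i in range(cfg.n_lncrna)])
    mrna_ids = np.array([f"MRNA{i:06d}" for i in range(cfg.n_mrna)])
    transcript_ids = np.concatenate([lnc_ids, mrna_ids])
    n_total = len(transcript_ids)

    baselines = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n_total)
    # planted transcripts must be detectable: keep their baselines clear of
    # the raw-intensity floor (2^9 = 512 > the default 200 filter), so that
    # at least one group of each contrast stays above it
    min_planted_baseline = 9.0

    # planted transcript indices (lncRNA indices, mRNA indices into mrna_ids)
    key_lnc_idx = rng.choice(cfg.n_lncrna, size=cfg.n_reversal_lncrna, replace=False) \
        if cfg.n_reversal_lncrna else np.array([], dtype=int)
    n_targets = cfg.n_reversal_lncrna * cfg.targets_per_lncrna
    planted_mrna_idx = rng.choice(cfg.n_mrna, size=n_targets + cfg.n_reversal_mrna,
                                  replace=False) if (n_targets + cfg.n_reversal_mrna) \
        else np.array([], dtype=int)
    target_idx = planted_mrna_idx[:n_targets].reshape(cfg.n_reversal_lncrna,
                                                      cfg.targets_per_lncrna)
    standalone_idx = planted_mrna_idx[n_targets:]
    planted_row_idx = np.concatenate([key_lnc_idx,
                                      cfg.n_lncrna + planted_mrna_idx]).astype(int)
    if len(planted_row_idx):
        baselines[planted_row_idx] = np.maximum(baselines[planted_row_idx],
                                                min_planted_baseline)

    log2 = baselines[:, None] + rng.normal(0.0, cfg.noise_log2_sd,
                                           size=(n_total, n_samples))

    # a fraction of UNPLANTED transcripts sit near the detection floor, to
    # exercise the raw-intensity expression filter
    planted_rows = set(key_lnc_idx.tolist())
    planted_rows.update((cfg.n_lncrna + i) for i in planted_mrna_idx.tolist())
    if cfg.low_intensity_fraction > 0:
        n_low = int(round(cfg.low_intensity_fraction * n_total))
        candidates = np.setdiff1d(np.arange(n_total), np.fromiter(planted_rows, dtype=int))
        low_rows = rng.choice(candidates, size=min(n_low, len(candidates)), replace=False)
        low_base = rng.normal(cfg.low_intensity_log2_mean, cfg.baseline_log2_sd,
                              len(low_rows))
        log2[low_rows] = low_base[:, None] + rng.normal(
            0.0, cfg.noise_log2_sd, size=(len(low_rows), n_samples))

    de_disease: dict[str, str] = {}
    de_treated: dict[str, str] = {}
    edges: set[tuple[str, str, int]] = set()
    reversal_mrna: set[str] = set()

    def pattern(sign: int) -> np.ndarray:
        d1 = np.log2(rng.uniform(*cfg.planted_fc_range))
        d2 = np.log2(rng.uniform(*cfg.planted_fc_range))
        return np.array([0.0, sign * d1, -sign * d2])

    def record(tid: str, sign: int) -> None:
        de_disease[tid] = UP if sign > 0 else DOWN
        de_treated[tid] = DOWN if sign > 0 else UP

    # key lncRNA families: shared latent profile = reversal pattern + wiggle
    for fam in range(cfg.n_reversal_lncrna):
        sign = int(rng.choice([-1, 1]))
        lam = pattern(sign)[group_of_sample] + _centered_wiggle(
            rng, cfg.latent_sd, n_groups, n_rep)
        row = int(key_lnc_idx[fam])
        log2[row] = baselines[row] + lam + rng.normal(0.0, cfg.coupling_sd, n_samples)
        lnc_id = lnc_ids[row]
        record(lnc_id, sign)
        for j in target_idx[fam]:
            csign = -1 if rng.uniform() < cfg.negative_coupling_fraction else 1
            mrow = cfg.n_lncrna + int(j)
            log2[mrow] = baselines[mrow] + csign * lam + rng.normal(
                0.0, cfg.coupling_sd, n_samples)
            mid = mrna_ids[int(j)]
            edges.add((lnc_id, mid, csign))
            reversal_mrna.add(mid)
            record(mid, sign * csign)

    # standalone reversal mRNAs: own pattern, no coupling
    for j in standalone_idx:
        sign = int(rng.choice([-1, 1]))
        lam = pattern(sign)[group_of_sample] + _centered_wiggle(
            rng, cfg.latent_sd, n_groups, n_rep)
        mrow = cfg.n_lncrna + int(j)
        log2[mrow] = baselines[mrow] + lam + rng.normal(0.0, cfg.noise_log2_sd,
                                                        n_samples)
        mid = mrna_ids[int(j)]
        reversal_mrna.add(mid)
        record(mid, sign)

    sample_ids = [f"{cfg.groups[g]}_{r + 1}" for g in range(n_groups) for r in range(n_rep)]
    matrix = pd.DataFrame(np.exp2(log2), index=pd.Index(transcript_ids, name="transcript_id"),
                          columns=sample_ids)
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "group": [cfg.groups[g] for g in group_of_sample],
        "replicate": [r + 1 for _ in range(n_groups) for r in range(n_rep)],
    })

    lengths = rng.integers(200, 4800, n_total)
    planted_arr = np.fromiter(planted_rows, dtype=int) if planted_rows else np.array([], dtype=int)
    if len(planted_arr):
        # planted transcripts stay below the 3 kb length filter
        lengths[planted_arr] = rng.integers(400, 2800, len(planted_arr))
    annotation = pd.DataFrame({
        "biotype": [LNCRNA] * cfg.n_lncrna + [MRNA] * cfg.n_mrna,
        "chromosome": rng.choice(_CHROMOSOMES, n_total),
        "strand": rng.choice(["+", "-"], n_total),
        "length_nt": lengths,
        "relationship": rng.choice(_RELATIONSHIPS, n_total),
    }, index=pd.Index(transcript_ids, name="transcript_id"))

    study = ExpressionStudy(matrix=matrix, samples=samples, annotation=annotation,
                            group_order=tuple(cfg.groups))
    truth = PlantedTruth(
        de_disease=de_disease,
        de_treated=de_treated,
        reversal_lncrna=frozenset(lnc_ids[key_lnc_idx]),
        reversal_mrna=frozenset(reversal_mrna),
        planted_edges=frozenset(edges),
    )
    logger.info("simulated study: %d transcripts x %d samples, %d planted edges",
                n_total, n_samples, len(edges))
    return study, truth


def write_study(study: ExpressionStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study as three TSVs (matrix, samples, annotation) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
    }
    study.matrix.to_csv(paths["matrix"], sep="\t", float_format="%.10g")
    study.samples.to_csv(paths["samples"], sep="\t", index=False)
    study.annotation.to_csv(paths["annotation"], sep="\t")
    return paths


def write_truth(truth: PlantedTruth, path: str | Path) -> Path:
    """Write planted truth as a TSV of (role, id, partner_id, sign)."""
    rows = []
    for tid in sorted(truth.reversal_lncrna):
        rows.append(("reversal_lncrna", tid, "", ""))
    for tid in sorted(truth.reversal_mrna):
        rows.append(("reversal_mrna", tid, "", ""))
    for tid, d in sorted(truth.de_disease.items()):
        rows.append(("de_disease", tid, "", d))
    for tid, d in sorted(truth.de_treated.items()):
        rows.append(("de_treated", tid, "", d))
    for lnc, m, s in sorted(truth.planted_edges):
        rows.append(("edge", lnc, m, f"{s:+d}"))
    df = pd.DataFrame(rows, columns=["role", "id", "partner_id", "sign"])
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (e.g. parsed YAML)."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation field {sorted(unknown)[0]!r}")
    d = dict(d)
    for key in ("groups", "planted_fc_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
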