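"""End-to-end orchestration: simulate/load -> DE -> reversal -> network ->
sub-network -> enrichment, from one config, with a machine-readable summary.

One seed in the config governs every stochastic stage, so an identical
config reproduces identical outputs byte for byte. Each stage writes its
TSV/SIF outputs under the output directory and the run ends with a
``summary.json`` of the headline counts (DE per contrast, reversal sizes
per pattern, network node/edge counts, core-mRNA count).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from lncnet import io
from lncnet.diffexp import Contrast, DEThresholds, contrast_statistics, filter_de
from lncnet.enrichment import hypergeom_enrich
from lncnet.exceptions import ConfigurationError, LncnetError
from lncnet.network import NetworkThresholds, build_network, select_key_lncrnas
from lncnet.reversal import reversal_counts, reversal_sets
from lncnet.subnetwork import core_mrnas, induced_subnetwork
from lncnet.synthetic import (LNCRNA, MRNA, SimulationConfig, config_from_dict,
                              simulate_study, write_study, write_truth)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one input source must be set: ``simulation`` (a
    :class:`SimulationConfig`) or the three study TSV paths. The two
    contrasts are derived from the ordered group labels (disease vs
    control, treated vs disease) and therefore always share the middle
    group.
    """

    out_dir: Path
    simulation: SimulationConfig | None = None
    matrix_path: Path | None = None
    metadata_path: Path | None = None
    annotation_path: Path | None = None
    de_thresholds: DEThresholds = field(default_factory=DEThresholds)
    network_thresholds: NetworkThresholds = field(default_factory=NetworkThresholds)
    k_key_lncrnas: int = 9
    key_lncrna_ids: tuple[str, ...] | None = None
    gmt_path: Path | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        file_input = all(p is not None for p in
                         (self.matrix_path, self.metadata_path, self.annotation_path))
        some_file = any(p is not None for p in
                        (self.matrix_path, self.metadata_path, self.annotation_path))
        if self.simulation is not None and some_file:
            raise ConfigurationError("give either a simulation block or study "
                                     "paths, not both")
        if self.simulation is None and not file_input:
            raise ConfigurationError("config needs a simulation block or all "
                                     "three study paths")
        if self.k_key_lncrnas < 0:
            raise ConfigurationError("k_key_lncrnas must be >= 0")
        if self.seed is not None and self.simulation is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("pipeline config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config field {sorted(unknown)[0]!r}")
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = config_from_dict(kwargs["simulation"])
        if "de_thresholds" in kwargs:
            kwargs["de_thresholds"] = DEThresholds(**kwargs["de_thresholds"])
        if "network_thresholds" in kwargs:
            kwargs["network_thresholds"] = NetworkThresholds(**kwargs["network_thresholds"])
        if "key_lncrna_ids" in kwargs and kwargs["key_lncrna_ids"] is not None:
            kwargs["key_lncrna_ids"] = tuple(kwargs["key_lncrna_ids"])
        if "out_dir" not in kwargs:
            raise ConfigurationError("config must set out_dir")
        return cls(**kwargs)


@dataclass(frozen=True)
class RunReport:
    """File manifest plus the summary counts of one pipeline run."""

    manifest: dict[str, str]
    summary: dict


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except LncnetError:
        logger.exception("stage %s failed", name)
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the stage, then re-raise
        logger.exception("stage %s failed", name)
        raise LncnetError(f"stage {name} failed: {exc}") from exc
    logger.info("stage %s: done", name)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in order and return the manifest and summary."""
    logging.getLogger("lncnet").setLevel(cfg.log_level.upper())
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    with _stage("input"):
        if cfg.simulation is not None:
            study, truth = simulate_study(cfg.simulation)
            for name, path in write_study(study, out / "study").items():
                manifest[f"study_{name}"] = str(path)
            manifest["planted_truth"] = str(write_truth(truth, out / "study" / "truth.tsv"))
        else:
            study = io.read_expression_study(cfg.matrix_path, cfg.metadata_path,
                                             cfg.annotation_path)
            truth = None
    control, disease, treated = study.group_order
    contrast_disease = Contrast(f"{disease} vs {control}", disease, control)
    contrast_treated = Contrast(f"{treated} vs {disease}", treated, disease)

    with _stage("differential_expression"):
        results = {}
        retained = {}
        for tag, contrast in (("disease", contrast_disease), ("treated", contrast_treated)):
            res = contrast_statistics(study, contrast)
            kept = filter_de(res, study, cfg.de_thresholds)
            res = res.assign(retained=res["transcript_id"].isin(kept))
            path = out / f"de_{tag}.tsv"
            res.to_csv(path, sep="\t", index=False, float_format="%.6g")
            manifest[f"de_{tag}"] = str(path)
            results[tag], retained[tag] = res, kept

    with _stage("reversal"):
        rev = reversal_sets(retained["disease"], retained["treated"],
                            results["disease"], results["treated"])
        rev_path = out / "reversal.tsv"
        records = rev.records.copy()
        if not records.empty:
            records["biotype"] = study.annotation.loc[
                records["transcript_id"], "biotype"].to_numpy()
        records.to_csv(rev_path, sep="\t", index=False, float_format="%.6g")
        manifest["reversal"] = str(rev_path)
        counts_lnc = reversal_counts(rev, study.annotation, LNCRNA)
        counts_mrna = reversal_counts(rev, study.annotation, MRNA)

    with _stage("key_lncrna_selection"):
        if cfg.key_lncrna_ids is not None:
            key_lncrnas = list(cfg.key_lncrna_ids)
        else:
            lnc_ids = sorted(t for t in rev.members()
                             if study.annotation.loc[t, "biotype"] == LNCRNA)
            fc_treated = results["treated"].set_index("transcript_id")["fc_magnitude"]
            k = cfg.k_key_lncrnas
            if k > len(lnc_ids):
                logger.warning("k=%d exceeds %d reversal lncRNAs; using all",
                               k, len(lnc_ids))
                k = len(lnc_ids)
            key_lncrnas = select_key_lncrnas(
                [(t, float(fc_treated.loc[t])) for t in lnc_ids], k)

    with _stage("network"):
        mrna_universe = sorted(
            t for t in (set(retained["disease"]) | set(retained["treated"]))
            if study.annotation.loc[t, "biotype"] == MRNA)
        network = build_network(study, key_lncrnas, mrna_universe,
                                cfg.network_thresholds)
        manifest["edges"] = str(io.write_edge_list(network, out / "edges.tsv", "TSV"))
        manifest["edges_sif"] = str(io.write_edge_list(network, out / "edges.sif", "SIF"))

    with _stage("subnetwork"):
        reversal_mrnas = {t for t in rev.members()
                          if study.annotation.loc[t, "biotype"] == MRNA}
        core = core_mrnas(reversal_mrnas, network)
        sub = induced_subnetwork(network, core)
        manifest["sub_edges"] = str(io.write_edge_list(sub, out / "sub_edges.tsv", "TSV"))
        manifest["sub_edges_sif"] = str(io.write_edge_list(sub, out / "sub_edges.sif", "SIF"))

    if cfg.gmt_path is not None:
        with _stage("enrichment"):
            gene_sets = io.read_gmt(cfg.gmt_path)
            universe = set(study.transcripts_of(MRNA))
            if core:
                enr = hypergeom_enrich(core, gene_sets, universe)
                enr_df = pd.DataFrame([dataclasses.asdict(e) for e in enr])
                if not enr_df.empty:
                    enr_df["overlap_ids"] = enr_df["overlap_ids"].map(
                        lambda s: ",".join(sorted(s)))
                path = out / "enrichment.tsv"
                enr_df.to_csv(path, sep="\t", index=False, float_format="%.6g")
                manifest["enrichment"] = str(path)
            else:
                logger.warning("no core mRNAs; skipping enrichment")

    summary = {
        "groups": list(study.group_order),
        "n_transcripts": int(study.matrix.shape[0]),
        "n_samples": int(study.matrix.shape[1]),
        "contrasts": {"disease": contrast_disease.name,
                      "treated": contrast_treated.name},
        "de": {tag: {"total": len(retained[tag]),
                     LNCRNA: sum(study.annotation.loc[t, "biotype"] == LNCRNA
                                 for t in retained[tag]),
                     MRNA: sum(study.annotation.loc[t, "biotype"] == MRNA
                               for t in retained[tag])}
               for tag in ("disease", "treated")},
        "reversal": {LNCRNA: counts_lnc, MRNA: counts_mrna,
                     "total": rev.total},
        "key_lncrnas": list(key_lncrnas),
        "network": {"n_lncrna": len(network.lncrna_nodes),
                    "n_mrna": len(network.mrna_nodes),
                    "n_edges": network.n_edges},
        "core_mrnas": len(core),
        "subnetwork": {"n_lncrna": len(sub.lncrna_nodes),
                       "n_mrna": len(sub.mrna_nodes),
                       "n_edges": sub.n_edges},
    }
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["summary"] = str(summary_path)
    return RunReport(manifest=manifest, summary=summary)
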