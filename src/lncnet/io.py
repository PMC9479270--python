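"""Readers and writers for the formats the pipeline touches.

TSV is used everywhere (decimal point, no thousands separators) so that
round-trips are bit-exact. The module also packages, as a checksum-guarded
fixture, the published table of 33 lncRNAs whose regulation direction was
reversed by treatment in the rat collagen-induced-arthritis (CIA) study that
this pipeline models: each record carries the p-value and fold change of
both contrasts (CIA vs Control, BZXD-treated vs CIA), the two regulation
directions, and the transcript's chromosome, strand and genomic-relationship
class. Chromosome and strand are opaque labels here; no coordinate
arithmetic is done anywhere.
"""

from __future__ import annotations

import hashlib
import logging
from io import BytesIO
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from lncnet.exceptions import DataError, FormatError, IntegrityError
from lncnet.synthetic import ExpressionStudy

logger = logging.getLogger(__name__)

_FIXTURE_NAME = "reversal_lncrnas.tsv"
_FIXTURE_SHA256 = "7eedbd666c733e001ff2b31931bc1810aaf038ae4a8077259468ca73514d1e03"

#: printed transcript ids use the Unicode minus sign; ASCII hyphen is accepted
#: as an alias when looking records up
_UNICODE_MINUS = "−"


@dataclass(frozen=True)
class ReversalLncRNARecord:
    """One published reversed lncRNA: statistics of both contrasts plus annotation."""

    transcript_id: str
    p_cia_vs_control: float
    p_bzxd_vs_cia: float
    fc_cia_vs_control: float
    fc_bzxd_vs_cia: float
    reg_cia_vs_control: str
    reg_bzxd_vs_cia: str
    chromosome: str
    strand: str
    relationship: str


def normalize_transcript_id(transcript_id: str) -> str:
    """Map ASCII hyphen to the Unicode minus used in the printed ids."""
    return transcript_id.replace("-", _UNICODE_MINUS)


def load_reversal_lncrna_table() -> list[ReversalLncRNARecord]:
    """Load the packaged 33-row reversed-lncRNA reference table.

    Values are transcribed verbatim from the published table, in its printed
    order. The file's SHA-256 checksum is verified on every load; a mismatch
    raises :class:`IntegrityError`.
    """
    raw = resources.files("lncnet.data").joinpath(_FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise IntegrityError(
            f"reversed-lncRNA fixture checksum mismatch: {digest}")
    df = pd.read_csv(BytesIO(raw), sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        records.append(ReversalLncRNARecord(
            transcript_id=row.transcript_id,
            p_cia_vs_control=float(row.p_cia_vs_control),
            p_bzxd_vs_cia=float(row.p_bzxd_vs_cia),
            fc_cia_vs_control=float(row.fc_cia_vs_control),
            fc_bzxd_vs_cia=float(row.fc_bzxd_vs_cia),
            reg_cia_vs_control=row.reg_cia_vs_control,
            reg_bzxd_vs_cia=row.reg_bzxd_vs_cia,
            chromosome=row.chromosome,
            strand=row.strand,
            relationship=row.relationship,
        ))
    return records


def lookup(records: list[ReversalLncRNARecord], transcript_id: str) -> ReversalLncRNARecord:
    """Find a record by id; ASCII '-' is accepted where the table prints a minus."""
    wanted = {transcript_id, normalize_transcript_id(transcript_id)}
    for rec in records:
        if rec.transcript_id in wanted:
            return rec
    raise KeyError(transcript_id)


def read_expression_study(matrix_path: str | Path,
                          metadata_path: str | Path,
                          annotation_path: str | Path,
                          group_order: tuple[str, ...] | None = None) -> ExpressionStudy:
    """Read a study from its three TSVs and validate all invariants.

    The matrix TSV has transcript_id as its first column and one column per
    sample; the metadata TSV has sample_id, group, replicate; the annotation
    TSV has transcript_id, biotype, chromosome, strand, length_nt,
    relationship. Samples are ordered as in the metadata. When
    ``group_order`` is omitted it is inferred from first appearance in the
    metadata and must contain exactly three groups.
    """
    samples = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group", "replicate"):
        if col not in samples.columns:
            raise FormatError(f"metadata is missing column {col!r}")
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "transcript_id"
    if not np.issubdtype(matrix.to_numpy().dtype, np.number):
        bad = matrix.columns[[not np.issubdtype(dt, np.number) for dt in matrix.dtypes]][0]
        raise FormatError(f"non-numeric cell in matrix column {bad!r}")
    missing = [c for c in matrix.columns if c not in set(samples["sample_id"])]
    if missing:
        raise FormatError(f"sample {missing[0]!r} in matrix absent from metadata")
    missing = [s for s in samples["sample_id"] if s not in set(matrix.columns)]
    if missing:
        raise FormatError(f"sample {missing[0]!r} in metadata absent from matrix")
    matrix = matrix[list(samples["sample_id"])]

    annotation = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype=str)
    annotation.index = annotation.index.astype(str)
    annotation.index.name = "transcript_id"
    for col in ("biotype", "chromosome", "strand", "length_nt", "relationship"):
        if col not in annotation.columns:
            raise FormatError(f"annotation is missing column {col!r}")
    annotation["length_nt"] = annotation["length_nt"].astype(int)
    if annotation.index.duplicated().any():
        dup = annotation.index[annotation.index.duplicated()][0]
        raise FormatError(f"duplicate transcript_id {dup!r} in annotation")

    if group_order is None:
        seen = list(dict.fromkeys(samples["group"]))
        if len(seen) > 3:
            raise DataError(f"unknown group {seen[3]!r}: three-group design expected")
        if len(seen) != 3:
            raise DataError(f"expected exactly 3 groups, found {len(seen)}")
        group_order = tuple(seen)
    return ExpressionStudy(matrix=matrix, samples=samples, annotation=annotation,
                           group_order=tuple(group_order))


def write_edge_list(network, path: str | Path, dialect: str = "TSV") -> Path:
    """Write a co-expression network's edges as TSV or SIF.

    The SIF dialect (a Cytoscape import format) emits one
    ``lncrna_id<TAB>relation<TAB>mrna_id`` line per edge, where the relation
    token is ``coexp_pos`` for positive and ``coexp_neg`` for negative
    correlation. The TSV dialect adds ``r`` and ``p_value`` columns with six
    significant digits.
    """
    dialect = dialect.upper()
    if dialect not in ("TSV", "SIF"):
        raise FormatError(f"unknown edge-list dialect {dialect!r}")
    path = Path(path)
    edges = sorted(network.edges, key=lambda e: (e.lncrna_id, e.mrna_id))
    with open(path, "w") as fh:
        if dialect == "SIF":
            for e in edges:
                rel = "coexp_pos" if e.r >= 0 else "coexp_neg"
                fh.write(f"{e.lncrna_id}\t{rel}\t{e.mrna_id}\n")
        else:
            fh.write("lncrna_id\tmrna_id\tr\tp_value\tn\n")
            for e in edges:
                fh.write(f"{e.lncrna_id}\t{e.mrna_id}\t{e.r:.6g}\t{e.p_value:.6g}\t{e.n}\n")
    return path


def read_edge_list(path: str | Path):
    """Read a TSV edge list written by :func:`write_edge_list` back into a network."""
    from lncnet.network import (CoexpressionEdge, CoexpressionNetwork,
                                NetworkThresholds)

    df = pd.read_csv(path, sep="\t")
    for col in ("lncrna_id", "mrna_id", "r", "p_value", "n"):
        if col not in df.columns:
            raise FormatError(f"edge list is missing column {col!r}")
    edges = tuple(
        CoexpressionEdge(str(row.lncrna_id), str(row.mrna_id), float(row.r),
                         float(row.p_value), int(row.n))
        for row in df.itertuples(index=False))
    abs_r = min((abs(e.r) for e in edges), default=0.98)
    return CoexpressionNetwork(
        lncrna_nodes=frozenset(e.lncrna_id for e in edges),
        mrna_nodes=frozenset(e.mrna_id for e in edges),
        edges=edges,
        thresholds=NetworkThresholds(min_abs_r=min(abs_r, 0.98), max_p=0.05),
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, then member ids.

    Duplicate members within a line are deduplicated. Lines with fewer than
    three fields raise :class:`FormatError` with the line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            members = {m for m in fields[2:] if m}
            if name in sets:
                logger.warning("duplicate gene set %r; keeping the last occurrence", name)
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
    return path
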