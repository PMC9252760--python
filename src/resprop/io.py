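"""Readers and writers: FASTA, annotation tables, prediction exports, config.

All writers are atomic (write to a temporary file in the target directory,
then rename), so a failed run never leaves a partial output file behind.
Positions are 1-based in user-facing tables; everything internal is 0-based.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    MAX_SEQUENCES,
    MAX_SEQ_LEN,
    MAX_TOTAL_RESIDUES,
    MIN_SEQ_LEN,
    ModelConfig,
    ProteinRecord,
    Q8_CLASSES,
    Q8_INDEX,
    Q3_CLASSES,
    ResidueAnnotations,
    ValidationError,
    validate_record,
)
from .network import PredictionBundle

PREDICTION_COLUMNS = [
    "id", "pos", "aa", "rsa", "asa",
    "q3", "p_helix", "p_strand", "p_coil",
    "q8", "p_H", "p_G", "p_I", "p_E", "p_B", "p_T", "p_S", "p_C",
    "disorder", "phi", "psi",
]

ANNOTATION_COLUMNS = ["id", "pos", "aa", "q8", "disorder", "rsa", "phi", "psi", "valid"]


def _atomic_write(path, write_fn) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            write_fn(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_fasta(
    path,
    min_len: int = MIN_SEQ_LEN,
    max_len: int = MAX_SEQ_LEN,
    max_sequences: int = MAX_SEQUENCES,
    max_total_residues: int = MAX_TOTAL_RESIDUES,
) -> list[ProteinRecord]:
    """Read and validate protein records from a FASTA file.

    Ids are the first whitespace-delimited header token; multi-line
    sequences are joined.  Duplicate ids, per-sequence length or alphabet
    violations, and job-size budgets all reject the whole file.
    """
    records = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    duplicates = sorted(k for k, v in seen.items() if v > 1)
    if duplicates:
        raise ValidationError(f"duplicate sequence ids in {path}: {duplicates}")
    if len(records) > max_sequences:
        raise ValidationError(
            f"job has {len(records)} sequences, exceeding the "
            f"limit of {max_sequences}"
        )
    total = sum(len(r) for r in records)
    if total > max_total_residues:
        raise ValidationError(
            f"job has {total} residues in total, exceeding the "
            f"budget of {max_total_residues}"
        )
    return [validate_record(r, min_len, max_len) for r in records]


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]

    def write(fh):
        SeqIO.write(seq_records, fh, "fasta")

    _atomic_write(path, write)


def write_annotations(dataset, path) -> None:
    """Write per-residue reference annotations as a CSV table.

    ``dataset`` is a sequence of (ProteinRecord, ResidueAnnotations).
    Float columns keep full precision so the table round-trips exactly.
    """
    rows = []
    for record, ann in dataset:
        if len(record) != len(ann):
            raise ValidationError(
                f"record {record.id!r}: sequence length {len(record)} "
                f"!= annotation length {len(ann)}"
            )
        for i in range(len(ann)):
            rows.append((
                record.id, i + 1, record.sequence[i], Q8_CLASSES[ann.q8[i]],
                int(ann.disorder[i]), repr(float(ann.rsa[i])),
                repr(float(ann.phi[i])), repr(float(ann.psi[i])),
                int(ann.valid_regression[i]),
            ))
    frame = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    _atomic_write(path, lambda fh: frame.to_csv(fh, index=False))


def read_annotations(path, records: Sequence[ProteinRecord] | None = None):
    """Read an annotation table back to (ProteinRecord, ResidueAnnotations)
    pairs, in file order.  When ``records`` is given, ids and sequences are
    checked for consistency and the returned pairs use those records.
    """
    frame = pd.read_csv(path, dtype={"id": str, "aa": str, "q8": str},
                        float_precision="round_trip")
    by_id = {r.id: r for r in records} if records is not None else None
    pairs = []
    for seq_id, grp in frame.groupby("id", sort=False):
        grp = grp.sort_values("pos")
        if not np.array_equal(grp["pos"].to_numpy(), np.arange(1, len(grp) + 1)):
            raise ValidationError(f"annotation positions for {seq_id!r} are not 1..L")
        sequence = "".join(grp["aa"])
        try:
            q8 = np.array([Q8_INDEX[c] for c in grp["q8"]])
        except KeyError as exc:
            raise ValidationError(
                f"unknown Q8 class {exc.args[0]!r} for {seq_id!r}"
            ) from None
        ann = ResidueAnnotations(
            q8=q8,
            disorder=grp["disorder"].to_numpy().astype(bool),
            rsa=grp["rsa"].to_numpy(dtype=np.float64),
            phi=grp["phi"].to_numpy(dtype=np.float64),
            psi=grp["psi"].to_numpy(dtype=np.float64),
            valid_regression=grp["valid"].to_numpy().astype(bool),
        )
        if by_id is not None:
            if seq_id not in by_id:
                raise ValidationError(f"annotations for unknown sequence {seq_id!r}")
            if by_id[seq_id].sequence != sequence:
                raise ValidationError(
                    f"annotation residues disagree with sequence {seq_id!r}"
                )
            record = by_id[seq_id]
        else:
            record = ProteinRecord(id=str(seq_id), sequence=sequence)
        pairs.append((record, ann))
    return pairs


def _prediction_rows(bundles, records):
    if len(bundles) != len(records):
        raise ValidationError("one prediction bundle per record is required")
    for record, bundle in zip(records, bundles):
        if len(bundle) != len(record):
            raise ValidationError(
                f"record {record.id!r}: bundle length {len(bundle)} "
                f"!= sequence length {len(record)}"
            )
        for i in range(len(record)):
            q3_idx = int(bundle.q3_probs[i].argmax())
            q8_idx = int(bundle.q8_probs[i].argmax())
            yield {
                "id": record.id,
                "pos": i + 1,
                "aa": record.sequence[i],
                "rsa": round(float(bundle.rsa[i]), 4),
                "asa": round(float(bundle.asa[i]), 4),
                "q3": Q3_CLASSES[q3_idx],
                "p_helix": round(float(bundle.q3_probs[i, 0]), 4),
                "p_strand": round(float(bundle.q3_probs[i, 1]), 4),
                "p_coil": round(float(bundle.q3_probs[i, 2]), 4),
                "q8": Q8_CLASSES[q8_idx],
                **{f"p_{c}": round(float(bundle.q8_probs[i, j]), 4)
                   for j, c in enumerate(Q8_CLASSES)},
                "disorder": round(float(bundle.disorder_probs[i, 1]), 4),
                "phi": round(float(bundle.phi_deg[i]), 4),
                "psi": round(float(bundle.psi_deg[i]), 4),
            }


def write_predictions(
    bundles: Sequence[PredictionBundle],
    records: Sequence[ProteinRecord],
    path,
    format: str = "csv",
) -> None:
    """Export per-residue predictions as CSV or JSON (4-decimal precision)."""
    rows = list(_prediction_rows(bundles, records))
    if format == "csv":
        frame = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
        _atomic_write(path, lambda fh: frame.to_csv(fh, index=False, float_format="%.4f"))
    elif format == "json":
        _atomic_write(path, lambda fh: json.dump(rows, fh, indent=1))
    else:
        raise ValidationError(f"unknown prediction format {format!r}")


def save_config(config: ModelConfig, path) -> None:
    """Write a model configuration (including the max-ASA table) as YAML."""
    _atomic_write(path, lambda fh: yaml.safe_dump(
        {"model": config.to_dict()}, fh, sort_keys=False))


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "model" not in data:
        raise ValidationError(f"config file {path} lacks a 'model' section")
    return ModelConfig.from_dict(data["model"])
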