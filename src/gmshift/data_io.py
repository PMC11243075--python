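"""Reading and writing shift tables, model files and prediction output.

The canonical shift-table dialect is a comma-separated file with a header
row and columns ``molecule_id,smiles,shift_ppm``; ``smiles`` is an
atom-tagged SMILES carrying the carbon of interest.  Shifts are written
with one decimal digit, matching the precision at which experimental
values are customarily reported.

Ensembles serialize to a versioned JSON file holding the layout, the
scaling metadata and every member's flat parameter vector; a round trip
reproduces predictions bit for bit.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_graph import parse_tagged_smiles
from .node_model import NodeFunctionParameters, ScalingSpec
from .prediction_eval import EnsembleModel
from .training import ShiftDataset

MODEL_FORMAT_VERSION = 1


class ShiftTableError(ValueError):
    """The shift table could not be loaded; carries per-line messages."""

    def __init__(self, message: str, line_errors: list[str] | None = None):
        self.line_errors = line_errors or []
        detail = "".join(f"\n  {e}" for e in self.line_errors[:20])
        super().__init__(message + detail)


class ModelFileError(ValueError):
    """A model file is truncated, malformed, or of the wrong version."""


@dataclass(frozen=True)
class ShiftTableDialect:
    """Column layout of a delimited shift table."""

    delimiter: str = ","
    smiles_column: str = "smiles"
    shift_column: str = "shift_ppm"
    id_column: str = "molecule_id"


DEFAULT_DIALECT = ShiftTableDialect()


def read_shift_table(
    path, dialect: ShiftTableDialect = DEFAULT_DIALECT
) -> tuple[ShiftDataset, list[str]]:
    """Load and validate a shift table.

    Returns the dataset together with the list of rejected-row messages
    (empty when every row parsed).  Rows with unparsable SMILES or
    non-finite shifts are collected with their line numbers; duplicate
    (molecule, tagged atom) pairs are an error naming both lines.  A table
    in which no row survives fails outright.
    """
    try:
        frame = pd.read_csv(path, sep=dialect.delimiter)
    except Exception as exc:
        raise ShiftTableError(f"cannot read {path}: {exc}") from None
    for col in (dialect.smiles_column, dialect.shift_column):
        if col not in frame.columns:
            raise ShiftTableError(f"missing required column {col!r} in {path}")

    records = []
    errors: list[str] = []
    seen: dict[str, int] = {}
    for row_pos, row in enumerate(frame.itertuples(index=False)):
        line = row_pos + 2  # 1-based, after the header
        smiles = getattr(row, dialect.smiles_column)
        shift = getattr(row, dialect.shift_column)
        try:
            mol = parse_tagged_smiles(str(smiles))
            shift = float(shift)
            if not np.isfinite(shift):
                raise ValueError("non-finite shift")
        except Exception as exc:
            errors.append(f"line {line}: {exc}")
            continue
        key = mol.canonical_tagged_smiles()
        if key in seen:
            errors.append(
                f"line {line}: duplicate tagged carbon (first seen line {seen[key]})"
            )
            continue
        seen[key] = line
        records.append((mol, shift))
    if not records:
        raise ShiftTableError(f"no valid record in {path}", errors)
    return ShiftDataset(records=records), errors


def write_shift_table(
    dataset: ShiftDataset, path, dialect: ShiftTableDialect = DEFAULT_DIALECT
) -> None:
    """Serialize a dataset in the canonical dialect (shifts to 0.1 ppm)."""
    rows = [
        {
            dialect.id_column: i,
            dialect.smiles_column: mol.canonical_tagged_smiles(),
            dialect.shift_column: round(shift, 1),
        }
        for i, (mol, shift) in enumerate(dataset.records)
    ]
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


def write_model(ensemble: EnsembleModel, path) -> None:
    """Write an ensemble to a versioned JSON model file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "h": ensemble.h,
        "n_in": ensemble.members[0].n_in,
        "state_dim": ensemble.members[0].state_dim,
        "scaling": {
            "center": ensemble.scaling.center,
            "half_range": ensemble.scaling.half_range,
        },
        "sequences": [
            [p.theta.tolist() for p in seq] for seq in ensemble.sequences
        ],
        "metadata": ensemble.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path) -> EnsembleModel:
    """Read a model file written by :func:`write_model`."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFileError(f"cannot read model file {path}: {exc}") from None
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFileError(
            f"model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    try:
        h = payload["h"]
        n_in = payload["n_in"]
        state_dim = payload.get("state_dim", 1)
        scaling = ScalingSpec(**payload["scaling"])
        sequences = tuple(
            tuple(
                NodeFunctionParameters(
                    h=h, n_in=n_in, state_dim=state_dim,
                    theta=np.asarray(t, dtype=float),
                )
                for t in seq
            )
            for seq in payload["sequences"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFileError(f"malformed model file {path}: {exc}") from None
    return EnsembleModel(
        sequences=sequences,
        scaling=scaling,
        h=h,
        metadata=payload.get("metadata", {}),
    )


def write_training_run(models, config, path) -> None:
    """Persist every restart of a multi-restart training run as JSON."""
    from dataclasses import asdict

    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": asdict(config),
        "models": [
            {
                "theta": m.params.theta.tolist(),
                "h": m.params.h,
                "n_in": m.params.n_in,
                "state_dim": m.params.state_dim,
                "scaling": {
                    "center": m.scaling.center,
                    "half_range": m.scaling.half_range,
                },
                "rmste": m.rmste,
                "vloo_score": m.vloo_score,
                "restart_index": m.restart_index,
                "n_iterations": m.n_iterations,
                "converged": m.converged,
                "failed": m.failed,
            }
            for m in models
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_training_run(path):
    """Read a file written by :func:`write_training_run`.

    Returns ``(models, config_dict)``.
    """
    from .training import TrainedModel

    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFileError(f"cannot read training run {path}: {exc}") from None
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFileError(f"unsupported training-run version in {path}")
    models = []
    for entry in payload["models"]:
        models.append(
            TrainedModel(
                params=NodeFunctionParameters(
                    h=entry["h"],
                    n_in=entry["n_in"],
                    state_dim=entry.get("state_dim", 1),
                    theta=np.asarray(entry["theta"], dtype=float),
                ),
                scaling=ScalingSpec(**entry["scaling"]),
                rmste=entry["rmste"],
                restart_index=entry["restart_index"],
                n_iterations=entry["n_iterations"],
                converged=entry["converged"],
                failed=entry.get("failed", False),
                vloo_score=entry["vloo_score"],
            )
        )
    return models, payload["config"]


@dataclass(frozen=True)
class DatasetSummary:
    """Descriptive statistics of a shift dataset."""

    n_records: int
    n_molecules: int
    min_shift_ppm: float
    max_shift_ppm: float
    element_molecule_counts: dict[str, int]
    carbon_classes: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_molecules": self.n_molecules,
            "min_shift_ppm": self.min_shift_ppm,
            "max_shift_ppm": self.max_shift_ppm,
            "element_molecule_counts": dict(self.element_molecule_counts),
            "carbon_classes": dict(self.carbon_classes),
        }


def dataset_summary(dataset: ShiftDataset) -> DatasetSummary:
    """Shift range, per-element molecule counts, and tagged-carbon classes.

    Carbon classes distinguish ring CH from substituted ring carbons — the
    coarse split that dominates a benzenic shift distribution.
    """
    element_mols: Counter[str] = Counter()
    classes: Counter[str] = Counter()
    seen_molecules: set[str] = set()
    for mol, _ in dataset.records:
        key = ShiftDataset._molecule_key(mol)
        if key not in seen_molecules:
            seen_molecules.add(key)
            for sym in {a.symbol for a in mol.atoms}:
                element_mols[sym] += 1
        tagged = mol.atoms[mol.tagged_index]
        classes["CH" if tagged.n_hydrogens > 0 else "substituted"] += 1
    lo, hi = dataset.shift_range()
    return DatasetSummary(
        n_records=dataset.n_records,
        n_molecules=dataset.n_molecules,
        min_shift_ppm=lo,
        max_shift_ppm=hi,
        element_molecule_counts=dict(sorted(element_mols.items())),
        carbon_classes=dict(classes),
    )
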