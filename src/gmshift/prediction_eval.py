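"""Ensemble prediction of shifts and the full evaluation report.

An ensemble holds the parameter vectors of the trained models with the
smallest VLOO scores, possibly grouped into several initialization
*sequences* (independent multi-restart runs).  The predicted shift of a
carbon is the mean of the per-sequence means of the member outputs; with a
single sequence this is the plain average over the members.

Evaluation computes the statistics customarily reported for shift
prediction: RMSE, MAE, root-mean-square relative error, the determination
coefficient of the estimated-versus-measured scatter, the extreme
deviations, and the carbons whose absolute deviation exceeds a threshold
(3 ppm by default).  Deviations are experimental minus estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_graph import (
    ApplicabilityReport,
    ApplicabilityWarning,
    TaggedMolecule,
    build_rooted_dag,
    check_applicability,
    enumerate_ring_carbons,
)
from .node_model import NodeFunctionParameters, PackedGraphs, ScalingSpec

#: deviations larger than this (ppm, absolute) flag a carbon as an outlier
OUTLIER_THRESHOLD_PPM = 3.0


@dataclass(frozen=True)
class EnsembleModel:
    """Selected graph-machine models used for averaged prediction."""

    sequences: tuple[tuple[NodeFunctionParameters, ...], ...]
    scaling: ScalingSpec
    h: int
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        members = self.members
        if not members:
            raise ValueError("ensemble needs at least one member")
        for m in members:
            if m.h != self.h or m.n_in != members[0].n_in:
                raise ValueError("ensemble members are dimensionally incompatible")

    @property
    def members(self) -> tuple[NodeFunctionParameters, ...]:
        return tuple(p for seq in self.sequences for p in seq)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @classmethod
    def from_members(
        cls,
        members,
        scaling: ScalingSpec,
        metadata: dict | None = None,
    ) -> "EnsembleModel":
        members = tuple(members)
        return cls(
            sequences=(members,),
            scaling=scaling,
            h=members[0].h,
            metadata=metadata or {},
        )


def _predict_packed(packed: PackedGraphs, ensemble: EnsembleModel) -> np.ndarray:
    seq_means = [
        np.mean(
            [ensemble.scaling.descale(packed.forward(p)) for p in seq], axis=0
        )
        for seq in ensemble.sequences
    ]
    return np.mean(seq_means, axis=0)


def ensemble_predict(mol: TaggedMolecule, ensemble: EnsembleModel) -> float:
    """Mean shift estimate for the tagged carbon, in ppm.

    With several sequences the per-sequence means are averaged
    (hierarchical mean); for equal sequence sizes this equals the flat
    mean over all members.
    """
    packed = PackedGraphs.from_dags([build_rooted_dag(mol)])
    return float(_predict_packed(packed, ensemble)[0])


def ensemble_predict_dataset(dataset, ensemble: EnsembleModel) -> np.ndarray:
    """Shift estimates (ppm) for every record of a :class:`ShiftDataset`."""
    return _predict_packed(dataset.packed(), ensemble)


@dataclass(frozen=True)
class CarbonPrediction:
    """One ring carbon's predicted shift with provenance."""

    atom_index: int
    tagged_smiles: str
    shift_ppm: float
    applicability: ApplicabilityReport


def predict_molecule(
    text: str, ensemble: EnsembleModel, training_elements: set[str] | None = None
) -> list[CarbonPrediction]:
    """Predict every benzenic ring carbon of a plain SMILES.

    Chemically equivalent carbons receive identical values because the
    rooted DAGs are canonical.  Molecules without an isolated benzenic
    ring yield an empty list and an :class:`ApplicabilityWarning`.
    """
    out = []
    for mol in enumerate_ring_carbons(text):
        report = check_applicability(mol, training_elements)
        for note in report.warnings:
            warnings.warn(note, ApplicabilityWarning, stacklevel=2)
        out.append(
            CarbonPrediction(
                atom_index=mol.tagged_index,
                tagged_smiles=mol.canonical_tagged_smiles(),
                shift_ppm=ensemble_predict(mol, ensemble),
                applicability=report,
            )
        )
    return out


@dataclass(frozen=True)
class EvaluationReport:
    """Agreement statistics between estimated and experimental shifts."""

    n: int
    rmse_ppm: float
    mae_ppm: float
    rmsre_percent: float
    r_squared: float
    min_deviation_ppm: float
    max_deviation_ppm: float
    outlier_threshold_ppm: float
    outlier_indices: tuple[int, ...]

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_indices)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rmse_ppm": self.rmse_ppm,
            "mae_ppm": self.mae_ppm,
            "rmsre_percent": self.rmsre_percent,
            "r_squared": self.r_squared,
            "min_deviation_ppm": self.min_deviation_ppm,
            "max_deviation_ppm": self.max_deviation_ppm,
            "outlier_threshold_ppm": self.outlier_threshold_ppm,
            "n_outliers": self.n_outliers,
            "outlier_indices": list(self.outlier_indices),
        }

    def table(self) -> str:
        return (
            f"N                 {self.n}\n"
            f"RMSE   (ppm)      {self.rmse_ppm:.2f}\n"
            f"MAE    (ppm)      {self.mae_ppm:.2f}\n"
            f"RMSRE  (%)        {self.rmsre_percent:.2f}\n"
            f"R^2               {self.r_squared:.4f}\n"
            f"min dev (ppm)     {self.min_deviation_ppm:.2f}\n"
            f"max dev (ppm)     {self.max_deviation_ppm:.2f}\n"
            f"outliers (>|{self.outlier_threshold_ppm:g}|) {self.n_outliers}\n"
        )


def evaluate(
    predictions,
    experimentals,
    threshold: float = OUTLIER_THRESHOLD_PPM,
) -> EvaluationReport:
    """Full evaluation of shift estimates against experimental values.

    Deviation is experimental minus estimated (ppm); R^2 is the squared
    Pearson correlation of the estimated-versus-measured scatter.
    """
    est = np.asarray(predictions, dtype=float)
    exp = np.asarray(experimentals, dtype=float)
    if est.shape != exp.shape or est.ndim != 1 or est.size < 1:
        raise ValueError("predictions and experimentals must be equal-length 1-D")
    dev = exp - est
    rmse = float(np.sqrt(np.mean(dev * dev)))
    mae = float(np.mean(np.abs(dev)))
    rmsre = float(np.sqrt(np.mean((dev / exp) ** 2))) * 100.0
    if est.size == 1 or np.ptp(est) == 0 or np.ptp(exp) == 0:
        r2 = 1.0 if rmse == 0 else 0.0
    else:
        r2 = float(np.corrcoef(est, exp)[0, 1] ** 2)
    outliers = tuple(int(i) for i in np.flatnonzero(np.abs(dev) > threshold))
    return EvaluationReport(
        n=int(est.size),
        rmse_ppm=rmse,
        mae_ppm=mae,
        rmsre_percent=rmsre,
        r_squared=r2,
        min_deviation_ppm=float(dev.min()),
        max_deviation_ppm=float(dev.max()),
        outlier_threshold_ppm=float(threshold),
        outlier_indices=outliers,
    )
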