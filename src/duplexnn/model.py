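"""Nearest-neighbour free-energy models for perfect-match DNA duplexes.

The model assumes the hybridization free energy of a perfect-match duplex is
a sum of context contributions, one per overlapping window of ``order``
adjacent base pairs:

    dG(seq) = sum_j  n_j(seq) * x_j

where ``n_j`` counts occurrences of motif class ``j`` in the sequence (both
strands collapse onto one count by rotational identity) and ``x_j`` is the
class's free-energy weight in kcal/mol. With ``order=2`` this is the
classical stacked-pair model (10 parameters); ``order=3`` extends the
context to base-pair triplets (32 parameters). There are deliberately no
initiation, symmetry, salt or temperature terms: the weights absorb the
averaged experimental conditions of the training data.

Weights are estimated by ordinary least squares over a training set of
experimental free energies. When the training set does not cover every
motif class the design matrix is rank-deficient; the minimum-norm solution
is returned and uncovered classes (weight pinned at zero) are flagged.

Typical use::

    model = NearestNeighborModel.from_dataset(dataset, order=3)
    res = model.fit()
    print(res.summary())
    dg = res.predict("ACGTACGT")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import DuplexDataset, is_perfect_match
from .motifs import class_labels, count_motifs

__all__ = [
    "ParameterSet",
    "FitProblem",
    "NearestNeighborModel",
    "NNResults",
    "build_fit_problem",
    "fit_parameters",
    "estimate_free_energy",
    "load_reference_parameters",
    "write_parameters",
    "read_parameters",
]

_N_CLASSES = {2: 10, 3: 32}


@dataclass(frozen=True)
class ParameterSet:
    """Free-energy weights [kcal/mol] for every motif class of one order."""

    order: int
    values: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        expected = class_labels(self.order)
        if set(self.values) != set(expected):
            missing = set(expected) - set(self.values)
            extra = set(self.values) - set(expected)
            raise ValueError(
                f"parameter set must cover all {len(expected)} order-{self.order} classes"
                + (f"; missing {sorted(missing)}" if missing else "")
                + (f"; unexpected {sorted(extra)}" if extra else "")
            )

    def as_vector(self) -> np.ndarray:
        """Weights in canonical class-enumeration order."""
        return np.array([self.values[lbl] for lbl in class_labels(self.order)])

    def __getitem__(self, label: str) -> float:
        return self.values[label]


@dataclass(frozen=True)
class FitProblem:
    """Design matrix of motif counts and response vector of experimental dG."""

    order: int
    counts: np.ndarray          # N x K non-negative integers
    response: np.ndarray        # N experimental dG [kcal/mol]
    duplex_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n, k = self.counts.shape
        if k != _N_CLASSES[self.order]:
            raise ValueError(f"expected {_N_CLASSES[self.order]} columns, got {k}")
        if n != len(self.response) or n != len(self.duplex_ids):
            raise ValueError("counts, response and duplex_ids disagree in length")
        if n < 1:
            raise ValueError("at least one duplex is required")

    @property
    def nobs(self) -> int:
        return self.counts.shape[0]


def build_fit_problem(dataset: DuplexDataset, order: int) -> FitProblem:
    """Assemble the least-squares problem from a perfect-match dataset.

    Row i holds the motif counts of seq1 of duplex i (single-strand counting:
    the complementary strand is the same physical stack and counting it too
    would only halve every weight); the response is the experimental dG.
    """
    rows, dgs, ids = [], [], []
    for r in dataset:
        if not is_perfect_match(r):
            raise ValueError(f"duplex {r.duplex_id!r} is not a perfect match")
        rows.append(count_motifs(r.seq1, order))
        dgs.append(r.dg_exp)
        ids.append(r.duplex_id)
    return FitProblem(order, np.array(rows), np.array(dgs, dtype=float), tuple(ids))


def fit_parameters(problem: FitProblem) -> "NNResults":
    """Minimum-norm least squares solution of counts @ x ~= response."""
    return NearestNeighborModel(problem).fit()


class NearestNeighborModel:
    """Least-squares estimator of nearest-neighbour free-energy weights.

    Parameters
    ----------
    problem : FitProblem
        Motif-count design matrix and experimental response.
    """

    def __init__(self, problem: FitProblem):
        self.problem = problem
        self.order = problem.order

    @classmethod
    def from_dataset(cls, dataset: DuplexDataset, order: int = 3) -> "NearestNeighborModel":
        """Build the model from a perfect-match duplex dataset."""
        return cls(build_fit_problem(dataset, order))

    def fit(self) -> "NNResults":
        """Solve min ||F x - R||^2.

        Rank-deficient designs (motif classes absent from the training set)
        yield the minimum-norm solution; absent classes get weight exactly 0
        and are listed in ``NNResults.uncovered``.
        """
        F = self.problem.counts.astype(float)
        R = self.problem.response
        x, _, rank, sv = np.linalg.lstsq(F, R, rcond=None)
        resid = R - F @ x
        return NNResults(model=self, params_vector=x, rank=int(rank),
                         singular_values=sv, residuals=resid)


@dataclass(frozen=True)
class NNResults:
    """Fit results: weight estimates, uncertainties and diagnostics."""

    model: NearestNeighborModel
    params_vector: np.ndarray
    rank: int
    singular_values: np.ndarray
    residuals: np.ndarray

    @property
    def order(self) -> int:
        return self.model.order

    @property
    def labels(self) -> list[str]:
        return class_labels(self.order)

    @property
    def params(self) -> ParameterSet:
        return ParameterSet(
            self.order,
            dict(zip(self.labels, self.params_vector)),
            provenance=f"least-squares fit, N={self.nobs}, rank={self.rank}",
        )

    @property
    def nobs(self) -> int:
        return self.model.problem.nobs

    @property
    def df_resid(self) -> int:
        return self.nobs - self.rank

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.residuals))

    @property
    def rmse(self) -> float:
        """Root mean squared training residual [kcal/mol]."""
        return float(np.sqrt(np.mean(self.residuals**2)))

    @property
    def scale(self) -> float:
        """Residual variance estimate; 0 when the fit interpolates exactly."""
        if self.df_resid <= 0:
            return 0.0
        return float(self.residuals @ self.residuals / self.df_resid)

    @property
    def coverage(self) -> np.ndarray:
        """Per-class number of training duplexes containing the class."""
        return (self.model.problem.counts > 0).sum(axis=0)

    @property
    def uncovered(self) -> list[str]:
        """Classes absent from the training set (weight pinned at 0)."""
        return [lbl for lbl, c in zip(self.labels, self.coverage) if c == 0]

    @property
    def bse(self) -> np.ndarray:
        """OLS standard errors via the pseudo-inverse of the normal matrix.

        NaN for uncovered classes, whose weight is a convention rather than
        an estimate.
        """
        F = self.model.problem.counts.astype(float)
        cov = self.scale * np.linalg.pinv(F.T @ F)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se[self.coverage == 0] = np.nan
        return se

    def predict(self, seq: str | Iterable[str]) -> float | np.ndarray:
        """Estimated dG [kcal/mol] for one sequence or an iterable of them."""
        if isinstance(seq, str):
            return estimate_free_energy(seq, self.params)
        return np.array([estimate_free_energy(s, self.params) for s in seq])

    def summary(self) -> str:
        """Human-readable fit report, one row per motif class."""
        se = self.bse
        lines = [
            f"Nearest-neighbour model (order {self.order}, "
            f"{len(self.labels)} classes)",
            f"N duplexes: {self.nobs}   rank: {self.rank}   "
            f"train RMSE: {self.rmse:.4f} kcal/mol   "
            f"residual norm: {self.residual_norm:.4f}",
        ]
        if self.uncovered:
            lines.append(f"uncovered classes (weight fixed at 0): {', '.join(self.uncovered)}")
        lines.append("")
        lines.append(f"{'class':>10} {'dG [kcal/mol]':>14} {'std err':>10} {'n duplexes':>11}")
        for lbl, x, s, c in zip(self.labels, self.params_vector, se, self.coverage):
            s_txt = f"{s:10.4f}" if np.isfinite(s) else "       n/a"
            lines.append(f"{lbl:>10} {x:14.6f} {s_txt} {c:11d}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "dg_kcal_mol": self.params_vector,
                "std_err": self.bse,
                "n_duplexes": self.coverage,
            }
        )


def estimate_free_energy(seq: str, params: ParameterSet) -> float:
    """Model free energy of a perfect-match duplex with first strand ``seq``.

    The dot product of the sequence's motif-class counts with the parameter
    weights; no initiation, symmetry, salt or temperature correction.
    """
    counts = count_motifs(seq, params.order)
    return float(counts @ params.as_vector())


# ---------------------------------------------------------------------------
# parameter-set serialization: two-column text table (label, kcal/mol)

def write_parameters(params: ParameterSet, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("label\tdg_kcal_mol\n")
        for lbl in class_labels(params.order):
            fh.write(f"{lbl}\t{params.values[lbl]:.6f}\n")


def read_parameters(path: str | Path, provenance: str | None = None) -> ParameterSet:
    """Load a tab-separated (label, kcal/mol) table; validates completeness."""
    path = Path(path)
    values: dict[str, float] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.lower().startswith("label"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed parameter line {line!r}")
        values[parts[0]] = float(parts[1])
    orders = {len(lbl.split("/")[0]) for lbl in values}
    if len(orders) != 1:
        raise ValueError(f"{path}: mixed or missing motif orders")
    return ParameterSet(orders.pop(), values, provenance or str(path))


def load_reference_parameters(order: int = 3) -> ParameterSet:
    """Bundled reference weights (published least-squares fit to a 340-duplex
    perfect-match compilation spanning mixed temperatures and salt)."""
    name = {2: "reference_doublets.tsv", 3: "reference_triplets.tsv"}[order]
    ref = resources.files("duplexnn.data") / name
    values: dict[str, float] = {}
    for line in ref.read_text(encoding="utf-8").splitlines()[1:]:
        label, dg, _count = line.split("\t")
        values[label] = float(dg)
    return ParameterSet(order, values, provenance=f"bundled reference ({name})")
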